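"""Core data containers for the two analysis tracks.

The morphometric track works on :class:`MeasurementMatrix` — specimens by
continuous linear measurements (mm or degrees) with an explicit missingness
mask.  The cladistic track works on :class:`CharacterMatrix` — taxa by
discrete unordered characters with states 0–4 plus missing ("?") and
inapplicable ("-") cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "INAPPLICABLE",
    "MAX_STATE",
    "MeasurementMatrix",
    "CharacterMatrix",
]

#: Cell codes for :class:`CharacterMatrix`.  States are small non-negative
#: integers; the two non-state codes are negative so that ``cells >= 0``
#: selects scored cells.
MISSING = -1
INAPPLICABLE = -2

#: Largest admissible character state.
MAX_STATE = 4

# Variables whose unit is degrees must lie in the open interval (0, 360);
# everything else is a length in mm and must simply be positive.
_ANGLE_RANGE = (0.0, 360.0)


class MeasurementMatrix:
    """Specimens x continuous measurement variables with missing cells.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are specimens (index = unique specimen ids), columns are
        measurement variables.  Missing cells are NaN.
    taxon_labels : sequence of str, optional
        Per-specimen genus/species assignment.  Defaults to "" for all.
    angle_variables : set of str, optional
        Variables measured in degrees; validated against (0, 360) instead
        of simple positivity.
    """

    def __init__(self, data: pd.DataFrame, taxon_labels=None, angle_variables=None,
                 strict_positive: bool = True):
        if data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError("measurement matrix needs at least one row and one column")
        if data.index.duplicated().any():
            dupes = data.index[data.index.duplicated()].tolist()
            raise ValueError(f"duplicate specimen ids: {dupes}")
        values = data.to_numpy(dtype=float)
        self._data = pd.DataFrame(values, index=data.index.astype(str), columns=[str(c) for c in data.columns])
        self.angle_variables = frozenset(angle_variables or ())
        if taxon_labels is None:
            taxon_labels = [""] * len(data)
        if len(taxon_labels) != len(data):
            raise ValueError("taxon_labels length must match specimen count")
        self.taxon_labels = list(map(str, taxon_labels))
        self.strict_positive = strict_positive
        self._validate()

    def _validate(self):
        vals = self._data.to_numpy()
        obs = ~np.isnan(vals)
        if not np.all(np.isfinite(vals[obs])):
            raise ValueError("non-finite measurement value")
        for j, name in enumerate(self.variable_names):
            col = vals[obs[:, j], j]
            if name in self.angle_variables:
                lo, hi = _ANGLE_RANGE
                if col.size and (col.min() <= lo or col.max() >= hi):
                    raise ValueError(f"angle variable {name!r} outside (0, 360)")
            elif self.strict_positive and col.size and col.min() <= 0:
                raise ValueError(f"non-positive value in length variable {name!r}")

    # -- basic accessors -------------------------------------------------
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def values(self) -> np.ndarray:
        return self._data.to_numpy()

    @property
    def mask(self) -> np.ndarray:
        """Boolean grid, True where a cell is missing."""
        return np.isnan(self._data.to_numpy())

    @property
    def specimen_ids(self) -> list[str]:
        return list(self._data.index)

    @property
    def variable_names(self) -> list[str]:
        return list(self._data.columns)

    @property
    def n_specimens(self) -> int:
        return self._data.shape[0]

    @property
    def n_variables(self) -> int:
        return self._data.shape[1]

    def is_complete(self) -> bool:
        return not self.mask.any()

    def copy(self) -> "MeasurementMatrix":
        return MeasurementMatrix(self._data.copy(), list(self.taxon_labels),
                                 self.angle_variables, self.strict_positive)

    def subset(self, specimens=None, variables=None) -> "MeasurementMatrix":
        """Return a sub-matrix restricted to the given specimens/variables."""
        df = self._data
        labels = pd.Series(self.taxon_labels, index=df.index)
        if specimens is not None:
            specimens = [str(s) for s in specimens]
            df = df.loc[specimens]
            labels = labels.loc[specimens]
        if variables is not None:
            df = df[[str(v) for v in variables]]
        return MeasurementMatrix(df, labels.tolist(), self.angle_variables,
                                 self.strict_positive)

    def __repr__(self):
        miss = int(self.mask.sum())
        return (f"<MeasurementMatrix {self.n_specimens} specimens x "
                f"{self.n_variables} variables, {miss} missing cells>")

    def __eq__(self, other):
        if not isinstance(other, MeasurementMatrix):
            return NotImplemented
        a, b = self.values, other.values
        return (self.specimen_ids == other.specimen_ids
                and self.variable_names == other.variable_names
                and self.taxon_labels == other.taxon_labels
                and np.array_equal(np.isnan(a), np.isnan(b))
                and np.allclose(a[~np.isnan(a)], b[~np.isnan(b)], rtol=0, atol=0))


@dataclass
class CharacterMatrix:
    """Taxa x discrete unordered characters.

    ``cells`` is an int8 grid: state integers in [0, MAX_STATE], or the
    negative codes :data:`MISSING` / :data:`INAPPLICABLE`.  Downstream
    algorithms treat INAPPLICABLE identically to MISSING; the distinction
    is preserved only for provenance and round-tripping.
    """

    taxon_names: list[str]
    cells: np.ndarray
    ordered_flags: list[bool] = field(default=None)
    #: specimen-level candidate matrices may leave a specimen unscored for
    #: every retained character; taxon-level cladistic matrices may not
    allow_unscored_taxa: bool = False

    def __post_init__(self):
        self.taxon_names = [str(t) for t in self.taxon_names]
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.ndim != 2:
            raise ValueError("cells must be 2-D")
        if len(self.taxon_names) != self.cells.shape[0]:
            raise ValueError("taxon count does not match cell rows")
        if len(set(self.taxon_names)) != len(self.taxon_names):
            raise ValueError("duplicate taxon names")
        if self.ordered_flags is None:
            self.ordered_flags = [False] * self.cells.shape[1]
        if len(self.ordered_flags) != self.cells.shape[1]:
            raise ValueError("ordered_flags length mismatch")
        bad = (self.cells > MAX_STATE) | (self.cells < INAPPLICABLE)
        if bad.any():
            raise ValueError("cell states must be in [0, 4], MISSING or INAPPLICABLE")
        unscored = self.cells < 0
        if (not self.allow_unscored_taxa and self.cells.shape[1]
                and unscored.all(axis=1).any()):
            rows = [self.taxon_names[i] for i in np.where(unscored.all(axis=1))[0]]
            raise ValueError(f"taxa with no scored characters: {rows}")

    @property
    def n_taxa(self) -> int:
        return self.cells.shape[0]

    @property
    def n_characters(self) -> int:
        return self.cells.shape[1]

    def scored_mask(self) -> np.ndarray:
        """True where a cell carries an actual state."""
        return self.cells >= 0

    def to_frame(self) -> pd.DataFrame:
        sym = np.where(self.cells == MISSING, "?",
                       np.where(self.cells == INAPPLICABLE, "-",
                                self.cells.astype(str)))
        return pd.DataFrame(sym, index=self.taxon_names,
                            columns=[f"char{i + 1}" for i in range(self.n_characters)])

    def subset_characters(self, keep) -> "CharacterMatrix":
        # a subset (e.g. a jackknife replicate) may leave taxa unscored
        keep = list(keep)
        return CharacterMatrix(list(self.taxon_names), self.cells[:, keep],
                               [self.ordered_flags[i] for i in keep],
                               allow_unscored_taxa=True)

    def __eq__(self, other):
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxon_names == other.taxon_names
                and self.ordered_flags == other.ordered_flags
                and np.array_equal(self.cells, other.cells))

    def __repr__(self):
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_characters} characters>"


def state_symbol(code: int) -> str:
    """Symbol used in all text dialects for one cell code."""
    if code == MISSING:
        return "?"
    if code == INAPPLICABLE:
        return "-"
    return str(int(code))


def parse_symbol(sym: str) -> int:
    """Inverse of :func:`state_symbol`; raises on anything unrecognised."""
    s = sym.strip()
    if s == "?":
        return MISSING
    if s in ("-", "−"):  # ASCII hyphen or true minus sign
        return INAPPLICABLE
    if s.isdigit():
        v = int(s)
        if v <= MAX_STATE:
            return v
    raise ValueError(f"unrecognised character-state symbol {sym!r}")
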