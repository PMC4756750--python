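"""Synthetic data with the statistical structure the pipeline assumes.

The morphometric generator draws per-species multivariate normals with an
optional sexual-dimorphism location shift (a 50/50 two-component mixture)
and deletes cells completely at random, emulating specimen tables of
fragmentary fossils.  The character generator evolves unordered discrete
characters along a known tree under a symmetric Mk model, so searches can
be judged against a known generating topology.  ``nimravid_fixture``
bundles a study-shaped dataset: an 85-specimen x 15-variable measurement
table, a 27-taxon x 33-character matrix simulated on a reference tree of
North American and European false saber-tooth cats plus outgroups, and
the published first/last stratigraphic appearance ages of those taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .containers import MISSING, CharacterMatrix, MeasurementMatrix

__all__ = [
    "SpeciesSpec",
    "MkSimSpec",
    "simulate_measurements",
    "simulate_characters",
    "nimravid_fixture",
    "NIMRAVID_TAXA",
]


@dataclass
class SpeciesSpec:
    """Morphometric profile of one simulated species."""

    name: str
    morpho_mean: np.ndarray           # length-p, mm
    morpho_cov: np.ndarray            # p x p, mm^2
    n_specimens: int
    dimorphism_shift: np.ndarray = None  # added to the "male" half
    fixed_states: dict = field(default_factory=dict)  # char index -> state

    def __post_init__(self):
        self.morpho_mean = np.asarray(self.morpho_mean, dtype=float)
        self.morpho_cov = np.asarray(self.morpho_cov, dtype=float)
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.dimorphism_shift is None:
            self.dimorphism_shift = np.zeros_like(self.morpho_mean)
        else:
            self.dimorphism_shift = np.asarray(self.dimorphism_shift, dtype=float)
        ev = np.linalg.eigvalsh(self.morpho_cov)
        if ev.min() < -1e-8 * max(1.0, abs(ev.max())):
            raise ValueError("morpho_cov must be positive semi-definite")


@dataclass
class MkSimSpec:
    """Mk-model character simulation settings."""

    tree: dendropy.Tree
    n_characters: int
    n_states: int = 2                  # per character, 2..5 (int or sequence)
    rate: float = 1.0                  # per-branch-length substitution rate
    seed: int = 0

    def states_per_char(self):
        if np.isscalar(self.n_states):
            ks = [int(self.n_states)] * self.n_characters
        else:
            ks = [int(k) for k in self.n_states]
        if len(ks) != self.n_characters or any(not 2 <= k <= 5 for k in ks):
            raise ValueError("n_states entries must lie in [2, 5]")
        return ks


def simulate_measurements(specs, miss_rate: float = 0.0,
                          mechanism: str = "MCAR", seed: int = 0):
    """Draw a measurement table from species-wise MVN mixtures.

    Returns ``(MeasurementMatrix, true_labels)``.  Cells are deleted
    independently at ``miss_rate`` (MCAR is the only mechanism; the
    downstream imputation model assumes ignorable missingness).  A mask
    that would leave a variable entirely missing is resampled.  Identical
    seeds give bit-identical datasets.
    """
    if mechanism != "MCAR":
        raise ValueError("only the MCAR mechanism is implemented")
    if not 0.0 <= miss_rate <= 0.6:
        raise ValueError("miss_rate must be in [0, 0.6]")
    specs = list(specs)
    p = specs[0].morpho_mean.shape[0]
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], []
    for spec in specs:
        X = rng.multivariate_normal(spec.morpho_mean, spec.morpho_cov,
                                    size=spec.n_specimens)
        if np.any(spec.dimorphism_shift != 0):
            male = rng.random(spec.n_specimens) < 0.5  # fixed 50/50 mixture
            X[male] += spec.dimorphism_shift
        rows.append(X)
        ids += [f"{spec.name}_{i + 1}" for i in range(spec.n_specimens)]
        labels += [spec.name] * spec.n_specimens
    X = np.vstack(rows)
    X = np.maximum(X, 1e-3)  # measurements are positive lengths
    if miss_rate > 0:
        for _ in range(100):
            mask = rng.random(X.shape) < miss_rate
            if not mask.all(axis=0).any() and not mask.all(axis=1).any():
                break
        else:
            raise RuntimeError("could not draw an admissible missingness mask")
        X = X.copy()
        X[mask] = np.nan
    df = pd.DataFrame(X, index=ids, columns=[f"v{j + 1}" for j in range(p)])
    return MeasurementMatrix(df, labels), list(labels)


def _mk_transition(k: int, rate: float, t: float, rng):
    """Sample child state given parent under the symmetric k-state Mk model.

    Off-diagonal rate ``rate/(k-1)`` each, so ``rate`` is the total rate of
    leaving the current state; P(stay) = 1/k + (k-1)/k * exp(-k*rate*t/(k-1)).
    """
    p_same = 1.0 / k + (k - 1.0) / k * np.exp(-k * rate * t / (k - 1.0))
    return p_same


def simulate_characters(spec: MkSimSpec) -> CharacterMatrix:
    """Evolve unordered characters along a tree from a uniform root state."""
    ks = spec.states_per_char()
    rng = np.random.default_rng(spec.seed)
    taxa = [leaf.taxon.label for leaf in spec.tree.leaf_node_iter()]
    cells = np.zeros((len(taxa), spec.n_characters), dtype=np.int8)
    row = {t: i for i, t in enumerate(taxa)}
    for c, k in enumerate(ks):
        state = {}
        for nd in spec.tree.preorder_node_iter():
            if nd.parent_node is None:
                state[nd] = int(rng.integers(k))
                continue
            t = nd.edge.length
            if t is None or t <= 0:
                raise ValueError("all branch lengths must be positive")
            parent = state[nd.parent_node]
            p_same = _mk_transition(k, spec.rate, t, rng)
            if rng.random() < p_same:
                state[nd] = parent
            else:
                others = [s for s in range(k) if s != parent]
                state[nd] = int(others[rng.integers(k - 1)])
            if nd.is_leaf():
                cells[row[nd.taxon.label], c] = state[nd]
    return CharacterMatrix(taxa, cells)


# ---------------------------------------------------------------------------
# the study-shaped fixture
# ---------------------------------------------------------------------------

#: Reference taxa: 9 outgroup genera and the 18 nimravid species.
NIMRAVID_TAXA = [
    "Viverravus", "Didymictis", "Protictis",
    "Miacis", "Vulpavus", "Oodectes",
    "Daphoenus", "Daphoenodon", "Paradaphoenus",
    "Dinictis felina", "Pogonodon platycopis", "Pogonodon davisi",
    "Nimravus brachyops", "Nimravus intermedius", "Dinaelurus crassus",
    "Eofelis", "Dinailurictis bonali", "Quercylurus major",
    "Nanosmilus kurteni", "Hoplophoneus oharrai", "Hoplophoneus primaevus",
    "Hoplophoneus occidentalis", "Hoplophoneus sicarius",
    "Hoplophoneus dakotensis", "Hoplophoneus cerebralis",
    "Eusmilus bidentatus", "Eusmilus villebramarensis",
]

# Reference topology: viverravid / miacid / daphoenine outgroups, then the
# ingroup with a Nimravini clade, a European clade, and a Hoplophoneini
# clade (Nanosmilus + Hoplophoneus + Eusmilus) on a long stem.
_FIXTURE_NEWICK = """
(((Viverravus:1,Didymictis:1):0.5,Protictis:1.5):0.5,
 ((Miacis:1,(Vulpavus:0.8,Oodectes:0.8):0.2):0.7,
  (((Daphoenus:0.8,Daphoenodon:0.8):0.3,Paradaphoenus:1.1):0.6,
   ((Dinictis_felina:0.9,(Pogonodon_platycopis:0.5,Pogonodon_davisi:0.5):0.4):0.35,
    ((((Nimravus_brachyops:0.4,Nimravus_intermedius:0.4):0.3,Dinaelurus_crassus:0.7):0.5,
      ((Eofelis:0.5,Dinailurictis_bonali:0.5):0.25,Quercylurus_major:0.75):0.45):0.3,
     (Nanosmilus_kurteni:0.55,(Hoplophoneus_oharrai:0.45,
       ((Hoplophoneus_primaevus:0.3,Hoplophoneus_occidentalis:0.3):0.1,
        ((Hoplophoneus_sicarius:0.25,Hoplophoneus_dakotensis:0.25):0.1,
         (Hoplophoneus_cerebralis:0.3,
          (Eusmilus_bidentatus:0.2,Eusmilus_villebramarensis:0.2):0.1):0.05):0.05):0.05):0.1):0.95):0.25):0.4):0.3):0.8);
"""

# First/last appearance data (Ma) of the study taxa as published; carried
# as a fixture for stratigraphically calibrated analyses (not used by the
# parsimony track).
_FAD_LAD = [
    ("Viverravus", 61.7, 40.24), ("Didymictis", 61.7, 40.4),
    ("Protictis", 66.0, 40.4), ("Miacis", 55.8, 33.9),
    ("Vulpavus", 55.8, 38.0), ("Oodectes", 55.8, 46.2),
    ("Daphoenodon", 30.8, 15.97), ("Daphoenus", 40.4, 20.43),
    ("Paradaphoenus", 33.9, 15.97), ("Dinaelurus crassus", 26.0, 23.03),
    ("Nimravus brachyops", 30.5, 28.7), ("Nimravus intermedius", 32.63, 27.24),
    ("Eofelis", 32.63, 30.83), ("Dinailurictis bonali", 30.83, 27.24),
    ("Quercylurus major", 28.82, 27.24), ("Dinictis felina", 35.5, 23.03),
    ("Pogonodon platycopis", 32.1, 28.7), ("Pogonodon davisi", 32.1, 27.5),
    ("Nanosmilus kurteni", 33.89, 32.1), ("Hoplophoneus oharrai", 34.0, 33.89),
    ("Hoplophoneus primaevus", 35.5, 30.25),
    ("Hoplophoneus occidentalis", 33.25, 30.5),
    ("Hoplophoneus dakotensis", 30.5, 29.75),
    ("Hoplophoneus sicarius", 33.89, 32.1),
    ("Hoplophoneus cerebralis", 34.0, 28.0),
    ("Eusmilus bidentatus", 33.77, 32.63),
    ("Eusmilus villebramarensis", 32.63, 30.83),
]

#: The fifteen linear variables of the fixture measurement table (mm unless
#: noted; lca is the lambdoid crest angle in degrees).
FIXTURE_VARIABLES = [
    "basilar_length", "palatal_length", "rostral_width", "zygomatic_width",
    "braincase_width", "lambdoid_crest_angle", "C1_length", "C1_width",
    "P4_length", "dentary_length", "dentary_depth", "p4_length",
    "m1_length", "coronoid_height", "genial_flange_depth",
]


def fixture_tree() -> dendropy.Tree:
    """The fixed 27-taxon reference topology with branch lengths."""
    return dendropy.Tree.get(data=_FIXTURE_NEWICK, schema="newick",
                             preserve_underscores=True)


def fad_lad_table() -> pd.DataFrame:
    """Published first/last appearance ages (Ma) of the 27 study taxa."""
    df = pd.DataFrame(_FAD_LAD, columns=["taxon", "FAD", "LAD"])
    return df.set_index("taxon")


def _hoplophoneus_like_specs(rng):
    """Four species profiles shaped like a large saber-tooth genus sample.

    Means are calibrated to the published per-species summaries (basilar
    length means of roughly 154, 177, 187 and 138 mm; lambdoid crest
    angles near 116-138 degrees); covariances give coefficient-of-
    variation near 7% with correlated size variation, and the most
    abundant species carries a mild dimorphism shift.
    """
    p = len(FIXTURE_VARIABLES)
    base = np.array([154, 72, 48, 95, 52, 116, 17, 9.5, 22, 112, 32,
                     11, 18, 46, 40], dtype=float)

    def cov_for(mean):
        sd = 0.07 * mean
        corr = 0.6 * np.ones((p, p)) + 0.4 * np.eye(p)
        return corr * np.outer(sd, sd)

    def spec(name, scale, n, shift_frac=0.0):
        mean = base * scale
        shift = shift_frac * mean
        return SpeciesSpec(name, mean, cov_for(mean), n,
                           dimorphism_shift=shift)

    return [
        spec("primaevus_like", 1.00, 45, shift_frac=0.06),
        spec("occidentalis_like", 1.15, 20),
        spec("cerebralis_like", 0.90, 12),
        spec("oharrai_like", 1.21, 8),
    ]


def nimravid_fixture(seed: int = 0):
    """Study-shaped synthetic bundle.

    Returns ``(MeasurementMatrix, CharacterMatrix, fad_lad DataFrame)``:
    an 85-specimen x 15-variable measurement table (41.18% cells deleted
    at random — the published missingness of the largest genus table), a
    27-taxon x 33-character matrix evolved on the reference tree, and the
    published FAD/LAD ages.  All synthetic content is deterministic per
    seed; the FAD/LAD ages are verbatim published values.
    """
    rng = np.random.default_rng(seed)
    specs = _hoplophoneus_like_specs(rng)
    mm, _ = simulate_measurements(specs, miss_rate=0.4118,
                                  seed=int(rng.integers(2 ** 31)))
    mm.data.columns = FIXTURE_VARIABLES
    # the Mk rate is calibrated so the simulated matrix shows the moderate
    # homoplasy typical of craniodental matrices (ensemble CI near 0.5)
    nstates = [2 + int(k) for k in rng.integers(0, 4, size=33) % 3]
    cm = simulate_characters(MkSimSpec(
        tree=fixture_tree(), n_characters=33, n_states=nstates,
        rate=0.15, seed=int(rng.integers(2 ** 31))))
    # reorder taxa into the reference listing and restore spaced names
    rename = {t.replace(" ", "_"): t for t in NIMRAVID_TAXA}
    names = [rename.get(t, t) for t in cm.taxon_names]
    cm = CharacterMatrix(names, cm.cells)
    order = [cm.taxon_names.index(t) for t in NIMRAVID_TAXA]
    cm = CharacterMatrix([cm.taxon_names[i] for i in order], cm.cells[order])
    return mm, cm, fad_lad_table()
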