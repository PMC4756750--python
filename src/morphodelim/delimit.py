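"""Phylogenetic-species-concept delimitation.

Under the PSC a species is the smallest aggregation of specimens
diagnosable by a unique combination of character states.  This module

* filters raw per-specimen character observations down to admissible,
  parsimony-informative characters (:func:`filter_characters`),
* discretises continuous candidate characters only where a natural gap
  exists (:func:`natural_gap_code`),
* finds fixed differential states between specimen groups
  (:func:`differential_states`), and
* reconciles DFA-supported morphogroups with those fixed differences into
  species hypotheses (:func:`delimit_species`): a supported morphometric
  split is a species boundary only if at least one character state is
  fixed and different across it; otherwise the metric split is read as
  intraspecific (e.g. sexual dimorphism) and the groups merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import INAPPLICABLE, MAX_STATE, MISSING, CharacterMatrix
from .discriminant import meets_support_cutoff

__all__ = [
    "POLYMORPHIC",
    "REJECT",
    "RawCharacterObservations",
    "SpeciesHypothesis",
    "filter_characters",
    "natural_gap_code",
    "differential_states",
    "delimit_species",
]


class _Sentinel:
    def __init__(self, name):
        self.name = name

    def __repr__(self):
        return self.name


#: A cell showing different states within one specimen (left vs right side,
#: repeated structures) — disqualifies the character under the PSC.
POLYMORPHIC = _Sentinel("POLYMORPHIC")

#: Returned by :func:`natural_gap_code` when no qualifying gap exists.
REJECT = _Sentinel("REJECT")


@dataclass
class RawCharacterObservations:
    """Per specimen x candidate character observations.

    Each cell is exactly one of: an int state, a float (continuous value
    awaiting discretisation), ``POLYMORPHIC``, or ``None`` (missing).
    ``continuous`` flags columns holding raw measurements; ``unscorable``
    flags columns that could not be consistently scored.
    """

    table: pd.DataFrame
    continuous: set = field(default_factory=set)
    unscorable: set = field(default_factory=set)

    def __post_init__(self):
        for col in self.table.columns:
            for v in self.table[col]:
                ok = (v is None or v is POLYMORPHIC
                      or isinstance(v, (int, np.integer))
                      or isinstance(v, (float, np.floating)))
                if not ok:
                    raise ValueError(f"bad cell {v!r} in character {col!r}")

    @staticmethod
    def is_missing(v) -> bool:
        return v is None or (isinstance(v, (float, np.floating)) and np.isnan(v))

    @property
    def specimen_ids(self):
        return list(self.table.index)


def natural_gap_code(values, min_gap_ratio: float = 3.0):
    """Discretise continuous values at natural gaps, or REJECT.

    Values are sorted; a state boundary is placed at every adjacent gap
    at least ``min_gap_ratio`` times the median adjacent gap.  Contiguous
    runs become states 0, 1, 2, ... in increasing value order.  Returns a
    list of states aligned with the input order, or ``REJECT`` when no
    qualifying gap (or more runs than the 5-state alphabet) exists.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size < 4:
        raise ValueError("need at least 4 observed values to look for a gap")
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite values")
    order = np.argsort(vals, kind="stable")
    svals = vals[order]
    gaps = np.diff(svals)
    positive = gaps[gaps > 0]
    if positive.size == 0:
        return REJECT
    ref = float(np.median(gaps))
    if ref <= 0:
        ref = float(np.median(positive))
    boundaries = gaps >= min_gap_ratio * ref
    if not boundaries.any():
        return REJECT
    states_sorted = np.concatenate([[0], np.cumsum(boundaries)])
    if states_sorted[-1] > MAX_STATE:
        return REJECT
    out = np.empty(vals.size, dtype=int)
    out[order] = states_sorted
    return out.tolist()


def filter_characters(raw: RawCharacterObservations,
                      min_gap_ratio: float = 3.0):
    """Apply the character criteria; return (CharacterMatrix, rejection log).

    Characters are dropped when (a) polymorphic within any specimen,
    (b) invariant across all specimens, (c) flagged unscorable,
    (d) continuous without a natural gap — and finally when not
    parsimony-informative (fewer than two states each carried by at least
    two specimens).  Every removal is logged with the rule that fired.
    """
    if len(raw.table) < 2:
        raise ValueError("need at least 2 specimens")
    log = []
    kept_cols = []
    kept_cells = []
    for col in raw.table.columns:
        cells = list(raw.table[col])
        if col in raw.unscorable:
            log.append((col, "unscorable"))
            continue
        if any(v is POLYMORPHIC for v in cells):
            log.append((col, "polymorphic_within_specimen"))
            continue
        miss = RawCharacterObservations.is_missing
        if col in raw.continuous:
            obs_idx = [i for i, v in enumerate(cells) if not miss(v)]
            coded = natural_gap_code([cells[i] for i in obs_idx], min_gap_ratio)
            if coded is REJECT:
                log.append((col, "no_natural_gap"))
                continue
            states = [MISSING] * len(cells)
            for i, s in zip(obs_idx, coded):
                states[i] = s
        else:
            states = [MISSING if miss(v) else int(v) for v in cells]
        observed = [s for s in states if s >= 0]
        uniq = set(observed)
        if len(uniq) < 2:
            log.append((col, "invariant"))
            continue
        counts = {s: observed.count(s) for s in uniq}
        informative = sum(1 for c in counts.values() if c >= 2) >= 2
        if not informative:
            log.append((col, "parsimony_uninformative"))
            continue
        kept_cols.append(col)
        kept_cells.append(states)
    if not kept_cols:
        raise ValueError("all characters removed by the filtering criteria")
    cells = np.array(kept_cells, dtype=np.int8).T
    cm = CharacterMatrix(raw.specimen_ids, cells, allow_unscored_taxa=True)
    cm.character_names = kept_cols
    return cm, log


def _fixed_state(cm: CharacterMatrix, rows: list[int], char: int):
    """Single state shared by all scored members, else None.

    Missing/inapplicable cells do not break fixation, but a group scored
    for none of its members contributes nothing.
    """
    col = cm.cells[rows, char]
    scored = col[col >= 0]
    if scored.size == 0:
        return None
    uniq = np.unique(scored)
    return int(uniq[0]) if uniq.size == 1 else None


def differential_states(cm: CharacterMatrix, group_a, group_b):
    """Characters fixed within each group with different states across.

    Groups are disjoint sets of taxon/specimen names from ``cm``.  Returns
    a set of ``(character index, state in A, state in B)`` triples.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    index = {t: i for i, t in enumerate(cm.taxon_names)}
    rows_a = [index[t] for t in group_a]
    rows_b = [index[t] for t in group_b]
    out = set()
    for c in range(cm.n_characters):
        sa = _fixed_state(cm, rows_a, c)
        sb = _fixed_state(cm, rows_b, c)
        if sa is not None and sb is not None and sa != sb:
            out.add((c, sa, sb))
    return out


@dataclass(frozen=True)
class SpeciesHypothesis:
    """A PSC species: a specimen set plus its diagnostic state combination."""

    member_specimens: frozenset
    diagnosis: frozenset  # of (character index, state)
    supporting_accuracy: float | None = None


def _split_is_valid(cm, members_a, members_b, accuracy):
    """A pair of groups separates into two species iff the DFA accuracy
    meets the cutoff (bypassed when either group is a single specimen,
    mirroring unique holotypes) and fixed differential states exist."""
    singleton_bypass = len(members_a) == 1 or len(members_b) == 1
    supported = singleton_bypass or (
        accuracy is not None and meets_support_cutoff(accuracy))
    return supported and bool(differential_states(cm, members_a, members_b))


def delimit_species(cm: CharacterMatrix, partitions) -> list[SpeciesHypothesis]:
    """Reconcile validated morphogroup partitions into species hypotheses.

    ``partitions`` is a list of :class:`MorphogroupPartition` (with
    ``dfa_accuracy`` attached) over the same specimens; multiple
    partitions must be nested (hierarchical dendrogram cuts).  The output
    hypotheses partition the specimens; each carries the diagnosis fixed
    in its members, and diagnoses of distinct species are pairwise
    distinct (PSC uniqueness, asserted).
    """
    if not partitions:
        raise ValueError("need at least one partition")
    all_ids = set(partitions[0].assignment)
    for p in partitions:
        if set(p.assignment) != all_ids:
            raise ValueError("partitions cover different specimen sets")
    # check nesting (no overlapping non-nested groups)
    group_sets = []
    for p in partitions:
        group_sets.append([frozenset(g) for g in p.groups()])
    flat = [g for gs in group_sets for g in gs]
    for i, ga in enumerate(flat):
        for gb in flat[i + 1:]:
            inter = ga & gb
            if inter and ga != gb and inter != ga and inter != gb:
                raise ValueError(
                    f"conflicting (overlapping, non-nested) groups: "
                    f"{sorted(ga)} vs {sorted(gb)}")

    # process coarse -> fine, splitting a current species only where the
    # finer partition's validated groups justify it
    species = [frozenset(all_ids)]
    acc_of = {}
    ordered = sorted(zip(partitions, group_sets), key=lambda t: t[0].k)
    for part, groups in ordered:
        new_species = []
        for sp in species:
            inside = [g & sp for g in groups if g & sp]
            if len(inside) < 2:
                new_species.append(sp)
                continue
            # pairwise merge indistinguishable subgroups within sp
            merged = [set(g) for g in inside]
            changed = True
            while changed:
                changed = False
                for i in range(len(merged)):
                    for j in range(i + 1, len(merged)):
                        if not _split_is_valid(cm, merged[i], merged[j],
                                               part.dfa_accuracy):
                            merged[i] |= merged[j]
                            del merged[j]
                            changed = True
                            break
                    if changed:
                        break
            for g in merged:
                fs = frozenset(g)
                new_species.append(fs)
                if len(merged) > 1:
                    acc_of[fs] = part.dfa_accuracy
        species = new_species

    out = []
    index = {t: i for i, t in enumerate(cm.taxon_names)}
    for sp in species:
        rows = [index[t] for t in sp]
        diag = set()
        for c in range(cm.n_characters):
            s = _fixed_state(cm, rows, c)
            if s is not None:
                # diagnostic only if it differs from some other species
                for other in species:
                    if other is sp:
                        continue
                    so = _fixed_state(cm, [index[t] for t in other], c)
                    if so is not None and so != s:
                        diag.add((c, s))
                        break
        out.append(SpeciesHypothesis(sp, frozenset(diag), acc_of.get(sp)))

    diagnoses = [h.diagnosis for h in out]
    if len(out) > 1:
        for i in range(len(out)):
            for j in range(i + 1, len(out)):
                assert diagnoses[i] != diagnoses[j], \
                    "distinct species share an identical diagnosis"
    return out
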