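"""End-to-end morphometric delimitation track.

Chains the stages of the species-delimitation workflow: impute the
measurement table if incomplete, cluster by UPGMA, cut candidate
morphogroups, validate them by discriminant accuracy (stratified split,
or leave-one-out jackknife when groups are too small to split), and —
given a specimen-level character matrix — reconcile the supported groups
with fixed differential character states into species hypotheses.
"""

from __future__ import annotations

from .cluster import MorphogroupPartition, cut_to_k, pairwise_distances, upgma
from .containers import CharacterMatrix, MeasurementMatrix
from .delimit import delimit_species
from .discriminant import (jackknife_cv_accuracy, split_validated_accuracy)
from .impute import da_impute

__all__ = ["morphometric_track", "delimit_track"]


def morphometric_track(m: MeasurementMatrix, k: int = 2, steps: int = 100,
                       seed: int = 0, mode: str = "auto",
                       standardize: bool = False):
    """Impute -> UPGMA -> cut k groups -> DFA validation.

    ``mode`` is "split", "jackknife", or "auto" (split unless some group
    has fewer than 4 members).  Returns ``(completed, dendrogram,
    partition)`` with ``partition.dfa_accuracy`` filled in.
    """
    completed = m if m.is_complete() else da_impute(m, steps=steps, seed=seed).completed
    d = pairwise_distances(completed, standardize=standardize)
    dend = upgma(d, completed.specimen_ids)
    # single-specimen groups (unique specimens, holotype-like) cannot enter
    # a DFA: deepen the cut until at least two multi-member groups exist,
    # then validate on the multi-member specimens only
    k_eff = k
    while True:
        part = cut_to_k(dend, k_eff)
        multi = [g for g in part.groups() if len(g) >= 2]
        if len(multi) >= 2 or k_eff >= completed.n_specimens:
            break
        k_eff += 1
    if len(multi) < 2:
        raise ValueError("no pair of multi-member groups at any cut depth")
    ids = [s for g in multi for s in g]
    group_ids = sorted({part.assignment[s] for s in ids})
    remap = {g: i for i, g in enumerate(group_ids)}
    sub = MorphogroupPartition(
        k=len(multi), assignment={s: remap[part.assignment[s]] for s in ids},
        source=part.source)
    sub_m = completed.subset(specimens=ids)
    if mode == "auto":
        mode = "jackknife" if min(sub.group_sizes()) < 4 else "split"
    if mode == "split":
        acc = split_validated_accuracy(sub_m, sub, seed)
    elif mode == "jackknife":
        acc = jackknife_cv_accuracy(sub_m, sub)
    else:
        raise ValueError("mode must be 'split', 'jackknife' or 'auto'")
    part.dfa_accuracy = acc
    part.validation_mode = mode
    return completed, dend, part


def delimit_track(cm: CharacterMatrix, partitions):
    """Species hypotheses from validated partitions plus characters."""
    if isinstance(partitions, MorphogroupPartition):
        partitions = [partitions]
    return delimit_species(cm, partitions)
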