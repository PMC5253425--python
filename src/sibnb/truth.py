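"""Ground truth from a complete pedigree: ki vectors, true Nb, dyad labels.

The PwoP (parentage without parents) estimator needs only the vector of
per-parent offspring counts ki; parents with zero sampled offspring carry no
information and may be omitted. Applied to a complete, accurate pedigree it
defines the true effective number of breeders Nb of the parental group.
"""
from __future__ import annotations

import math

import numpy as np

from .data import DyadLabelSet, KiVector, Pedigree


def ki_vector(pedigree: Pedigree, sampled_offspring: list[str]) -> KiVector:
    """Count sampled offspring per parent. sum(ki) = 2 * |sample| always."""
    sample = list(sampled_offspring)
    if not sample:
        raise ValueError("empty offspring sample")
    counts: dict[str, int] = {}
    for oid in sample:
        sire, dam = pedigree.offspring[oid]
        counts[sire] = counts.get(sire, 0) + 1
        counts[dam] = counts.get(dam, 0) + 1
    return KiVector(counts=counts, S=len(sample))


def pwop_nb(ki: KiVector) -> float:
    """Nb = (2S - 1) / (sum(ki^2) / (2S) - 1), +inf when the denominator <= 0.

    This is the single-cohort variant of the Crow-Denniston inbreeding
    effective size; it equals the closed form (N*kbar - 1)/(kbar - 1 + Vk/kbar)
    over the implied parent set.
    """
    if ki.S < 1:
        raise ValueError("need at least one offspring")
    k = ki.values()
    two_s = 2 * ki.S
    if int(k.sum()) != two_s:
        raise ValueError(
            f"inconsistent pedigree: sum(ki)={int(k.sum())} but 2S={two_s}"
        )
    denom = float((k.astype(np.float64) ** 2).sum()) / two_s - 1.0
    if denom <= 0:
        return math.inf
    return (two_s - 1) / denom


def label_dyads(pedigree: Pedigree, sampled_offspring: list[str] | None = None) -> DyadLabelSet:
    """Exhaustive FS/HS/U labels over all C(n,2) sampled offspring pairs."""
    ids, sires, dams = pedigree.parent_arrays(sampled_offspring)
    if len(ids) < 2:
        raise ValueError("need at least two sampled offspring to form dyads")
    return DyadLabelSet.from_parent_codes(ids, sires, dams)


def truth_summary(pedigree: Pedigree) -> dict:
    """True Nb, ki histogram and dyad counts for a complete pedigree (JSON-able)."""
    ids = pedigree.offspring_ids
    ki = ki_vector(pedigree, ids)
    nb = pwop_nb(ki)
    dyads = label_dyads(pedigree, ids) if len(ids) >= 2 else None
    hist: dict[str, int] = {}
    for v in ki.counts.values():
        hist[str(v)] = hist.get(str(v), 0) + 1
    n_zero = len(pedigree.parents) - len(ki.counts)
    hist["0"] = hist.get("0", 0) + n_zero
    out = {
        "true_nb": nb if math.isfinite(nb) else "inf",
        "n_offspring": len(ids),
        "n_parents_total": len(pedigree.parents),
        "n_successful_parents": len(ki.counts),
        "ki_histogram": dict(sorted(hist.items(), key=lambda kv: int(kv[0]))),
    }
    if dyads is not None:
        out["dyad_counts"] = dyads.counts
        out["hs_paternal"] = dyads.hs_paternal
        out["hs_maternal"] = dyads.hs_maternal
    return out
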