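"""Single-sample Nb estimators from sibship structure: SA and PwoP.

The sibship-assignment (SA) estimator inverts the relationship between Nb
and the probabilities that a random offspring pair shares a sire only (Q1),
a dam only (Q2), or both parents (Q3):

    Nb = 1 / [ (1 + 3*alpha)/4 * (Q1 + Q2 + 2*Q3) - alpha/2 * (1/N1 + 1/N2) ]

where alpha is the deviation from Hardy-Weinberg genotype proportions
(Wright's F_IS) estimated from the same sample, and the parental sex counts
N1, N2 are replaced by their sibship-implied values 1/(Q1+Q3) and 1/(Q2+Q3).
With alpha = 0 the formula reduces to 4 / (Q1 + Q2 + 2*Q3).

The PwoP (parentage without parents) route instead reconstructs per-parent
offspring counts ki from the sibship partition and applies the
Crow-Denniston-type formula (see :func:`sibnb.truth.pwop_nb`). Infinity is a
first-class estimate (no related dyads found), not an exception.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data import MISSING, DyadLabelSet, GenotypeTable, KiVector, SibshipPartition
from .recon import AlleleFreqs
from .truth import pwop_nb


@dataclass(frozen=True)
class SibshipFrequencies:
    """Exclusive dyad frequencies: Q1 share-sire-only, Q2 share-dam-only, Q3 FS."""

    q1: float
    q2: float
    q3: float
    n: int

    def __post_init__(self) -> None:
        if min(self.q1, self.q2, self.q3) < 0 or self.q1 + self.q2 + self.q3 > 1 + 1e-12:
            raise ValueError("dyad frequencies must be non-negative and sum to <= 1")

    @property
    def n_dyads(self) -> int:
        return self.n * (self.n - 1) // 2


@dataclass(frozen=True)
class AlphaEstimate:
    """Multilocus F_IS: 1 - Hobs/Hexp pooled over loci (ratio of averages)."""

    alpha: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [-1, 1]")


@dataclass(frozen=True)
class NbEstimate:
    method: str  # "SA" or "PwoP"
    value: float  # positive real or +inf
    n: int
    alpha: float | None = None
    q: SibshipFrequencies | None = None


def estimate_alpha(genotypes: GenotypeTable, freqs: AlleleFreqs | None = None) -> AlphaEstimate:
    """Sample F_IS from observed vs Hardy-Weinberg expected heterozygosity.

    Expected heterozygosity uses sample allele frequencies (unclamped);
    observed and expected are each averaged over loci before taking the
    ratio, which is stable at modest locus counts.
    """
    codes = genotypes.codes
    obs = codes != MISSING
    m = obs.sum(axis=0)
    ok = m > 0
    if not ok.any():
        raise ValueError("no genotyped loci")
    het = ((codes == 1) & obs).sum(axis=0)
    minor = np.where(obs, codes, 0).sum(axis=0, dtype=np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = minor / (2.0 * m)
    h_obs = float(np.mean(het[ok] / m[ok]))
    h_exp = float(np.mean(2.0 * p[ok] * (1.0 - p[ok])))
    if h_exp <= 0:
        raise ValueError("all loci monomorphic in sample; alpha undefined")
    return AlphaEstimate(float(np.clip(1.0 - h_obs / h_exp, -1.0, 1.0)))


def sibship_frequencies(source: DyadLabelSet | SibshipPartition) -> SibshipFrequencies:
    """Q1/Q2/Q3 from either labelled dyads or a sibship partition.

    Definitions are exclusive: Q1 excludes full-sib pairs, so Q1 + Q3 is the
    probability of sharing a sire.
    """
    if isinstance(source, SibshipPartition):
        n = source.n
        if n < 2:
            raise ValueError("need at least two offspring")
        denom = n * (n - 1) / 2.0
        share_sire = sum(
            c * (c - 1) // 2 for c in np.bincount(source.sires).tolist()
        )
        share_dam = sum(
            c * (c - 1) // 2 for c in np.bincount(source.dams).tolist()
        )
        fs = sum(len(v) * (len(v) - 1) // 2 for v in source.clusters().values())
        return SibshipFrequencies(
            (share_sire - fs) / denom, (share_dam - fs) / denom, fs / denom, n
        )
    n = source.n
    if n < 2:
        raise ValueError("need at least two offspring")
    denom = n * (n - 1) / 2.0
    counts = source.counts
    return SibshipFrequencies(
        source.hs_paternal / denom, source.hs_maternal / denom, counts["FS"] / denom, n
    )


def sa_nb(q: SibshipFrequencies, alpha: AlphaEstimate | float = 0.0) -> NbEstimate:
    """Sibship-assignment Nb with nonrandom-mating correction.

    The 1/N1 + 1/N2 term uses the sibship-implied substitutions
    1/N1 = Q1 + Q3 and 1/N2 = Q2 + Q3 (no division, so empty sib classes are
    handled naturally). Returns +inf when the denominator is <= 0, e.g. when
    no sib dyads were found.
    """
    a = alpha.alpha if isinstance(alpha, AlphaEstimate) else float(alpha)
    denom = (1.0 + 3.0 * a) / 4.0 * (q.q1 + q.q2 + 2.0 * q.q3)
    denom -= a / 2.0 * ((q.q1 + q.q3) + (q.q2 + q.q3))
    value = math.inf if denom <= 0 else 1.0 / denom
    return NbEstimate("SA", value, q.n, alpha=a, q=q)


def ki_from_partition(partition: SibshipPartition) -> KiVector:
    """Per-latent-parent offspring counts from a sibship partition; sum = 2S."""
    counts: dict[str, int] = {}
    for s in partition.sires.tolist():
        counts[f"S{s}"] = counts.get(f"S{s}", 0) + 1
    for d in partition.dams.tolist():
        counts[f"D{d}"] = counts.get(f"D{d}", 0) + 1
    return KiVector(counts=counts, S=partition.n)


def pwop_nb_from_partition(partition: SibshipPartition) -> NbEstimate:
    """PwoP Nb via the reconstructed ki vector (same formula as pedigree truth)."""
    value = pwop_nb(ki_from_partition(partition))
    return NbEstimate("PwoP", value, partition.n)


# ---------------------------------------------------------------------------
# BestCluster-compatible text interchange

_BC_COLUMNS = ["ClusterIndex", "ClusterProbability", "OffspringID", "FatherID", "MotherID"]


def write_best_cluster(partition: SibshipPartition, path) -> None:
    """Write a partition as whitespace-delimited BestCluster-style text."""
    clusters = partition.clusters()
    order = {key: i + 1 for i, key in enumerate(sorted(clusters, key=lambda k: min(clusters[k])))}
    with open(path, "w") as fh:
        fh.write("  ".join(_BC_COLUMNS) + "\n")
        for k, oid in enumerate(partition.ids):
            s, d = int(partition.sires[k]), int(partition.dams[k])
            fh.write(
                f"{order[(s, d)]}  1.0  {oid}  S{s + 1}  D{d + 1}\n"
            )


def read_best_cluster(path) -> SibshipPartition:
    """Parse BestCluster-style text into a sibship partition.

    Expects whitespace-delimited columns ClusterIndex, ClusterProbability,
    OffspringID, FatherID, MotherID; a header line is tolerated. Latent
    parent IDs become integer labels (sire and dam namespaces separate).
    """
    ids: list[str] = []
    sires: list[int] = []
    dams: list[int] = []
    sire_code: dict[str, int] = {}
    dam_code: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if lineno == 1 and not _looks_like_row(fields):
                continue
            if len(fields) < 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 whitespace-delimited columns "
                    f"(ClusterIndex ClusterProbability OffspringID FatherID MotherID), got {len(fields)}"
                )
            _, _, oid, father, mother = fields[:5]
            if oid in ids:
                raise ValueError(f"{path}: duplicate OffspringID {oid!r} at line {lineno}")
            ids.append(oid)
            sires.append(sire_code.setdefault(father, len(sire_code)))
            dams.append(dam_code.setdefault(mother, len(dam_code)))
    if not ids:
        raise ValueError(f"{path}: no offspring rows found")
    return SibshipPartition(
        ids, np.array(sires, dtype=np.int64), np.array(dams, dtype=np.int64)
    )


def _looks_like_row(fields: list[str]) -> bool:
    try:
        float(fields[0])
        return True
    except ValueError:
        return False


def estimates_record(
    partition: SibshipPartition,
    genotypes: GenotypeTable | None = None,
    method: str = "both",
) -> dict:
    """JSON-able SA/PwoP estimates for a partition (alpha from genotypes if given)."""
    out: dict = {"n": partition.n}
    if method in ("sa", "both"):
        q = sibship_frequencies(partition)
        alpha = estimate_alpha(genotypes) if genotypes is not None else AlphaEstimate(0.0)
        sa = sa_nb(q, alpha)
        out.update(
            method=method,
            sa_nb=sa.value if math.isfinite(sa.value) else "inf",
            alpha=alpha.alpha,
            q1=q.q1,
            q2=q.q2,
            q3=q.q3,
        )
    if method in ("pwop", "both"):
        pw = pwop_nb_from_partition(partition)
        out["pwop_nb"] = pw.value if math.isfinite(pw.value) else "inf"
        out["method"] = method
    return out
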