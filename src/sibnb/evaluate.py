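"""Evaluation designs: dyad confusion, subsampling bias/RMSB, SA-vs-PwoP.

Reproduces the three study designs against simulated truth: (i) full-cohort
grids of mating-system x assumed-error-rate reconstruction runs scored by
3x3 dyad confusion matrices with type-I (unrelated called sib) and type-II
(related called non-sib) totals; (ii) the subsampling experiment — random
draws of 10%..90% of offspring, replicated, scored by average bias and
percent root-mean-squared bias (RMSB); (iii) concordance between the SA and
PwoP estimators computed from identical sibship partitions.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    DYAD_FS,
    DYAD_HS,
    DYAD_U,
    DyadLabelSet,
    GenotypeTable,
    Pedigree,
    SibshipPartition,
)
from .estimators import estimate_alpha, pwop_nb_from_partition, sa_nb, sibship_frequencies
from .recon import ReconConfig, classify_dyads, reconstruct
from .truth import ki_vector, label_dyads, pwop_nb

_LABEL_ORDER = (DYAD_FS, DYAD_HS, DYAD_U)  # row/column order FS, HS, U


@dataclass
class ConfusionMatrix:
    """3x3 dyad cross-tabulation; rows true {FS,HS,U}, columns inferred."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3):
            raise ValueError("confusion matrix must be 3x3")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> dict[str, int]:
        return {"FS": int(self.counts[0].sum()), "HS": int(self.counts[1].sum()), "U": int(self.counts[2].sum())}

    def row_percent(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return 100.0 * self.counts / self.counts.sum(axis=1, keepdims=True)

    @property
    def type_I(self) -> int:
        """True-unrelated pairs inferred as FS or HS."""
        return int(self.counts[2, 0] + self.counts[2, 1])

    @property
    def type_II(self) -> int:
        """True-related pairs inferred as unrelated."""
        return int(self.counts[0, 2] + self.counts[1, 2])

    def accuracy(self, label: str) -> float:
        """Percent of true dyads of a class recovered (NaN if class absent)."""
        i = {"FS": 0, "HS": 1, "U": 2}[label]
        row = self.counts[i].sum()
        return float("nan") if row == 0 else 100.0 * self.counts[i, i] / row

    def to_frame(self) -> pd.DataFrame:
        names = ["FS", "HS", "U"]
        return pd.DataFrame(self.counts, index=pd.Index(names, name="true"), columns=names)


def confusion(true: DyadLabelSet, inferred: DyadLabelSet) -> ConfusionMatrix:
    """Cross-tabulate true vs inferred labels over all C(n,2) dyads."""
    if set(true.ids) != set(inferred.ids):
        raise ValueError("true and inferred label sets cover different individuals")
    inferred = inferred.reordered(true.ids)
    idx = {lab: k for k, lab in enumerate(_LABEL_ORDER)}
    t = np.array([idx[v] for v in range(3)])[np.clip(true.labels, 0, 2)]
    f = np.array([idx[v] for v in range(3)])[np.clip(inferred.labels, 0, 2)]
    counts = np.bincount(t * 3 + f, minlength=9).reshape(3, 3)
    return ConfusionMatrix(counts)


@dataclass(frozen=True)
class RmsbResult:
    """Percent root-mean-squared bias over finite replicate estimates."""

    value: float  # NaN when every estimate was infinite
    n_used: int
    n_excluded: int

    @property
    def is_na(self) -> bool:
        return math.isnan(self.value)


def rmsb(estimates, true_nb: float) -> RmsbResult:
    """100 * sqrt(mean(((est - true)/true)^2)) over finite estimates.

    Infinite estimates are excluded and counted; if none are finite the
    result is flagged NA (the smallest draws of the smallest population can
    yield all-infinite batches).
    """
    if not true_nb > 0:
        raise ValueError("true Nb must be positive")
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    finite = np.isfinite(est)
    n_exc = int((~finite).sum())
    if not finite.any():
        return RmsbResult(float("nan"), 0, n_exc)
    rel = (est[finite] - true_nb) / true_nb
    return RmsbResult(100.0 * float(np.sqrt(np.mean(rel**2))), int(finite.sum()), n_exc)


@dataclass(frozen=True)
class SubsampleDesign:
    """Random-draw design: fractions of offspring, replicate draws per fraction.

    Sampling is without replacement within a draw and with full replacement
    between draws. Draw size is floor(fraction * n), which reproduces every
    published draw size.
    """

    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    replicates: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(not 0 < f <= 1 for f in self.fractions):
            raise ValueError("fractions must lie in (0, 1]")
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates for dispersion statistics")

    def draw_sizes(self, n: int) -> list[int]:
        return [math.floor(f * n) for f in self.fractions]

    def schedule(self, ns: dict[str, int]) -> list[tuple[str, float, int, int]]:
        """All (population, fraction, replicate, draw size) runs the design implies."""
        return [
            (pop, f, r, math.floor(f * n))
            for pop, n in ns.items()
            for f in self.fractions
            for r in range(self.replicates)
        ]


def subsample_experiment(
    genotypes: GenotypeTable,
    true_nb: float,
    design: SubsampleDesign,
    recon: ReconConfig,
    method: str = "sa",
) -> pd.DataFrame:
    """Draw, reconstruct, estimate and summarise per sampling fraction.

    Returns one row per fraction with Table-3-style columns: average bias,
    average percent bias, absolute average percent bias, percent RMSB,
    standard deviation s over finite estimates and the count of infinite
    estimates excluded.
    """
    if not true_nb > 0:
        raise ValueError("true Nb must be positive")
    n = genotypes.n
    rng = np.random.default_rng(design.seed)
    rows = []
    run = 0
    for f in design.fractions:
        size = math.floor(f * n)
        if size < 2:
            warnings.warn(f"fraction {f} gives draw size {size} < 2; skipped", stacklevel=2)
            continue
        ests = []
        for _r in range(design.replicates):
            draw = rng.choice(n, size=size, replace=False)
            sub = genotypes.subset([genotypes.ids[int(i)] for i in sorted(draw)])
            run_seed = None if recon.seed is None else (int(recon.seed) + 104729 * run) % 2**31
            part = reconstruct(sub, recon.replace(seed=run_seed))
            ests.append(_estimate(part, sub, method))
            run += 1
        rows.append(_summary_row(f, size, ests, true_nb))
    return pd.DataFrame(rows)


def _estimate(partition: SibshipPartition, genotypes: GenotypeTable, method: str) -> float:
    if method == "sa":
        return sa_nb(sibship_frequencies(partition), estimate_alpha(genotypes)).value
    if method == "pwop":
        return pwop_nb_from_partition(partition).value
    raise ValueError(f"unknown method {method!r}")


def _summary_row(fraction: float, size: int, ests: list[float], true_nb: float) -> dict:
    est = np.asarray(ests, dtype=float)
    finite = est[np.isfinite(est)]
    r = rmsb(est, true_nb)
    if finite.size:
        bias = finite - true_nb
        pct = 100.0 * bias / true_nb
        row = {
            "fraction": fraction,
            "n_sampled": size,
            "avg_bias": float(bias.mean()),
            "avg_pct_bias": float(pct.mean()),
            "abs_avg_pct_bias": float(np.abs(pct).mean()),
            "rmsb_pct": r.value,
            "s": float(np.std(finite, ddof=1)) if finite.size > 1 else float("nan"),
            "n_infinite": r.n_excluded,
        }
    else:
        row = {
            "fraction": fraction,
            "n_sampled": size,
            "avg_bias": float("nan"),
            "avg_pct_bias": float("nan"),
            "abs_avg_pct_bias": float("nan"),
            "rmsb_pct": float("nan"),
            "s": float("nan"),
            "n_infinite": r.n_excluded,
        }
    return row


@dataclass
class ConcordanceResult:
    """Per-run SA/PwoP comparison plus a ratio histogram (Figure-4 analogue)."""

    table: pd.DataFrame
    n_excluded: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def max_pct_diff(self) -> float:
        return float(self.table["pct_diff"].max()) if len(self.table) else float("nan")


def sa_pwop_concordance(runs, bins: int = 20) -> ConcordanceResult:
    """Compare SA and PwoP estimates computed from identical partitions.

    ``runs`` yields (partition, genotypes) pairs; genotypes may be None to
    force alpha = 0. Percent difference is 100*|SA - PwoP| / PwoP. Runs with
    infinite PwoP are excluded and counted.
    """
    records = []
    excluded = 0
    for partition, genotypes in runs:
        q = sibship_frequencies(partition)
        alpha = estimate_alpha(genotypes) if genotypes is not None else None
        sa = sa_nb(q, alpha if alpha is not None else 0.0)
        pw = pwop_nb_from_partition(partition)
        if not math.isfinite(pw.value):
            excluded += 1
            continue
        records.append(
            {
                "n": partition.n,
                "sa": sa.value,
                "pwop": pw.value,
                "ratio": sa.value / pw.value,
                "pct_diff": 100.0 * abs(sa.value - pw.value) / pw.value,
                "alpha": alpha.alpha if alpha is not None else 0.0,
            }
        )
    table = pd.DataFrame(records)
    if len(table):
        ratios = table["ratio"].to_numpy()
        lo, hi = float(ratios.min()), float(ratios.max())
        if hi - lo < 1e-6:  # nearly identical ratios: widen the range
            lo, hi = lo - 0.005, hi + 0.005
        counts, edges = np.histogram(ratios, bins=np.linspace(lo, hi, bins + 1))
    else:
        counts, edges = np.zeros(bins, dtype=np.int64), np.linspace(0, 1, bins + 1)
    return ConcordanceResult(table, excluded, counts, edges)


# ---------------------------------------------------------------------------
# full-cohort grid (Table-2 / Figure-2 analogue)


@dataclass(frozen=True)
class GridCell:
    population: str
    mating_system: str
    error_rate: float


@dataclass
class CellResult:
    cell: GridCell
    confusion: ConfusionMatrix
    true_nb: float
    sa_nb: float
    pwop_nb: float


def grid_plan(
    populations: dict[str, object],
    mating_systems=("monogamy", "male_polygamy_female_monogamy", "polygamy"),
    error_rates=(0.0001, 0.001, 0.01),
) -> list[GridCell]:
    """Every (population, mating system, assumed error rate) cell scheduled."""
    return [
        GridCell(pop, ms, e)
        for pop in populations
        for ms in mating_systems
        for e in error_rates
    ]


def full_cohort_experiment(
    populations: dict[str, tuple[GenotypeTable, Pedigree]],
    mating_systems=("monogamy", "male_polygamy_female_monogamy", "polygamy"),
    error_rates=(0.0001, 0.001, 0.01),
    recon: ReconConfig = ReconConfig(),
) -> dict[GridCell, CellResult]:
    """Run the reconstruction grid and score each cell against pedigree truth."""
    out: dict[GridCell, CellResult] = {}
    for k, cell in enumerate(grid_plan(populations, mating_systems, error_rates)):
        genotypes, pedigree = populations[cell.population]
        seed = None if recon.seed is None else (int(recon.seed) + 15485863 * k) % 2**31
        cfg = recon.replace(mating_system=cell.mating_system, error_rate=cell.error_rate, seed=seed)
        part = reconstruct(genotypes, cfg)
        truth_labels = label_dyads(pedigree, list(part.ids))
        cm = confusion(truth_labels, classify_dyads(part))
        true_nb = pwop_nb(ki_vector(pedigree, pedigree.offspring_ids))
        sa = sa_nb(sibship_frequencies(part), estimate_alpha(genotypes))
        pw = pwop_nb_from_partition(part)
        out[cell] = CellResult(cell, cm, true_nb, sa.value, pw.value)
    return out


def downward_bias_signs(
    genotypes: GenotypeTable,
    true_nb: float,
    draw_size: int,
    n_draws: int,
    recon: ReconConfig,
    seed: int | None = None,
) -> list[float]:
    """SA biases (est - true) over repeated small draws; sign pattern is the
    directional check for the small-sample downward bias of large cohorts."""
    rng = np.random.default_rng(seed)
    biases = []
    for r in range(n_draws):
        draw = rng.choice(genotypes.n, size=draw_size, replace=False)
        sub = genotypes.subset([genotypes.ids[int(i)] for i in sorted(draw)])
        run_seed = None if recon.seed is None else (int(recon.seed) + 7 * r) % 2**31
        part = reconstruct(sub, recon.replace(seed=run_seed))
        est = sa_nb(sibship_frequencies(part), estimate_alpha(sub)).value
        if math.isfinite(est):
            biases.append(est - true_nb)
    return biases
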