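# Methods

## Scope and model

`sibnb` estimates the effective number of breeders *N*<sub>b</sub> of the
parental group behind a single offspring cohort, from offspring genotypes
alone, via sibship reconstruction. It contains a generative model of
hatchery-style breeding (the simulator), an inference engine (the
reconstructor), the two estimators (SA and PwoP), and the evaluation designs
that score them against simulated truth. Everything downstream of the
simulator sees only offspring genotypes; pedigree truth is used exclusively
for scoring.

## Simulator

**Breeding structure.** Spawning is modelled as hatcheries run it: every
female is crossed once; males are drawn from an unused pool, and with
probability `male_reuse_rate` (default 0.05) — or by necessity whenever
females outnumber unused males — a previously used male, drawn uniformly,
serves a second female. Each cross is independently flagged with probability
`contamination_rate` (default 0.02) and flagged crosses are merged pairwise
into 2♂×2♀ cross-matrices in which every offspring draws its sire and dam
uniformly. The reuse and contamination defaults encode "predominantly
monogamous with a small, known amount of polygamy"; neither rate is published
as a number, so they are fixed package choices. Capacity is validated
up-front: a configuration needing more than two crosses per male is an
error.

**Family sizes.** Offspring counts over mating units follow a symmetric
Dirichlet-multinomial with concentration θ (`fecundity_dispersion`). One
parameter controls the whole shape: small θ produces the long tail of
zero-offspring parents that drives *N*<sub>b</sub>/*N*<sub>C</sub> well below
1, θ→∞ gives a maximally even allocation (implemented exactly: floor split
plus randomly placed remainders). The default θ = 0.45 puts
*N*<sub>b</sub>/*N*<sub>C</sub> near 0.30 at hatchery-scale configurations,
matching the 0.27–0.34 band observed across the five reference populations;
`calibrate_dispersion` bisects θ in log space against the PwoP-on-truth
oracle (mean over ≥20 pedigree replicates) when a specific ratio is wanted.
A target above what the θ ceiling delivers raises an error naming the
achievable bound, except when it is within tolerance of the ceiling ratio, in
which case the ceiling is returned flagged `at_ceiling`.

**Genotypes.** 95 biallelic SNPs by default, minor-allele frequency uniform
on [0.1, 0.5] per locus (the real panel's frequency spectrum is not
published; both bounds are user-tunable). Founders are Hardy–Weinberg draws;
transmission is fair Mendelian. Genotyping error is a single catch-all
uniform miscall: with probability *e* the observed code is replaced by one of
the other two codes uniformly. This mirrors treating dropout, miscalls and
mutations as one rate; the study conditions are *e* ∈ {0.0001, 0.001, 0.01}.
Missingness (default 0) is independent per genotype. Offspring carry no
cohort-year structure — return years are pooled, as the reference design
pools them.

**Determinism.** Pedigree and genotype streams are separate substreams of
the config seed; identical seeds give byte-identical outputs.

## Reconstruction

**Likelihood.** Each offspring has a latent sire and latent dam (separate
label namespaces). Latent parental genotypes have Hardy–Weinberg priors at
the sample allele frequencies (allele-count estimates clamped to
[1/(4m), 1−1/(4m)] at each locus, m = non-missing count; frequencies stay
fixed during search). Observations pass through the same uniform miscall
model with an *assumed* rate that may deliberately differ from the simulated
one. The configuration likelihood is exact: per locus, parental genotypes
are marginalised jointly over each connected component of the latent
parent–offspring graph by variable elimination (greedy min-width ordering,
per-locus rescaling against underflow). Two-parent components — full-sib
clusters — use a closed 3×3 contraction; components above
`max_component_parents` (default 12) fall back to a mean-field lower bound
(iterated single-parent updates) and flag the partition as approximate.
Missing genotypes contribute likelihood 1. With assumed *e* > 0 every
observation has positive probability, so no configuration scores −∞.

**Search.** Simulated annealing from the all-singleton configuration with
restarts (defaults: 20 restarts × 50 sweeps of n proposals, geometric
cooling 0.95 per sweep). The move set is: move one offspring to another
family (or a fresh singleton), merge two families, split a family, and —
under polygamy — reassign an offspring's sire or dam independently; under
female monogamy, dams move between sires as units. The initial temperature,
when not given, is tuned so roughly half of early downhill moves accept
(median downhill cost / ln 2). Proposals are guided: a precomputed pairwise
full-sib log-likelihood-ratio matrix supplies, for each offspring, the set
of plausible co-sibs, and 60% of move/merge proposals target the family of a
sampled candidate. Guidance only shapes the proposal distribution — the
Metropolis step always uses the exact configuration likelihood, and the
returned configuration never scores below the all-singleton start. During
polygamy search, proposals that would grow a component beyond the parent cap
are vetoed outright, keeping marginalisation exact; real sibship components
at these scales sit far below the cap. No sibship-size prior is imposed
(uniform over configurations); search effort (restarts, sweeps) is an
optimizer knob, distinct from the study conditions.

**Mating systems.** `monogamy` constrains sires and dams to pair 1:1, so the
output can contain no half-sib dyads — true half-sibs are necessarily forced
into full-sib or unrelated calls, exactly the behaviour being studied.
`male_polygamy_female_monogamy` ties each dam to one sire but lets sires
span dams. `polygamy` is unconstrained.

## Estimators

`sa_nb` implements the sibship-frequency estimator with nonrandom-mating
correction; *Q* definitions are exclusive (*Q*₁ excludes full sibs), so
*Q*₁+*Q*₃ is the probability of sharing a sire and the parental-count
substitutions 1/*N*₁ = *Q*₁+*Q*₃, 1/*N*₂ = *Q*₂+*Q*₃ need no division. α is
1 − H̄obs/H̄exp pooled over loci as a ratio of averages (more stable at ~95
loci than averaging per-locus ratios), clipped to [−1, 1], and estimated
from the current sample — never assumed zero. `pwop_nb` is shared verbatim
between truth computation and partition-based estimation, so
PwoP-on-true-partition reproduces true *N*<sub>b</sub> by construction — an
identity the tests assert. Infinity is a first-class estimate value
(returned, propagated, counted — never raised), because the smallest draws
legitimately produce it. Estimates are kept unrounded internally; the CLI
additionally prints integer-rounded values, the convention for reported
*N*<sub>b</sub>.

Under monogamy with α = 0 the two estimators obey
SA/PwoP = 2(n−1)/(2n−1) exactly for any clustering — hence they can never
differ by more than 100/(2n−1) percent, which is below 7% for n ≥ 8. With α
estimated, differences stay of the same order for near-Hardy-Weinberg
samples.

## Evaluation designs

- **Confusion matrices**: exhaustive 3×3 cross-tabulation of true vs
  inferred FS/HS/U over all C(n,2) dyads, with type-I (unrelated called sib)
  and type-II (related called non-sib) totals.
- **Subsampling**: fractions 10%…90%, 10 replicate draws each, without
  replacement within a draw, full replacement between draws; draw size is
  floor(f·n), which reproduces every published draw size. Per fraction:
  average bias, average and absolute-average percent bias, percent RMSB
  (100·√(mean of squared relative errors over the finite estimates)),
  standard deviation, and the count of infinite estimates excluded.
- **Concordance**: SA and PwoP from identical partitions; percent difference
  is 100·|SA−PwoP|/PwoP (the reference convention is unstated; this is a
  documented package choice). Runs with infinite PwoP are excluded and
  counted. A ratio histogram is produced.
- **Grid**: populations × mating systems × assumed error rates, each cell a
  reconstruction scored by confusion matrix and both estimators; the
  standard design is 5 × 3 × 3 = 45 cells, and the subsampling design over
  five populations schedules 450 runs.

## Problem sizes and what the tests show

The shipped tests and the acceptance script run at desk scale: cohorts of
20–400 offspring (one 1,516-offspring pedigree for arithmetic and
small-draw bias checks), 95 loci, light search budgets (3–5 restarts,
20–30 sweeps) that the guided proposals make sufficient — at these sizes
heavier search does not change the recovered partitions materially. At
these scales the package reproduces the qualitative findings: full-sib and
unrelated dyad recovery above 95% and 99% under monogamy at 95 SNPs,
half-sib recovery poor under polygamy, SA-vs-PwoP differences within 7%,
and downward-biased estimates when draws are much smaller than true
*N*<sub>b</sub> in cohorts where forced male reuse creates many half-sib
dyads (the sign, not the magnitude, is asserted — the magnitude depends on
reconstruction details that differ between implementations).

The simulator emulates the *statistical* structure of hatchery cohorts —
family-size skew, male reuse, cross-contamination, biallelic SNPs with
uniform MAF spectrum and uniform miscalls. It does not emulate linkage,
age structure, iteroparity, sex-biased survival, locus-specific error, or
the real panel's allele-frequency spectrum. Passing tests therefore
demonstrate correctness of the estimators and the reconstruction machinery
under the stated model, not performance guarantees on any particular
empirical panel.

## Known limitations

- Free-polygamy search is the weakest link: with only ~95 SNPs, half-sib
  components are barely identifiable (this is the scientific finding, but it
  also means the search surface is flat; expect low HS recovery).
- No confidence intervals; a dyad bootstrap would be straightforward but is
  out of scope.
- Parentage with candidate parental genotypes, sibship-size priors, and
  Bayesian pedigree posteriors are out of scope.
- `--threads` is accepted for interface stability but currently runs
  sequentially; results are seed-deterministic either way.
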