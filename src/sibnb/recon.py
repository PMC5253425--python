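"""Full-likelihood sibship reconstruction from offspring genotypes alone.

The model: each offspring has a latent sire and latent dam. Latent parent
genotypes carry Hardy-Weinberg priors at the sample allele frequencies,
offspring genotypes arise by fair Mendelian transmission, and observations
pass through a uniform miscall model (with probability e the true code is
replaced by one of the other two codes). The likelihood of a configuration
is exact: per locus, parental genotypes are marginalised jointly over each
connected component of the latent parent-offspring graph by variable
elimination (components above a parent-count cap fall back to a flagged
mean-field approximation). Missing genotypes contribute likelihood 1.

The search is simulated annealing over sibship configurations, started from
all singletons, with restarts; the mating-system assumption constrains the
move set (monogamy permits only disjoint full-sib clusters; female monogamy
ties each dam to a single sire; full polygamy reassigns sires and dams
independently).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .data import (
    MALE_POLYGAMY_FEMALE_MONOGAMY,
    MATING_SYSTEMS,
    MISSING,
    MONOGAMY,
    POLYGAMY,
    DyadLabelSet,
    GenotypeTable,
    SibshipPartition,
)


class LocusError(ValueError):
    pass


class ComponentTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class ReconConfig:
    """Search and model settings for sibship reconstruction.

    ``error_rate`` is the *assumed* miscall rate; it may deliberately differ
    from the rate used to simulate the data. ``sweeps`` counts annealing
    sweeps per restart (one sweep = n proposals); cooling is geometric per
    sweep. ``initial_temperature=None`` auto-tunes so roughly half of early
    uphill-cost moves are accepted. ``max_component_parents`` caps exact
    marginalisation under polygamy.
    """

    mating_system: str = MONOGAMY
    error_rate: float = 0.01
    seed: int | None = None
    restarts: int = 20
    sweeps: int = 50
    cooling: float = 0.95
    initial_temperature: float | None = None
    max_component_parents: int = 12
    allow_approximate: bool = True

    def validate(self) -> None:
        if self.mating_system not in MATING_SYSTEMS:
            raise ValueError(f"unknown mating system {self.mating_system!r}")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("assumed error_rate must lie in [0, 1)")
        if self.sweeps < 1 or self.restarts < 1:
            raise ValueError("sweeps and restarts must be >= 1")
        if self.max_component_parents < 2:
            raise ValueError("max_component_parents must be >= 2")

    def replace(self, **changes) -> "ReconConfig":
        return replace(self, **changes)


@dataclass
class AlleleFreqs:
    """Per-locus minor-allele frequencies estimated from the offspring sample."""

    loci: list[str]
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (len(self.loci),):
            raise ValueError("frequency vector inconsistent with loci")
        if np.any((self.freqs <= 0) | (self.freqs >= 1)):
            raise ValueError("allele frequencies must lie in (0, 1)")


def estimate_allele_freqs(genotypes: GenotypeTable) -> AlleleFreqs:
    """Allele-count frequencies per locus, clamped away from the 0/1 boundary.

    The clamp to [1/(4m), 1 - 1/(4m)] (m = non-missing genotypes at the
    locus) keeps Hardy-Weinberg priors proper at loci that happen to be
    monomorphic in the sample.
    """
    codes = genotypes.codes
    obs = codes != MISSING
    m = obs.sum(axis=0)
    bad = np.flatnonzero(m < 2)
    if bad.size:
        names = [genotypes.loci[int(j)] for j in bad]
        raise LocusError(f"loci with fewer than two non-missing genotypes: {names}")
    minor = np.where(obs, codes, 0).sum(axis=0, dtype=np.int64)
    p = minor / (2.0 * m)
    lo = 1.0 / (4.0 * m)
    p = np.clip(p, lo, 1.0 - lo)
    return AlleleFreqs(list(genotypes.loci), p)


def _transmission_tensor() -> np.ndarray:
    """T[gs, gd, gt]: Mendelian probability of offspring code gt given parents."""
    T = np.zeros((3, 3, 3))
    for gs in range(3):
        for gd in range(3):
            ps, pd = gs / 2.0, gd / 2.0
            for bs in (0, 1):
                for bd in (0, 1):
                    pr = (ps if bs else 1 - ps) * (pd if bd else 1 - pd)
                    T[gs, gd, bs + bd] += pr
    return T


_T = _transmission_tensor()

_CHUNK = 32  # offspring per product chunk before rescaling (underflow guard)


class SibshipLikelihood:
    """Exact configuration likelihood engine for one genotype table.

    Precomputes, for every offspring o and locus l, the 3x3 factor
    ``M[o, l, gs, gd] = sum_gt T[gs,gd,gt] * P(obs | gt, e)`` so cluster and
    component likelihoods reduce to products and small contractions.
    """

    def __init__(self, genotypes: GenotypeTable, freqs: AlleleFreqs, error_rate: float):
        if freqs.loci != genotypes.loci:
            raise ValueError("allele frequencies do not align with genotype loci")
        if not 0.0 <= error_rate < 1.0:
            raise ValueError("error rate must lie in [0, 1)")
        self.n = genotypes.n
        self.L = genotypes.n_loci
        p = freqs.freqs
        self.prior = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)  # (L,3)
        self.pair_prior = self.prior[:, :, None] * self.prior[:, None, :]  # (L,3,3)

        codes = genotypes.codes
        w = np.full((self.n, self.L, 3), error_rate / 2.0)
        for g in range(3):
            w[..., g][codes == g] = 1.0 - error_rate
        w[codes == MISSING] = 1.0  # marginalised out
        self.obs_weight = w
        self.M = np.einsum("abg,nlg->nlab", _T, w)  # (n, L, 3, 3)

    # -- two-parent (full-sib cluster) fast path ---------------------------

    def cluster_loglik(self, members) -> float:
        """log P(observed genotypes of a full-sib cluster sharing one sire+dam)."""
        members = np.asarray(members, dtype=np.int64)
        if members.size == 0:
            return 0.0
        P, logscale = self._member_product(members)
        per_locus = (self.pair_prior * P).sum(axis=(1, 2))
        with np.errstate(divide="ignore"):
            return float((np.log(per_locus) + logscale).sum())

    def _member_product(self, members: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if members.size <= _CHUNK:
            return self.M[members].prod(axis=0), np.zeros(self.L)
        P = np.ones((self.L, 3, 3))
        logscale = np.zeros(self.L)
        for k in range(0, members.size, _CHUNK):
            P = P * self.M[members[k : k + _CHUNK]].prod(axis=0)
            s = P.max(axis=(1, 2))
            s = np.where(s > 0, s, 1.0)
            P /= s[:, None, None]
            with np.errstate(divide="ignore"):
                logscale += np.log(s)
        return P, logscale

    def singleton_loglik_total(self) -> float:
        """Sum of per-offspring marginal log-likelihoods (the all-singleton start)."""
        return sum(self.cluster_loglik([i]) for i in range(self.n))

    def pairwise_fs_logratio(self) -> np.ndarray:
        """log LR of 'i and j are full sibs' vs 'unrelated', for all pairs.

        Used to guide annealing proposals toward plausible sib merges; the
        accept/reject step still uses the exact configuration likelihood.
        """
        single = np.array([self.cluster_loglik([i]) for i in range(self.n)])
        out = np.empty((self.n, self.n))
        for i in range(self.n):
            A = self.pair_prior * self.M[i]  # (L,3,3)
            lik = np.einsum("lab,jlab->jl", A, self.M)
            with np.errstate(divide="ignore"):
                out[i] = np.log(lik).sum(axis=1)
        out -= single[None, :]
        out -= single[:, None]
        np.fill_diagonal(out, -np.inf)
        return out

    # -- general component path -------------------------------------------

    def component_loglik(
        self,
        off_idx,
        off_sires,
        off_dams,
        max_parents: int = 12,
        allow_approximate: bool = True,
    ) -> tuple[float, bool]:
        """Joint marginal log-likelihood of one connected latent-parent component.

        ``off_sires``/``off_dams`` give each offspring's latent labels; sire
        and dam namespaces are distinct. Returns (loglik, approximated).
        """
        off_idx = list(off_idx)
        svars = [("S", int(s)) for s in off_sires]
        dvars = [("D", int(d)) for d in off_dams]
        parents = sorted(set(svars) | set(dvars))
        if len(parents) == 2 and len(set(svars)) == 1 and len(set(dvars)) == 1:
            return self.cluster_loglik(np.asarray(off_idx)), False
        factors: list[tuple[tuple, np.ndarray]] = [((v,), self.prior) for v in parents]
        for o, sv, dv in zip(off_idx, svars, dvars):
            factors.append(((sv, dv), self.M[o]))
        if len(parents) > max_parents:
            if not allow_approximate:
                raise ComponentTooLargeError(
                    f"component has {len(parents)} parents (cap {max_parents})"
                )
            return self._meanfield_loglik(parents, factors), True
        return self._ve_loglik(factors), False

    def _ve_loglik(self, factors) -> float:
        """Exact marginalisation by greedy variable elimination (per locus)."""
        factors = [(tuple(v), a) for v, a in factors]
        remaining = set()
        for v, _ in factors:
            remaining.update(v)
        logscale = np.zeros(self.L)
        while remaining:
            def _width(var):
                u = set()
                for fv, _ in factors:
                    if var in fv:
                        u.update(fv)
                return len(u)

            var = min(sorted(remaining), key=_width)
            group = [f for f in factors if var in f[0]]
            rest = [f for f in factors if var not in f[0]]
            union: list = []
            for fv, _ in group:
                for v in fv:
                    if v not in union:
                        union.append(v)
            prod = np.ones((self.L,) + (3,) * len(union))
            for fv, arr in group:
                prod = prod * _align(arr, fv, union)
            new = prod.sum(axis=1 + union.index(var))
            new_vars = tuple(v for v in union if v != var)
            s = new.max(axis=tuple(range(1, new.ndim))) if new.ndim > 1 else new
            s = np.where(s > 0, s, 1.0)
            new = new / s.reshape((self.L,) + (1,) * (new.ndim - 1))
            with np.errstate(divide="ignore"):
                logscale += np.log(s)
            factors = rest + [(new_vars, new)]
            remaining.discard(var)
        lik = np.ones(self.L)
        for _, arr in factors:
            lik = lik * arr
        with np.errstate(divide="ignore"):
            return float((np.log(lik) + logscale).sum())

    def _meanfield_loglik(self, parents, factors) -> float:
        """Naive mean-field lower bound, iterated single-parent updates."""
        beliefs = {v: self.prior.copy() for v in parents}
        logf = {}
        for fv, arr in factors:
            with np.errstate(divide="ignore"):
                logf[fv] = np.maximum(np.log(arr), -745.0)
        for _ in range(60):
            delta = 0.0
            for v in parents:
                field = np.zeros((self.L, 3))
                for fv, la in logf.items():
                    if v not in fv:
                        continue
                    if len(fv) == 1:
                        field += la
                    else:
                        other = fv[0] if fv[1] == v else fv[1]
                        b = beliefs[other]
                        if fv[0] == v:
                            field += np.einsum("lab,lb->la", la, b)
                        else:
                            field += np.einsum("lab,la->lb", la, b)
                field -= field.max(axis=1, keepdims=True)
                nb = np.exp(field)
                nb /= nb.sum(axis=1, keepdims=True)
                delta = max(delta, float(np.abs(nb - beliefs[v]).max()))
                beliefs[v] = nb
            if delta < 1e-10:
                break
        elbo = np.zeros(self.L)
        for fv, la in logf.items():
            if len(fv) == 1:
                elbo += np.einsum("la,la->l", beliefs[fv[0]], la)
            else:
                elbo += np.einsum("la,lb,lab->l", beliefs[fv[0]], beliefs[fv[1]], la)
        for v in parents:
            b = beliefs[v]
            elbo -= np.einsum("la,la->l", b, np.where(b > 0, np.log(np.maximum(b, 1e-300)), 0.0))
        return float(elbo.sum())


def _align(arr: np.ndarray, fvars, union) -> np.ndarray:
    """Broadcast a (L, 3^k) factor onto the (L, 3^len(union)) axis layout."""
    fvars = list(fvars)
    perm = [0] + [1 + fvars.index(v) for v in union if v in fvars]
    a = arr.transpose(perm)
    shape = [arr.shape[0]] + [3 if v in fvars else 1 for v in union]
    return a.reshape(shape)


def config_log_likelihood(
    partition: SibshipPartition,
    genotypes: GenotypeTable,
    freqs: AlleleFreqs | None = None,
    error_rate: float = 0.01,
    max_component_parents: int = 12,
    allow_approximate: bool = True,
) -> float:
    """Exact log-likelihood of a sibship configuration given offspring genotypes."""
    if freqs is None:
        freqs = estimate_allele_freqs(genotypes)
    if list(partition.ids) != list(genotypes.ids):
        genotypes = genotypes.subset(list(partition.ids))
    engine = SibshipLikelihood(genotypes, freqs, error_rate)
    total = 0.0
    for off_idx, s_lab, d_lab in _components(partition.sires, partition.dams):
        ll, _ = engine.component_loglik(
            off_idx, s_lab, d_lab, max_parents=max_component_parents,
            allow_approximate=allow_approximate,
        )
        total += ll
    return total


def _components(sires: np.ndarray, dams: np.ndarray):
    """Connected components of the latent sire-dam graph linked by offspring.

    Yields (offspring indices, their sire labels, their dam labels).
    """
    n = len(sires)
    by_sire: dict[int, list[int]] = {}
    by_dam: dict[int, list[int]] = {}
    for k in range(n):
        by_sire.setdefault(int(sires[k]), []).append(k)
        by_dam.setdefault(int(dams[k]), []).append(k)
    seen_off = np.zeros(n, dtype=bool)
    for start in range(n):
        if seen_off[start]:
            continue
        stack = [start]
        comp: list[int] = []
        seen_off[start] = True
        while stack:
            o = stack.pop()
            comp.append(o)
            for sib in by_sire[int(sires[o])] + by_dam[int(dams[o])]:
                if not seen_off[sib]:
                    seen_off[sib] = True
                    stack.append(sib)
        comp.sort()
        yield comp, sires[comp], dams[comp]


def classify_dyads(partition: SibshipPartition) -> DyadLabelSet:
    """FS/HS/U labels over all C(n,2) pairs implied by a sibship partition."""
    if partition.n < 2:
        raise ValueError("need at least two offspring to classify dyads")
    return DyadLabelSet.from_parent_codes(partition.ids, partition.sires, partition.dams)


def reconstruct(genotypes: GenotypeTable, config: ReconConfig) -> SibshipPartition:
    """Maximum-likelihood sibship reconstruction by simulated annealing.

    Starts from the all-singleton configuration; the returned configuration's
    log-likelihood never falls below that start. Deterministic given
    ``config.seed``. Individuals with no genotypes at all are excluded with a
    warning.
    """
    config.validate()
    if genotypes.n < 2:
        raise ValueError("need at least two genotyped offspring")
    all_missing = (genotypes.codes == MISSING).all(axis=1)
    if all_missing.any():
        dropped = [genotypes.ids[int(i)] for i in np.flatnonzero(all_missing)]
        warnings.warn(f"excluding individuals with no genotypes: {dropped}", stacklevel=2)
        keep = [i for i, m in zip(genotypes.ids, all_missing) if not m]
        genotypes = genotypes.subset(keep)
    freqs = estimate_allele_freqs(genotypes)
    engine = SibshipLikelihood(genotypes, freqs, config.error_rate)
    rng = np.random.default_rng(config.seed)
    if config.mating_system == MONOGAMY:
        assign, loglik = _anneal_monogamy(engine, config, rng)
        return SibshipPartition(
            list(genotypes.ids), assign, assign.copy(),
            mating_system=MONOGAMY, log_likelihood=loglik,
        )
    sires, dams, loglik, approx = _anneal_pedigree(engine, config, rng)
    return SibshipPartition(
        list(genotypes.ids), sires, dams,
        mating_system=config.mating_system, log_likelihood=loglik, approximate=approx,
    )


# ---------------------------------------------------------------------------
# monogamy annealer: state is a disjoint full-sib clustering


def _initial_temperature(deltas: list[float]) -> float:
    downhill = [-d for d in deltas if d < 0]
    if not downhill:
        return 1.0
    return float(np.median(downhill)) / math.log(2.0)


def _sib_partners(pair_lr: np.ndarray) -> list[np.ndarray]:
    """Candidate co-sib lists per offspring: pairs with positive FS log-LR."""
    return [np.flatnonzero(row > 0.0) for row in pair_lr]


def _anneal_monogamy(
    engine: SibshipLikelihood, config: ReconConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    n = engine.n
    single = np.array([engine.cluster_loglik([i]) for i in range(n)])
    best_assign = np.arange(n)
    best_total = float(single.sum())
    pair_lr = engine.pairwise_fs_logratio()
    partners = _sib_partners(pair_lr)

    t0 = config.initial_temperature
    if t0 is None:
        probe: list[float] = []
        for _ in range(min(100, 4 * n)):
            i, j = rng.integers(n), rng.integers(n)
            if i == j:
                continue
            probe.append(float(pair_lr[int(i), int(j)]))
        t0 = _initial_temperature(probe)

    def sample_partner(o: int) -> int | None:
        cand = partners[o]
        if cand.size == 0:
            return None
        return int(cand[int(rng.integers(cand.size))])

    for _ in range(config.restarts):
        assign = np.arange(n)
        members: dict[int, list[int]] = {i: [i] for i in range(n)}
        lik: dict[int, float] = {i: float(single[i]) for i in range(n)}
        total = float(single.sum())
        next_id = n
        temp = t0
        for _sweep in range(config.sweeps):
            for _p in range(n):
                kind = rng.random()
                if kind < 0.7 or len(members) < 2:
                    o = int(rng.integers(n))
                    src = int(assign[o])
                    # guided target: the cluster of a plausible co-sib
                    j = sample_partner(o) if rng.random() < 0.6 else None
                    if j is not None and int(assign[j]) != src:
                        tgt = int(assign[j])
                        make_new = False
                    else:
                        cids = list(members)
                        tgt = cids[int(rng.integers(len(cids)))]
                        make_new = tgt == src or rng.random() < 1.0 / (len(cids) + 1)
                    if make_new and len(members[src]) == 1:
                        continue
                    src_rest = [x for x in members[src] if x != o]
                    new_src = engine.cluster_loglik(src_rest) if src_rest else 0.0
                    if make_new:
                        new_tgt = float(single[o])
                        delta = new_src + new_tgt - lik[src]
                        accept = delta >= 0 or rng.random() < math.exp(delta / temp)
                        if accept:
                            members[src] = src_rest
                            lik[src] = new_src
                            if not src_rest:
                                del members[src], lik[src]
                            members[next_id] = [o]
                            lik[next_id] = new_tgt
                            assign[o] = next_id
                            next_id += 1
                            total += delta
                    else:
                        if tgt == src:
                            continue
                        new_tgt = engine.cluster_loglik(members[tgt] + [o])
                        delta = new_src + new_tgt - lik[src] - lik[tgt]
                        accept = delta >= 0 or rng.random() < math.exp(delta / temp)
                        if accept:
                            members[src] = src_rest
                            lik[src] = new_src
                            if not src_rest:
                                del members[src], lik[src]
                            members[tgt] = members[tgt] + [o]
                            lik[tgt] = new_tgt
                            assign[o] = tgt
                            total += delta
                elif kind < 0.85:
                    cids = list(members)
                    o = int(rng.integers(n))
                    j = sample_partner(o) if rng.random() < 0.6 else None
                    if j is not None and int(assign[j]) != int(assign[o]):
                        ca, cb = int(assign[o]), int(assign[j])
                    else:
                        a, b = rng.choice(len(cids), size=2, replace=False)
                        ca, cb = cids[int(a)], cids[int(b)]
                    new = engine.cluster_loglik(members[ca] + members[cb])
                    delta = new - lik[ca] - lik[cb]
                    if delta >= 0 or rng.random() < math.exp(delta / temp):
                        members[ca] = members[ca] + members[cb]
                        lik[ca] = new
                        for o in members[cb]:
                            assign[o] = ca
                        del members[cb], lik[cb]
                        total += delta
                else:
                    big = [c for c, ms in members.items() if len(ms) >= 2]
                    if not big:
                        continue
                    c = big[int(rng.integers(len(big)))]
                    ms = members[c]
                    side = rng.random(len(ms)) < 0.5
                    if side.all() or not side.any():
                        side[int(rng.integers(len(ms)))] ^= True
                    left = [o for o, s in zip(ms, side) if s]
                    right = [o for o, s in zip(ms, side) if not s]
                    new_l = engine.cluster_loglik(left)
                    new_r = engine.cluster_loglik(right)
                    delta = new_l + new_r - lik[c]
                    if delta >= 0 or rng.random() < math.exp(delta / temp):
                        members[c] = left
                        lik[c] = new_l
                        members[next_id] = right
                        lik[next_id] = new_r
                        for o in right:
                            assign[o] = next_id
                        next_id += 1
                        total += delta
                if total > best_total:
                    best_total = total
                    best_assign = assign.copy()
            temp = max(temp * config.cooling, 1e-9)

    return _canonical_labels(best_assign), best_total


def _canonical_labels(assign: np.ndarray) -> np.ndarray:
    seen: dict[int, int] = {}
    out = np.empty_like(assign)
    for k, a in enumerate(assign.tolist()):
        out[k] = seen.setdefault(a, len(seen))
    return out


# ---------------------------------------------------------------------------
# polygamy / female-monogamy annealer: state is (sire, dam) label arrays


class _PedigreeState:
    """Mutable latent-parent assignment with component-local likelihood."""

    def __init__(self, engine: SibshipLikelihood, config: ReconConfig):
        self.engine = engine
        self.cfg = config
        n = engine.n
        self.sires = np.arange(n)
        self.dams = np.arange(n)
        self.next_sire = n
        self.next_dam = n
        self.approx_used = False
        self._cache: dict[tuple, float] = {}
        self.total = float(
            sum(engine.cluster_loglik([i]) for i in range(n))
        )

    def _component_of(self, var: tuple[str, int]) -> tuple[list[int], frozenset]:
        """Offspring of the component containing a parent var; set of its vars."""
        kind, lab = var
        n = self.engine.n
        if kind == "S":
            seed = [k for k in range(n) if self.sires[k] == lab]
        else:
            seed = [k for k in range(n) if self.dams[k] == lab]
        if not seed:
            return [], frozenset()
        seen = set(seed)
        stack = list(seed)
        vars_seen = set()
        while stack:
            o = stack.pop()
            vars_seen.add(("S", int(self.sires[o])))
            vars_seen.add(("D", int(self.dams[o])))
            for k in range(n):
                if k not in seen and (
                    self.sires[k] == self.sires[o] or self.dams[k] == self.dams[o]
                ):
                    seen.add(k)
                    stack.append(k)
        return sorted(seen), frozenset(vars_seen)

    def oversized(self, varset: set[tuple[str, int]]) -> bool:
        """Would any component touching these vars exceed the parent cap?

        Used to veto proposals during search, keeping marginalisation exact;
        real sibship components at hatchery scales are far below the cap.
        """
        for var in varset:
            off, vs = self._component_of(var)
            if off and len(vs) > self.cfg.max_component_parents:
                return True
        return False

    def loglik_of_vars(self, varset: set[tuple[str, int]]) -> float:
        done: set[frozenset] = set()
        total = 0.0
        for var in sorted(varset):
            off, vs = self._component_of(var)
            if not off or vs in done:
                continue
            done.add(vs)
            key = (tuple(off), tuple(self.sires[off].tolist()), tuple(self.dams[off].tolist()))
            ll = self._cache.get(key)
            if ll is None:
                ll, approx = self.engine.component_loglik(
                    off, self.sires[off], self.dams[off],
                    max_parents=self.cfg.max_component_parents,
                    allow_approximate=self.cfg.allow_approximate,
                )
                if approx:
                    self.approx_used = True
                if len(self._cache) > 100_000:
                    self._cache.clear()
                self._cache[key] = ll
            total += ll
        return total


def _anneal_pedigree(
    engine: SibshipLikelihood, config: ReconConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    n = engine.n
    female_mono = config.mating_system == MALE_POLYGAMY_FEMALE_MONOGAMY
    best = None
    pair_lr = engine.pairwise_fs_logratio()
    partners = _sib_partners(pair_lr)

    t0 = config.initial_temperature
    if t0 is None:
        probe = []
        for _ in range(min(100, 4 * n)):
            i, j = rng.integers(n), rng.integers(n)
            if i == j:
                continue
            probe.append(float(pair_lr[int(i), int(j)]))
        t0 = _initial_temperature(probe)

    for _ in range(config.restarts):
        state = _PedigreeState(engine, config)
        temp = t0
        if best is None or state.total > best[2]:
            best = (state.sires.copy(), state.dams.copy(), state.total)
        for _sweep in range(config.sweeps):
            for _p in range(n):
                _propose_pedigree_move(state, rng, temp, female_mono, partners)
                if state.total > best[2]:
                    best = (state.sires.copy(), state.dams.copy(), state.total)
            temp = max(temp * config.cooling, 1e-9)

    sires, dams, total = best
    return (
        _canonical_labels(sires),
        _canonical_labels(dams),
        total,
        _any_approx(engine, sires, dams, config),
    )


def _any_approx(engine, sires, dams, config) -> bool:
    for _, s_lab, d_lab in _components(sires, dams):
        if len(set(("S", int(s)) for s in s_lab) | set(("D", int(d)) for d in d_lab)) > config.max_component_parents:
            return True
    return False


def _propose_pedigree_move(
    state: _PedigreeState,
    rng: np.random.Generator,
    temp: float,
    female_mono: bool,
    partners: list[np.ndarray],
) -> None:
    n = state.engine.n
    o = int(rng.integers(n))

    def sample_partner(i: int) -> int | None:
        cand = partners[i]
        if cand.size == 0:
            return None
        return int(cand[int(rng.integers(cand.size))])

    if female_mono:
        # move an offspring between dams (inheriting the dam's sire), or
        # reassign a dam (and all her offspring) to another sire
        if rng.random() < 0.7:
            old_d = int(state.dams[o])
            j = sample_partner(o) if rng.random() < 0.6 else None
            if j is not None and int(state.dams[j]) != old_d:
                new_d = int(state.dams[j])
                new_s = int(state.sires[j])
            else:
                dam_labels = sorted(set(state.dams.tolist()))
                pick = int(rng.integers(len(dam_labels) + 1))
                if pick == len(dam_labels):
                    new_d, new_s = state.next_dam, state.next_sire
                else:
                    new_d = dam_labels[pick]
                    if new_d == old_d:
                        return
                    new_s = int(state.sires[state.dams == new_d][0])
            _apply_offspring_move(state, rng, temp, o, new_s, new_d, move_both=True)
        else:
            old_d = int(state.dams[o])
            sire_labels = sorted(set(state.sires.tolist()))
            pick = int(rng.integers(len(sire_labels) + 1))
            new_s = state.next_sire if pick == len(sire_labels) else sire_labels[pick]
            dam_off = np.flatnonzero(state.dams == old_d)
            old_s = int(state.sires[dam_off[0]])
            if new_s == old_s:
                return
            affected = {("S", old_s), ("S", new_s), ("D", old_d)}
            before = state.loglik_of_vars(affected)
            saved = state.sires[dam_off].copy()
            state.sires[dam_off] = new_s
            if state.oversized(affected):
                state.sires[dam_off] = saved
                return
            after = state.loglik_of_vars(affected)
            delta = after - before
            if delta >= 0 or rng.random() < math.exp(delta / temp):
                state.total += delta
                if new_s == state.next_sire:
                    state.next_sire += 1
            else:
                state.sires[dam_off] = saved
    else:
        which = rng.random()
        j = sample_partner(o) if rng.random() < 0.6 else None
        if which < 0.5:
            if j is not None and int(state.sires[j]) != int(state.sires[o]):
                new_s = int(state.sires[j])
            else:
                labels = sorted(set(state.sires.tolist()))
                pick = int(rng.integers(len(labels) + 1))
                new_s = state.next_sire if pick == len(labels) else labels[pick]
            if new_s == int(state.sires[o]):
                return
            _apply_offspring_move(state, rng, temp, o, new_s, int(state.dams[o]), move_both=False)
        else:
            if j is not None and int(state.dams[j]) != int(state.dams[o]):
                new_d = int(state.dams[j])
            else:
                labels = sorted(set(state.dams.tolist()))
                pick = int(rng.integers(len(labels) + 1))
                new_d = state.next_dam if pick == len(labels) else labels[pick]
            if new_d == int(state.dams[o]):
                return
            _apply_offspring_move(state, rng, temp, o, int(state.sires[o]), new_d, move_both=False)


def _apply_offspring_move(
    state: _PedigreeState,
    rng: np.random.Generator,
    temp: float,
    o: int,
    new_s: int,
    new_d: int,
    move_both: bool,
) -> None:
    old_s, old_d = int(state.sires[o]), int(state.dams[o])
    affected = {("S", old_s), ("D", old_d), ("S", new_s), ("D", new_d)}
    before = state.loglik_of_vars(affected)
    state.sires[o], state.dams[o] = new_s, new_d
    if state.oversized(affected):
        state.sires[o], state.dams[o] = old_s, old_d
        return
    after = state.loglik_of_vars(affected)
    delta = after - before
    if delta >= 0 or rng.random() < math.exp(delta / temp):
        state.total += delta
        if new_s == state.next_sire:
            state.next_sire += 1
        if new_d == state.next_dam:
            state.next_dam += 1
    else:
        state.sires[o], state.dams[o] = old_s, old_d
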