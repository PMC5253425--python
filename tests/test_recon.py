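"""Sibship likelihood engine and annealing search."""
import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sibnb
from sibnb.data import MISSING, SibshipPartition
from sibnb.recon import (
    LocusError,
    ReconConfig,
    SibshipLikelihood,
    _components,
    estimate_allele_freqs,
)


def _table(codes, rng=None):
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    return sibnb.GenotypeTable(
        [f"o{i}" for i in range(n)], [f"L{j}" for j in range(L)], codes
    )


def brute_force_loglik(engine, off_idx, off_sires, off_dams) -> float:
    """Enumerate every parental genotype combination (independent oracle)."""
    pvars = sorted(
        {("S", int(s)) for s in off_sires} | {("D", int(d)) for d in off_dams}
    )
    total = 0.0
    for l in range(engine.L):
        acc = 0.0
        for combo in itertools.product(range(3), repeat=len(pvars)):
            g = dict(zip(pvars, combo))
            pr = 1.0
            for v in pvars:
                pr *= engine.prior[l, g[v]]
            for o, s, d in zip(off_idx, off_sires, off_dams):
                pr *= engine.M[o, l, g[("S", int(s))], g[("D", int(d))]]
            acc += pr
        total += math.log(acc)
    return total


class TestAlleleFreqs:
    def test_all_heterozygous(self):
        gt = _table([[1, 1], [1, 1], [1, 1]])
        assert np.allclose(estimate_allele_freqs(gt).freqs, 0.5)

    def test_allele_counting(self):
        gt = _table([[0], [0], [2]])
        assert estimate_allele_freqs(gt).freqs[0] == pytest.approx(1 / 3)

    def test_monomorphic_locus_clamped_into_open_interval(self):
        gt = _table([[0], [0], [0], [0]])
        p = estimate_allele_freqs(gt).freqs[0]
        assert p == pytest.approx(1 / 16)

    def test_missing_locus_rejected_by_name(self):
        gt = _table([[0, MISSING], [1, MISSING]])
        with pytest.raises(LocusError, match="L1"):
            estimate_allele_freqs(gt)

    def test_large_sample_tracks_simulating_frequency(self):
        cfg = sibnb.SimConfig(n_females=250, n_males=250, total_offspring=500,
                              n_loci=10, maf_low=0.3, maf_high=0.3,
                              error_rate=0.0, seed=8)
        ped = sibnb.simulate_pedigree(cfg)
        gt = sibnb.simulate_genotypes(ped, cfg)
        p = estimate_allele_freqs(gt).freqs
        se = math.sqrt(0.3 * 0.7 / (2 * gt.n))
        assert np.all(np.abs(p - 0.3) < 4 * se)


class TestConfigLogLikelihood:
    def test_singleton_equals_hardy_weinberg_marginal(self, rng):
        codes = rng.integers(0, 3, size=(1, 6)).astype(np.int8)
        gt = _table(codes)
        freqs = sibnb.AlleleFreqs(gt.loci, np.full(6, 0.3))
        e = 0.01
        engine = SibshipLikelihood(gt, freqs, e)
        expected = 0.0
        for l in range(6):
            p = 0.3
            hw = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
            acc = sum(hw[g] * ((1 - e) if g == codes[0, l] else e / 2) for g in range(3))
            expected += math.log(acc)
        assert engine.cluster_loglik([0]) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("e", [0.0, 0.01])
    def test_two_fullsibs_match_nine_term_enumeration(self, e, rng):
        codes = rng.integers(0, 3, size=(2, 1)).astype(np.int8)
        gt = _table(codes)
        freqs = sibnb.AlleleFreqs(gt.loci, np.array([0.25]))
        engine = SibshipLikelihood(gt, freqs, e)
        ours = engine.cluster_loglik([0, 1])
        oracle = brute_force_loglik(engine, [0, 1], [0, 0], [0, 0])
        assert ours == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("e", [0.0, 0.01])
    def test_polygamy_component_matches_enumeration(self, e, rng):
        # 1 sire, 2 dams, 3 offspring: 27-term sum
        codes = rng.integers(0, 3, size=(3, 1)).astype(np.int8)
        gt = _table(codes)
        freqs = sibnb.AlleleFreqs(gt.loci, np.array([0.4]))
        engine = SibshipLikelihood(gt, freqs, e)
        part = SibshipPartition(gt.ids, np.array([0, 0, 0]), np.array([0, 0, 1]))
        ours = sibnb.config_log_likelihood(part, gt, freqs, e)
        oracle = brute_force_loglik(engine, [0, 1, 2], [0, 0, 0], [0, 0, 1])
        assert ours == pytest.approx(oracle, abs=1e-10)

    @given(st.integers(0, 10**6), st.sampled_from([0.0, 0.01]))
    @settings(max_examples=20)
    def test_random_components_match_enumeration(self, seed, e):
        """Exact marginalisation equals brute-force parental enumeration on
        every component with up to 4 latent parents."""
        rng = np.random.default_rng(seed)
        n, L = 5, 3
        codes = rng.integers(0, 3, size=(n, L)).astype(np.int8)
        gt = _table(codes)
        freqs = sibnb.AlleleFreqs(gt.loci, rng.uniform(0.1, 0.5, L))
        engine = SibshipLikelihood(gt, freqs, e)
        sires = rng.integers(0, 2, n)
        dams = rng.integers(0, 2, n)
        part = SibshipPartition(gt.ids, sires, dams)
        ours = sibnb.config_log_likelihood(part, gt, freqs, e)
        oracle = sum(
            brute_force_loglik(engine, list(c), s, d)
            for c, s, d in _components(sires, dams)
        )
        assert ours == pytest.approx(oracle, abs=1e-10)

    def test_loglik_monotone_in_loci(self, rng):
        codes = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        part = SibshipPartition.from_clusters([["o0", "o1"], ["o2", "o3"]])
        prev = 0.0
        for L in range(1, 11):
            gt = _table(codes[:, :L])
            ll = sibnb.config_log_likelihood(part, gt, error_rate=0.01)
            assert ll <= prev + 1e-12
            prev = ll

    def test_missing_genotypes_contribute_likelihood_one(self, rng):
        codes = rng.integers(0, 3, size=(2, 4)).astype(np.int8)
        gt_full = _table(codes)
        codes_miss = codes.copy()
        codes_miss[:, 3] = MISSING
        gt_miss = _table(codes_miss)
        part = SibshipPartition.from_clusters([["o0", "o1"]])
        freqs = sibnb.AlleleFreqs(gt_full.loci, np.full(4, 0.3))
        full3 = sibnb.config_log_likelihood(part, _table(codes[:, :3]),
                                            sibnb.AlleleFreqs(gt_full.loci[:3], np.full(3, 0.3)),
                                            0.01)
        with_missing = sibnb.config_log_likelihood(part, gt_miss, freqs, 0.01)
        assert with_missing == pytest.approx(full3, abs=1e-12)

    def test_positive_error_rate_never_gives_minus_infinity(self, rng):
        """With assumed e > 0 the miscall model makes every observation
        possible, so no configuration scores -inf."""
        for _ in range(10):
            n = 6
            codes = rng.integers(0, 3, size=(n, 8)).astype(np.int8)
            gt = _table(codes)
            freqs = sibnb.AlleleFreqs(gt.loci, rng.uniform(0.05, 0.5, 8))
            part = SibshipPartition(
                gt.ids, rng.integers(0, 3, n), rng.integers(0, 3, n)
            )
            ll = sibnb.config_log_likelihood(part, gt, freqs, 0.01)
            assert math.isfinite(ll)


class TestReconstruct:
    def test_perfect_information_recovers_truth_exactly(self):
        """500 error-free loci, families of 5, monogamy: clusters == truth."""
        cfg = sibnb.SimConfig(n_females=5, n_males=5, total_offspring=25,
                              male_reuse_rate=0.0, contamination_rate=0.0,
                              n_loci=500, error_rate=0.0,
                              fecundity_dispersion=float("inf"), seed=13)
        ped = sibnb.simulate_pedigree(cfg)
        gt = sibnb.simulate_genotypes(ped, cfg)
        rc = ReconConfig(mating_system="monogamy", error_rate=0.001, seed=14,
                         restarts=3, sweeps=30)
        part = sibnb.reconstruct(gt, rc)
        true_part = SibshipPartition.truth(ped)
        cm = sibnb.confusion(sibnb.classify_dyads(true_part), sibnb.classify_dyads(part))
        assert cm.type_I == 0 and cm.type_II == 0
        assert part.cluster_sizes() == [5, 5, 5, 5, 5]

    def test_monogamy_partition_never_implies_half_sibs(self, small_recon):
        labels = sibnb.classify_dyads(small_recon)
        assert labels.counts["HS"] == 0

    def test_unrelated_pair_stays_split(self):
        cfg = sibnb.SimConfig(n_females=2, n_males=2, total_offspring=2,
                              male_reuse_rate=0.0, contamination_rate=0.0,
                              n_loci=95, error_rate=0.0, seed=17,
                              fecundity_dispersion=float("inf"))
        ped = sibnb.simulate_pedigree(cfg)
        # both offspring come from different crosses by construction
        assert len({ped.offspring[o] for o in ped.offspring}) == 2
        gt = sibnb.simulate_genotypes(ped, cfg)
        rc = ReconConfig(mating_system="monogamy", error_rate=0.01, seed=18,
                         restarts=2, sweeps=10)
        part = sibnb.reconstruct(gt, rc)
        assert part.cluster_sizes() == [1, 1]
        # merged-vs-split likelihood ratio is negative
        freqs = estimate_allele_freqs(gt)
        engine = SibshipLikelihood(gt, freqs, 0.01)
        assert engine.pairwise_fs_logratio()[0, 1] < 0

    def test_returned_loglik_not_below_singleton_start(self, small_cohort, small_recon):
        _, _, gt, _ = small_cohort
        freqs = estimate_allele_freqs(gt)
        engine = SibshipLikelihood(gt, freqs, 0.01)
        assert small_recon.log_likelihood >= engine.singleton_loglik_total() - 1e-9

    def test_deterministic_given_seed(self, small_cohort):
        _, _, gt, _ = small_cohort
        rc = ReconConfig(mating_system="monogamy", error_rate=0.01, seed=3,
                         restarts=2, sweeps=10)
        p1, p2 = sibnb.reconstruct(gt, rc), sibnb.reconstruct(gt, rc)
        assert np.array_equal(p1.sires, p2.sires) and p1.log_likelihood == p2.log_likelihood

    def test_all_missing_individual_excluded_with_warning(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(4, 20)).astype(np.int8)
        codes[2] = MISSING
        gt = _table(codes)
        rc = ReconConfig(restarts=1, sweeps=5, seed=1)
        with pytest.warns(UserWarning, match="o2"):
            part = sibnb.reconstruct(gt, rc)
        assert "o2" not in part.ids and part.n == 3

    def test_mating_system_accuracy_ordering(self):
        """At 95 SNPs: FS accuracy assuming monogamy >= assuming polygamy,
        and polygamy half-sib accuracy is low."""
        cfg = sibnb.SimConfig(n_females=12, n_males=8, total_offspring=30,
                              male_reuse_rate=0.3, contamination_rate=0.1,
                              seed=23)
        ped = sibnb.simulate_pedigree(cfg)
        gt = sibnb.simulate_genotypes(ped, cfg)
        truth = sibnb.label_dyads(ped)
        accs = {}
        for ms in ("monogamy", "polygamy"):
            rc = ReconConfig(mating_system=ms, error_rate=0.01, seed=24,
                             restarts=3, sweeps=25)
            part = sibnb.reconstruct(gt, rc)
            cm = sibnb.confusion(truth, sibnb.classify_dyads(part))
            accs[ms] = cm
        fs_mono = accs["monogamy"].accuracy("FS")
        fs_poly = accs["polygamy"].accuracy("FS")
        assert fs_mono >= fs_poly or math.isnan(fs_poly)
        hs_poly = accs["polygamy"].accuracy("HS")
        assert math.isnan(hs_poly) or hs_poly < 50.0


class TestClassifyDyads:
    def test_two_clusters_monogamy(self):
        part = SibshipPartition.from_clusters([["A", "B"], ["C"]])
        assert sibnb.classify_dyads(part).counts == {"FS": 1, "HS": 0, "U": 2}

    def test_shared_sire_across_dams(self):
        part = SibshipPartition(
            ["A", "B", "C"], np.array([0, 0, 0]), np.array([0, 0, 1])
        )
        assert sibnb.classify_dyads(part).counts == {"FS": 1, "HS": 2, "U": 0}

    @given(st.integers(0, 10**6))
    def test_counts_match_pair_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        sires, dams = rng.integers(0, 5, n), rng.integers(0, 5, n)
        part = SibshipPartition([f"o{i}" for i in range(n)], sires, dams)
        counts = sibnb.classify_dyads(part).counts
        brute = {"FS": 0, "HS": 0, "U": 0}
        for i in range(n):
            for j in range(i + 1, n):
                shared = int(sires[i] == sires[j]) + int(dams[i] == dams[j])
                brute[{2: "FS", 1: "HS", 0: "U"}[shared]] += 1
        assert counts == brute
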