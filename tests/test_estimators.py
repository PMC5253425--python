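"""SA and PwoP estimators, alpha, sibship frequencies, BestCluster IO."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sibnb
from sibnb.data import SibshipPartition


def _table(codes):
    codes = np.asarray(codes, dtype=np.int8)
    n, L = codes.shape
    return sibnb.GenotypeTable([f"o{i}" for i in range(n)], [f"L{j}" for j in range(L)], codes)


class TestAlpha:
    def test_all_heterozygous_gives_minus_one(self):
        gt = _table([[1], [1], [1], [1]])
        assert sibnb.estimate_alpha(gt).alpha == pytest.approx(-1.0)

    def test_no_heterozygotes_gives_plus_one(self):
        gt = _table([[0], [2], [0], [2]])
        assert sibnb.estimate_alpha(gt).alpha == pytest.approx(1.0)

    def test_monomorphic_sample_rejected(self):
        gt = _table([[0], [0], [0]])
        with pytest.raises(ValueError, match="monomorphic"):
            sibnb.estimate_alpha(gt)

    def test_hardy_weinberg_sample_near_zero(self):
        rng = np.random.default_rng(33)
        n, L, p = 800, 50, 0.3
        codes = rng.binomial(2, p, size=(n, L)).astype(np.int8)
        a = sibnb.estimate_alpha(_table(codes)).alpha
        # SE of F_IS is roughly 1/sqrt(n*L) at independent loci
        assert abs(a) < 3.0 / math.sqrt(n * L)


class TestSibshipFrequencies:
    def test_all_singletons(self):
        part = SibshipPartition.from_clusters([["a"], ["b"], ["c"]])
        q = sibnb.sibship_frequencies(part)
        assert (q.q1, q.q2, q.q3) == (0.0, 0.0, 0.0)

    def test_monogamy_clusters_three_two(self):
        part = SibshipPartition.from_clusters([list("abc"), list("de")])
        q = sibnb.sibship_frequencies(part)
        assert q.q3 == pytest.approx(0.4) and q.q1 == q.q2 == 0.0

    @given(st.integers(0, 10**6))
    def test_matches_pair_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 14
        sires, dams = rng.integers(0, 6, n), rng.integers(0, 6, n)
        part = SibshipPartition([f"o{i}" for i in range(n)], sires, dams)
        q = sibnb.sibship_frequencies(part)
        fs = hs_p = hs_m = 0
        for i in range(n):
            for j in range(i + 1, n):
                ss, sd = sires[i] == sires[j], dams[i] == dams[j]
                fs += ss and sd
                hs_p += ss and not sd
                hs_m += sd and not ss
        denom = n * (n - 1) / 2
        assert q.q3 == pytest.approx(fs / denom)
        assert q.q1 == pytest.approx(hs_p / denom)
        assert q.q2 == pytest.approx(hs_m / denom)

    def test_from_dyad_labels_equals_from_partition(self):
        cfg = sibnb.SimConfig(n_females=8, n_males=6, total_offspring=20,
                              male_reuse_rate=0.3, seed=2)
        ped = sibnb.simulate_pedigree(cfg)
        part = SibshipPartition.truth(ped)
        q_part = sibnb.sibship_frequencies(part)
        q_lab = sibnb.sibship_frequencies(sibnb.label_dyads(ped))
        assert (q_part.q1, q_part.q2, q_part.q3) == (q_lab.q1, q_lab.q2, q_lab.q3)


class TestSaNb:
    def test_fullsib_only(self):
        q = sibnb.SibshipFrequencies(0.0, 0.0, 0.01, 100)
        assert sibnb.sa_nb(q).value == pytest.approx(200.0)

    def test_halfsib_only(self):
        q = sibnb.SibshipFrequencies(0.01, 0.01, 0.0, 100)
        assert sibnb.sa_nb(q).value == pytest.approx(200.0)

    def test_no_sibs_gives_infinity(self):
        q = sibnb.SibshipFrequencies(0.0, 0.0, 0.0, 100)
        assert sibnb.sa_nb(q).value == math.inf

    def test_monotone_decreasing_in_each_q_at_alpha_zero(self):
        base = sibnb.sa_nb(sibnb.SibshipFrequencies(0.01, 0.01, 0.01, 100)).value
        for dq in ((0.02, 0.01, 0.01), (0.01, 0.02, 0.01), (0.01, 0.01, 0.02)):
            assert sibnb.sa_nb(sibnb.SibshipFrequencies(*dq, 100)).value < base

    def test_alpha_correction_changes_estimate(self):
        q = sibnb.SibshipFrequencies(0.0, 0.0, 0.01, 100)
        with_alpha = sibnb.sa_nb(q, sibnb.AlphaEstimate(0.05))
        assert with_alpha.value != pytest.approx(200.0)


class TestKiFromPartition:
    def test_monogamy_two_pairs(self):
        part = SibshipPartition.from_clusters([["a", "b"], ["c", "d"]])
        ki = sibnb.ki_from_partition(part)
        assert sorted(ki.counts.values()) == [2, 2, 2, 2] and ki.S == 4

    def test_shared_sire(self):
        part = SibshipPartition(["a", "b", "c"], np.array([0, 0, 0]), np.array([0, 0, 1]))
        ki = sibnb.ki_from_partition(part)
        assert ki.counts["S0"] == 3 and sorted(
            v for k, v in ki.counts.items() if k.startswith("D")
        ) == [1, 2]

    @given(st.integers(0, 10**6))
    def test_sum_ki_is_twice_n(self, seed):
        rng = np.random.default_rng(seed)
        n = 11
        part = SibshipPartition(
            [f"o{i}" for i in range(n)], rng.integers(0, 4, n), rng.integers(0, 4, n)
        )
        assert sibnb.ki_from_partition(part).total == 2 * n


class TestPwopFromPartition:
    def test_two_pair_clusters(self):
        part = SibshipPartition.from_clusters([["a", "b"], ["c", "d"]])
        assert sibnb.pwop_nb_from_partition(part).value == pytest.approx(7.0)

    def test_all_singletons_is_infinite(self):
        part = SibshipPartition.from_clusters([[f"o{i}"] for i in range(9)])
        assert sibnb.pwop_nb_from_partition(part).value == math.inf

    def test_truth_partition_reproduces_true_nb(self):
        cfg = sibnb.SimConfig(n_females=40, n_males=35, total_offspring=90,
                              male_reuse_rate=0.2, contamination_rate=0.1, seed=9)
        ped = sibnb.simulate_pedigree(cfg)
        true_nb = sibnb.pwop_nb(sibnb.ki_vector(ped, ped.offspring_ids))
        part = SibshipPartition.truth(ped)
        assert sibnb.pwop_nb_from_partition(part).value == pytest.approx(true_nb)


class TestSaPwopIdentity:
    @given(st.lists(st.integers(1, 6), min_size=4, max_size=40))
    def test_monogamy_ratio_identity(self, sizes):
        """For any monogamous clustering with alpha=0:
        SA/PwoP = 2(n-1)/(2n-1) exactly."""
        clusters = [[f"c{i}_{j}" for j in range(c)] for i, c in enumerate(sizes)]
        part = SibshipPartition.from_clusters(clusters)
        n = sum(sizes)
        sa = sibnb.sa_nb(sibnb.sibship_frequencies(part)).value
        pw = sibnb.pwop_nb_from_partition(part).value
        if math.isinf(pw):
            assert math.isinf(sa)
        else:
            assert sa / pw == pytest.approx(2 * (n - 1) / (2 * n - 1), abs=1e-10)

    def test_percent_difference_below_seven_for_n_at_least_eight(self):
        # 100*(1 - 2(n-1)/(2n-1)) = 100/(2n-1) < 7 whenever n >= 8
        for n in range(8, 200):
            assert 100.0 / (2 * n - 1) < 7.0


class TestBestClusterIO:
    def test_four_row_fixture_two_clusters(self, tmp_path):
        path = tmp_path / "bc.txt"
        path.write_text(
            "ClusterIndex ClusterProbability OffspringID FatherID MotherID\n"
            "1 1.0 kid1 S1 D1\n"
            "1 1.0 kid2 S1 D1\n"
            "2 0.98 kid3 S2 D2\n"
            "2 0.98 kid4 S2 D2\n"
        )
        part = sibnb.read_best_cluster(path)
        assert part.cluster_sizes() == [2, 2]
        assert sibnb.classify_dyads(part).counts == {"FS": 2, "HS": 0, "U": 4}

    def test_round_trip_preserves_dyad_classification(self, tmp_path):
        rng = np.random.default_rng(3)
        n = 15
        part = SibshipPartition(
            [f"o{i}" for i in range(n)], rng.integers(0, 5, n), rng.integers(0, 5, n)
        )
        path = tmp_path / "bc.txt"
        sibnb.write_best_cluster(part, path)
        back = sibnb.read_best_cluster(path)
        assert back.ids == part.ids
        assert np.array_equal(
            sibnb.classify_dyads(back).labels, sibnb.classify_dyads(part).labels
        )

    def test_write_read_write_is_byte_identical(self, tmp_path):
        part = SibshipPartition.from_clusters([["a", "b"], ["c"]])
        p1, p2 = tmp_path / "a.txt", tmp_path / "b.txt"
        sibnb.write_best_cluster(part, p1)
        sibnb.write_best_cluster(sibnb.read_best_cluster(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_shared_father_across_clusters_yields_half_sibs(self, tmp_path):
        path = tmp_path / "bc.txt"
        path.write_text(
            "1 1.0 kid1 S1 D1\n"
            "1 1.0 kid2 S1 D1\n"
            "2 1.0 kid3 S1 D2\n"
        )
        part = sibnb.read_best_cluster(path)
        assert sibnb.classify_dyads(part).counts["HS"] == 2

    def test_duplicate_offspring_rejected(self, tmp_path):
        path = tmp_path / "bc.txt"
        path.write_text("1 1.0 kid1 S1 D1\n1 1.0 kid1 S1 D1\n")
        with pytest.raises(ValueError, match="duplicate"):
            sibnb.read_best_cluster(path)

    def test_missing_columns_named_by_line(self, tmp_path):
        path = tmp_path / "bc.txt"
        path.write_text("1 1.0 kid1 S1 D1\n1 1.0 kid2\n")
        with pytest.raises(ValueError, match="line 2"):
            sibnb.read_best_cluster(path)
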