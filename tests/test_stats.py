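"""Switching statistics against enumeration/brute-force oracles."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats as sps

from cd5switch.simulate import SimulationConfig, assign_cd5_states, simulate_clone
from cd5switch.stats import (
    cocluster_bootstrap_test,
    distance_matrix,
    hamming,
    hypergeom_sf_exact,
    hypergeometric_overlap_test,
    mutation_combinations,
    pairwise_distance_means,
    subclonal_correlation,
)
from tests.conftest import random_seqs

BASES = "ACGT"


def enumerate_d_mutants(seq: str, d: int) -> int:
    """Count distinct sequences at Hamming distance exactly d by enumeration."""
    count = 0
    for positions in itertools.combinations(range(len(seq)), d):
        for repl in itertools.product(*[[b for b in BASES if b != seq[p]] for p in positions]):
            count += 1
    return count


class TestMutationCombinations:
    def test_zero_mutations_single_combination(self):
        assert mutation_combinations(17, 0) == 1

    def test_single_position_three_bases(self):
        assert mutation_combinations(1, 1) == 3

    def test_matches_enumeration_small(self):
        for l in range(1, 9):
            for d in range(0, min(l, 3) + 1):
                assert mutation_combinations(l, d) == enumerate_d_mutants("A" * l, d)

    def test_ten_choose_two_times_nine(self):
        assert mutation_combinations(10, 2) == 405 == enumerate_d_mutants("ACGTACGTAC", 2)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            mutation_combinations(3, 4)
        with pytest.raises(ValueError):
            mutation_combinations(-1, 0)


def enumerate_hypergeom_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) by literal enumeration of all C(N, n) draws."""
    marked = set(range(K))
    hits = sum(
        1 for draw in itertools.combinations(range(N), n) if len(marked & set(draw)) >= k
    )
    return Fraction(hits, math.comb(N, n))


class TestHypergeometricTail:
    def test_overlap_of_zero_is_certain(self):
        assert hypergeom_sf_exact(0, 1000, 10, 10) == 1

    def test_three_of_three_in_universe_twelve(self):
        # l=4, d=1: universe 12; all 3 low variants among the 3 high ones
        p = hypergeom_sf_exact(3, 12, 3, 3)
        assert p == Fraction(1, 220)
        assert float(p) == pytest.approx(1 / math.comb(12, 3))

    @pytest.mark.parametrize(
        "N,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 3), (14, 4, 7)]
    )
    def test_matches_draw_enumeration(self, N, K, n):
        for k in range(0, min(K, n) + 1):
            assert hypergeom_sf_exact(k, N, K, n) == enumerate_hypergeom_tail(k, N, K, n)

    def test_matches_scipy_for_large_universe(self):
        for N, K, n, k in [(10**6, 500, 300, 4), (900, 40, 12, 8), (403650, 20, 6, 2)]:
            exact = float(hypergeom_sf_exact(k, N, K, n))
            ref = float(sps.hypergeom.sf(k - 1, N, K, n))
            assert exact == pytest.approx(ref, rel=1e-9)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_sf_exact(1, 10, 11, 2)


class TestOverlapTest:
    def test_disjoint_sets_give_unit_pvalues(self):
        central = "AAAAAA"
        high = {"TAAAAA", "ATAAAA"}
        low = {"AATAAA", "AAATAA"}
        res = hypergeometric_overlap_test(high, low, central)
        assert (res.table["p_value"] == 1.0).all()
        assert res.pooled_p > 0.5

    def test_central_excluded_from_variant_sets(self):
        central = "AAAA"
        res = hypergeometric_overlap_test({central, "AAAT"}, {central, "AAAT"}, central)
        assert res.table["n_high"].sum() == 1  # only the d=1 variant counts
        assert res.table.loc[res.table["d"] == 1, "n_shared"].item() == 1

    def test_shared_variants_shrink_pvalue(self):
        central = "A" * 50
        shared = {"T" + "A" * 49, "A" * 49 + "G", "AC" + "A" * 48}
        res = hypergeometric_overlap_test(shared, shared, central)
        # 3 shared of 3 drawn from a universe of 150 single mutants
        expected = enumerate_hypergeom_tail(3, 150, 3, 3)
        got = res.table.loc[res.table["d"] == 1, "p_value"].item()
        assert got == pytest.approx(float(expected))
        assert res.pooled_p < 1e-4

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_overlap_test({"AAAA"}, {"AAA"}, "AAAA")


class TestDistanceRatio:
    def test_hand_example(self):
        mw, mb, ratio = pairwise_distance_means({"AAAA", "AAAT"}, {"GGGG", "GGGC"})
        assert (mw, mb, ratio) == (1.0, 4.0, 0.25)

    def test_identical_sets_ratio_one(self):
        s = {"AAAA", "AATT", "GGTT"}
        _, _, ratio = pairwise_distance_means(s, set(s))
        assert ratio == pytest.approx(1.0)

    def test_brute_force_oracle_on_random_sets(self):
        rng = np.random.default_rng(0)
        high = set(random_seqs(rng, 12, 20))
        low = set(random_seqs(rng, 9, 20))
        mw, mb, ratio = pairwise_distance_means(high, low)
        hi, lo = sorted(high), sorted(low)
        wd = [hamming(a, b) for g in (hi, lo) for a, b in itertools.combinations(g, 2)]
        bd = [hamming(a, b) for a in hi for b in lo]
        assert mw == pytest.approx(np.mean(wd))
        assert mb == pytest.approx(np.mean(bd))
        assert ratio == pytest.approx(np.mean(wd) / np.mean(bd))

    def test_singleton_set_rejected_by_name(self):
        with pytest.raises(ValueError, match="low"):
            pairwise_distance_means({"AAAA", "AAAT"}, {"GGGG"})


class TestCoClusterBootstrap:
    def test_records_exactly_n_boot_null_ratios(self):
        rng = np.random.default_rng(1)
        s = random_seqs(rng, 20, 15)
        res = cocluster_bootstrap_test(set(s[:10]), set(s[10:]), n_boot=50, seed=0)
        assert res.n_boot == 50 and len(res.null_ratios) == 50

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        s = random_seqs(rng, 24, 15)
        r1 = cocluster_bootstrap_test(set(s[:12]), set(s[12:]), n_boot=100, seed=5)
        r2 = cocluster_bootstrap_test(set(s[:12]), set(s[12:]), n_boot=100, seed=5)
        assert r1.p_value == r2.p_value
        assert np.array_equal(r1.null_ratios, r2.null_ratios)

    def test_duplicated_set_rarely_significant(self):
        """With identical high/low populations the test must not reject."""
        rng = np.random.default_rng(3)
        n_sig = 0
        for seed in range(50):
            pool = set(random_seqs(rng, 18, 25))
            res = cocluster_bootstrap_test(pool, set(pool), n_boot=100, seed=seed)
            n_sig += res.p_value <= 0.05
        assert n_sig <= 5  # > 0.05 in >= 90% of seeds

    def test_separated_clusters_highly_significant(self):
        rng = np.random.default_rng(4)
        base_a, base_b = "A" * 40, "T" * 40
        def jitter(base, n):
            out = set()
            while len(out) < n:
                pos = int(rng.integers(0, 40))
                out.add(base[:pos] + "G" + base[pos + 1 :])
            return out
        res = cocluster_bootstrap_test(jitter(base_a, 12), jitter(base_b, 12),
                                       n_boot=1000, seed=0)
        assert res.ratio < 0.2
        assert res.p_value <= 0.001

    def test_invalid_n_boot(self):
        with pytest.raises(ValueError):
            cocluster_bootstrap_test({"AA", "AT"}, {"GG", "GC"}, n_boot=0)


class TestSubclonalCorrelation:
    def test_identity_map(self):
        f = {"a": 0.5, "b": 0.3, "c": 0.2}
        res = subclonal_correlation(f, dict(f))
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_exact_linear_map(self):
        f = {"a": 0.5, "b": 0.3, "c": 0.2, "d": 0.1}
        res = subclonal_correlation(f, {k: 0.5 * v for k, v in f.items()})
        assert res.slope == pytest.approx(0.5)
        assert res.r_squared == pytest.approx(1.0)

    def test_private_variants_reported_not_imputed(self):
        high = {"a": 0.5, "b": 0.3, "c": 0.1, "x": 0.1}
        low = {"a": 0.4, "b": 0.4, "c": 0.1, "y": 0.1}
        res = subclonal_correlation(high, low)
        assert res.n_shared == 3
        assert res.only_high == ["x"] and res.only_low == ["y"]

    def test_too_few_shared_variants_rejected(self):
        with pytest.raises(ValueError):
            subclonal_correlation({"a": 1.0, "b": 0.5}, {"a": 0.9, "b": 0.4})

    def test_deep_scenario_c_sampling_highly_correlated(self):
        """Under common switching both gates sample the same subclonal
        structure, so per-variant frequencies correlate strongly."""
        cfg = SimulationConfig(seed=20, clone_cells=4000, background_clones=0)
        truth = simulate_clone(cfg)
        assign_cd5_states(truth, "C", 0.3, seed=20)
        freqs = {}
        for gate in ("high", "low"):
            cells = truth.gate_cells(gate)
            counts = {}
            for c in cells:
                counts[c.bcr_sequence] = counts.get(c.bcr_sequence, 0) + 1
            total = sum(counts.values())
            freqs[gate] = {s: n / total for s, n in counts.items()}
        res = subclonal_correlation(freqs["high"], freqs["low"])
        assert res.n_shared >= 3
        assert res.r_squared > 0.9


def test_distance_matrix_matches_pairwise_hamming():
    rng = np.random.default_rng(5)
    seqs = random_seqs(rng, 10, 30)
    D = distance_matrix(seqs)
    for i in range(10):
        for j in range(10):
            assert D[i, j] == hamming(seqs[i], seqs[j])
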