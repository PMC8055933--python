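"""Clinical-correlation pipeline: two-stage lesion averaging, combination
enumeration, Spearman/permutation machinery against exhaustive oracles, and
Benjamini-Hochberg against the literal step-up rule."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata, spearmanr

from attnrank.correlation import (
    benjamini_hochberg,
    build_patient_table,
    combine,
    enumerate_combinations,
    lesion_patient_mean,
    permutation_pvalue,
    run_correlation_analysis,
    spearman_rho,
)


class TestLesionPatientMean:
    def test_unweighted_over_lesions(self):
        vol = np.zeros((20, 20, 20))
        labels = np.zeros_like(vol, dtype=np.int32)
        labels[0, 0, :10] = 1
        vol[0, 0, :10] = 1.0                     # lesion 1: 10 voxels, mean 1
        labels[1:11, :10, :10] = 2
        vol[1:11, :10, :10] = 3.0                # lesion 2: 1000 voxels, mean 3
        assert lesion_patient_mean(vol, labels) == pytest.approx(2.0)
        # the size-weighted voxel mean would be ~2.98 — distinguishes the rule
        voxel_mean = vol[labels > 0].mean()
        assert voxel_mean == pytest.approx(2.98, abs=0.01)

    def test_single_lesion_and_constant(self):
        labels = np.zeros((5, 5, 5), np.int32)
        labels[1:3, 1:3, 1:3] = 1
        vol = np.full((5, 5, 5), 4.2)
        assert lesion_patient_mean(vol, labels) == pytest.approx(4.2)

    def test_no_lesions_raises(self):
        with pytest.raises(ValueError):
            lesion_patient_mean(np.zeros((3, 3, 3)), np.zeros((3, 3, 3), np.int32))


class TestCombinations:
    @pytest.mark.parametrize("m,expected", [(1, 1), (3, 7), (4, 15)])
    def test_counts(self, m, expected):
        subsets = enumerate_combinations([f"m{i}" for i in range(m)])
        assert len(subsets) == expected == 2 ** m - 1
        assert len(set(subsets)) == expected

    def test_order_by_size_then_lexicographic(self):
        subsets = enumerate_combinations(["a", "b"])
        assert subsets == [("a",), ("b",), ("a", "b")]

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            enumerate_combinations([])

    def test_combine_is_unweighted_sum(self):
        np.testing.assert_allclose(combine(np.array([[0.2, -0.5]])), [-0.3])
        np.testing.assert_allclose(combine(np.array([[1.0], [2.0]])), [1.0, 2.0])

    def test_redundant_pair_keeps_rank_correlation(self, rng):
        a = rng.standard_normal(30)
        y = rng.standard_normal(30)
        doubled = combine(np.stack([a, a], axis=1))
        assert spearman_rho(doubled, y) == pytest.approx(spearman_rho(a, y))


class TestSpearman:
    def test_monotone_limits(self):
        x = np.arange(10.0)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)
        assert spearman_rho(x, -x ** 3) == pytest.approx(-1.0)

    def test_hand_computed_five_points(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 summing to 4
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_matches_scipy_with_ties(self, rng):
        for _ in range(10):
            x = rng.integers(0, 5, 20).astype(float)
            y = rng.integers(0, 5, 20).astype(float)
            if rankdata(x).std() == 0 or rankdata(y).std() == 0:
                continue
            assert spearman_rho(x, y) == pytest.approx(spearmanr(x, y).statistic)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(15)
        y = rng.standard_normal(15)
        rho = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y) == pytest.approx(rho)
        assert spearman_rho(x, 3 * y - 7) == pytest.approx(rho)
        assert spearman_rho(x, np.arctan(y)) == pytest.approx(rho)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            spearman_rho([1.0, 2.0], [1.0, 2.0])


def exhaustive_two_sided_p(x, y):
    """All n! permutations of y; two-sided exceedance of |rho|."""
    obs = abs(spearman_rho(x, y))
    count = 0
    total = 0
    for perm in itertools.permutations(y):
        total += 1
        if abs(spearman_rho(x, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / total


class TestPermutationPvalue:
    def test_within_3se_of_exhaustive_at_n6(self):
        rng = np.random.default_rng(0)
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.1, -1.1])
        y = np.array([0.2, 0.9, -0.1, 1.4, 0.6, -0.8])
        exact = exhaustive_two_sided_p(x, y)
        n_perm = 20_000
        p = permutation_pvalue(x, y, n_perm=n_perm, rng=rng)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(p - exact) <= 3 * se + 2 / n_perm

    def test_lower_bound(self):
        rng = np.random.default_rng(1)
        x = np.arange(12.0)
        p = permutation_pvalue(x, x, n_perm=1000, rng=rng)
        assert p >= 1 / 1001

    def test_perfect_rank_agreement_n8(self):
        """Only the identity and the full reversal reach |rho| = 1, so the
        p-value sits near (1 + 2 n_perm / 8!) / (1 + n_perm)."""
        rng = np.random.default_rng(2)
        x = np.arange(8.0)
        y = 2 * x + 1
        p = permutation_pvalue(x, y, n_perm=20_000, rng=rng)
        assert 1 / 20_001 <= p <= 6 / 20_001

    def test_constant_x_raises(self):
        with pytest.raises(ValueError):
            permutation_pvalue(np.ones(6), np.arange(6.0), n_perm=10,
                               rng=np.random.default_rng(0))

    def test_deterministic_under_seed(self):
        x = np.random.default_rng(3).standard_normal(15)
        y = np.random.default_rng(4).standard_normal(15)
        p1 = permutation_pvalue(x, y, n_perm=500, rng=np.random.default_rng(9))
        p2 = permutation_pvalue(x, y, n_perm=500, rng=np.random.default_rng(9))
        assert p1 == p2


def step_up_oracle(p, q):
    """Literal Benjamini-Hochberg: largest i with p_(i) <= q i/m."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    cutoff = 0.0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= q * i / m:
            cutoff = p[idx]
    return p <= cutoff if cutoff > 0 else np.zeros(m, bool)


# p-values as printed in the disability-correlation table (14 reported tests)
PRINTED_P = [0.41, 0.12, 0.017, 0.057, 0.013, 0.58, 0.014,
             0.007, 0.023, 0.012, 0.004, 0.007, 0.009, 0.009]


class TestBenjaminiHochberg:
    def test_printed_p_column(self):
        flags = benjamini_hochberg(PRINTED_P, q=0.05)
        np.testing.assert_array_equal(flags, step_up_oracle(PRINTED_P, 0.05))
        assert flags.sum() == 10  # ten asterisks in the printed table
        assert not flags[0] and not flags[1] and not flags[3] and not flags[5]

    def test_all_ones_no_flags(self):
        assert not benjamini_hochberg([1.0] * 8).any()

    def test_single_test_reduces_to_threshold(self):
        assert benjamini_hochberg([0.04], q=0.05)[0]
        assert not benjamini_hochberg([0.06], q=0.05)[0]

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_oracle_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 25))
        p = rng.uniform(1e-6, 1.0, m)
        flags = benjamini_hochberg(p, q=0.05)
        np.testing.assert_array_equal(flags, step_up_oracle(p, 0.05))
        # monotone in p: no flagged test has larger p than an unflagged one
        if flags.any() and (~flags).any():
            assert p[flags].max() <= p[~flags].min()

    def test_invalid_p_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.0, 0.5])


class TestRunAnalysis:
    def _table(self, n=20, seed=0, link=True):
        rng = np.random.default_rng(seed)
        latent = rng.standard_normal(n)
        rows = {"patient_id": [f"p{i}" for i in range(n)],
                "lesion_count": rng.integers(1, 6, n),
                "lesion_volume": rng.integers(30, 600, n),
                "disability": -latent + 0.3 * rng.standard_normal(n) if link
                else rng.standard_normal(n)}
        for j in range(4):
            rows[f"m{j}"] = latent + 0.5 * rng.standard_normal(n)
        return pd.DataFrame(rows)

    def test_seventeen_tests_for_four_measures(self):
        records = run_correlation_analysis(self._table(), [f"m{j}" for j in range(4)],
                                           "disability", n_perm=200,
                                           rng=np.random.default_rng(0))
        assert len(records) == 17
        names = [r.variable for r in records]
        assert names[:2] == ["lesion_count", "lesion_volume"]
        assert "m0+m1+m2+m3" in names

    def test_fdr_flags_monotone_in_p(self):
        records = run_correlation_analysis(self._table(), [f"m{j}" for j in range(4)],
                                           "disability", n_perm=500,
                                           rng=np.random.default_rng(1))
        flagged = [r.p_value for r in records if r.significant]
        unflagged = [r.p_value for r in records if not r.significant]
        if flagged and unflagged:
            assert max(flagged) <= min(unflagged)

    def test_exclusion_flag(self):
        table = self._table()
        records = run_correlation_analysis(table, ["m0"], "disability", n_perm=100,
                                           rng=np.random.default_rng(2),
                                           exclude=["p0", "p1"])
        assert records  # ran on the reduced cohort without error

    def test_too_few_patients_raises(self):
        with pytest.raises(ValueError):
            run_correlation_analysis(self._table(n=2), ["m0"], "disability",
                                     n_perm=10, rng=np.random.default_rng(0))


def test_build_patient_table(small_cohort):
    config, cohort = small_cohort
    table = build_patient_table(cohort, measure_indices=[0, 2])
    assert len(table) == len(cohort)
    assert {"patient_id", "lesion_count", "lesion_volume",
            "disability", "biomarker", "m0", "m2"} <= set(table.columns)
    assert (table["lesion_count"] >= 1).all()
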