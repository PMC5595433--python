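"""NB differential expression: size factors, dispersion, Wald test, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from conftest import nb_counts
from theriacomp.differential_expression import (
    DEError,
    adjust_bh,
    differential_transcripts,
    estimate_dispersion,
    nb_wald_test,
    size_factors_median_of_ratios,
)
from theriacomp.io_formats import CountMatrix


def make_matrix(values):
    values = np.asarray(values, dtype=float)
    return CountMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
    )


def simulate_two_group(rng, n_genes, n_a, n_b, alpha, lfc_log2=0.0, frac_de=0.0):
    """NB counts with an optional planted symmetric fold change."""
    mu = rng.lognormal(4.0, 1.0, n_genes)
    signs = np.zeros(n_genes)
    n_de = int(frac_de * n_genes)
    if n_de:
        idx = rng.choice(n_genes, n_de, replace=False)
        signs[idx] = rng.choice([-1.0, 1.0], n_de)
    mu_a = mu * 2 ** (signs * lfc_log2 / 2)
    mu_b = mu * 2 ** (-signs * lfc_log2 / 2)
    counts = np.column_stack(
        [nb_counts(rng, mu_a, alpha) for _ in range(n_a)]
        + [nb_counts(rng, mu_b, alpha) for _ in range(n_b)]
    )
    return make_matrix(counts), ["A"] * n_a + ["B"] * n_b, signs


def brute_force_size_factors(values):
    """Literal median-of-ratios over all-positive genes, then recentre."""
    keep = (values > 0).all(axis=1)
    ref = values[keep]
    geo = np.exp(np.log(ref).mean(axis=1))
    raw = np.array([np.median(ref[:, j] / geo) for j in range(values.shape[1])])
    return raw / np.exp(np.mean(np.log(raw)))


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        matrix = make_matrix([[10, 10], [3, 3]])
        np.testing.assert_allclose(size_factors_median_of_ratios(matrix), [1, 1])

    def test_doubled_column_splits_symmetrically(self):
        rng = np.random.default_rng(0)
        col = rng.integers(1, 200, 50).astype(float)
        matrix = make_matrix(np.column_stack([col, 2 * col]))
        np.testing.assert_allclose(
            size_factors_median_of_ratios(matrix),
            [1 / np.sqrt(2), np.sqrt(2)],
            rtol=1e-12,
        )

    def test_single_gene_closed_form(self):
        matrix = make_matrix([[4, 9]])
        np.testing.assert_allclose(
            size_factors_median_of_ratios(matrix), [4 / 6, 9 / 6], rtol=1e-12
        )

    def test_no_universally_positive_gene_is_error(self):
        matrix = make_matrix([[0, 5], [5, 0]])
        with pytest.raises(DEError, match="positive counts in every sample"):
            size_factors_median_of_ratios(matrix)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), m=st.integers(2, 6))
    def test_matches_brute_force_and_gene_permutation_invariant(self, seed, m):
        rng = np.random.default_rng(seed)
        values = rng.integers(1, 500, (20, m)).astype(float)
        factors = size_factors_median_of_ratios(make_matrix(values))
        np.testing.assert_allclose(factors, brute_force_size_factors(values), rtol=1e-12)
        perm = rng.permutation(20)
        np.testing.assert_allclose(
            size_factors_median_of_ratios(make_matrix(values[perm])), factors, rtol=1e-12
        )
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), c=st.floats(0.2, 5.0))
    def test_scaling_one_sample_moves_its_factor_by_c_to_m_minus_1_over_m(self, seed, c):
        rng = np.random.default_rng(seed)
        m = 4
        values = rng.integers(1, 500, (30, m)).astype(float)
        base = size_factors_median_of_ratios(make_matrix(values))
        scaled = values.copy()
        scaled[:, 0] *= c
        after = size_factors_median_of_ratios(make_matrix(scaled))
        assert after[0] == pytest.approx(base[0] * c ** ((m - 1) / m), rel=1e-9)


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(100, (500, 50)).astype(float)
        disp = estimate_dispersion(
            make_matrix(counts), np.ones(50), ["A"] * 25 + ["B"] * 25, "A", "B"
        )
        assert np.median(disp) < 0.01

    def test_nb_dispersion_recovered_at_large_n(self):
        rng = np.random.default_rng(12)
        counts = nb_counts(rng, np.full((400, 200), 100.0), 0.5).astype(float)
        disp = estimate_dispersion(
            make_matrix(counts), np.ones(200), ["A"] * 100 + ["B"] * 100, "A", "B"
        )
        assert 0.3 < np.median(disp) < 0.7
        assert ((disp > 0.3) & (disp < 0.7)).mean() > 0.9

    def test_constant_counts_floor_at_zero(self):
        matrix = make_matrix(np.full((3, 6), 7.0))
        disp = estimate_dispersion(
            matrix, np.ones(6), ["A"] * 3 + ["B"] * 3, "A", "B"
        )
        np.testing.assert_array_equal(disp, 0.0)

    def test_small_group_is_error(self):
        matrix = make_matrix(np.ones((3, 3)))
        with pytest.raises(DEError, match=">= 2 samples"):
            estimate_dispersion(matrix, np.ones(3), ["A", "B", "B"], "A", "B")


class TestWaldTest:
    def test_type_one_error_is_calibrated(self):
        rng = np.random.default_rng(7)
        matrix, groups, _ = simulate_two_group(rng, 2000, 10, 10, alpha=0.2)
        sf = size_factors_median_of_ratios(matrix)
        disp = estimate_dispersion(matrix, sf, groups, "A", "B")
        res = nb_wald_test(matrix, sf, disp, groups, "A", "B")
        rate = (res["p_value"] <= 0.05).mean()
        assert 0.025 <= rate <= 0.10

    def test_recovers_eightfold_change(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(4.0, 0.5, 500)
        counts = np.column_stack(
            [nb_counts(rng, mu * 2**1.5, 0.1) for _ in range(5)]
            + [nb_counts(rng, mu * 2**-1.5, 0.1) for _ in range(5)]
        )
        matrix = make_matrix(counts)
        groups = ["A"] * 5 + ["B"] * 5
        disp = estimate_dispersion(matrix, np.ones(10), groups, "A", "B")
        res = nb_wald_test(matrix, np.ones(10), disp, groups, "A", "B")
        assert res["log2_fold_change"].mean() == pytest.approx(3.0, abs=0.75)

    def test_all_zero_gene_flagged_with_null_result(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 100, (5, 8)).astype(float)
        counts[2] = 0.0
        matrix = make_matrix(counts)
        groups = ["A"] * 4 + ["B"] * 4
        sf = size_factors_median_of_ratios(matrix)
        disp = estimate_dispersion(matrix, sf, groups, "A", "B")
        res = nb_wald_test(matrix, sf, disp, groups, "A", "B")
        assert res.loc["g2", "p_value"] == 1.0
        assert res.loc["g2", "log2_fold_change"] == 0.0
        assert bool(res.loc["g2", "all_zero"])

    def test_swapping_groups_negates_lfc_and_keeps_p(self):
        rng = np.random.default_rng(9)
        matrix, groups, _ = simulate_two_group(rng, 200, 4, 6, alpha=0.2, lfc_log2=2.0, frac_de=0.3)
        sf = size_factors_median_of_ratios(matrix)
        disp = estimate_dispersion(matrix, sf, groups, "A", "B")
        res_ab = nb_wald_test(matrix, sf, disp, groups, "A", "B")
        res_ba = nb_wald_test(matrix, sf, disp, groups, "B", "A")
        np.testing.assert_allclose(
            res_ab["log2_fold_change"], -res_ba["log2_fold_change"], atol=1e-6
        )
        np.testing.assert_allclose(res_ab["p_value"], res_ba["p_value"], atol=1e-9)


class TestBenjaminiHochberg:
    def test_single_p_is_identity(self):
        np.testing.assert_allclose(adjust_bh([0.03]), [0.03])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_bh([1.0, 1.0]), [1.0, 1.0])

    @pytest.mark.parametrize("bad", [[-0.1], [1.5], [np.nan]])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(DEError):
            adjust_bh(bad)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000), m=st.integers(1, 40))
    def test_matches_quadratic_oracle_and_statsmodels(self, seed, m):
        rng = np.random.default_rng(seed)
        p = np.round(rng.uniform(0, 1, m), 4)  # rounding forces ties
        q = adjust_bh(p)
        # O(m^2) literal step-up: q_i = min over j with p_j >= p_i of p_j*m/rank_j
        order = np.argsort(p, kind="stable")
        oracle = np.empty(m)
        for pos, i in enumerate(order):
            candidates = [
                p[order[k]] * m / (k + 1) for k in range(pos, m)
            ]
            oracle[i] = min(1.0, min(candidates))
        np.testing.assert_allclose(q, oracle, atol=1e-12)
        np.testing.assert_allclose(
            q, multipletests(p, method="fdr_bh")[1], atol=1e-12
        )

    def test_null_fdr_control_over_replicates(self):
        rng = np.random.default_rng(21)
        fractions = []
        for _ in range(10):
            matrix, groups, _ = simulate_two_group(rng, 500, 5, 5, alpha=0.2)
            sf = size_factors_median_of_ratios(matrix)
            disp = estimate_dispersion(matrix, sf, groups, "A", "B")
            res = nb_wald_test(matrix, sf, disp, groups, "A", "B")
            q = adjust_bh(res["p_value"].to_numpy())
            fractions.append((q <= 0.05).mean())
        assert np.mean(fractions) <= 0.07


class TestDifferentialTranscripts:
    def make_results(self, q, lfc):
        return pd.DataFrame(
            {"q_value": q, "log2_fold_change": lfc},
            index=[f"g{i + 1}" for i in range(len(q))],
        )

    def test_partition_by_sign(self):
        up_a, up_b = differential_transcripts(
            self.make_results([0.01, 0.2, 0.04], [2.0, 3.0, -1.0]), alpha=0.05
        )
        assert up_a.genes == {"g1"}
        assert up_b.genes == {"g3"}

    def test_nothing_significant_gives_empty_sets(self):
        up_a, up_b = differential_transcripts(
            self.make_results([0.5, 0.9], [2.0, -2.0]), alpha=0.05
        )
        assert up_a.genes == frozenset() and up_b.genes == frozenset()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n=st.integers(1, 30))
    def test_counts_conserved(self, seed, n):
        rng = np.random.default_rng(seed)
        q = rng.uniform(0, 1, n)
        lfc = np.where(rng.random(n) < 0.5, 1.0, -1.0) * rng.uniform(0.1, 3, n)
        up_a, up_b = differential_transcripts(self.make_results(q, lfc), alpha=0.3)
        assert len(up_a.genes) + len(up_b.genes) == int((q <= 0.3).sum())
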