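"""Per-cell Spearman statistic, cell filtering, BH adjustment, depth correction."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

import ercell
from ercell.er import (
    adjust_pvalues,
    cell_er_profile,
    correct_for_depth,
    er_profiles,
    filter_cells,
    significant_profiles,
    spearman_rho,
)

from conftest import build_matrix, rate_frame


def brute_force_midrank_rho(x, y):
    """Independent oracle: Pearson of average ranks computed by sorting."""
    def midrank(v):
        v = np.asarray(v, dtype=float)
        r = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            r[i] = less + (equal + 1) / 2.0
        return r
    rx, ry = midrank(x), midrank(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearman:
    def test_perfect_antimonotone(self):
        rho, _ = spearman_rho([1, 2, 3, 4], [0.4, 0.3, 0.2, 0.1])
        assert rho == pytest.approx(-1.0)

    def test_closed_form_no_ties(self):
        x = np.array([5, 1, 3, 2, 4], dtype=float)
        y = np.array([1, 2, 3, 4, 5], dtype=float)
        d = st.rankdata(x) - st.rankdata(y)
        n = len(x)
        expected = 1 - 6 * np.sum(d**2) / (n * (n**2 - 1))
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_all_120_orderings_match_closed_form(self):
        y = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        for perm in permutations([1.0, 2.0, 3.0, 4.0, 5.0]):
            x = np.array(perm)
            d = st.rankdata(x) - st.rankdata(y)
            expected = 1 - 6 * np.sum(d**2) / (5 * 24)
            rho, _ = spearman_rho(x, y)
            assert rho == pytest.approx(expected, abs=1e-12)

    def test_ties_match_midrank_oracle_and_scipy(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 4, size=12).astype(float)
        y = rng.normal(size=12)
        rho, p = spearman_rho(x, y)
        assert rho == pytest.approx(brute_force_midrank_rho(x, y), abs=1e-12)
        sp_rho, sp_p = st.spearmanr(x, y)
        assert rho == pytest.approx(sp_rho, abs=1e-12)
        assert p == pytest.approx(sp_p, abs=1e-10)  # t approximation path

    def test_small_n_exact_p_uniform_support(self):
        # n=4 distinct values: exact two-sided p from 24 orderings
        rho, p = spearman_rho([1, 2, 3, 4], [1, 2, 4, 3])
        perms = np.array(list(permutations([1.0, 2.0, 3.0, 4.0])))
        oracle = np.mean([
            abs(np.corrcoef(pp, [1, 2, 4, 3])[0, 1]) >= abs(rho) - 1e-12
            for pp in perms
        ])
        assert p == pytest.approx(oracle)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [5, 5, 5])

    @settings(deadline=None, max_examples=30)
    @given(hst.integers(0, 2**32 - 1), hst.integers(10, 40))
    def test_rank_statistic_invariances(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.exponential(size=n)
        y = rng.normal(size=n)
        rho, _ = spearman_rho(x, y)
        rho_scaled, _ = spearman_rho(x * 17.3, y)     # positive scaling
        rho_log, _ = spearman_rho(np.log1p(x), y)     # monotone transform
        assert rho_scaled == pytest.approx(rho, abs=1e-12)
        assert rho_log == pytest.approx(rho, abs=1e-12)


class TestFilterCells:
    def make(self, detected_per_cell, n_genes=300):
        counts = np.zeros((n_genes, len(detected_per_cell)), dtype=int)
        for j, k in enumerate(detected_per_cell):
            counts[:k, j] = 1
        return build_matrix(counts)

    def test_threshold_is_strict_below(self):
        m = self.make([199, 200, 250])
        out, ann = filter_cells(m, min_detected=200)
        assert list(out.cells) == ["c1", "c2"]
        assert ann["detected_genes"].tolist() == [200, 250]

    def test_orphan_gene_dropped(self):
        counts = np.array([[1, 1], [5, 0]])  # g1 only in the removed cell
        m = build_matrix(counts)
        out, _ = filter_cells(m, min_detected=2)
        assert list(out.cells) == ["c0"] and list(out.genes) == ["g0", "g1"]
        out2, _ = filter_cells(build_matrix(np.array([[1, 1], [0, 5]])), 2)
        assert list(out2.genes) == ["g0", "g1"] and list(out2.cells) == ["c1"]

    def test_all_cells_removed_is_an_error(self):
        with pytest.raises(ValueError, match="below min_detected"):
            filter_cells(self.make([10, 20]), min_detected=200)


class TestAdjustPvalues:
    def test_hand_bh_example(self):
        # step-up: p_(i) * m / i then running min from the largest p
        adj = adjust_pvalues([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_and_ceiling(self):
        assert adjust_pvalues([0.2]) == pytest.approx([0.2])
        assert adjust_pvalues([1.0, 1.0, 1.0]) == pytest.approx([1, 1, 1])

    def test_monotone_in_p_ordering(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=40)
        adj = adjust_pvalues(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj <= 1).all() and (adj >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])


class TestCellProfiles:
    def test_perfectly_inverse_cell(self):
        rates = rate_frame([0.1, 0.2, 0.3, 0.4])
        m = build_matrix(np.array([[40, 30, 20, 10]]).T)
        prof = er_profiles(m, rates)
        assert prof.iloc[0]["rho_ratio"] == pytest.approx(-1.0)
        assert prof.iloc[0]["n_genes_used"] == 4

    def test_matches_manually_assembled_vectors(self):
        rng = np.random.default_rng(8)
        n = 50
        rates = rate_frame(rng.uniform(0.01, 1.5, size=n))
        counts = rng.poisson(5, size=(n, 1))
        m = build_matrix(counts)
        prof = er_profiles(m, rates)
        nz = counts[:, 0] > 0
        expect_rho, expect_p = spearman_rho(
            counts[nz, 0], rates["ratio"].to_numpy()[nz]
        )
        assert prof.iloc[0]["rho_ratio"] == pytest.approx(expect_rho)
        assert prof.iloc[0]["p_ratio"] == pytest.approx(expect_p)
        assert prof.iloc[0]["n_genes_used"] == int(nz.sum())

    def test_cell_sharing_too_few_genes_is_invalid(self):
        rates = rate_frame([0.1, 0.5], genes=["g0", "g1"])
        counts = np.array([[3], [1], [2], [9]])
        m = build_matrix(counts)  # only g0,g1 have rates
        prof = er_profiles(m, rates)
        assert not prof.iloc[0]["valid"]

    def test_single_cell_accessor_matches(self):
        rng = np.random.default_rng(9)
        rates = rate_frame(rng.uniform(0.01, 1, 30))
        m = build_matrix(rng.poisson(4, size=(30, 5)))
        prof = er_profiles(m, rates)
        one = cell_er_profile(m, rates, "c3")
        assert one["rho_ratio"] == pytest.approx(prof.loc["c3", "rho_ratio"])


class TestDepthCorrection:
    def make_profiles(self, rho, detected):
        df = pd.DataFrame(
            {"rho_ratio": rho, "detected_genes": detected,
             "valid": True, "p_ratio": 0.5, "adj_p_ratio": 0.5},
            index=[f"c{i}" for i in range(len(rho))],
        )
        return df

    def test_perfect_linear_gives_zero_residuals(self):
        d = np.array([100.0, 200, 300, 400])
        prof = correct_for_depth(self.make_profiles(-0.1 - 0.001 * d, d))
        assert prof["corrected"].abs().max() < 1e-10

    def test_residuals_match_normal_equations_oracle(self):
        d = np.array([10.0, 20, 30, 40, 50])
        rho = np.array([-0.1, -0.25, -0.2, -0.35, -0.3])
        # closed-form OLS via normal equations
        X = np.column_stack([np.ones(5), d])
        beta = np.linalg.solve(X.T @ X, X.T @ rho)
        expected = rho - X @ beta
        prof = correct_for_depth(self.make_profiles(rho, d))
        assert prof["corrected"].to_numpy() == pytest.approx(expected, abs=1e-10)
        assert abs(prof["corrected"].sum()) < 1e-10

    def test_intercept_absorbed(self):
        d = np.array([10.0, 25, 30, 47, 50])
        rho = np.array([-0.1, -0.25, -0.2, -0.35, -0.3])
        a = correct_for_depth(self.make_profiles(rho, d))["corrected"]
        b = correct_for_depth(self.make_profiles(rho + 0.7, d))["corrected"]
        assert b.to_numpy() == pytest.approx(a.to_numpy(), abs=1e-12)

    def test_residual_orthogonal_to_depth(self):
        rng = np.random.default_rng(1)
        d = rng.integers(100, 2000, size=80).astype(float)
        rho = -0.1 - 0.0001 * d + rng.normal(0, 0.02, 80)
        prof = correct_for_depth(self.make_profiles(rho, d))
        r = st.pearsonr(prof["corrected"], prof["detected_genes"])[0]
        assert abs(r) < 1e-10

    def test_constant_depth_falls_back_to_centering(self):
        prof = correct_for_depth(
            self.make_profiles(np.array([-0.1, -0.2, -0.3]), np.array([5.0, 5, 5]))
        )
        assert prof["corrected"].sum() == pytest.approx(0.0, abs=1e-12)


class TestSignificantProfiles:
    def make(self, adj_p, rho):
        return pd.DataFrame(
            {"adj_p_ratio": adj_p, "rho_ratio": rho, "valid": True},
            index=[f"c{i}" for i in range(len(adj_p))],
        )

    def test_alpha_boundary_and_sign_rule(self):
        prof = self.make([0.051, 0.05, 0.01], [-0.3, -0.3, 0.2])
        kept = significant_profiles(prof, alpha=0.05)
        assert list(kept.index) == ["c1"]  # 0.051 > alpha out; positive rho out

    def test_sign_rule_configurable_and_empty_input(self):
        prof = self.make([0.01], [0.2])
        assert len(significant_profiles(prof, require_negative=False)) == 1
        assert len(significant_profiles(prof.iloc[:0])) == 0


def test_coupling_monotonicity_across_levels(filtered_rates_500):
    """Stronger imposed coupling -> more negative mean per-cell rho."""
    means = []
    for i, target in enumerate([-0.3, -0.15, 0.0]):
        des = ercell.SimulationDesign(
            n_genes=len(filtered_rates_500),
            cell_types=[ercell.CellTypeSpec("t", 60, target, 1e5)],
            seed=77,  # same seed: paired comparison across coupling levels
        )
        m, ann, _ = ercell.simulate_expression(des, filtered_rates_500)
        prof = er_profiles(m, filtered_rates_500, ann)
        means.append(prof["rho_ratio"].mean())
    assert means[0] < means[1] < means[2]
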