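import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

import wuescreen as w
from wuescreen.screen import DegenerateGeneError, trait_ratio_matrix


def spearman_oracle(m1, m2):
    """Independent Spearman over jointly defined flattened cells (scipy)."""
    joint = m1.mask & m2.mask
    return spearmanr(m1.values[joint], m2.values[joint]).statistic


class TestMedianZeroFilter:
    def test_median_zero_gene_removed_others_kept(self, tiny_expr):
        filtered, removed = w.median_zero_filter(tiny_expr)
        assert removed == ["gZeroMedian"]  # median of {0,0,0,5,0,0} is 0
        assert filtered.gene_ids == ["gA", "gUp", "gDown"]

    def test_matches_brute_force_median_on_zero_inflated_data(self):
        expr, *_ = w.simulate(
            w.SimConfig(n_genes=100, n_per_site=10, n_causal=0, zero_inflation=0.6, seed=1)
        )
        _, removed = w.median_zero_filter(expr)
        brute = [
            g for g in expr.gene_ids
            if float(np.median(expr.values.loc[g].to_numpy())) == 0.0
        ]
        assert removed == brute
        assert len(removed) > 0  # heavy zero inflation must trip the filter


class TestRatioMatrix:
    def test_all_pairs_arithmetic(self):
        m = w.build_ratio_matrix(np.array([2.0, 4.0]), np.array([1.0, 2.0]))
        assert m.values.tolist() == [[2.0, 1.0], [4.0, 2.0]]
        assert m.mask.all()

    def test_zero_denominator_masks_cell(self):
        m = w.build_ratio_matrix(np.array([1.0, 2.0]), np.array([0.0, 2.0]))
        assert m.mask.tolist() == [[False, True], [False, True]]

    def test_all_masked_is_unusable(self):
        with pytest.raises(DegenerateGeneError, match="unusable"):
            w.build_ratio_matrix(np.array([1.0]), np.array([0.0]))

    def test_pseudocount_policy_defines_every_cell(self):
        m = w.build_ratio_matrix(
            np.array([1.0, 0.0]), np.array([0.0, 2.0]), zero_policy="pseudocount",
            pseudocount=0.5,
        )
        assert m.mask.all()
        assert m.values[0, 0] == (1.0 + 0.5) / 0.5

    def test_field_design_gives_39_by_39(self):
        rng = np.random.default_rng(0)
        m = w.build_ratio_matrix(rng.random(39) + 0.1, rng.random(39) + 0.1)
        assert m.values.shape == (39, 39)


class TestMantelSpearman:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.m1 = w.build_ratio_matrix(rng.random(5) + 0.2, rng.random(5) + 0.2)
        self.config = w.ScreenConfig(n_perm=99, seed=1)

    def test_identity_gives_r_one(self):
        r, p = w.mantel_spearman(self.m1, self.m1, self.config)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_reciprocal_gives_r_minus_one(self):
        recip = w.RatioMatrix(
            self.m1.row_ids, self.m1.col_ids, 1.0 / self.m1.values, self.m1.mask.copy()
        )
        r, _ = w.mantel_spearman(self.m1, recip, self.config)
        assert r == pytest.approx(-1.0)

    def test_r_matches_scipy_spearman(self):
        rng = np.random.default_rng(8)
        m2 = w.build_ratio_matrix(rng.random(5) + 0.2, rng.random(5) + 0.2)
        r, _ = w.mantel_spearman(self.m1, m2, self.config)
        assert r == pytest.approx(spearman_oracle(self.m1, m2), abs=1e-12)

    def test_r_matches_scipy_spearman_with_masked_cells(self):
        rng = np.random.default_rng(9)
        qg = rng.random(6) + 0.2
        jh = rng.random(6) + 0.2
        jh[2] = 0.0  # one masked column
        m2 = w.build_ratio_matrix(qg, jh)
        m1 = w.build_ratio_matrix(rng.random(6) + 0.2, rng.random(6) + 0.2)
        r, p = w.mantel_spearman(m1, m2, self.config)
        assert r == pytest.approx(spearman_oracle(m1, m2), abs=1e-12)
        assert 0 < p <= 1

    def test_swap_symmetry_of_r(self):
        rng = np.random.default_rng(10)
        m2 = w.build_ratio_matrix(rng.random(5) + 0.2, rng.random(5) + 0.2)
        r12, _ = w.mantel_spearman(self.m1, m2, self.config)
        r21, _ = w.mantel_spearman(m2, self.m1, self.config)
        assert r12 == pytest.approx(r21, abs=1e-12)

    def test_consistent_relabeling_leaves_r_and_p_unchanged(self):
        """Renaming individuals the same way in both matrices changes nothing:
        exact (r, p) on a 3x3 pair, sampled r on a 5x5 pair."""
        rng = np.random.default_rng(11)

        def relabel(m, rows, cols):
            return w.RatioMatrix(
                [m.row_ids[i] for i in rows],
                [m.col_ids[j] for j in cols],
                m.values[np.ix_(rows, cols)],
                m.mask[np.ix_(rows, cols)],
            )

        a1 = w.build_ratio_matrix(rng.random(3) + 0.2, rng.random(3) + 0.2)
        a2 = w.build_ratio_matrix(rng.random(3) + 0.2, rng.random(3) + 0.2)
        r0, p0 = w.mantel_spearman_exact(a1, a2)
        rows, cols = rng.permutation(3), rng.permutation(3)
        r1, p1 = w.mantel_spearman_exact(relabel(a1, rows, cols), relabel(a2, rows, cols))
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-15)

        m2 = w.build_ratio_matrix(rng.random(5) + 0.2, rng.random(5) + 0.2)
        rows, cols = rng.permutation(5), rng.permutation(5)
        rs0, _ = w.mantel_spearman(self.m1, m2, self.config)
        rs1, _ = w.mantel_spearman(
            relabel(self.m1, rows, cols), relabel(m2, rows, cols), self.config
        )
        assert rs1 == pytest.approx(rs0, abs=1e-12)

    def test_too_few_cells_raises(self):
        m = w.build_ratio_matrix(np.array([1.0, 2.0]), np.array([3.0, 0.0]))
        with pytest.raises(DegenerateGeneError):
            w.mantel_spearman(m, m, self.config)

    def test_constant_matrix_is_degenerate(self):
        m2 = w.RatioMatrix(
            self.m1.row_ids, self.m1.col_ids,
            np.ones_like(self.m1.values), self.m1.mask.copy(),
        )
        with pytest.raises(DegenerateGeneError, match="degenerate"):
            w.mantel_spearman(self.m1, m2, self.config)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_rank_invariance_under_monotone_transforms(self, seed):
        """r is unchanged by strictly increasing transforms of either matrix."""
        rng = np.random.default_rng(seed)
        m1 = w.build_ratio_matrix(rng.random(4) + 0.2, rng.random(4) + 0.2)
        m2 = w.build_ratio_matrix(rng.random(4) + 0.2, rng.random(4) + 0.2)
        cfg = w.ScreenConfig(n_perm=19, seed=0)
        r0, _ = w.mantel_spearman(m1, m2, cfg)
        for f in (np.log, np.exp, lambda v: 3.0 * v + 7.0):
            mt = w.RatioMatrix(m2.row_ids, m2.col_ids, f(m2.values), m2.mask.copy())
            r1, _ = w.mantel_spearman(m1, mt, cfg)
            assert r1 == pytest.approx(r0, abs=1e-12)


class TestExactEnumeration:
    def _random_pair(self, seed):
        rng = np.random.default_rng(seed)
        m1 = w.build_ratio_matrix(rng.random(3) + 0.2, rng.random(3) + 0.2)
        m2 = w.build_ratio_matrix(rng.random(3) + 0.2, rng.random(3) + 0.2)
        return m1, m2

    def test_exact_p_equals_brute_force_enumeration(self):
        """Exact p agrees with a from-scratch scipy-based enumeration of all
        3! x 3! = 36 row/column relabelings."""
        m1, m2 = self._random_pair(21)
        r_obs = spearman_oracle(m1, m2)
        hits = 0
        for rows in itertools.permutations(range(3)):
            for cols in itertools.permutations(range(3)):
                v = m2.values[np.ix_(rows, cols)]
                r = spearmanr(m1.values.ravel(), v.ravel()).statistic
                hits += r >= r_obs - 1e-12
        r_x, p_x = w.mantel_spearman_exact(m1, m2)
        assert r_x == pytest.approx(r_obs, abs=1e-12)
        assert p_x == pytest.approx(hits / 36, abs=1e-15)

    def test_exact_p_includes_identity_relabeling(self):
        m1, m2 = self._random_pair(22)
        _, p = w.mantel_spearman_exact(m1, m2)
        assert p >= 1 / 36

    def test_size_guard(self):
        rng = np.random.default_rng(1)
        m = w.build_ratio_matrix(rng.random(8) + 0.2, rng.random(8) + 0.2)
        with pytest.raises(ValueError, match="relabelings"):
            w.mantel_spearman_exact(m, m)


class TestScreenAllGenes:
    def test_minimum_p_is_add_one_corrected(self, tiny_expr, tiny_trait):
        filtered, _ = w.median_zero_filter(tiny_expr)
        res = w.screen_all_genes(filtered, tiny_trait, w.ScreenConfig(n_perm=49, seed=3))
        defined = [r for r in res if not math.isnan(r.p)]
        assert defined  # at least one testable gene
        assert all(1 / 50 <= r.p <= 1 for r in defined)

    def test_sorted_by_descending_r(self, small_sim):
        expr, trait, _, _ = small_sim
        filtered, _ = w.median_zero_filter(expr)
        res = w.screen_all_genes(filtered, trait, w.ScreenConfig(n_perm=29, seed=4))
        rs = [r.r for r in res if not math.isnan(r.r)]
        assert rs == sorted(rs, reverse=True)

    def test_degenerate_genes_reported_not_fatal(self, tiny_trait, tiny_expr):
        expr = tiny_expr
        # make one gene all-zero at QG: every ratio cell is 0, zero rank variance
        vals = expr.values.copy()
        vals.loc["gA", expr.sample_ids("QG")] = 0.0
        expr2 = w.ExpressionTable(vals, expr.samples)
        res = w.screen_all_genes(expr2, tiny_trait, w.ScreenConfig(n_perm=19, seed=5))
        by_id = {r.gene_id: r for r in res}
        assert math.isnan(by_id["gA"].r) and not by_id["gA"].is_candidate
        # gUp is constant within each site -> constant ratio cells, also degenerate
        assert math.isnan(by_id["gUp"].r)
        assert not math.isnan(by_id["gDown"].r)

    def test_joint_scheme_runs_on_square_design(self, small_sim):
        expr, trait, _, _ = small_sim
        filtered, _ = w.median_zero_filter(expr)
        cfg = w.ScreenConfig(n_perm=29, seed=6, permutation_scheme="joint")
        res = w.screen_all_genes(filtered, trait, cfg)
        assert len(res) == filtered.n_genes

    def test_two_sided_tail_supported(self, small_sim):
        expr, trait, _, _ = small_sim
        filtered, _ = w.median_zero_filter(expr)
        cfg = w.ScreenConfig(n_perm=29, seed=6, tail="two_sided")
        res = w.screen_all_genes(filtered, trait, cfg)
        assert all(0 < r.p <= 1 for r in res if not math.isnan(r.p))


class TestTraitMatrix:
    def test_trait_matrix_orientation_and_values(self, tiny_expr, tiny_trait):
        m = trait_ratio_matrix(tiny_expr, tiny_trait, w.ScreenConfig())
        assert m.row_ids == ["QG_1", "QG_2", "QG_3"]
        assert m.col_ids == ["JH_1", "JH_2", "JH_3"]
        assert m.values[0, 0] == pytest.approx(3.9 / 3.0)

    def test_missing_trait_sample_is_an_error(self, tiny_expr, tiny_trait):
        shrunk = w.TraitTable(tiny_trait.values.drop(index=["QG_3"]))
        with pytest.raises(ValueError, match="QG_3"):
            trait_ratio_matrix(tiny_expr, shrunk, w.ScreenConfig())
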