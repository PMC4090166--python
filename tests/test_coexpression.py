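import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coexprior import (
    WeightVector,
    combination_weights,
    combine_correlations,
    null_distribution,
    pairwise_correlation,
    significance_cutoff,
)
from coexprior.coexpression import nearest_rank_quantile

from conftest import make_corr, make_panel


class TestPairwiseCorrelation:
    def test_hand_computed_pearson(self):
        # x=(1,2,3,4), y=(1,3,2,4): product-moment formula gives r = 4/5
        panel = make_panel([[1, 2, 3, 4], [1, 3, 2, 4]])
        m = pairwise_correlation(panel)
        assert m.loc("G0", "G1") == pytest.approx(0.8)

    def test_collinear_vectors(self):
        panel = make_panel([[1, 2, 3, 4], [2, 4, 6, 8], [8, 6, 4, 2]])
        m = pairwise_correlation(panel)
        assert m.loc("G0", "G1") == pytest.approx(1.0)
        assert m.loc("G0", "G2") == pytest.approx(-1.0)

    def test_self_correlation_is_one(self, small_panel):
        m = pairwise_correlation(small_panel)
        np.testing.assert_allclose(np.diag(m.r), 1.0)

    def test_matrix_invariants(self, small_panel):
        m = pairwise_correlation(small_panel)
        np.testing.assert_allclose(m.r, m.r.T)
        assert np.abs(m.r).max() <= 1.0

    def test_zero_variance_gene_dropped_with_warning(self, caplog):
        panel = make_panel([[1, 2, 3, 4], [5, 5, 5, 5], [4, 3, 2, 1]])
        with caplog.at_level("WARNING"):
            m = pairwise_correlation(panel)
        assert m.genes == ("G0", "G2")
        assert "zero-variance" in caplog.text

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_spearman_equals_pearson_on_ranks(self, seed):
        """On tie-free data the Spearman path is Pearson applied to ranks."""
        rng = np.random.default_rng(seed)
        values = rng.normal(size=(10, 15))
        panel = make_panel(values)
        spearman = pairwise_correlation(panel, method="spearman")
        ranked = make_panel(stats.rankdata(values, axis=1))
        pearson_on_ranks = pairwise_correlation(ranked, method="pearson")
        np.testing.assert_allclose(spearman.r, pearson_on_ranks.r, atol=1e-12)

    def test_spearman_matches_scipy(self, small_panel):
        m = pairwise_correlation(small_panel, method="spearman")
        expected, _ = stats.spearmanr(small_panel.values.T)
        np.testing.assert_allclose(m.r, expected, atol=1e-12)


class TestCombinationWeights:
    def make_matrices(self, variances):
        """Matrices whose off-diagonal sample variance is exactly as given."""
        mats = []
        for i, v in enumerate(variances):
            sd = math.sqrt(v)
            # three genes -> off-diagonal sample {m-sd, m, m+sd} has variance v
            a, b, c = 0.3 - sd, 0.3, 0.3 + sd
            r = [[1, a, b], [a, 1, c], [b, c, 1]]
            mats.append(make_corr(r, source=f"ind{i + 1}"))
        return mats

    def test_equal_variability_gives_equal_weights(self):
        w = combination_weights(self.make_matrices([0.02, 0.02]))
        np.testing.assert_allclose(w.w, [0.5, 0.5])

    def test_inverse_variance_normalization(self):
        w = combination_weights(self.make_matrices([0.01, 0.04]))
        np.testing.assert_allclose(w.w, [0.8, 0.2])

    def test_weights_sum_to_one_and_are_nonnegative(self, rng):
        panels = [make_panel(rng.normal(size=(8, 20)), individual_id=f"i{k}")
                  for k in range(4)]
        mats = [pairwise_correlation(p) for p in panels]
        w = combination_weights(mats)
        assert w.w.sum() == pytest.approx(1.0)
        assert (w.w >= 0).all()

    def test_lower_variability_receives_larger_weight(self):
        mats = self.make_matrices([0.01, 0.05, 0.02])
        w = combination_weights(mats)
        assert w.w[0] > w.w[2] > w.w[1]

    def test_permuting_individuals_permutes_weights(self):
        mats = self.make_matrices([0.01, 0.05, 0.02])
        w = combination_weights(mats)
        w_perm = combination_weights([mats[2], mats[0], mats[1]])
        np.testing.assert_allclose(w_perm.w, w.w[[2, 0, 1]])

    def test_degenerate_constant_correlations_rejected(self):
        flat = make_corr([[1, 0.5, 0.5], [0.5, 1, 0.5], [0.5, 0.5, 1]])
        with pytest.raises(ValueError, match="variance"):
            combination_weights([flat, flat])

    def test_single_individual_rejected(self):
        with pytest.raises(ValueError):
            combination_weights(self.make_matrices([0.01]))


class TestCombineCorrelations:
    def test_single_matrix_identity(self):
        m = make_corr([[1, 0.6], [0.6, 1]])
        w = WeightVector(("ind1",), np.array([1.0]))
        out = combine_correlations([m], w)
        np.testing.assert_allclose(out.r, m.r)
        assert out.source == "combined:pooled"

    def test_equal_weights_give_plain_mean(self):
        m1 = make_corr([[1, 0.6], [0.6, 1]], source="ind1")
        m2 = make_corr([[1, 0.2], [0.2, 1]], source="ind2")
        w = WeightVector(("ind1", "ind2"), np.array([0.5, 0.5]))
        out = combine_correlations([m1, m2], w)
        assert out.loc("G0", "G1") == pytest.approx(0.4)

    def test_convexity_bounds(self, rng):
        panels = [make_panel(rng.normal(size=(6, 10)), individual_id=f"i{k}")
                  for k in range(3)]
        mats = [pairwise_correlation(p) for p in panels]
        w = combination_weights(mats)
        out = combine_correlations(mats, w)
        stack = np.stack([m.r for m in mats])
        assert (out.r <= stack.max(axis=0) + 1e-12).all()
        assert (out.r >= stack.min(axis=0) - 1e-12).all()
        assert np.abs(out.r).max() <= 1.0

    def test_misaligned_gene_panels_rejected(self):
        m1 = make_corr([[1, 0.5], [0.5, 1]], genes=["A", "B"], source="ind1")
        m2 = make_corr([[1, 0.5], [0.5, 1]], genes=["A", "C"], source="ind2")
        w = WeightVector(("ind1", "ind2"), np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="misaligned"):
            combine_correlations([m1, m2], w)


class TestNearestRankQuantile:
    def test_uniform_grid(self):
        values = np.arange(1, 101) / 100.0
        assert nearest_rank_quantile(values, 0.95) == pytest.approx(0.95)

    def test_constant_distribution(self):
        assert nearest_rank_quantile(np.full(500, 0.3), 0.95) == pytest.approx(0.3)


class TestSignificanceCutoff:
    def test_cutoff_matches_fisher_z_null(self, rng):
        """Independent genes, 30 samples: the 95% |r| quantile should sit near
        tanh(z_0.975 / sqrt(n-3)), the Fisher-z closed form."""
        panel = make_panel(rng.normal(size=(300, 30)))
        spec = significance_cutoff([panel], n_sampled_pairs=40_000, seed=7)
        expected = math.tanh(stats.norm.ppf(0.975) / math.sqrt(30 - 3))
        assert spec.cutoff == pytest.approx(expected, abs=0.03)

    def test_monotone_in_quantile(self, rng):
        panel = make_panel(rng.normal(size=(50, 20)))
        cuts = [
            significance_cutoff([panel], quantile=q, n_sampled_pairs=5000, seed=1).cutoff
            for q in (0.5, 0.8, 0.9, 0.95, 0.99)
        ]
        assert cuts == sorted(cuts)

    def test_too_few_pairs_rejected(self, small_panel):
        with pytest.raises(ValueError, match="unstable"):
            significance_cutoff([small_panel], n_sampled_pairs=50)

    def test_seeded_runs_reproduce(self, small_panel):
        a = significance_cutoff([small_panel], n_sampled_pairs=500, seed=3)
        b = significance_cutoff([small_panel], n_sampled_pairs=500, seed=3)
        assert a.cutoff == b.cutoff


class TestNullDistribution:
    def test_pair_count_for_29_genes(self, rng):
        panel = make_panel(rng.normal(size=(40, 10)))
        out = null_distribution([panel], n_genes=29, seed=0)
        assert len(out.null_abs_r) == 406

    def test_requesting_more_genes_than_universe_fails(self, small_panel):
        with pytest.raises(ValueError, match="available"):
            null_distribution([small_panel], n_genes=11)

    def test_excluded_genes_not_drawn(self, rng):
        panel = make_panel(rng.normal(size=(30, 10)))
        exclude = [f"G{i}" for i in range(10)]
        out = null_distribution([panel], n_genes=20, exclude=exclude, seed=1)
        assert len(out.null_abs_r) == 190  # 20 choose 2: exclusion left exactly 20

    def test_independent_genes_have_median_r_near_zero(self, rng):
        panel = make_panel(rng.normal(size=(80, 100)))
        out = null_distribution([panel], n_genes=29, seed=2)
        # SE of a single null r is ~1/sqrt(n_samples); the median of 406
        # (correlated) pair values stays well within 3x that
        assert abs(out.median_r_null) < 3 / math.sqrt(100)

    def test_ecdf_frame_nondecreasing(self, rng):
        panel = make_panel(rng.normal(size=(30, 12)))
        out = null_distribution([panel], n_genes=15, seed=3)
        frame = out.to_frame()
        ecdf = frame.loc[frame["group"] == "null", "ecdf"].to_numpy()
        assert (np.diff(ecdf) >= 0).all()
        assert ecdf[0] > 0 and ecdf[-1] == pytest.approx(1.0)
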