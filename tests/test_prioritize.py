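import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coexprior import (
    GeneSet,
    connectivity,
    connectivity_table,
    efdr_curve,
    efdr_from_samples,
    leave_one_out_connectivity,
    pairwise_correlation,
    select_prioritized,
)

from conftest import make_corr, make_panel


def matrix_with_candidate_row(correlations):
    """Square matrix for candidate C plus references R1..Rn with given r(C, Ri)."""
    n = len(correlations)
    genes = ["C"] + [f"R{i + 1}" for i in range(n)]
    r = np.eye(n + 1)
    r[0, 1:] = correlations
    r[1:, 0] = correlations
    return make_corr(r, genes=genes)


class TestConnectivity:
    def test_count_and_sum_above_cutoff(self):
        # edges above 0.44: |0.50| and |-0.60| -> K* = 2, K = 1.10
        m = matrix_with_candidate_row([0.50, 0.20, -0.60])
        ref = GeneSet("ref", ("R1", "R2", "R3"))
        k_star, k = connectivity("C", ref, m, cutoff=0.44)
        assert k_star == 2
        assert k == pytest.approx(1.10)

    def test_no_edges_gives_zero_scores(self):
        m = matrix_with_candidate_row([0.1, -0.2, 0.3])
        ref = GeneSet("ref", ("R1", "R2", "R3"))
        assert connectivity("C", ref, m, cutoff=0.44) == (0, 0.0)

    def test_perfect_correlation_reaches_upper_bound(self):
        m = matrix_with_candidate_row([1.0] * 29)
        ref = GeneSet("ref", tuple(f"R{i + 1}" for i in range(29)))
        k_star, k = connectivity("C", ref, m, cutoff=0.44)
        assert k_star == 29 and k == pytest.approx(29.0)

    def test_candidate_in_reference_rejected(self):
        m = matrix_with_candidate_row([0.5, 0.5])
        ref = GeneSet("ref", ("C", "R1", "R2"))
        with pytest.raises(ValueError, match="reference"):
            connectivity("C", ref, m, cutoff=0.4)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), cutoff=st.floats(0.05, 0.95))
    def test_score_bounds_hold(self, seed, cutoff):
        """cutoff*K_star <= K <= K_star: each edge contributes |r| in (cutoff, 1]."""
        rng = np.random.default_rng(seed)
        correlations = rng.uniform(-1, 1, size=8)
        m = matrix_with_candidate_row(correlations)
        ref = GeneSet("ref", tuple(f"R{i + 1}" for i in range(8)))
        k_star, k = connectivity("C", ref, m, cutoff=cutoff)
        assert cutoff * k_star <= k <= k_star

    def test_scores_nonincreasing_in_cutoff(self, rng):
        correlations = rng.uniform(-1, 1, size=10)
        m = matrix_with_candidate_row(correlations)
        ref = GeneSet("ref", tuple(f"R{i + 1}" for i in range(10)))
        results = [connectivity("C", ref, m, cutoff=c) for c in (0.1, 0.3, 0.5, 0.7, 0.9)]
        k_stars = [r[0] for r in results]
        ks = [r[1] for r in results]
        assert k_stars == sorted(k_stars, reverse=True)
        assert ks == sorted(ks, reverse=True)


class TestConnectivityTable:
    def test_ranks_by_descending_K_with_lexicographic_ties(self):
        genes = ["B", "A", "D"]
        # equal K for A and B -> A ranks before B (lexicographic tie-break)
        from coexprior import ConnectivityTable

        t = ConnectivityTable.from_scores(genes, [1, 1, 2], [0.5, 0.5, 0.9])
        frame = t.frame
        assert frame.loc["D", "rank"] == 1
        assert frame.loc["A", "rank"] == 2
        assert frame.loc["B", "rank"] == 3

    def test_ranks_are_a_permutation(self, rng):
        from coexprior import ConnectivityTable

        k = rng.uniform(0, 5, size=20)
        t = ConnectivityTable.from_scores([f"g{i}" for i in range(20)],
                                          np.zeros(20, dtype=int), k)
        assert sorted(t.frame["rank"]) == list(range(1, 21))


class TestLeaveOneOut:
    def test_complete_block_scores_n_minus_one(self):
        n = 5
        r = np.full((n, n), 0.9)
        np.fill_diagonal(r, 1.0)
        m = make_corr(r)
        ref = GeneSet("ref", tuple(m.genes))
        t = leave_one_out_connectivity(ref, m, cutoff=0.5)
        assert (t.K_star == n - 1).all()

    def test_isolated_gene_scores_zero(self):
        n = 4
        r = np.full((n, n), 0.9)
        r[3, :] = r[:, 3] = 0.1
        np.fill_diagonal(r, 1.0)
        m = make_corr(r)
        ref = GeneSet("ref", tuple(m.genes))
        t = leave_one_out_connectivity(ref, m, cutoff=0.5)
        assert t.frame.loc["G3", "K_star"] == 0
        assert (t.frame.loc[["G0", "G1", "G2"], "K_star"] == 2).all()

    def test_agrees_with_brute_force_per_gene(self, rng):
        """Independent oracle: score each gene with the single-candidate path
        on a matrix from which it was never removed."""
        panel = make_panel(rng.normal(size=(6, 30)))
        m = pairwise_correlation(panel)
        ref = GeneSet("ref", tuple(m.genes))
        cutoff = 0.2
        t = leave_one_out_connectivity(ref, m, cutoff)
        for gene in m.genes:
            others = GeneSet("rest", tuple(g for g in m.genes if g != gene))
            k_star, k = connectivity(gene, others, m, cutoff)
            assert t.frame.loc[gene, "K_star"] == k_star
            assert t.frame.loc[gene, "K"] == pytest.approx(k)


class TestEfdrFromSamples:
    def test_ratio_definition(self):
        """Mean of 2.0 random exceedances over 8 observed -> eFDR 0.25."""
        observed = np.array([5.0] * 8 + [1.0] * 12)  # 8 genes exceed T=2
        # each resample row has exactly 2 values above T=2
        resampled = np.tile([5.0, 5.0] + [0.0] * 18, (50, 1))
        curve = efdr_from_samples(observed, resampled, thresholds=np.array([2.0]))
        assert curve.efdr_raw[0] == pytest.approx(0.25)

    def test_undefined_where_no_observed_exceedance(self):
        observed = np.array([1.0, 2.0])
        resampled = np.array([[5.0, 0.0]])
        curve = efdr_from_samples(observed, resampled, thresholds=np.array([3.0]))
        assert np.isnan(curve.efdr_raw[0])

    def test_monotonized_curve_nonincreasing(self, rng):
        observed = rng.uniform(0, 10, size=30)
        resampled = rng.uniform(0, 10, size=(100, 30))
        curve = efdr_from_samples(observed, resampled)
        valid = curve.efdr[~np.isnan(curve.efdr)]
        assert (np.diff(valid) <= 1e-12).all()

    def test_reported_efdr_truncated_at_one(self, rng):
        observed = np.array([1.0])
        resampled = np.full((10, 3), 10.0)  # 3 null exceedances per resample
        curve = efdr_from_samples(observed, resampled, thresholds=np.array([0.5]))
        assert curve.efdr_raw[0] == pytest.approx(3.0)  # raw ratio kept
        assert curve.efdr[0] == 1.0

    def test_chosen_T_is_where_curve_crosses_target_from_above(self):
        observed = np.array([1.0, 2.0, 3.0, 4.0])
        resampled = np.tile([2.5, 0.0, 0.0, 0.0], (20, 1))
        curve = efdr_from_samples(observed, resampled, target=0.25)
        # raw eFDR is 0 for T just below 3 and above, but 0.5 at T=2; the
        # raw dip to 0.25 just below T=1 cannot claim the target because
        # stricter thresholds in between exceed it
        assert curve.chosen_T == np.nextafter(3.0, -np.inf)

    def test_lax_threshold_cannot_undercut_stricter_one(self):
        observed = np.array([1.0, 5.0])
        resampled = np.tile([4.0, 0.0], (10, 1))
        curve = efdr_from_samples(observed, resampled, target=0.3)
        # just below T=5 the raw ratio is 0; just below T=1 it is 1/2 -> the
        # monotone curve keeps every T below 4 at >= 1/2
        i = np.searchsorted(curve.thresholds, 1.0) - 1
        assert curve.efdr[i] >= 0.5
        assert curve.chosen_T == np.nextafter(5.0, -np.inf)


class TestEndToEndEfdr:
    def test_null_candidates_give_efdr_near_one_at_small_T(self, rng):
        """Candidates exchangeable with the resampled null sets: for small T
        observed and resampled exceedance counts agree, so eFDR ~ 1."""
        panel = make_panel(rng.normal(size=(120, 40)))
        ref = GeneSet("ref", tuple(panel.genes[:10]))
        cands = GeneSet("cand", tuple(panel.genes[10:40]))
        m = pairwise_correlation(panel)
        table = connectivity_table(cands, ref, m, cutoff=0.4)
        curve = efdr_curve(table, [panel], ref, 0.4, n_resamples=200, seed=9)
        # at the smallest threshold nearly all observed and null genes exceed,
        # so the ratio concentrates near 1 (Monte-Carlo noise allowed)
        assert curve.efdr_raw[0] == pytest.approx(1.0, abs=0.4)

    def test_resampling_is_bit_reproducible(self, rng):
        panel = make_panel(rng.normal(size=(80, 20)))
        ref = GeneSet("ref", tuple(panel.genes[:8]))
        cands = GeneSet("cand", tuple(panel.genes[8:20]))
        m = pairwise_correlation(panel)
        table = connectivity_table(cands, ref, m, cutoff=0.4)
        a = efdr_curve(table, [panel], ref, 0.4, n_resamples=50, seed=11)
        b = efdr_curve(table, [panel], ref, 0.4, n_resamples=50, seed=11)
        np.testing.assert_array_equal(a.efdr_raw, b.efdr_raw)
        assert a.chosen_T == b.chosen_T

    def test_resample_size_exceeding_universe_rejected(self, rng):
        panel = make_panel(rng.normal(size=(20, 10)))
        ref = GeneSet("ref", tuple(panel.genes[:5]))
        cands = GeneSet("cand", tuple(panel.genes[5:15]))
        m = pairwise_correlation(panel)
        table = connectivity_table(cands, ref, m, cutoff=0.4)
        with pytest.raises(ValueError, match="eligible"):
            efdr_curve(table, [panel], ref, 0.4, set_size=10, n_resamples=10, seed=0)


class TestSelectPrioritized:
    def test_candidate_just_above_threshold_is_prioritized(self):
        from coexprior import ConnectivityTable, EFDRCurve

        t = ConnectivityTable.from_scores(["A", "B"], [8, 2], [7.5, 2.0])
        curve = EFDRCurve(
            thresholds=np.array([2.0, 7.4]),
            efdr_raw=np.array([0.8, 0.2]),
            efdr=np.array([0.8, 0.2]),
            target=0.25, chosen_T=7.4, n_resamples=100, seed=0,
        )
        out = select_prioritized(t, curve)
        assert out.frame.loc["A", "prioritized"]
        assert not out.frame.loc["B", "prioritized"]

    def test_no_threshold_reaches_target_prioritizes_nothing(self, caplog):
        from coexprior import ConnectivityTable, EFDRCurve

        t = ConnectivityTable.from_scores(["A", "B"], [1, 1], [1.0, 2.0])
        curve = EFDRCurve(
            thresholds=np.array([1.0, 2.0]),
            efdr_raw=np.array([0.9, 0.8]),
            efdr=np.array([0.9, 0.8]),
            target=0.25, chosen_T=None, n_resamples=100, seed=0,
        )
        with caplog.at_level("WARNING"):
            out = select_prioritized(t, curve)
        assert not out.frame["prioritized"].any()
        assert "prioritizing nothing" in caplog.text
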