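"""Detection filter, quantile normalization, fold changes, probe collapse."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import myocourse as mc
from myocourse.containers import FoldChangeTable, ProbeGeneMap

from conftest import make_matrix


class TestFilterDetected:
    def test_boundary_inclusive_and_removal(self):
        # probe detected in exactly min_samples samples is kept; 0 removed
        flags = np.zeros((3, 24), dtype=bool)
        flags[1, :3] = True          # exactly 3 of 24
        flags[2, :10] = True
        m = make_matrix(np.full((3, 24), 7.0), flags=flags)
        out = mc.filter_detected(m, 3)
        assert list(out.probes) == ["p1", "p2"]

    def test_count_matches_brute_force(self, rng):
        flags = rng.random((200, 24)) > 0.4
        m = make_matrix(rng.normal(7, 1, (200, 24)), flags=flags)
        out = mc.filter_detected(m, 3)
        assert out.values.shape[0] == int((flags.sum(axis=1) >= 3).sum())

    def test_monotone_in_threshold(self, rng):
        flags = rng.random((100, 12)) > 0.5
        m = make_matrix(rng.normal(7, 1, (100, 12)), flags=flags)
        prev = set(mc.filter_detected(m, 2).probes)
        for k in (4, 6, 8):
            cur = set(mc.filter_detected(m, k).probes)
            assert cur <= prev
            prev = cur

    def test_min_samples_above_count_errors(self):
        m = make_matrix(np.ones((2, 4)) * 6)
        with pytest.raises(ValueError):
            mc.filter_detected(m, 5)


class TestQuantileNormalize:
    def test_two_column_hand_case(self):
        m = make_matrix(np.array([[1.0, 6.0], [2.0, 4.0], [3.0, 5.0]]))
        out = mc.quantile_normalize(m).values.to_numpy()
        expected = np.array([[2.5, 4.5], [3.5, 2.5], [4.5, 3.5]])
        np.testing.assert_allclose(out, expected)

    def test_identical_columns_fixed_point(self):
        col = np.array([5.0, 9.0, 7.0, 6.0])
        m = make_matrix(np.column_stack([col] * 4))
        out = mc.quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out, np.column_stack([col] * 4))

    def test_sorted_columns_identical_and_idempotent(self, rng):
        m = make_matrix(rng.normal(8, 2, (50, 6)))
        out = mc.quantile_normalize(m)
        arr = out.values.to_numpy()
        ref = np.sort(arr[:, 0])
        for j in range(arr.shape[1]):
            np.testing.assert_allclose(np.sort(arr[:, j]), ref, atol=1e-9)
        again = mc.quantile_normalize(out).values.to_numpy()
        np.testing.assert_allclose(again, arr, atol=1e-12)

    def test_rank_preserving_per_column(self, rng):
        m = make_matrix(rng.normal(8, 2, (40, 5)))
        out = mc.quantile_normalize(m)
        for col in m.values.columns:
            before = m.values[col].rank()
            after = out.values[col].rank()
            assert (before == after).all()

    def test_missing_values_rejected(self):
        vals = np.ones((3, 3)) * 7
        vals[1, 1] = np.nan
        m = make_matrix(vals)
        with pytest.raises(ValueError, match="missing"):
            mc.quantile_normalize(m)


class TestLog2FC:
    def test_simple_subtraction(self):
        m = make_matrix(np.array([[5.0, 5.0, 7.0]]), days=[0, 0, 2])
        fc = mc.log2fc_vs_reference(m, ["s0", "s1"])
        assert fc.replicates.loc["p0", "s2"] == pytest.approx(2.0)

    def test_reference_mean_fc_zero(self, rng):
        m = make_matrix(rng.normal(7, 1, (20, 6)), days=[0, 0, 0, 2, 2, 2])
        ref = m.samples_where(day=0)
        fc = mc.log2fc_vs_reference(m, ref)
        np.testing.assert_allclose(
            fc.replicates[ref].mean(axis=1), 0.0, atol=1e-12
        )

    def test_quiescent_minus_activated_mean_direction(self):
        # early-activated sample minus mean of late-activated triplicates
        m = make_matrix(
            np.array([[8.0, 6.0, 6.5, 5.5]]), days=[0, 3, 3, 3],
        )
        fc = mc.log2fc_vs_reference(m, m.samples_where(day=3))
        assert fc.replicates.loc["p0", "s0"] == pytest.approx(8.0 - 6.0)

    def test_empty_reference_errors(self):
        m = make_matrix(np.ones((2, 3)) * 6)
        with pytest.raises(ValueError, match="empty reference"):
            mc.log2fc_vs_reference(m, [])


class TestCollapseToGenes:
    def _fc(self, rows: dict[str, list[float]]) -> FoldChangeTable:
        return FoldChangeTable(pd.DataFrame(rows).T)

    def test_max_abs_fc_wins(self):
        fc = self._fc({"pA": [1.5, 1.5], "pB": [-2.3, -2.3]})
        pg = ProbeGeneMap({"pA": "G1", "pB": "G1"})
        out = mc.collapse_to_genes(fc, pg)
        assert out.mean.loc["G1"] == pytest.approx(-2.3)

    def test_single_probe_unchanged_and_idempotent(self):
        fc = self._fc({"pA": [0.5, 1.0]})
        pg = ProbeGeneMap({"pA": "G1"})
        out = mc.collapse_to_genes(fc, pg)
        assert list(out.index) == ["G1"]
        ident = ProbeGeneMap({"G1": "G1"})
        again = mc.collapse_to_genes(out, ident)
        pd.testing.assert_frame_equal(again.replicates, out.replicates)

    def test_tie_breaks_lexicographic(self):
        fc = self._fc({"pB": [2.0], "pA": [-2.0]})
        pg = ProbeGeneMap({"pA": "G1", "pB": "G1"})
        out = mc.collapse_to_genes(fc, pg)
        assert out.replicates.iloc[0, 0] == pytest.approx(-2.0)

    def test_matches_brute_force_argmax(self, rng):
        n_genes, max_probes = 40, 3
        rows, mapping = {}, {}
        for g in range(n_genes):
            for p in range(int(rng.integers(1, max_probes + 1))):
                pid = f"g{g}_p{p}"
                rows[pid] = list(rng.normal(0, 2, 3))
                mapping[pid] = f"G{g}"
        fc = self._fc(rows)
        out = mc.collapse_to_genes(fc, ProbeGeneMap(mapping))
        means = fc.mean
        for gene in out.index:
            probes = [p for p, g in mapping.items() if g == gene]
            best = max(sorted(probes), key=lambda p: abs(means[p]))
            assert out.mean[gene] == pytest.approx(means[best])

    def test_unmapped_probes_dropped_with_warning(self):
        fc = self._fc({"pA": [1.0], "pX": [9.0]})
        pg = ProbeGeneMap({"pA": "G1"})
        with pytest.warns(UserWarning, match="without gene mapping"):
            out = mc.collapse_to_genes(fc, pg)
        assert list(out.index) == ["G1"]


class TestVariationFilter:
    @pytest.mark.parametrize(
        "profile,kept",
        [
            ([8.0, 8.0, 8.0], False),       # flat: range 0 < 2
            ([2.0, 3.0, 4.5], False),       # max 4.5 < floor 5
            ([4.0, 5.0, 6.5], True),        # range 2.5, max 6.5
            ([3.0, 4.0, 5.0], True),        # boundaries exactly met
        ],
    )
    def test_threshold_rules(self, profile, kept):
        m = make_matrix(np.array([profile]))
        assert (len(mc.variation_filter(m, 2.0, 5.0)) == 1) is kept

    def test_monotone_in_both_thresholds(self, rng):
        m = make_matrix(rng.normal(6, 2, (200, 8)))
        base = set(mc.variation_filter(m, 2.0, 5.0))
        assert set(mc.variation_filter(m, 3.0, 5.0)) <= base
        assert set(mc.variation_filter(m, 2.0, 6.0)) <= base


class TestCoexpressionNeighbors:
    def test_self_always_r1(self, rng):
        m = make_matrix(rng.normal(7, 1, (10, 8)))
        out = mc.coexpression_neighbors(m, "p0", 0.8)
        assert out.index[0] == "p0"
        assert out.iloc[0] == pytest.approx(1.0)

    def test_exact_negation_excluded(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        m = make_matrix(np.vstack([base, -base + 10]))
        out = mc.coexpression_neighbors(m, "p0", 0.8)
        assert "p1" not in out.index

    def test_planted_cluster_mates_recovered(self):
        hits = 0
        for seed in range(20):
            spec = mc.SynthSpec(n_genes=60, n_background_genes=40,
                                noise_sd=0.2, seed=seed,
                                probes_per_gene={1: 1.0})
            m, pg, truth = mc.simulate_timecourse(spec)
            query = truth.partition()["myotome"][0] + "_p1"
            out = mc.coexpression_neighbors(m, query, 0.8)
            mates = {g + "_p1" for g in truth.partition()["myotome"]}
            if mates <= set(out.index):
                hits += 1
        assert hits >= 18     # >= 90% of seeds recover all cluster-mates

    def test_zero_variance_query_errors(self):
        m = make_matrix(np.vstack([np.ones(5) * 7, np.arange(5.0)]))
        with pytest.raises(ValueError, match="zero variance"):
            mc.coexpression_neighbors(m, "p0", 0.8)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_quantile_normalize_definition_on_random_matrices(seed):
    """Columnwise sorted vectors agree to 1e-9 for arbitrary inputs."""
    r = np.random.default_rng(seed)
    m = make_matrix(r.normal(0, 3, (30, 4)))
    arr = mc.quantile_normalize(m).values.to_numpy()
    ref = np.sort(arr[:, 0])
    for j in range(1, 4):
        np.testing.assert_allclose(np.sort(arr[:, j]), ref, atol=1e-9)
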