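"""Trace quantification: clearance formula, repair, summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import pytagsim as pt
from pytagsim.quantify import RepairSettings


def cell(cyt, times=None, pre=1, nuc=None, exp="e0", cid="c0", rexp=None,
         zexp=None):
    cyt = np.asarray(cyt, float)
    t = np.arange(len(cyt), dtype=float) * 30.0 if times is None else times
    return pt.CellTrace(cell_id=cid, times=t, cytosolic=cyt, nuclear=nuc,
                        pre_stimulus_frames=pre, experiment_id=exp,
                        receptor_expression=rexp, reporter_expression=zexp)


class TestClearanceActivity:
    def test_constant_intensity_reads_zero(self):
        act = pt.clearance_activity(cell([100, 100, 100, 100]))
        np.testing.assert_allclose(act.activity, 0.0)

    def test_intensity_drop_is_positive_clearance(self):
        act = pt.clearance_activity(cell([100.0, 60.0]))
        assert act.activity[1] == pytest.approx(40.0)

    def test_brightening_is_negative_clearance(self):
        act = pt.clearance_activity(cell([100.0, 120.0]))
        assert act.activity[1] == pytest.approx(-20.0)

    def test_baseline_is_mean_of_prestimulus_frames(self):
        act = pt.clearance_activity(cell([90.0, 110.0, 50.0], pre=2))
        assert act.baseline == pytest.approx(100.0)
        assert act.activity[2] == pytest.approx(50.0)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            pt.clearance_activity(cell([0.0, 10.0]))


class TestAberrantFrameRepair:
    def make_experiment(self, n_cells=10, n_frames=20, seed=0):
        rng = np.random.default_rng(seed)
        return [cell(100.0 * (1 + 0.02 * rng.standard_normal(n_frames)),
                     cid=f"c{i}") for i in range(n_cells)]

    def test_clean_experiment_untouched(self):
        traces = self.make_experiment()
        repaired, flagged = pt.repair_aberrant_frames(traces)
        assert flagged == []
        for a, b in zip(traces, repaired):
            np.testing.assert_array_equal(a.cytosolic, b.cytosolic)

    @pytest.mark.parametrize("fold", [3.0, 1 / 3.0])
    def test_injected_frame_wide_artifact_flagged_and_replaced(self, fold):
        traces = self.make_experiment()
        bad = 7
        corrupted = [cell(np.where(np.arange(20) == bad, fold, 1.0)
                          * tr.cytosolic, cid=tr.cell_id) for tr in traces]
        repaired, flagged = pt.repair_aberrant_frames(corrupted)
        assert flagged == [bad]
        for orig, rep in zip(traces, repaired):
            # placeholder rule: flagged frame takes the previous frame
            assert rep.cytosolic[bad] == orig.cytosolic[bad - 1]
            # repair locality: all other frames untouched
            keep = np.arange(20) != bad
            np.testing.assert_array_equal(rep.cytosolic[keep],
                                          orig.cytosolic[keep])

    def test_single_cell_spike_not_flagged(self):
        traces = self.make_experiment()
        spiked = [tr.cytosolic.copy() for tr in traces]
        spiked[0][7] *= 5.0
        out, flagged = pt.repair_aberrant_frames(
            [cell(s, cid=f"c{i}") for i, s in enumerate(spiked)])
        assert flagged == []

    def test_consecutive_artifacts_both_flagged(self):
        traces = self.make_experiment()
        factor = np.ones(20)
        factor[[7, 8]] = 3.0
        corrupted = [cell(factor * tr.cytosolic, cid=tr.cell_id)
                     for tr in traces]
        _, flagged = pt.repair_aberrant_frames(corrupted)
        assert flagged == [7, 8]

    def test_first_frame_artifact_is_an_error(self):
        # frame 0 has no predecessor to serve as placeholder; a corrupted
        # frame 0 makes every later frame look like a coordinated jump and
        # must raise rather than silently "repair" the whole movie
        traces = self.make_experiment()
        factor = np.ones(20)
        factor[0] = 3.0
        corrupted = [cell(factor * tr.cytosolic, cid=tr.cell_id)
                     for tr in traces]
        with pytest.raises(ValueError, match="first frame"):
            pt.repair_aberrant_frames(corrupted)

    def test_thresholds_configurable(self):
        traces = self.make_experiment()
        factor = np.ones(20)
        factor[7] = 1.2              # below the default 30% rule
        corrupted = [cell(factor * tr.cytosolic, cid=tr.cell_id)
                     for tr in traces]
        _, flagged = pt.repair_aberrant_frames(corrupted)
        assert flagged == []
        _, flagged = pt.repair_aberrant_frames(
            corrupted, RepairSettings(median_change=0.10))
        assert flagged == [7]


class TestNormalization:
    def test_minmax_examples(self):
        np.testing.assert_allclose(pt.minmax_normalize([0, 50, 100]),
                                   [0, 0.5, 1.0])
        np.testing.assert_allclose(pt.minmax_normalize([-10, 0, 30]),
                                   [0, 0.25, 1.0])

    @given(st.lists(st.integers(-1000, 1000), min_size=3, max_size=30,
                    unique=True))
    def test_minmax_idempotent_and_order_preserving(self, values):
        v = np.array(values, dtype=float) / 10.0
        n1 = pt.minmax_normalize(v)
        np.testing.assert_allclose(pt.minmax_normalize(n1), n1, atol=1e-12)
        assert np.array_equal(np.argsort(v), np.argsort(n1))

    def test_constant_trace_rejected(self):
        with pytest.raises(ValueError):
            pt.minmax_normalize([5.0, 5.0, 5.0])


class TestTimeToHalfMax:
    def test_linear_ramp(self):
        t = np.array([0, 1, 2, 3, 4.0]) * 60
        th, ok = pt.time_to_half_max([0, 25, 50, 75, 100.0], t)
        assert ok and th == pytest.approx(120.0)

    def test_interpolated_crossing(self):
        th, ok = pt.time_to_half_max([0, 100, 100.0],
                                     np.array([0, 60, 120.0]))
        assert ok and th == pytest.approx(30.0)

    def test_degenerate_start_above_half(self):
        th, ok = pt.time_to_half_max([80, 90, 100.0],
                                     np.array([0, 60, 120.0]))
        assert not ok and th == 0.0

    def test_never_positive_rejected(self):
        with pytest.raises(ValueError):
            pt.time_to_half_max([-5, -2, -10.0], np.array([0, 1, 2.0]))


class TestKtr:
    def test_ratio_formula(self):
        tr = cell([100, 200, 300.0], nuc=np.array([100, 100, 100.0]))
        np.testing.assert_allclose(pt.ktr_activity(tr), [1, 2, 3.0])

    def test_missing_nuclear_channel_rejected(self):
        with pytest.raises(ValueError, match="nuclear"):
            pt.ktr_activity(cell([1, 2, 3.0]))


class TestMembraneEnrichment:
    def test_flat_profile(self):
        peak, pos = pt.membrane_enrichment(np.full(10, 7.0))
        assert peak == 7.0

    def test_gaussian_bump_on_baseline(self):
        x, y = pt.generate_line_profile(membrane_position=4.0, amplitude=10,
                                        width=0.5, baseline=2.0)
        peak, pos = pt.membrane_enrichment(y, x)
        assert peak == pytest.approx(12.0, rel=1e-6)
        assert pos == pytest.approx(4.0, abs=0.11)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            pt.membrane_enrichment(np.array([]))


class TestReplicateAggregation:
    def act(self, values, exp, cid):
        return pt.ActivityTrace(cell_id=cid, times=np.arange(3.0),
                                activity=np.asarray(values, float),
                                baseline=1.0, experiment_id=exp)

    def test_single_experiment_has_zero_sd(self):
        s = pt.aggregate_replicates([self.act([1, 2, 3], "a", "c1"),
                                     self.act([3, 4, 5], "a", "c2")])
        np.testing.assert_allclose(s.grand_mean, [2, 3, 4])
        np.testing.assert_allclose(s.sd, 0.0)

    def test_two_constant_experiments(self):
        s = pt.aggregate_replicates([self.act([10] * 3, "a", "c1"),
                                     self.act([30] * 3, "b", "c2")])
        np.testing.assert_allclose(s.grand_mean, 20.0)
        np.testing.assert_allclose(s.sd, 14.142135623730951)

    def test_hierarchical_differs_from_pooled_on_unbalanced_design(self):
        # experiment a: 3 cells at 0; experiment b: 1 cell at 12
        traces = [self.act([0] * 3, "a", f"c{i}") for i in range(3)]
        traces.append(self.act([12] * 3, "b", "c9"))
        s = pt.aggregate_replicates(traces)
        # hierarchical: mean of (0, 12) = 6; pooled would give 3
        np.testing.assert_allclose(s.grand_mean, 6.0)
        pooled = np.mean([0, 0, 0, 12])
        assert not np.allclose(s.grand_mean, pooled)
        np.testing.assert_allclose(s.sd, np.std([0, 12], ddof=1))

    def test_invariant_to_cell_and_experiment_order(self):
        traces = [self.act([1, 2, 3], "a", "c1"), self.act([5, 1, 0], "a",
                                                           "c2"),
                  self.act([2, 2, 2], "b", "c3")]
        s1 = pt.aggregate_replicates(traces)
        s2 = pt.aggregate_replicates(traces[::-1])
        np.testing.assert_allclose(s1.grand_mean, s2.grand_mean)
        np.testing.assert_allclose(s1.sd, s2.sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pt.aggregate_replicates([])


class TestExpressionRatioSorting:
    def test_orders_rows_by_ratio(self):
        traces = [cell([1, 1.0], cid="hi", rexp=10.0, zexp=1.0),
                  cell([1, 1.0], cid="lo", rexp=1.0, zexp=1.0),
                  cell([1, 1.0], cid="mid", rexp=5.0, zexp=1.0)]
        df = pt.sort_by_expression_ratio(traces)
        assert list(df["cell_id"]) == ["lo", "mid", "hi"]
        assert df["expression_ratio"].is_monotonic_increasing
        # reverse input gives the same output order
        df2 = pt.sort_by_expression_ratio(traces[::-1])
        assert list(df2["cell_id"]) == ["lo", "mid", "hi"]

    def test_zero_reporter_expression_rejected(self):
        with pytest.raises(ValueError):
            pt.sort_by_expression_ratio(
                [cell([1, 1.0], rexp=1.0, zexp=0.0)])


class TestTidyTableInterchange:
    def test_roundtrip(self, tmp_path):
        traces = [cell([10, 9, 8.0], cid="c1", rexp=2.0, zexp=1.0,
                       nuc=np.array([5, 5, 5.0])),
                  cell([7, 6, 5.0], cid="c2", rexp=1.0, zexp=1.0,
                       nuc=np.array([4, 4, 4.0]))]
        df = pt.traces_to_frame(traces)
        path = tmp_path / "traces.tsv"
        df.to_csv(path, sep="\t", index=False)
        import pandas as pd
        back = pt.frame_to_traces(pd.read_csv(path, sep="\t"))
        assert len(back) == 2
        np.testing.assert_allclose(back[0].cytosolic, traces[0].cytosolic)
        np.testing.assert_allclose(back[1].nuclear, traces[1].nuclear)
        assert back[0].receptor_expression == 2.0
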