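"""Simulated experiments: readout, regimes, scenarios, serialization."""

import numpy as np
import pytest

import pytagsim as pt
from pytagsim.simulate import ClassifierThresholds, Trajectory


def make_trace(times, clearance, params):
    """Trajectory wrapper around a hand-built clearance trace."""
    states = np.zeros((len(times), 16))
    return Trajectory(times=np.asarray(times, float),
                      states=states,
                      clearance=np.asarray(clearance, float),
                      params=params, ligand=pt.LigandSpec())


class TestClearanceReadout:
    def test_prestimulus_state_reads_zero(self, params, index):
        state = np.zeros(16)
        state[index.free_reporter] = params.reporter_total
        assert pt.clearance_from_state(state, index,
                                       params.reporter_total) == 0.0

    def test_all_bound_reads_hundred(self, params, index):
        state = np.zeros(16)
        assert pt.clearance_from_state(state, index,
                                       params.reporter_total) == 100.0

    def test_partial_clearance(self, params, index):
        state = np.zeros(16)
        state[index.free_reporter] = 0.6 * params.reporter_total
        assert pt.clearance_from_state(
            state, index, params.reporter_total) == pytest.approx(40.0)

    def test_nonpositive_reporter_total_rejected(self, index):
        with pytest.raises(ValueError):
            pt.clearance_from_state(np.zeros(16), index, 0.0)


class TestTimecourse:
    def test_zero_dose_stays_flat(self, params):
        traj = pt.simulate_timecourse(params, pt.LigandSpec(dose_ng_ml=0.0),
                                      duration=600.0)
        assert np.abs(traj.clearance).max() < 1e-8

    def test_high_dose_biphasic_shape(self, base_trajectory):
        c, t = base_trajectory.clearance, base_trajectory.times
        assert c[0] == 0.0
        assert np.all(np.diff(c) > -1e-6)            # monotone rise
        # fast phase: half the 5-min level inside the first minute
        assert np.interp(60, t, c) > 0.5 * np.interp(300, t, c)
        # continued slow rise after 5 min
        assert c[-1] > 1.05 * np.interp(300, t, c)

    def test_clearance_bounds_and_conservation(self, base_trajectory, index):
        tr = base_trajectory
        assert np.all(tr.clearance >= 0.0) and np.all(tr.clearance <= 100.0)
        rec = index.receptor_weights @ tr.states.T
        rep = index.reporter_weights @ tr.states.T
        assert np.abs(rec / tr.params.receptor_total - 1).max() < 1e-6
        assert np.abs(rep / tr.params.reporter_total - 1).max() < 1e-6

    def test_serialization_roundtrip(self, base_trajectory, tmp_path):
        path = tmp_path / "traj.tsv"
        base_trajectory.write(path)
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns[1:17]) == list(base_trajectory.index.labels)
        np.testing.assert_allclose(df["clearance_pct"],
                                   base_trajectory.clearance)
        assert path.with_suffix(".tsv.json").exists()


class TestRegimeClassifier:
    def test_flat_zero_trace(self, params):
        t = np.arange(0, 1801, 5.0)
        lab = pt.classify_kinetics(make_trace(t, np.zeros_like(t), params))
        assert lab.label == "flat"

    def test_constructed_peak_plateau(self, params):
        t = np.arange(0, 1801, 5.0)
        c = 20.0 * np.exp(-t / 2000) * (1 - np.exp(-t / 20.0))
        lab = pt.classify_kinetics(make_trace(t, c, params))
        assert lab.label == "peak-plateau"
        assert lab.diagnostics["overshoot_ratio"] > 1.02

    def test_constructed_biphasic(self, params):
        t = np.arange(0, 1801, 5.0)
        c = 20 * (1 - np.exp(-t / 20.0)) + 10 * (1 - np.exp(-t / 900.0))
        lab = pt.classify_kinetics(make_trace(t, c, params))
        assert lab.label == "biphasic-rising"

    def test_constructed_gradual(self, params):
        # steady ramp: no fast phase, no overshoot
        t = np.arange(0, 1801, 5.0)
        c = 30 * t / 1800.0
        lab = pt.classify_kinetics(make_trace(t, c, params))
        assert lab.label == "gradual-rising"

    def test_short_trace_rejected(self, params):
        t = np.arange(0, 601, 5.0)
        with pytest.raises(ValueError, match="30 min"):
            pt.classify_kinetics(make_trace(t, np.zeros_like(t), params))

    def test_thresholds_are_configurable(self, params):
        t = np.arange(0, 1801, 5.0)
        c = 30 * (1 - np.exp(-t / 600.0))
        th = ClassifierThresholds(flat_end_pct=50.0)
        assert pt.classify_kinetics(make_trace(t, c, params),
                                    th).label == "flat"


class TestGbmScenario:
    def test_mutant_response_stronger_and_more_gradual(self, params):
        res = pt.simulate_gbm_scenario(params)
        wt, gbm = res["wt"], res["gbm"]
        assert gbm.clearance_at(1800) > wt.clearance_at(1800)
        t_wt = pt.time_to_half_max(wt.clearance, wt.times)[0]
        t_gbm = pt.time_to_half_max(gbm.clearance, gbm.times)[0]
        assert t_gbm > t_wt

    def test_reverting_scalings_reproduces_wt(self, params):
        res = pt.simulate_gbm_scenario(params)
        again = pt.simulate_timecourse(
            params, pt.LigandSpec(name="x", beta=50.0, gamma=100.0,
                                  dose_ng_ml=20.0))
        assert np.array_equal(res["wt"].clearance, again.clearance)

    def test_literal_interpretation_is_available(self, params):
        res = pt.simulate_gbm_scenario(params, interpretation="literal")
        assert res["gbm"].params.k3 == pytest.approx(
            params.k3 * 100 * 650, rel=1e-12)
        with pytest.raises(ValueError):
            pt.simulate_gbm_scenario(params, interpretation="bogus")


class TestExpressionRatioSweep:
    def test_translocation_monotone_and_saturating(self, params):
        df = pt.expression_ratio_sweep(
            params, ratios=np.linspace(0.1, 6.0, 12), duration=900.0)
        y = df["translocation_pct"].to_numpy()
        assert np.all(np.diff(y) >= -1e-9)
        # saturation: last increment much smaller than first
        assert (y[-1] - y[-2]) < 0.2 * (y[1] - y[0])

    def test_vanishing_ratio_gives_vanishing_translocation(self, params):
        df = pt.expression_ratio_sweep(params, ratios=[1e-3], duration=600.0)
        assert df["translocation_pct"].iloc[0] < 0.5

    def test_invalid_ratios_rejected(self, params):
        with pytest.raises(ValueError):
            pt.expression_ratio_sweep(params, ratios=[])
        with pytest.raises(ValueError):
            pt.expression_ratio_sweep(params, ratios=[-1.0])


class TestK6Scan:
    def test_single_default_value_matches_plain_run(self, params,
                                                    base_trajectory):
        df = pt.scan_k6(params, [params.k6], pt.LigandSpec())
        assert df["amplitude_pct"].iloc[0] == pytest.approx(
            base_trajectory.clearance[-1])

    def test_prestimulus_dimer_decreases_with_k6(self, params):
        df = pt.scan_k6(params, [5e-4, 5e-3, 5e-2], pt.LigandSpec())
        d = df["prestimulus_dimer_M"].to_numpy()
        assert np.all(np.diff(d) < 0)

    def test_empty_scan_rejected(self, params):
        with pytest.raises(ValueError):
            pt.scan_k6(params, [], pt.LigandSpec())
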