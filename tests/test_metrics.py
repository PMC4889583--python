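import numpy as np
import pytest

from remapnet.geometry import SheetSpec, encode_bump
from remapnet.metrics import (
    RemappingTrace,
    aggregate_runs,
    centroid_distances,
    extract_trace,
    jump_statistic,
    remapping_onset,
    snapshot_step,
    weight_magnitude_ratio,
)
from remapnet.network import NetworkConfig, TrialRecord, init_weights
from remapnet.trials import LatencyConfig, TrialSpec, make_trial


def _record_with_fef(fef, sheet, spec=None, latencies=None):
    spec = spec or TrialSpec((10.0, 0.0), (0.0, -20.0))
    tl = make_trial(spec, latencies or LatencyConfig(), sheet)
    T = tl.n_steps
    nan = np.full((T, 2), np.nan)
    return TrialRecord(timeline=tl, hidden=np.zeros_like(fef), fef=fef,
                       bc=None, decoded=nan, error=nan,
                       error_magnitude=np.full(T, np.nan))


def _trace(ff, rf=None, mid=None, dt=10.0, onset_ms=120.0):
    ff = np.asarray(ff, float)
    T = ff.size
    z = np.zeros(T)
    return RemappingTrace(
        times_ms=np.arange(T) * dt, rf=np.asarray(rf, float) if rf is not None
        else z, ff=ff, midpoint=np.asarray(mid, float) if mid is not None
        else z, centroid=np.full((T, 2), np.nan), saccade_onset_ms=onset_ms,
        sc_on_ms=50.0, ep_switch_ms=100.0, retina_switch_ms=140.0)


class TestExtractTrace:
    def test_static_rf_bump_leaves_ff_and_midpoint_silent(self, sheet):
        spec = TrialSpec((10.0, 0.0), (0.0, -20.0))
        tl = make_trial(spec, LatencyConfig(), sheet)
        fef = np.tile(encode_bump(spec.retinal_pre, sheet),
                      (tl.n_steps, 1, 1))
        trace = extract_trace(_record_with_fef(fef, sheet, spec), sheet)
        assert np.all(trace.rf == 1.0)
        # RF and FF are 20 deg apart; with a 3 deg bump both the FF and the
        # midpoint unit see only a negligible tail
        assert trace.ff.max() < 1e-4
        assert trace.midpoint.max() < 0.01

    def test_centroid_of_pure_rf_bump_is_rf_location(self, sheet):
        spec = TrialSpec((10.0, 0.0), (0.0, -20.0))
        tl = make_trial(spec, LatencyConfig(), sheet)
        fef = np.tile(encode_bump(spec.retinal_pre, sheet), (tl.n_steps, 1, 1))
        trace = extract_trace(_record_with_fef(fef, sheet, spec), sheet)
        assert np.allclose(trace.centroid, spec.retinal_pre, atol=1e-9)

    def test_event_times_recorded(self, sheet):
        trace = extract_trace(
            _record_with_fef(np.zeros((17, 21, 21)), sheet), sheet)
        assert trace.saccade_onset_ms == 100.0
        assert trace.sc_on_ms == 50.0


class TestRemappingOnset:
    def test_step_function_onset_at_the_step_time(self):
        ff = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1], float)
        t = remapping_onset(_trace(ff, onset_ms=0.0))
        assert t == 50.0

    def test_linear_ramp_interpolated(self):
        ff = np.array([0, 0.2, 0.4, 0.6, 0.8, 1.0, 1.0, 1.0, 1.0, 1.0])
        # final level 1.0, criterion 0.5 crossed midway between 20 and 30 ms
        t = remapping_onset(_trace(ff, onset_ms=0.0))
        assert t == pytest.approx(25.0)

    def test_monotone_in_criterion(self):
        ff = np.array([0, 0.1, 0.25, 0.45, 0.7, 0.9, 1.0, 1.0, 1.0, 1.0])
        tr = _trace(ff, onset_ms=0.0)
        t25 = remapping_onset(tr, 0.25)
        t50 = remapping_onset(tr, 0.5)
        t75 = remapping_onset(tr, 0.75)
        assert t25 <= t50 <= t75

    def test_silent_trace_undefined(self):
        assert remapping_onset(_trace(np.zeros(10))) is None

    def test_invariant_to_uniform_scaling(self):
        ff = np.array([0, 0.1, 0.25, 0.45, 0.7, 0.9, 1.0, 1.0, 1.0, 1.0])
        assert remapping_onset(_trace(ff)) == \
            remapping_onset(_trace(ff * 0.37))


class TestJumpStatistic:
    def test_jump_trace_has_small_ratio(self):
        rf = np.array([1, 1, 1, 1, 0, 0, 0, 0], float)
        ff = np.array([0, 0, 0, 0, 1, 1, 1, 1], float)
        mid = np.full(8, 0.02)
        assert jump_statistic(_trace(ff, rf, mid)) == pytest.approx(0.02)

    def test_traveling_bump_ratio_near_one(self):
        # activity sweeps through the midpoint on its way from RF to FF
        rf = np.array([1, 0.8, 0.4, 0.1, 0, 0, 0, 0], float)
        mid = np.array([0, 0.3, 0.9, 0.95, 0.3, 0.05, 0, 0], float)
        ff = np.array([0, 0, 0, 0.3, 0.8, 1, 1, 1], float)
        assert jump_statistic(_trace(ff, rf, mid)) > 0.9

    def test_all_zero_trace_undefined(self):
        assert jump_statistic(_trace(np.zeros(8))) is None


class TestWeightRatio:
    def test_identical_matrices_ratio_one(self, sheet):
        from remapnet.metrics import TRAINED_VISUAL_POINTS
        cfg = NetworkConfig(variant="feedforward", sheet=sheet)
        w = init_weights(cfg, 0)
        w.sc_to_hidden = w.retina_to_hidden.copy()
        # same afferent subset for both pathways isolates the ratio itself
        rep = weight_magnitude_ratio(w, sheet,
                                     visual_points=TRAINED_VISUAL_POINTS,
                                     cd_points=TRAINED_VISUAL_POINTS)
        assert rep.ratio == pytest.approx(1.0)
        assert (rep.n_visual_units, rep.n_cd_units) == (5, 5)

    def test_scaled_cd_matrix_scales_ratio(self, sheet):
        from remapnet.metrics import TRAINED_VISUAL_POINTS
        cfg = NetworkConfig(variant="feedforward", sheet=sheet)
        w = init_weights(cfg, 0)
        w.sc_to_hidden = 0.41 * w.retina_to_hidden
        rep = weight_magnitude_ratio(w, sheet,
                                     visual_points=TRAINED_VISUAL_POINTS,
                                     cd_points=TRAINED_VISUAL_POINTS)
        assert rep.ratio == pytest.approx(0.41)

    def test_sign_mix_reported(self, sheet):
        cfg = NetworkConfig(variant="feedforward", sheet=sheet)
        w = init_weights(cfg, 0)
        w.retina_to_hidden = np.abs(w.retina_to_hidden)
        rep = weight_magnitude_ratio(w, sheet)
        assert rep.frac_visual_negative == 0.0
        assert 0.3 < rep.frac_cd_negative < 0.7  # random init


class TestAggregateRuns:
    def test_identical_runs_zero_se(self):
        runs = [np.ones(5), np.ones(5), np.ones(5)]
        mean, se = aggregate_runs(runs)
        assert np.allclose(mean, 1) and np.allclose(se, 0)

    def test_two_constant_runs_mean(self):
        mean, se = aggregate_runs([np.full(4, 2.0), np.full(4, 6.0)])
        assert np.allclose(mean, 4.0)

    def test_ragged_runs_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([np.ones(5), np.ones(6)])

    def test_se_matches_bootstrap(self, rng):
        runs = [rng.normal(size=30) + i * 0.01 for i in range(20)]
        mean, se = aggregate_runs(runs)
        stacked = np.stack(runs)
        boot = np.std([stacked[rng.integers(0, 20, 20)].mean(axis=0)
                       for _ in range(2000)], axis=0)
        assert np.all(np.abs(boot - se) / se < 0.2)

    def test_single_run_rejected(self):
        with pytest.raises(ValueError):
            aggregate_runs([np.ones(5)])


class TestCentroidDistances:
    def test_pure_rf_bump_distances(self, sheet):
        spec = TrialSpec((10.0, 0.0), (0.0, -20.0))
        tl = make_trial(spec, LatencyConfig(), sheet)
        fef = np.tile(encode_bump(spec.retinal_pre, sheet), (tl.n_steps, 1, 1))
        d_ff, d_rf = centroid_distances(
            _record_with_fef(fef, sheet, spec), sheet)
        assert d_rf == pytest.approx(0.0, abs=1e-9)
        assert d_ff == pytest.approx(20.0, abs=1e-9)

    def test_snapshot_is_20ms_before_saccade(self, sheet):
        tl = make_trial(TrialSpec((10.0, 0.0), (0.0, -20.0)),
                        LatencyConfig(), sheet)
        assert snapshot_step(tl) == tl.saccade_onset_step - 2
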