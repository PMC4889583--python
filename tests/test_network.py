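import numpy as np
import pytest
from scipy.signal import fftconvolve

from remapnet.geometry import SheetSpec, decode_centroid, encode_bump
from remapnet.network import (
    NetworkConfig,
    bc_forward,
    bc_sheet_spec,
    init_weights,
    load_weights,
    make_initial_state,
    forward_step,
    pretrain_bc,
    run_trial,
    save_weights,
)
from remapnet.trials import LatencyConfig, TrialSpec, make_trial


@pytest.fixture(scope="module")
def bc_kernel(sheet):
    return pretrain_bc(sheet)


class TestInitWeights:
    def test_uniform_bounds_and_determinism(self, small_sheet):
        cfg = NetworkConfig(variant="recurrent", sheet=small_sheet)
        w1 = init_weights(cfg, 7)
        w2 = init_weights(cfg, 7)
        for name, m in w1.trainable_items():
            assert np.all(np.abs(m) <= 0.1)
            assert np.array_equal(m, getattr(w2, name))

    def test_different_seeds_differ(self, small_sheet):
        cfg = NetworkConfig(variant="feedforward", sheet=small_sheet)
        assert not np.array_equal(init_weights(cfg, 0).retina_to_hidden,
                                  init_weights(cfg, 1).retina_to_hidden)

    def test_mean_near_zero(self, sheet):
        cfg = NetworkConfig(variant="feedforward", sheet=sheet)
        w = init_weights(cfg, 3)
        vals = w.retina_to_hidden.ravel()  # > 10^5 draws from U(-0.1, 0.1)
        se = 0.1 / np.sqrt(3) / np.sqrt(vals.size)
        assert abs(vals.mean()) < 3 * se

    def test_feedforward_variant_has_no_recurrence(self, small_sheet):
        cfg = NetworkConfig(variant="feedforward", sheet=small_sheet)
        assert init_weights(cfg, 0).hidden_to_hidden is None


class TestBCCombiner:
    @pytest.mark.parametrize("r,e", [((10, 0), (0, -20)), ((0, 0), (0, 0)),
                                     ((-20, 20), (20, 0)), ((15, -5), (-10, 10))])
    def test_decoded_bc_is_vector_sum(self, sheet, bc_kernel, r, e):
        pre, bc = bc_forward(encode_bump(r, sheet), encode_bump(e, sheet),
                             bc_kernel)
        dec = decode_centroid(bc, bc_sheet_spec(sheet))
        target = np.asarray(r, float) + np.asarray(e, float)
        assert np.linalg.norm(dec - target) < sheet.spacing_deg / 2

    def test_commutative_in_its_inputs(self, sheet, bc_kernel):
        a, _ = bc_forward(encode_bump((10, 0), sheet),
                          encode_bump((0, -20), sheet), bc_kernel)
        b, _ = bc_forward(encode_bump((0, -20), sheet),
                          encode_bump((10, 0), sheet), bc_kernel)
        assert np.allclose(a, b)

    def test_grid_swept_addition_within_half_spacing(self, sheet, bc_kernel):
        bc = bc_sheet_spec(sheet)
        for rx in (-20, 0, 20):
            for ex in (-20, 0, 20):
                for ey in (-20, 20):
                    pre, out = bc_forward(encode_bump((rx, 10), sheet),
                                          encode_bump((ex, ey), sheet),
                                          bc_kernel)
                    dec = decode_centroid(out, bc)
                    assert np.linalg.norm(
                        dec - np.array([rx + ex, 10 + ey])
                    ) < sheet.spacing_deg / 2


class TestForwardDynamics:
    def test_zero_weights_give_flat_sigmoid_activity(self, small_sheet):
        cfg = NetworkConfig(variant="feedforward", sheet=small_sheet,
                            include_bc=False)
        w = init_weights(cfg, 0)
        for name, m in w.trainable_items():
            m[:] = 0.0
        tl = make_trial(TrialSpec((10.0, 0.0), (0.0, -10.0)),
                        cfg.latencies, small_sheet)
        rec = run_trial(tl, w, cfg)
        assert np.allclose(rec.hidden, 0.5)
        assert np.allclose(rec.fef, 0.5)

    def test_visual_afference_lag_is_70ms(self, small_sheet):
        """A retinal input change first alters FEF activity 7 steps later."""
        cfg = NetworkConfig(variant="feedforward", sheet=small_sheet,
                            include_bc=False)
        w = init_weights(cfg, 1)
        w.sc_to_hidden[:] = 0.0  # isolate the visual pathway
        spec = TrialSpec((10.0, 0.0), (0.0, -10.0))
        tl = make_trial(spec, cfg.latencies, small_sheet)
        switch = tl.retina_switch_step
        lag = cfg.latencies.steps(cfg.latencies.visual_afference_ms)
        # extend the trial so the lagged change is observable
        tl2 = make_trial(spec, cfg.latencies, small_sheet, post_ms=150)
        rec = run_trial(tl2, w, cfg)
        fef = rec.fef.reshape(tl2.n_steps, -1)
        first_change = next(t for t in range(1, tl2.n_steps)
                            if not np.allclose(fef[t], fef[t - 1], atol=1e-12))
        assert first_change == switch + lag

    def test_cd_delay_is_10ms(self, small_sheet):
        cfg = NetworkConfig(variant="feedforward", sheet=small_sheet,
                            include_bc=False)
        w = init_weights(cfg, 1)
        w.retina_to_hidden[:] = 0.0  # isolate the CD pathway
        tl = make_trial(TrialSpec((10.0, 0.0), (0.0, -10.0)),
                        cfg.latencies, small_sheet)
        rec = run_trial(tl, w, cfg)
        fef = rec.fef.reshape(tl.n_steps, -1)
        first_change = next(t for t in range(1, tl.n_steps)
                            if not np.allclose(fef[t], fef[t - 1], atol=1e-12))
        assert first_change == tl.sc_on_step + 1

    def test_recurrent_variant_has_no_input_delay(self, small_sheet):
        cfg = NetworkConfig(variant="recurrent", sheet=small_sheet,
                            include_bc=False)
        w = init_weights(cfg, 1)
        w.retina_to_hidden[:] = 0.0  # isolate the CD pathway
        w.hidden_to_hidden[:] = 0.0  # suppress the initial-state transient
        tl = make_trial(TrialSpec((10.0, 0.0), (0.0, -10.0)),
                        cfg.latencies, small_sheet)
        rec = run_trial(tl, w, cfg)
        fef = rec.fef.reshape(tl.n_steps, -1)
        first_change = next(t for t in range(1, tl.n_steps)
                            if not np.allclose(fef[t], fef[t - 1], atol=1e-12))
        assert first_change == tl.sc_on_step

    def test_forward_step_matches_run_trial(self, small_sheet):
        cfg = NetworkConfig(variant="recurrent", sheet=small_sheet,
                            bc_kernel_size=3)
        w = init_weights(cfg, 2)
        w.bc_kernel = pretrain_bc(small_sheet, kernel_size=3,
                                  pairs=[((0, 0), (0, 0)),
                                         ((10, 0), (0, -10))], tol=1e9)
        tl = make_trial(TrialSpec((10.0, 0.0), (0.0, -10.0)),
                        cfg.latencies, small_sheet)
        rec = run_trial(tl, w, cfg)
        state = make_initial_state(cfg, tl.retina[0], tl.sc[0])
        for t in range(tl.n_steps):
            hidden, fef, bc = forward_step(state, tl.retina[t], tl.sc[t],
                                           tl.ep[t], w, cfg)
            assert np.allclose(hidden, rec.hidden[t])
            assert np.allclose(fef, rec.fef[t])
            assert np.allclose(bc, rec.bc[t])

    def test_untrained_weights_point_poorly(self, sheet, bc_kernel):
        cfg = NetworkConfig(variant="feedforward", sheet=sheet)
        w = init_weights(cfg, 0)
        w.bc_kernel = bc_kernel
        tl = make_trial(TrialSpec((20.0, 0.0), (0.0, 20.0)),
                        cfg.latencies, sheet)
        rec = run_trial(tl, w, cfg)
        # no better than a ball-agnostic baseline (ball at 20 deg, decode ~0)
        assert np.nanmean(rec.error_magnitude) > 10


class TestSerialization:
    def test_save_load_round_trip(self, small_sheet, tmp_path):
        cfg = NetworkConfig(variant="recurrent", sheet=small_sheet)
        w = init_weights(cfg, 5)
        w.bc_kernel = np.ones((3, 3))
        path = tmp_path / "w.npz"
        save_weights(path, w, cfg, seed=5)
        w2, manifest = load_weights(path)
        assert manifest["seed"] == 5
        assert manifest["config_hash"] == cfg.hash()
        for name, m in w.trainable_items():
            assert np.array_equal(m, getattr(w2, name))
        assert np.array_equal(w.bc_kernel, w2.bc_kernel)
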