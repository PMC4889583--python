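"""Learning: backpropagation through time on the pointing objective.

The differentiable loss is the squared mismatch, summed over all time steps,
between the BC activity sheet and the encoded desired-output bump at the
ball's (constant) workspace location.  This sheet-level loss is a surrogate
for the behavioral pointing error -- backpropagating through a
center-of-mass decode is ill-conditioned near low activity -- and the decoded
pointing error is reported alongside as the behavioral metric.  When the BC
stage is bypassed the FEF sheet is compared against the desired bump
directly.

One *trial* is one BPTT pass over one timeline, cycling through the training
set in seeded shuffled order.  Each weight update is perturbed by a small
amount of zero-mean uniform noise to avoid stagnation in local minima.  The
frozen BC kernel is never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .geometry import encode_bump
from .metrics import centroid_distances
from .network import (
    NetworkConfig,
    TrialRecord,
    WeightSet,
    bc_sheet_spec,
    forward_pass,
    init_weights,
    pretrain_bc,
    run_trial,
)
from .trials import TrialSpec, TrialTimeline, make_trial

__all__ = [
    "TrainHyperparams",
    "TrainedModel",
    "TrainingDivergedError",
    "desired_sheet",
    "compute_loss",
    "bptt_gradients",
    "bptt_update",
    "train_core",
    "evaluate",
]


class TrainingDivergedError(RuntimeError):
    """A non-finite gradient was encountered."""


def _safe_nanmean(a) -> float:
    a = np.asarray(a, dtype=float)
    return float(np.nanmean(a)) if np.any(np.isfinite(a)) else float("nan")


@lru_cache(maxsize=8)
def _cached_bc_kernel(sheet, kernel_size):
    # the fit is deterministic in (sheet, kernel_size); reuse across runs
    return pretrain_bc(sheet, kernel_size=kernel_size)


@dataclass(frozen=True)
class TrainHyperparams:
    """Learning-rate, noise, and stopping configuration.

    ``weight_noise_scale`` is the half-width of the zero-mean uniform noise
    added to every weight on every update (~1e-5).  Training stops when the
    update norm averaged over one full pass through the set falls below
    ``convergence_tol`` times the first pass's average, or at ``max_trials``.
    """

    learning_rate: float = 0.1
    weight_noise_scale: float = 1e-5
    max_trials: int = 400
    convergence_tol: float = 1e-4
    seed: int = 0
    shuffle: bool = True
    eval_every: int = 5
    #: flat-spot elimination: constant added to the FEF-layer sigmoid
    #: derivative during backprop so output units saturated at the wrong
    #: extreme keep receiving gradient (classic backprop practice; 0 recovers
    #: the exact gradient).
    flat_spot: float = 0.05
    #: flat-spot constant for the Hidden layer.  Kept 0 by default: in the
    #: recurrent variant a nonzero hidden flat spot inflates the backward
    #: Jacobian product through time and explodes the gradient.
    flat_spot_hidden: float = 0.0
    #: global gradient-norm cap per update (numerical safeguard for the
    #: recurrent variant); 0 disables clipping.
    max_grad_norm: float = 100.0
    #: optional hyperbolic learning-rate decay: the rate on trial k is
    #: learning_rate / (1 + k / lr_decay_trials); 0 disables decay.
    lr_decay_trials: int = 0

    def rate_at(self, trial: int) -> float:
        if self.lr_decay_trials <= 0:
            return self.learning_rate
        return self.learning_rate / (1.0 + trial / self.lr_decay_trials)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.weight_noise_scale < 0:
            raise ValueError("weight_noise_scale must be non-negative")


@dataclass
class TrainedModel:
    weights: WeightSet
    config: NetworkConfig
    hyper: TrainHyperparams
    converged: bool
    n_trials: int
    checkpoints: dict = field(default_factory=dict)


def desired_sheet(timeline: TrialTimeline, config: NetworkConfig) -> np.ndarray:
    """Encoded desired output: a bump at the ball's workspace location on the
    BC sheet (or on the FEF sheet when the BC stage is bypassed)."""
    spec = bc_sheet_spec(config.sheet) if config.include_bc else config.sheet
    return encode_bump(timeline.ball, spec)


def compute_loss(record: TrialRecord, timeline: TrialTimeline,
                 config: NetworkConfig) -> float:
    """Squared sheet mismatch summed over every step of the trial."""
    D = desired_sheet(timeline, config)
    out = record.bc if config.include_bc else record.fef
    return float(((out - D[None]) ** 2).sum())


def bptt_gradients(timeline: TrialTimeline, weights: WeightSet,
                   config: NetworkConfig, flat_spot: float = 0.0,
                   flat_spot_hidden: float = 0.0):
    """Analytic gradient of the trial loss w.r.t. every trainable matrix.

    ``flat_spot`` is added to the sigmoid derivative terms during the
    backward pass (flat-spot elimination); with 0 the gradient is exact.
    Returns ``(grads, loss, cache)`` where ``cache`` is the forward-pass
    record the gradient was computed from.
    """
    cache = forward_pass(timeline, weights, config)
    T = timeline.n_steps
    n = config.n
    nu = config.n_units
    h, f = cache["h"], cache["f"]
    D = desired_sheet(timeline, config)

    if config.include_bc:
        Gb = 2.0 * (cache["bc"] - D[None])
        loss = 0.25 * float((Gb ** 2).sum())
        K = weights.bc_kernel
        dP = fftconvolve(Gb, K[::-1, ::-1][None], mode="same", axes=(1, 2))
        Gf = fftconvolve(dP, timeline.ep[:, ::-1, ::-1], mode="valid",
                         axes=(1, 2)).reshape(T, nu)
    else:
        diff = f - D.ravel()[None]
        loss = float((diff ** 2).sum())
        Gf = 2.0 * diff

    df = Gf * config.fef_gain * (f * (1.0 - f) + flat_spot)
    grads = {"hidden_to_fef": df.T @ h}

    Wf_T = weights.hidden_to_fef.T
    recurrent = config.variant == "recurrent"
    Wh_T = weights.hidden_to_hidden.T if recurrent else None
    sprime = h * (1.0 - h) + flat_spot_hidden
    if recurrent:
        dh = np.empty((T, nu))     # dL/d(pre-sigmoid hidden input)
        d_next = np.zeros(nu)
        for t in range(T - 1, -1, -1):
            g = Wf_T @ df[t]
            g = g + config.recurrent_gain * (Wh_T @ d_next)
            dh[t] = g * sprime[t]
            d_next = dh[t]
    else:
        dh = (df @ weights.hidden_to_fef) * sprime

    grads["retina_to_hidden"] = config.hidden_gain * (dh.T @ cache["x"])
    grads["sc_to_hidden"] = config.hidden_gain * (dh.T @ cache["c"])
    if recurrent:
        h_prev = np.vstack([cache["h0"], h[:-1]])
        grads["hidden_to_hidden"] = config.recurrent_gain * (dh.T @ h_prev)

    for name, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise TrainingDivergedError(f"non-finite gradient in {name}")
    return grads, loss, cache


def bptt_update(weights: WeightSet, timelines, hyper: TrainHyperparams,
                config: NetworkConfig, rng: np.random.Generator,
                lr: float | None = None):
    """Accumulate gradients over a batch of timelines and apply one noisy
    SGD step in place.  The frozen BC kernel is untouched.

    Returns ``(total_loss, update_norm, caches)`` where ``update_norm`` is
    the norm of the deterministic (pre-noise) update.
    """
    if isinstance(timelines, TrialTimeline):
        timelines = [timelines]
    total = {name: 0.0 for name, _ in weights.trainable_items()}
    loss = 0.0
    caches = []
    for tl in timelines:
        grads, li, cache = bptt_gradients(
            tl, weights, config, flat_spot=hyper.flat_spot,
            flat_spot_hidden=hyper.flat_spot_hidden)
        loss += li
        caches.append(cache)
        for name, g in grads.items():
            total[name] = total[name] + g

    if lr is None:
        lr = hyper.learning_rate
    if hyper.max_grad_norm > 0:
        gnorm = np.sqrt(sum(float((g ** 2).sum()) for g in total.values()))
        if gnorm > hyper.max_grad_norm:
            scale = hyper.max_grad_norm / gnorm
            total = {k: g * scale for k, g in total.items()}
    sq = 0.0
    for name, _ in weights.trainable_items():
        delta = -lr * total[name]
        sq += float((delta ** 2).sum())
        w = getattr(weights, name)
        w += delta
        if hyper.weight_noise_scale > 0:
            w += rng.uniform(-hyper.weight_noise_scale,
                             hyper.weight_noise_scale, size=w.shape)
    return loss, float(np.sqrt(sq)), caches


def evaluate(weights: WeightSet, config: NetworkConfig, timelines) -> dict:
    """Behavioral and remapping metrics over a set of trials.

    Returns per-config arrays of time-averaged pointing error magnitude and
    presaccadic centroid-to-FF / centroid-to-RF distances.
    """
    errs, d_ff, d_rf = [], [], []
    for tl in timelines:
        rec = run_trial(tl, weights, config)
        errs.append(_safe_nanmean(rec.error_magnitude))
        ff, rf = centroid_distances(rec, config.sheet)
        d_ff.append(ff)
        d_rf.append(rf)
    d_ff = np.asarray(d_ff)
    d_rf = np.asarray(d_rf)
    return {
        "pointing_error": np.asarray(errs),
        "dist_ff": d_ff,
        "dist_rf": d_rf,
        "all_ff_closer": bool(np.all(d_ff < d_rf)),
    }


def _order_generator(n: int, rng: np.random.Generator, shuffle: bool):
    while True:
        idx = np.arange(n)
        if shuffle:
            rng.shuffle(idx)
        yield from idx


def train_core(config: NetworkConfig, specs: list[TrialSpec],
               hyper: TrainHyperparams, *,
               analyzed_specs: list[TrialSpec] | None = None,
               post_ms: int = 50,
               checkpoint_trials: tuple[int, ...] = (),
               weights: WeightSet | None = None,
               clamp_cd: bool = False,
               ) -> tuple[TrainedModel, pd.DataFrame]:
    """Stage-two training of the core network.

    Iterates one-trial BPTT updates in seeded shuffled order until the
    convergence criterion or ``max_trials``.  The history records, per trial,
    the loss, update norm, and the presaccadic centroid-to-FF/RF distances
    and pointing error of the trial just trained on; every ``eval_every``
    trials the analyzed set (defaults to the training set) is evaluated in
    full and its means recorded in the ``eval_*`` columns.

    Fully reproducible from ``(config, hyper)``: the same seed yields
    bit-identical histories and weights.
    """
    if weights is None:
        weights = init_weights(config, hyper.seed)
    if clamp_cd:
        weights.sc_to_hidden[:] = 0.0
    if config.include_bc and weights.bc_kernel is None:
        weights.bc_kernel = _cached_bc_kernel(config.sheet,
                                              config.bc_kernel_size).copy()

    timelines = [make_trial(s, config.latencies, config.sheet, post_ms=post_ms)
                 for s in specs]
    analyzed = analyzed_specs if analyzed_specs is not None else specs
    analyzed_tls = [make_trial(s, config.latencies, config.sheet,
                               post_ms=post_ms) for s in analyzed]

    rng = np.random.default_rng(hyper.seed)
    order = _order_generator(len(timelines), rng, hyper.shuffle)

    rows = []
    checkpoints: dict[int, dict] = {}
    pass_norms: list[float] = []
    first_pass_norm: float | None = None
    converged = False
    n_set = len(timelines)

    trial = 0
    for trial in range(1, hyper.max_trials + 1):
        k = next(order)
        tl = timelines[k]
        loss, unorm, caches = bptt_update(weights, tl, hyper, config, rng,
                                          lr=hyper.rate_at(trial - 1))
        if clamp_cd:
            weights.sc_to_hidden[:] = 0.0

        row = {
            "trial": trial,
            "spec_index": int(k),
            "loss": loss,
            "update_norm": unorm,
            "pointing_error": np.nan,
            "dist_ff": np.nan,
            "dist_rf": np.nan,
            "eval_pointing_error": np.nan,
            "eval_dist_ff": np.nan,
            "eval_dist_rf": np.nan,
        }
        if hyper.eval_every:
            # metrics of the trial just trained on (pre-update state)
            rec = _record_from_cache(caches[0], tl, config)
            d_ff, d_rf = centroid_distances(rec, config.sheet)
            row["pointing_error"] = _safe_nanmean(rec.error_magnitude)
            row["dist_ff"], row["dist_rf"] = d_ff, d_rf

        if hyper.eval_every and trial % hyper.eval_every == 0:
            ev = evaluate(weights, config, analyzed_tls)
            row["eval_pointing_error"] = float(ev["pointing_error"].mean())
            row["eval_dist_ff"] = float(np.nanmean(ev["dist_ff"]))
            row["eval_dist_rf"] = float(np.nanmean(ev["dist_rf"]))

        rows.append(row)

        if trial in checkpoint_trials:
            ev = evaluate(weights, config, analyzed_tls)
            checkpoints[trial] = ev

        pass_norms.append(unorm)
        if len(pass_norms) == n_set:
            mean_norm = float(np.mean(pass_norms))
            pass_norms.clear()
            if first_pass_norm is None:
                first_pass_norm = mean_norm
            elif mean_norm < hyper.convergence_tol * first_pass_norm:
                converged = True
                break

    history = pd.DataFrame(rows)
    model = TrainedModel(weights=weights, config=config, hyper=hyper,
                         converged=converged, n_trials=trial,
                         checkpoints=checkpoints)
    return model, history


def _record_from_cache(cache: dict, timeline: TrialTimeline,
                       config: NetworkConfig) -> TrialRecord:
    """Build a TrialRecord from an existing forward cache (no recompute)."""
    from .geometry import decode_centroid, pointing_error

    T = timeline.n_steps
    n = config.n
    if config.include_bc:
        src = cache["bc"]
        spec = bc_sheet_spec(config.sheet)
    else:
        src = cache["f"].reshape(T, n, n)
        spec = config.sheet
    decoded = np.full((T, 2), np.nan)
    error = np.full((T, 2), np.nan)
    mag = np.full(T, np.nan)
    for t in range(T):
        d = decode_centroid(src[t], spec)
        if d is None:
            continue
        decoded[t] = d
        pe = pointing_error(d, timeline.ball)
        error[t] = pe.vector
        mag[t] = pe.magnitude_deg
    return TrialRecord(
        timeline=timeline,
        hidden=cache["h"].reshape(T, n, n),
        fef=cache["f"].reshape(T, n, n),
        bc=cache.get("bc"),
        decoded=decoded,
        error=error,
        error_magnitude=mag,
    )
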