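"""Forward dynamics of the sheet network.

Two variants share one hidden-layer architecture:

* ``feedforward`` -- hard-coded pathway delays (visual afference to the
  Hidden layer, a short corollary-discharge delay from the SC), no
  recurrence.
* ``recurrent`` -- no imposed input delays; the Hidden layer feeds back on
  itself with a one-step delay and any useful timing must be learned.

In both, the Hidden layer receives the Retina and SC sheets all-to-all, the
FEF sheet reads the Hidden layer all-to-all, and every non-input unit applies
a logistic sigmoid.  The FEF output is combined with the eye-position (EP)
sheet in a frozen body-centered (BC) stage: the two sheets are convolved
(the bilinear, shift-invariant form of vector addition for bump codes) and
passed through a small sharpening kernel fit once by ridge least squares and
never trained again.  Pointing is decoded from the BC sheet, or directly
from the FEF sheet when the BC stage is bypassed.
"""

from __future__ import annotations

import hashlib
import json
from collections import deque
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import expit

from .geometry import SheetSpec, decode_centroid, encode_bump, pointing_error
from .trials import LatencyConfig, TrialTimeline

__all__ = [
    "NetworkConfig",
    "WeightSet",
    "TrialRecord",
    "PretrainError",
    "bc_sheet_spec",
    "init_weights",
    "pretrain_bc",
    "forward_pass",
    "forward_step",
    "make_initial_state",
    "run_trial",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture, nonlinearity, and latency configuration."""

    variant: str = "recurrent"            # "feedforward" | "recurrent"
    sheet: SheetSpec = field(default_factory=SheetSpec)
    latencies: LatencyConfig = field(default_factory=LatencyConfig)
    include_bc: bool = True
    hidden_gain: float = 1.0
    hidden_offset: float = 0.0
    fef_gain: float = 1.0
    fef_offset: float = 0.0
    #: gain on the Hidden->Hidden feedback term (recurrent variant only);
    #: kept separate from hidden_gain so a high input gain does not let the
    #: feedback loop swamp the afferent drive.
    recurrent_gain: float = 1.0
    bc_kernel_size: int = 9

    def __post_init__(self):
        if self.variant not in ("feedforward", "recurrent"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.bc_kernel_size % 2 == 0:
            raise ValueError("bc_kernel_size must be odd")

    @property
    def n(self) -> int:
        return self.sheet.n_units_per_side

    @property
    def n_units(self) -> int:
        return self.sheet.n_units

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def bc_sheet_spec(sheet: SheetSpec) -> SheetSpec:
    """BC sheet hosting the full convolution of two sheets: (2n-1) units per
    side spanning twice the input span, same unit spacing and bump width."""
    return SheetSpec(
        n_units_per_side=2 * sheet.n_units_per_side - 1,
        span_deg=2 * sheet.span_deg,
        sigma_deg=sheet.sigma_deg,
    )


@dataclass
class WeightSet:
    """All inter-sheet connection matrices.

    Trainable: ``retina_to_hidden``, ``sc_to_hidden``, ``hidden_to_fef`` and,
    in the recurrent variant, ``hidden_to_hidden``.  ``bc_kernel`` is the
    frozen BC combiner kernel: it is set once by :func:`pretrain_bc` and must
    never be touched by training.
    """

    retina_to_hidden: np.ndarray
    sc_to_hidden: np.ndarray
    hidden_to_fef: np.ndarray
    hidden_to_hidden: np.ndarray | None = None
    bc_kernel: np.ndarray | None = None

    TRAINABLE = ("retina_to_hidden", "sc_to_hidden", "hidden_to_fef",
                 "hidden_to_hidden")

    def trainable_items(self):
        for name in self.TRAINABLE:
            w = getattr(self, name)
            if w is not None:
                yield name, w

    def copy(self) -> "WeightSet":
        return WeightSet(
            retina_to_hidden=self.retina_to_hidden.copy(),
            sc_to_hidden=self.sc_to_hidden.copy(),
            hidden_to_fef=self.hidden_to_fef.copy(),
            hidden_to_hidden=None if self.hidden_to_hidden is None
            else self.hidden_to_hidden.copy(),
            bc_kernel=None if self.bc_kernel is None else self.bc_kernel.copy(),
        )


def init_weights(config: NetworkConfig, seed: int) -> WeightSet:
    """Random initial connectivity: every trainable weight drawn uniformly
    from [-0.1, 0.1].  Deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    nu = config.n_units

    def u(shape):
        return rng.uniform(-0.1, 0.1, size=shape)

    return WeightSet(
        retina_to_hidden=u((nu, nu)),
        sc_to_hidden=u((nu, nu)),
        hidden_to_fef=u((nu, nu)),
        hidden_to_hidden=u((nu, nu)) if config.variant == "recurrent" else None,
        bc_kernel=None,
    )


def _sigmoid(z: np.ndarray, gain: float, offset: float) -> np.ndarray:
    return expit(gain * z + offset)


class PretrainError(RuntimeError):
    """BC pretraining failed to reach the decoding tolerance."""


def _shift2d(a: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Shift a 2-D array by (dy, dx) with zero fill."""
    out = np.zeros_like(a)
    src_y = slice(max(0, -dy), a.shape[0] - max(0, dy))
    src_x = slice(max(0, -dx), a.shape[1] - max(0, dx))
    dst_y = slice(max(0, dy), a.shape[0] - max(0, -dy))
    dst_x = slice(max(0, dx), a.shape[1] - max(0, -dx))
    out[dst_y, dst_x] = a[src_y, src_x]
    return out


def default_bc_training_pairs(span: float = 20.0):
    """(retinal, eye) pairs covering the +/-20 deg training region."""
    r_vals = np.arange(-span, span + 1, 10.0)
    e_vals = np.arange(-span, span + 1, 20.0)
    pairs = []
    for rx in r_vals:
        for ry in r_vals:
            for ex in e_vals:
                for ey in e_vals:
                    pairs.append(((rx, ry), (ex, ey)))
    return pairs


def pretrain_bc(sheet: SheetSpec, *, kernel_size: int = 9, seed: int = 0,
                reg: float = 1e-5, pairs=None, tol: float | None = None,
                ) -> np.ndarray:
    """Fit the frozen BC combiner so that BC decodes to ``retinal + eye``.

    For bump inputs at FEF position ``r`` and EP position ``e``, the full
    2-D convolution of the two sheets already carries a (wider) bump whose
    centroid is exactly ``r + e``; the ridge least-squares kernel fit here
    maps that product onto the standard unit-peak bump at ``r + e`` on the
    BC sheet.  Raises :class:`PretrainError` if the decoded error exceeds
    half a unit spacing on any training pair.  The returned kernel is frozen:
    core training must never modify it.

    ``seed`` is accepted for interface uniformity; the fit is a deterministic
    least-squares solve and does not consume randomness.
    """
    del seed
    bc = bc_sheet_spec(sheet)
    if pairs is None:
        pairs = default_bc_training_pairs()
    k = kernel_size
    c = k // 2
    shifts = [(u - c, v - c) for u in range(k) for v in range(k)]

    A = np.zeros((k * k, k * k))
    b = np.zeros(k * k)
    cache = []
    for r, e in pairs:
        F = encode_bump(r, sheet)
        E = encode_bump(e, sheet)
        P = fftconvolve(F, E, mode="full")
        Y = encode_bump(np.asarray(r) + np.asarray(e), bc)
        V = np.stack([_shift2d(P, dy, dx).ravel() for dy, dx in shifts])
        A += V @ V.T
        b += V @ Y.ravel()
        cache.append((P, np.asarray(r) + np.asarray(e)))

    lam = reg * np.trace(A) / (k * k)
    kernel = np.linalg.solve(A + lam * np.eye(k * k), b).reshape(k, k)

    tol = tol if tol is not None else sheet.spacing_deg / 2
    worst = 0.0
    for P, target in cache:
        B = fftconvolve(P, kernel, mode="same")
        dec = decode_centroid(B, bc)
        err = np.inf if dec is None else float(np.linalg.norm(dec - target))
        worst = max(worst, err)
    if worst > tol:
        raise PretrainError(
            f"BC pretraining decode error {worst:.3f} deg exceeds {tol:.3f} deg")
    return kernel


def bc_forward(fef2d: np.ndarray, ep2d: np.ndarray, kernel: np.ndarray):
    """BC stage: full convolution of FEF and EP, then the frozen kernel.

    Returns ``(pre, bc)`` where ``pre`` is the raw convolution (kept for
    gradient computation)."""
    pre = fftconvolve(fef2d, ep2d, mode="full")
    return pre, fftconvolve(pre, kernel, mode="same")


# ---------------------------------------------------------------------------
# stepping API


@dataclass
class NetworkState:
    """Mutable per-trial state: previous hidden activity and delay buffers."""

    h_prev: np.ndarray
    retina_buf: deque
    sc_buf: deque


def make_initial_state(config: NetworkConfig, first_retina: np.ndarray,
                       first_sc: np.ndarray) -> NetworkState:
    """Initial state for a trial.

    Delay buffers are primed with the first input frame: the visual probe is
    persistent, so the pre-trial input is assumed identical to the trial's
    first frame.  The hidden state starts at its zero-input fixed value
    ``sigmoid(offset)``.
    """
    lat, nu = config.latencies, config.n_units
    if config.variant == "feedforward":
        dv = lat.steps(lat.visual_afference_ms)
        dc = lat.steps(lat.cd_delay_ms)
    else:
        dv = dc = 0
    h0 = np.full(nu, _sigmoid(np.zeros(1), config.hidden_gain,
                              config.hidden_offset)[0])
    return NetworkState(
        h_prev=h0,
        retina_buf=deque([np.asarray(first_retina).ravel()] * dv),
        sc_buf=deque([np.asarray(first_sc).ravel()] * dc),
    )


def _core_step(x: np.ndarray, c: np.ndarray, h_prev: np.ndarray,
               weights: WeightSet, config: NetworkConfig):
    z_h = config.hidden_gain * (weights.retina_to_hidden @ x
                                + weights.sc_to_hidden @ c)
    if config.variant == "recurrent":
        z_h = z_h + config.recurrent_gain * (weights.hidden_to_hidden @ h_prev)
    h = _sigmoid(z_h, 1.0, config.hidden_offset)
    f = _sigmoid(weights.hidden_to_fef @ h, config.fef_gain, config.fef_offset)
    return h, f


def forward_step(state: NetworkState, retina: np.ndarray, sc: np.ndarray,
                 ep: np.ndarray, weights: WeightSet, config: NetworkConfig):
    """Advance the network one 10 ms tick.

    Returns ``(hidden, fef, bc)`` as 2-D sheets (``bc`` is ``None`` when the
    BC stage is bypassed); ``state`` is updated in place.
    """
    n = config.n
    x = np.asarray(retina).ravel()
    c = np.asarray(sc).ravel()
    if len(state.retina_buf):
        state.retina_buf.append(x)
        x = state.retina_buf.popleft()
    if len(state.sc_buf):
        state.sc_buf.append(c)
        c = state.sc_buf.popleft()
    h, f = _core_step(x, c, state.h_prev, weights, config)
    state.h_prev = h
    bc = None
    if config.include_bc:
        if weights.bc_kernel is None:
            raise ValueError("include_bc=True but bc_kernel is not set "
                             "(run pretrain_bc first)")
        _, bc = bc_forward(f.reshape(n, n), np.asarray(ep), weights.bc_kernel)
    return h.reshape(n, n), f.reshape(n, n), bc


def forward_pass(timeline: TrialTimeline, weights: WeightSet,
                 config: NetworkConfig) -> dict:
    """Run a whole trial and keep every intermediate needed for learning.

    Returns a cache with the (delayed) inputs actually seen by the Hidden
    layer and all per-step activities, flattened to vectors.
    """
    lat = config.latencies
    T = timeline.n_steps
    nu = config.n_units
    n = config.n

    retina = timeline.retina.reshape(T, nu)
    sc = timeline.sc.reshape(T, nu)
    if config.variant == "feedforward":
        dv = lat.steps(lat.visual_afference_ms)
        dc = lat.steps(lat.cd_delay_ms)
    else:
        dv = dc = 0
    idx = np.arange(T)
    x = retina[np.maximum(idx - dv, 0)]
    c = sc[np.maximum(idx - dc, 0)]

    h0 = np.full(nu, _sigmoid(np.zeros(1), 1.0, config.hidden_offset)[0])
    # afferent drive is input-determined: compute it for all steps at once
    z_in = config.hidden_gain * (x @ weights.retina_to_hidden.T
                                 + c @ weights.sc_to_hidden.T)
    if config.variant == "feedforward":
        h = _sigmoid(z_in, 1.0, config.hidden_offset)
    else:
        h = np.empty((T, nu))
        Wh = weights.hidden_to_hidden
        h_prev = h0
        for t in range(T):
            z = z_in[t] + config.recurrent_gain * (Wh @ h_prev)
            h[t] = _sigmoid(z, 1.0, config.hidden_offset)
            h_prev = h[t]
    f = _sigmoid(h @ weights.hidden_to_fef.T, config.fef_gain,
                 config.fef_offset)

    cache = {"x": x, "c": c, "h": h, "f": f, "h0": h0}
    if config.include_bc:
        if weights.bc_kernel is None:
            raise ValueError("include_bc=True but bc_kernel is not set "
                             "(run pretrain_bc first)")
        pre = fftconvolve(f.reshape(T, n, n), timeline.ep, mode="full",
                          axes=(1, 2))
        bc = fftconvolve(pre, weights.bc_kernel[None], mode="same",
                         axes=(1, 2))
        cache["pre"] = pre
        cache["bc"] = bc
    return cache


@dataclass
class TrialRecord:
    """Per-step activities, decoded pointing coordinate, and pointing error."""

    timeline: TrialTimeline
    hidden: np.ndarray            # (T, n, n)
    fef: np.ndarray               # (T, n, n)
    bc: np.ndarray | None         # (T, 2n-1, 2n-1) or None
    decoded: np.ndarray           # (T, 2); NaN where no signal
    error: np.ndarray             # (T, 2) signed; NaN where undefined
    error_magnitude: np.ndarray   # (T,)

    @property
    def n_steps(self) -> int:
        return self.timeline.n_steps


def run_trial(timeline: TrialTimeline, weights: WeightSet,
              config: NetworkConfig) -> TrialRecord:
    """Iterate the forward dynamics over a trial and score pointing.

    Pointing is decoded from the BC sheet (body-centered coordinates), or
    from the FEF sheet directly when ``include_bc`` is false -- the
    configuration in which the retinotopic output itself drives the arm.
    """
    cache = forward_pass(timeline, weights, config)
    T = timeline.n_steps
    n = config.n
    if config.include_bc:
        decode_src = cache["bc"]
        decode_spec = bc_sheet_spec(config.sheet)
    else:
        decode_src = cache["f"].reshape(T, n, n)
        decode_spec = config.sheet

    decoded = np.full((T, 2), np.nan)
    error = np.full((T, 2), np.nan)
    mag = np.full(T, np.nan)
    for t in range(T):
        d = decode_centroid(decode_src[t], decode_spec)
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


def save_weights(path, weights: WeightSet, config: NetworkConfig,
                 seed: int | None = None) -> None:
    """Save a weight bundle with a manifest (config hash, seed) for reload."""
    arrays = {name: w for name, w in weights.trainable_items()}
    if weights.bc_kernel is not None:
        arrays["bc_kernel"] = weights.bc_kernel
    manifest = json.dumps({"config_hash": config.hash(), "seed": seed,
                           "config": config.to_dict()})
    np.savez(path, manifest=np.array(manifest), **arrays)


def load_weights(path) -> tuple[WeightSet, dict]:
    data = np.load(path, allow_pickle=False)
    manifest = json.loads(str(data["manifest"]))
    ws = WeightSet(
        retina_to_hidden=data["retina_to_hidden"],
        sc_to_hidden=data["sc_to_hidden"],
        hidden_to_fef=data["hidden_to_fef"],
        hidden_to_hidden=data["hidden_to_hidden"]
        if "hidden_to_hidden" in data else None,
        bc_kernel=data["bc_kernel"] if "bc_kernel" in data else None,
    )
    return ws, manifest
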