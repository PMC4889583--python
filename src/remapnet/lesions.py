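"""Graded inactivation experiments on trained models.

A lesion scales every weight of one afferent pathway onto the Hidden layer --
the corollary-discharge pathway (SC->Hidden) or the visual pathway
(Retina->Hidden) -- by a factor in [0, 1], at test time, without retraining.
This mirrors pharmacological inactivation of the corresponding pathway: the
model is trained intact and then probed with the pathway partially silenced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import (
    PRESACCADIC_STEPS,
    extract_trace,
    final_ff_level,
    presaccadic_slice,
)
from .network import NetworkConfig, WeightSet, run_trial
from .trials import TrialSpec, make_trial

__all__ = [
    "LesionSpec",
    "apply_lesion",
    "ff_presaccadic_activity",
    "cd_sweep",
    "find_factor_for_reduction",
    "visual_sweep",
    "no_stimulus_control",
]

_PATHWAYS = {"cd": "sc_to_hidden", "visual": "retina_to_hidden"}


@dataclass(frozen=True)
class LesionSpec:
    """A pathway identifier and the weight-scaling factor in [0, 1]."""

    pathway: str            # "cd" | "visual"
    factor: float

    def __post_init__(self):
        if self.pathway not in _PATHWAYS:
            raise ValueError(f"unknown pathway {self.pathway!r}")
        if not 0.0 <= self.factor <= 1.0:
            raise ValueError(f"lesion factor {self.factor} outside [0, 1]")


def apply_lesion(weights: WeightSet, spec: LesionSpec) -> WeightSet:
    """Scaled copy of the weight set; the original is never mutated."""
    out = weights.copy()
    name = _PATHWAYS[spec.pathway]
    setattr(out, name, getattr(out, name) * spec.factor)
    return out


def _timelines(specs, config: NetworkConfig, post_ms: int):
    return [make_trial(s, config.latencies, config.sheet, post_ms=post_ms)
            for s in specs]


def ff_presaccadic_activity(weights: WeightSet, config: NetworkConfig,
                            timelines) -> float:
    """Mean future-field-unit activity over the 50 ms presaccadic window,
    averaged across the trial set."""
    vals = []
    for tl in timelines:
        rec = run_trial(tl, weights, config)
        trace = extract_trace(rec, config.sheet)
        win = presaccadic_slice(tl, PRESACCADIC_STEPS)
        vals.append(float(trace.ff[win].mean()))
    return float(np.mean(vals))


def cd_sweep(weights: WeightSet, config: NetworkConfig,
             specs: list[TrialSpec], factors, *, post_ms: int = 50,
             ) -> pd.DataFrame:
    """Presaccadic future-field activity as a function of CD strength.

    Returns a tidy frame with one row per factor: the mean presaccadic FF
    activity and its value relative to the intact (factor 1.0) model.  The
    intact activity is taken from the sweep itself when 1.0 is among the
    factors, otherwise computed separately.
    """
    factors = sorted(float(f) for f in factors)
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    tls = _timelines(specs, config, post_ms)
    rows = []
    for f in factors:
        lesioned = apply_lesion(weights, LesionSpec("cd", f))
        rows.append({"factor": f,
                     "ff_presaccadic": ff_presaccadic_activity(
                         lesioned, config, tls)})
    df = pd.DataFrame(rows)
    if np.isclose(factors[-1], 1.0):
        intact = df["ff_presaccadic"].iloc[-1]
    else:
        intact = ff_presaccadic_activity(weights, config, tls)
    if intact <= 1e-9:
        raise RuntimeError("intact future-field activity is zero; "
                           "sweep undefined")
    df["relative"] = df["ff_presaccadic"] / intact
    return df


def find_factor_for_reduction(sweep: pd.DataFrame, reduction: float) -> float:
    """CD factor at which FF activity drops by ``reduction`` (fraction of the
    intact level), by inverse linear interpolation on the sweep curve."""
    if not 0.0 < reduction < 1.0:
        raise ValueError("reduction must be in (0, 1)")
    target = 1.0 - reduction
    rel = sweep["relative"].to_numpy()
    fac = sweep["factor"].to_numpy()
    # enforce monotone order for interpolation (curve is non-decreasing in
    # factor up to noise)
    order = np.argsort(fac)
    return float(np.interp(target, rel[order], fac[order]))


def visual_sweep(weights: WeightSet, config: NetworkConfig,
                 specs: list[TrialSpec], factors, *, post_ms: int = 50,
                 crossover_floor: float = 0.10) -> dict:
    """RF/FF activity traces and remapping crossover per visual-input level.

    For each factor the mean RF and FF traces over the trial set are
    recorded, together with the *crossover time*: the time (ms, relative to
    saccade onset, linearly interpolated) at which FF activity first exceeds
    RF activity.  The crossover is undefined (``None``) when the lesioned
    final FF level falls below ``crossover_floor`` of the intact final FF
    level -- with almost no activity the timing cannot be assessed.
    """
    factors = sorted(float(f) for f in factors)
    if len(factors) < 2:
        raise ValueError("need at least 2 factors")
    tls = _timelines(specs, config, post_ms)

    def traces_for(w):
        rf, ff, finals = [], [], []
        for tl in tls:
            trace = extract_trace(run_trial(tl, w, config), config.sheet)
            rf.append(trace.rf)
            ff.append(trace.ff)
            finals.append(final_ff_level(trace))
        return (np.mean(rf, axis=0), np.mean(ff, axis=0),
                float(np.mean(finals)))

    _, _, intact_final = traces_for(weights)
    tl0 = tls[0]
    onset_ms = tl0.saccade_onset_step * tl0.latencies.dt_ms
    times = tl0.times_ms.astype(float)

    out = {"factors": factors, "times_ms": times,
           "saccade_onset_ms": onset_ms, "rf": {}, "ff": {}, "crossover": {}}
    for f in factors:
        lesioned = apply_lesion(weights, LesionSpec("visual", f))
        rf, ff, final = traces_for(lesioned)
        out["rf"][f] = rf
        out["ff"][f] = ff
        out["crossover"][f] = (
            None if final < crossover_floor * intact_final
            else _crossover_ms(times, rf, ff, onset_ms))
    return out


def _crossover_ms(times, rf, ff, onset_ms):
    d = ff - rf
    above = np.nonzero(d > 0)[0]
    if above.size == 0:
        return None
    t = int(above[0])
    if t == 0:
        return float(times[0] - onset_ms)
    frac = -d[t - 1] / (d[t] - d[t - 1])
    dt = times[1] - times[0]
    return float(times[t - 1] + frac * dt - onset_ms)


def no_stimulus_control(weights: WeightSet, config: NetworkConfig,
                        specs: list[TrialSpec], *, post_ms: int = 50) -> dict:
    """Probe the trained model with the visual stimulus omitted.

    Runs each configuration twice -- stimulus present and omitted -- and
    returns the per-step maximum FEF activity for both, maximized across
    configurations.  In a trained model the no-stimulus maxima stay a small
    fraction of the stimulus-present maximum at every step, including during
    the CD window: corollary discharge modulates visual responses but does
    not drive the FEF by itself.
    """
    from dataclasses import replace

    tls = _timelines(specs, config, post_ms)
    no_stim = [make_trial(replace(s, variant="no_stimulus"), config.latencies,
                          config.sheet, post_ms=post_ms) for s in specs]
    with_max = None
    without_max = None
    for tl_s, tl_n in zip(tls, no_stim):
        a = run_trial(tl_s, weights, config).fef.max(axis=(1, 2))
        b = run_trial(tl_n, weights, config).fef.max(axis=(1, 2))
        with_max = a if with_max is None else np.maximum(with_max, a)
        without_max = b if without_max is None else np.maximum(without_max, b)
    return {
        "with_stimulus_max": with_max,
        "no_stimulus_max": without_max,
        "peak_ratio": float(without_max.max() / with_max.max()),
        "per_step_ratio": without_max / with_max.max(),
    }
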