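"""Derived measurements on trial records and trained weights.

Conventions: the *receptive field* (RF) unit of a trial is the FEF unit whose
center sits at the presaccadic retinal target location; the *future field*
(FF) unit sits at the postsaccadic retinal location; the *midpoint* unit is
nearest the sheet-coordinate midpoint of the two.  The presaccadic window is
the 50 ms (5 steps) leading up to saccade onset, and the presaccadic
*snapshot* is taken 20 ms before saccade onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import SheetSpec, decode_centroid
from .network import TrialRecord, WeightSet
from .trials import TrialTimeline

__all__ = [
    "RemappingTrace",
    "WeightRatioReport",
    "snapshot_step",
    "presaccadic_slice",
    "extract_trace",
    "remapping_onset",
    "jump_statistic",
    "weight_magnitude_ratio",
    "aggregate_runs",
    "centroid_distances",
    "remapping_shift",
]

#: Steps in the presaccadic averaging window (50 ms at 10 ms resolution).
PRESACCADIC_STEPS = 5
#: Snapshot lead time before saccade onset, in steps (20 ms).
SNAPSHOT_LEAD_STEPS = 2


def snapshot_step(timeline: TrialTimeline) -> int:
    """Step of the presaccadic snapshot: 20 ms before saccade onset."""
    return max(timeline.saccade_onset_step - SNAPSHOT_LEAD_STEPS, 0)


def presaccadic_slice(timeline: TrialTimeline,
                      n_steps: int = PRESACCADIC_STEPS) -> slice:
    """The ``n_steps`` steps immediately preceding saccade onset."""
    onset = timeline.saccade_onset_step
    return slice(max(onset - n_steps, 0), onset)


@dataclass
class RemappingTrace:
    """Per-step FEF activity at the RF, FF, and midpoint units, the FEF
    activity centroid, and the trial's event times."""

    times_ms: np.ndarray
    rf: np.ndarray
    ff: np.ndarray
    midpoint: np.ndarray
    centroid: np.ndarray                   # (T, 2), NaN where silent
    saccade_onset_ms: float
    sc_on_ms: float
    ep_switch_ms: float
    retina_switch_ms: float
    rf_loc: np.ndarray = field(default_factory=lambda: np.zeros(2))
    ff_loc: np.ndarray = field(default_factory=lambda: np.zeros(2))
    saccade_vector: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])


def extract_trace(record: TrialRecord, sheet: SheetSpec) -> RemappingTrace:
    """Sample the RF/FF/midpoint activities and centroid from a trial record.

    The centroid is the raw (unthresholded) activity-weighted average; it may
    pass between the RF and FF even when the activity itself jumps.
    """
    tl = record.timeline
    spec = tl.spec
    rf_loc = spec.retinal_pre
    ff_loc = spec.retinal_post
    mid_loc = (rf_loc + ff_loc) / 2.0
    rf_ij = sheet.nearest_unit(rf_loc)
    ff_ij = sheet.nearest_unit(ff_loc)
    mid_ij = sheet.nearest_unit(mid_loc)

    T = tl.n_steps
    centroid = np.full((T, 2), np.nan)
    for t in range(T):
        a = record.fef[t]
        total = a.sum()
        if total > 1e-12:
            ax = sheet.axis_deg
            centroid[t] = [(a.sum(axis=0) * ax).sum() / total,
                           (a.sum(axis=1) * ax).sum() / total]

    dt = tl.latencies.dt_ms
    return RemappingTrace(
        times_ms=tl.times_ms.astype(float),
        rf=record.fef[:, rf_ij[0], rf_ij[1]].copy(),
        ff=record.fef[:, ff_ij[0], ff_ij[1]].copy(),
        midpoint=record.fef[:, mid_ij[0], mid_ij[1]].copy(),
        centroid=centroid,
        saccade_onset_ms=tl.saccade_onset_step * dt,
        sc_on_ms=tl.sc_on_step * dt,
        ep_switch_ms=tl.ep_switch_step * dt,
        retina_switch_ms=tl.retina_switch_step * dt,
        rf_loc=rf_loc,
        ff_loc=ff_loc,
        saccade_vector=np.asarray(spec.saccade_vector, dtype=float),
    )


def final_ff_level(trace: RemappingTrace, n_steps: int = 3) -> float:
    """Final sustained FF level: mean over the last ``n_steps`` steps."""
    return float(np.mean(trace.ff[-n_steps:]))


def remapping_onset(trace: RemappingTrace, criterion_fraction: float = 0.5,
                    *, floor: float = 1e-3):
    """Time (ms, relative to saccade onset) at which FF activity first
    exceeds ``criterion_fraction`` of its final sustained level.

    The crossing is linearly interpolated between samples when the trace is
    already ramping; a jump out of silence is dated at the sample itself
    (sheet activity holds its level between 10 ms updates).  Returns ``None``
    when the final level never rises above ``floor``.
    """
    final = final_ff_level(trace)
    if final <= floor:
        return None
    thr = criterion_fraction * final
    above = np.nonzero(trace.ff >= thr)[0]
    if above.size == 0:
        return None
    t = int(above[0])
    if t == 0:
        cross_ms = trace.times_ms[0]
    else:
        lo, hi = trace.ff[t - 1], trace.ff[t]
        if lo <= floor:
            cross_ms = trace.times_ms[t]
        else:
            frac = (thr - lo) / (hi - lo)
            cross_ms = trace.times_ms[t - 1] + frac * trace.dt_ms
    return float(cross_ms - trace.saccade_onset_ms)


def jump_statistic(trace: RemappingTrace):
    """max midpoint activity / max(RF peak, FF peak).

    A ratio below ~0.1 indicates that activity jumped from the RF to the FF
    without a transient at intermediate locations; a traveling bump yields a
    ratio near 1.  Returns ``None`` for an all-silent trace.
    """
    denom = max(float(trace.rf.max()), float(trace.ff.max()))
    if denom < 1e-9:
        return None
    return float(trace.midpoint.max()) / denom


@dataclass(frozen=True)
class WeightRatioReport:
    """Mean |CD| vs mean |visual| afferent weight onto the Hidden layer."""

    mean_abs_cd: float
    mean_abs_visual: float
    frac_cd_negative: float
    frac_visual_negative: float
    n_visual_units: int
    n_cd_units: int

    @property
    def ratio(self) -> float:
        return self.mean_abs_cd / self.mean_abs_visual


#: Input locations exercised by the 20-combination training set.
TRAINED_VISUAL_POINTS = ((0.0, 0.0), (-20.0, 0.0), (20.0, 0.0),
                         (0.0, -20.0), (0.0, 20.0))
TRAINED_CD_POINTS = ((-20.0, 0.0), (20.0, 0.0), (0.0, -20.0), (0.0, 20.0))


def central_grid_points(step: float = 10.0,
                        span: float = 20.0) -> list[tuple[float, float]]:
    """The central 5 x 5 input grid (for models trained on the full cross)."""
    vals = np.arange(-span, span + step / 2, step)
    return [(float(x), float(y)) for y in vals for x in vals]


def _columns(sheet: SheetSpec, pts) -> np.ndarray:
    n = sheet.n_units_per_side
    return np.asarray([i * n + j for i, j in
                       (sheet.nearest_unit(p) for p in pts)])


def weight_magnitude_ratio(weights: WeightSet, sheet: SheetSpec,
                           visual_points=None,
                           cd_points=None) -> WeightRatioReport:
    """Compare CD (SC->Hidden) against visual (Retina->Hidden) afferents.

    Restricted to afferents from the trained input locations: by default the
    5 retinal locations and 4 saccade vectors of the 20-combination training
    set (use :func:`central_grid_points` for models trained on the full
    cross).  Also reports the sign mix of each pathway.
    """
    vis_pts = visual_points if visual_points is not None \
        else TRAINED_VISUAL_POINTS
    cd_pts = cd_points if cd_points is not None else TRAINED_CD_POINTS
    w_cd = weights.sc_to_hidden[:, _columns(sheet, cd_pts)]
    w_vis = weights.retina_to_hidden[:, _columns(sheet, vis_pts)]
    return WeightRatioReport(
        mean_abs_cd=float(np.abs(w_cd).mean()),
        mean_abs_visual=float(np.abs(w_vis).mean()),
        frac_cd_negative=float((w_cd < 0).mean()),
        frac_visual_negative=float((w_vis < 0).mean()),
        n_visual_units=w_vis.shape[1],
        n_cd_units=w_cd.shape[1],
    )


def aggregate_runs(runs) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise mean and standard error across >= 2 equally long runs."""
    runs = [np.asarray(r, dtype=float) for r in runs]
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to aggregate")
    lengths = {r.shape for r in runs}
    if len(lengths) != 1:
        raise ValueError(f"ragged run lengths: {sorted(lengths)}")
    stacked = np.stack(runs)
    mean = stacked.mean(axis=0)
    se = stacked.std(axis=0, ddof=1) / np.sqrt(stacked.shape[0])
    return mean, se


def centroid_distances(record: TrialRecord, sheet: SheetSpec,
                       step: int | None = None) -> tuple[float, float]:
    """(centroid-to-FF, centroid-to-RF) distances in sheet degrees at the
    presaccadic snapshot (or a given step)."""
    tl = record.timeline
    t = snapshot_step(tl) if step is None else step
    c = decode_centroid(record.fef[t], sheet, floor_frac=0.0)
    if c is None:
        return float("nan"), float("nan")
    d_ff = float(np.linalg.norm(c - tl.spec.retinal_post))
    d_rf = float(np.linalg.norm(c - tl.spec.retinal_pre))
    return d_ff, d_rf


def remapping_shift(record: TrialRecord, sheet: SheetSpec) -> np.ndarray:
    """Presaccadic shift of the FEF centroid in sheet coordinates.

    Difference between the centroid at the presaccadic snapshot and the
    centroid just before the SC command.  In a trained model this shift is
    antiparallel to the saccade vector (visual sensitivity shifts parallel to
    the saccade in visual space).
    """
    tl = record.timeline
    before = max(tl.sc_on_step - 1, 0)
    c0 = decode_centroid(record.fef[before], sheet, floor_frac=0.0)
    c1 = decode_centroid(record.fef[snapshot_step(tl)], sheet, floor_frac=0.0)
    if c0 is None or c1 is None:
        return np.full(2, np.nan)
    return c1 - c0
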