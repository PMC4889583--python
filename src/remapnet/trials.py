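"""Trial timelines: everything the network ever sees.

A trial is a short schedule of sheet inputs at 10 ms resolution.  The
standard trial has three segments: the target is shown at its presaccadic
retinal location with no motor activity (50 ms); the SC sheet then signals
the upcoming saccade vector while the target stays put (70 ms); finally the
SC activity is quenched and the target appears at its postsaccadic retinal
location (50 ms), for 17 steps in total.  The saccade itself begins one
efferent delay after the SC command onset, and the retinal image is treated
as switching discretely shortly after saccade onset.  The eye-position (EP)
input likewise switches exactly once, at a configurable delay referenced to
either the SC command or to saccade onset.

The ball never moves in the workspace during these trials: the desired
pointing target is constant, and only the eye (and hence the retinal image)
moves.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .geometry import (
    SheetSpec,
    TargetNotVisibleError,
    as_point,
    encode_bump,
    to_workspace,
)

__all__ = [
    "LatencyConfig",
    "TrialSpec",
    "TrialTimeline",
    "make_trial",
    "feedforward_training_set",
    "recurrent_training_set",
    "delayed_saccade_variant",
    "specs_to_json",
    "specs_from_json",
]

#: Duration of the initial fixation segment (target at presaccadic location).
PRE_MS = 50
#: Duration of the SC saccade-command window.
SC_WINDOW_MS = 70
#: Lag between saccade onset and the discrete retinal-image switch.  With the
#: default 50 ms efferent delay this places the switch exactly at the end of
#: the SC command window (trial step 12 of 17).
RETINA_SWITCH_LAG_MS = 20


@dataclass(frozen=True)
class LatencyConfig:
    """Pathway and event latencies, all whole multiples of ``dt_ms``.

    ``visual_afference_ms`` and ``cd_delay_ms`` are hard transmission delays
    used only by the delayed-feedforward network variant; the recurrent
    variant receives its inputs without imposed delays and must learn any
    useful timing.  ``efferent_delay_ms`` separates the SC command onset from
    saccade onset.  ``ep_update_delay_ms`` is referenced to either the SC
    command onset (``ep_reference="sc_command"``) or to saccade onset
    (``ep_reference="saccade_onset"``).
    """

    dt_ms: int = 10
    visual_afference_ms: int = 70
    cd_delay_ms: int = 10
    efferent_delay_ms: int = 50
    ep_update_delay_ms: int = 50
    ep_reference: str = "sc_command"

    def __post_init__(self):
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        for name in ("visual_afference_ms", "cd_delay_ms", "efferent_delay_ms",
                     "ep_update_delay_ms"):
            v = getattr(self, name)
            if v < 0 or v % self.dt_ms:
                raise ValueError(f"{name}={v} must be a non-negative multiple of dt")
        if self.ep_reference not in ("sc_command", "saccade_onset"):
            raise ValueError("ep_reference must be 'sc_command' or 'saccade_onset'")

    def steps(self, ms: int) -> int:
        return int(round(ms / self.dt_ms))


@dataclass(frozen=True)
class TrialSpec:
    """One stimulus/saccade configuration.

    ``target_retinal`` is the presaccadic retinal location of the ball;
    ``saccade_vector`` the commanded eye displacement.  ``variant`` is one of
    ``standard`` or ``no_stimulus`` (the latter omits the visual probe while
    keeping SC and EP inputs unchanged).
    """

    target_retinal: tuple[float, float]
    saccade_vector: tuple[float, float]
    initial_eye: tuple[float, float] = (0.0, 0.0)
    variant: str = "standard"

    def __post_init__(self):
        if self.variant not in ("standard", "no_stimulus"):
            raise ValueError(f"unknown trial variant {self.variant!r}")

    @property
    def retinal_pre(self) -> np.ndarray:
        return as_point(self.target_retinal)

    @property
    def retinal_post(self) -> np.ndarray:
        return as_point(self.target_retinal) - as_point(self.saccade_vector)

    @property
    def ball(self) -> np.ndarray:
        """Workspace location of the ball (constant within a trial)."""
        return to_workspace(self.target_retinal, self.initial_eye)


@dataclass
class TrialTimeline:
    """Per-step sheet inputs plus the desired pointing target and event steps."""

    spec: TrialSpec
    latencies: LatencyConfig
    retina: np.ndarray          # (T, n, n)
    sc: np.ndarray              # (T, n, n)
    ep: np.ndarray              # (T, n, n)
    ball: np.ndarray            # (2,) constant workspace target
    n_steps: int
    sc_on_step: int
    sc_off_step: int            # exclusive
    saccade_onset_step: int
    retina_switch_step: int
    ep_switch_step: int         # may be >= n_steps (no in-trial update)
    eye_pre: np.ndarray = field(default_factory=lambda: np.zeros(2))
    eye_post: np.ndarray = field(default_factory=lambda: np.zeros(2))

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.latencies.dt_ms

    def desired_ball(self) -> np.ndarray:
        """(T, 2) desired pointing coordinate: the ball, at every step."""
        return np.tile(self.ball, (self.n_steps, 1))


def make_trial(spec: TrialSpec, lat: LatencyConfig,
               sheet: SheetSpec | None = None, *,
               post_ms: int = 50) -> TrialTimeline:
    """Build the input schedule for one trial.

    ``post_ms`` sets the duration of the postsaccadic segment (50 ms for the
    standard 17-step trial; presets lengthen it when post-saccadic afference
    must arrive within the record).
    """
    sheet = sheet or SheetSpec()
    dt = lat.dt_ms

    r_pre = spec.retinal_pre
    r_post = spec.retinal_post
    for r, label in ((r_pre, "presaccadic"), (r_post, "postsaccadic")):
        if not sheet.contains(r):
            raise TargetNotVisibleError(
                f"{label} retinal location {r} off the retina sheet")

    sc_on = lat.steps(PRE_MS)
    sc_off = sc_on + lat.steps(SC_WINDOW_MS)
    onset = lat.steps(PRE_MS + lat.efferent_delay_ms)
    switch = onset + lat.steps(RETINA_SWITCH_LAG_MS)
    n_steps = switch + lat.steps(post_ms)

    if lat.ep_reference == "sc_command":
        ep_switch = sc_on + lat.steps(lat.ep_update_delay_ms)
    else:
        ep_switch = onset + lat.steps(lat.ep_update_delay_ms)

    eye_pre = as_point(spec.initial_eye)
    eye_post = eye_pre + as_point(spec.saccade_vector)

    n = sheet.n_units_per_side
    retina = np.zeros((n_steps, n, n))
    sc = np.zeros((n_steps, n, n))
    ep = np.zeros((n_steps, n, n))

    if spec.variant != "no_stimulus":
        bump_pre = encode_bump(r_pre, sheet)
        bump_post = encode_bump(r_post, sheet)
        retina[:switch] = bump_pre
        retina[switch:] = bump_post

    sc[sc_on:sc_off] = encode_bump(spec.saccade_vector, sheet)

    ep_pre = encode_bump(eye_pre, sheet)
    ep[:] = ep_pre
    if ep_switch < n_steps:
        ep[ep_switch:] = encode_bump(eye_post, sheet)

    return TrialTimeline(
        spec=spec, latencies=lat, retina=retina, sc=sc, ep=ep,
        ball=spec.ball, n_steps=n_steps, sc_on_step=sc_on, sc_off_step=sc_off,
        saccade_onset_step=onset, retina_switch_step=switch,
        ep_switch_step=ep_switch, eye_pre=eye_pre, eye_post=eye_post,
    )


def _grid(lo: float, hi: float, step: float) -> list[tuple[float, float]]:
    vals = np.arange(lo, hi + step / 2, step)
    return [(float(x), float(y)) for y in vals for x in vals]


def feedforward_training_set(sheet: SheetSpec | None = None, *,
                             restrict_to_analyzed: bool = False,
                             ) -> list[TrialSpec]:
    """Training set for the delayed-feedforward variant.

    25 target locations (5 x 5 grid, -20 to 20 deg in 10 deg steps) crossed
    with 25 saccade vectors on the same grid.  Combinations whose
    postsaccadic retinal location falls off the retina sheet are dropped.
    With ``restrict_to_analyzed`` only the 20 combinations shared with the
    recurrent training set are returned (the subset used for analysis).
    """
    if restrict_to_analyzed:
        return recurrent_training_set()
    sheet = sheet or SheetSpec()
    targets = _grid(-20, 20, 10)
    vectors = _grid(-20, 20, 10)
    specs = []
    for t, v in itertools.product(targets, vectors):
        s = TrialSpec(target_retinal=t, saccade_vector=v)
        if sheet.contains(s.retinal_pre) and sheet.contains(s.retinal_post):
            specs.append(s)
    return specs


def recurrent_training_set() -> list[TrialSpec]:
    """Training set for the recurrent variant: 5 retinal locations
    (horizontal and vertical extremes at +/-20 deg plus the center) crossed
    with the 4 cardinal 20 deg saccade vectors -- 20 combinations."""
    targets = [(0.0, 0.0), (-20.0, 0.0), (20.0, 0.0), (0.0, -20.0), (0.0, 20.0)]
    vectors = [(-20.0, 0.0), (20.0, 0.0), (0.0, -20.0), (0.0, 20.0)]
    return [TrialSpec(target_retinal=t, saccade_vector=v)
            for t, v in itertools.product(targets, vectors)]


def delayed_saccade_variant(lat: LatencyConfig,
                            efferent_delay_ms: int = 70) -> LatencyConfig:
    """Latency config with the saccade delayed relative to the SC command.

    Lengthening the efferent delay from 50 to 70 ms expands the presaccadic
    window for analysis and extends the standard trial from 17 to 19 steps.
    """
    return replace(lat, efferent_delay_ms=efferent_delay_ms)


def specs_to_json(specs: list[TrialSpec]) -> str:
    return json.dumps([asdict(s) for s in specs], indent=1)


def specs_from_json(text: str) -> list[TrialSpec]:
    return [TrialSpec(target_retinal=tuple(d["target_retinal"]),
                      saccade_vector=tuple(d["saccade_vector"]),
                      initial_eye=tuple(d.get("initial_eye", (0.0, 0.0))),
                      variant=d.get("variant", "standard"))
            for d in json.loads(text)]
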