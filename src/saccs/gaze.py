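"""Live gaze-stream analysis: fixation monitoring and saccade classification.

A trial's gaze trace is a 1 kHz stream of screen-pixel positions.  The
participant must hold fixation within a 1° radius of the screen centre; the
first valid sample found outside that radius defines the saccade, whose
direction is

    beta_g = atan2(y_eye - y_center, x_eye - x_center)

computed in the raw screen-pixel frame (y increasing downward).  The target
meridian is expressed in the same frame, so the axis convention cancels in
classification: a saccade is a correct response when the circular distance
between ``beta_g`` and the target meridian is at most 22.5° (inclusive), i.e.
the four cardinal meridians carry disjoint 45°-wide acceptance cones.
Invalid samples (track loss) signal a blink and the trial is repeated.
Only the first boundary crossing is scored; the landing point is never used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "GazeSample",
    "GazeTrace",
    "ScreenGeometry",
    "FixationEvent",
    "SaccadeVerdict",
    "saccade_direction",
    "circular_distance",
    "classify_saccade",
    "monitor_fixation",
    "score_trial",
    "CONE_HALFWIDTH_DEG",
    "FIXATION_RADIUS_DEG",
]

CONE_HALFWIDTH_DEG = 22.5
FIXATION_RADIUS_DEG = 1.0

#: Reporting map from screen-frame meridians (y increasing downward) to
#: visual-field directions of the tested right eye: rightward gaze lands in
#: the temporal field, downward in the inferior field.
MERIDIAN_LABELS = {0: "temporal", 90: "inferior", 180: "nasal", 270: "superior"}


@dataclass(frozen=True)
class GazeSample:
    """One eye-tracker sample: time (ms from trial onset) and screen pixels."""

    t: float
    x: float
    y: float
    valid: bool = True


@dataclass
class GazeTrace:
    """A timestamped gaze stream for one trial, stored as flat arrays."""

    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_px = np.asarray(self.x_px, dtype=float)
        self.y_px = np.asarray(self.y_px, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t_ms.size
        if not (self.x_px.size == self.y_px.size == self.valid.size == n):
            raise ValueError("trace arrays must share one length")
        if n and np.any(np.diff(self.t_ms) < 0):
            raise ValueError("sample times must be non-decreasing")

    def __len__(self) -> int:
        return self.t_ms.size

    def sample(self, i: int) -> GazeSample:
        return GazeSample(
            t=float(self.t_ms[i]), x=float(self.x_px[i]),
            y=float(self.y_px[i]), valid=bool(self.valid[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_ms": self.t_ms,
                "x_px": self.x_px,
                "y_px": self.y_px,
                "valid": self.valid.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GazeTrace":
        return cls(
            t_ms=df["t_ms"].to_numpy(float),
            x_px=df["x_px"].to_numpy(float),
            y_px=df["y_px"].to_numpy(float),
            valid=df["valid"].to_numpy().astype(bool),
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "GazeTrace":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen-pixel frame: centre coordinates and the pixel scale of 1°.

    ``y_axis_downward`` records the screen convention (row index grows
    downward); both the gaze angle and the target meridian live in this same
    frame, so classification is convention-free.
    """

    center_x: float
    center_y: float
    pixels_per_degree: float
    y_axis_downward: bool = True

    def __post_init__(self) -> None:
        if not self.pixels_per_degree > 0:
            raise ValueError("pixels_per_degree must be positive")


#: Geometry of the reference setup: 1920x1200 display at 62 cm.  At that
#: distance one degree of visual angle subtends ~40 px on a 0.27 mm pitch.
DEFAULT_GEOMETRY = ScreenGeometry(center_x=960.0, center_y=600.0, pixels_per_degree=40.0)


@dataclass(frozen=True)
class FixationEvent:
    """Outcome of fixation monitoring: held, first exit, or blink."""

    status: str  # "held" | "exit" | "blink"
    index: Optional[int] = None
    sample: Optional[GazeSample] = None


@dataclass(frozen=True)
class SaccadeVerdict:
    """Scored saccade response for one trial."""

    exited: bool
    correct: bool
    beta_g: Optional[float] = None  # degrees in [0, 360)
    angular_error: Optional[float] = None  # degrees in [0, 180]
    exit_time: Optional[float] = None  # ms from trial onset
    blink: bool = False
    false_positive: bool = False

    def __post_init__(self) -> None:
        if self.correct and not (
            self.exited and self.angular_error is not None
            and self.angular_error <= CONE_HALFWIDTH_DEG
        ):
            raise ValueError("a correct verdict requires an in-cone exit")


def saccade_direction(sample: GazeSample, geom: ScreenGeometry) -> float:
    """Saccade direction beta_g = atan2(y - y_c, x - x_c), degrees in [0, 360)."""
    dx = sample.x - geom.center_x
    dy = sample.y - geom.center_y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("gaze sample at the exact centre has no direction")
    return math.degrees(math.atan2(dy, dx)) % 360.0


def circular_distance(a_deg: float, b_deg: float) -> float:
    """Smallest absolute angular difference between two angles, in [0, 180]."""
    d = abs(a_deg - b_deg) % 360.0
    return min(d, 360.0 - d)


def classify_saccade(
    beta_g: float, target_meridian: float, cone_halfwidth: float = CONE_HALFWIDTH_DEG
) -> bool:
    """True when beta_g falls inside the target's acceptance cone (inclusive)."""
    if not (math.isfinite(beta_g) and math.isfinite(target_meridian)):
        raise ValueError("angles must be finite")
    return circular_distance(beta_g, target_meridian) <= cone_halfwidth


def monitor_fixation(
    trace: GazeTrace,
    geom: ScreenGeometry,
    radius_deg: float = FIXATION_RADIUS_DEG,
    t_start: float = -math.inf,
    t_end: float = math.inf,
) -> FixationEvent:
    """Find the first fixation exit (or blink) within a time window.

    Scans samples with ``t_start <= t <= t_end`` in order.  An invalid sample
    flags a blink; a valid sample strictly farther than ``radius_deg`` from
    the centre is the first exit.  Exactly-at-radius samples count as held.
    Whichever event comes first in time wins.
    """
    if len(trace) == 0:
        raise ValueError("empty gaze trace")
    radius_px = radius_deg * geom.pixels_per_degree
    in_window = (trace.t_ms >= t_start) & (trace.t_ms <= t_end)
    idx = np.flatnonzero(in_window)
    if idx.size == 0:
        return FixationEvent(status="held")
    r = np.hypot(
        trace.x_px[idx] - geom.center_x, trace.y_px[idx] - geom.center_y
    )
    outside = r > radius_px
    invalid = ~trace.valid[idx]
    first_out = np.flatnonzero(outside & ~invalid)
    first_bad = np.flatnonzero(invalid)
    i_out = first_out[0] if first_out.size else None
    i_bad = first_bad[0] if first_bad.size else None
    if i_bad is not None and (i_out is None or i_bad < i_out):
        j = int(idx[i_bad])
        return FixationEvent(status="blink", index=j, sample=trace.sample(j))
    if i_out is not None:
        j = int(idx[i_out])
        return FixationEvent(status="exit", index=j, sample=trace.sample(j))
    return FixationEvent(status="held")


def score_trial(
    trace: GazeTrace,
    trial,
    geom: ScreenGeometry,
    response_window_ms: Optional[float] = None,
) -> SaccadeVerdict:
    """Score one trial's gaze trace against its target meridian.

    ``trial`` needs ``meridian_deg`` (ignored for catch trials), ``is_catch``
    and a presentation window; the response window defaults to the stimulus
    presentation limit plus the post-stimulus grace period (both stored on the
    trial's condition, 500 ms each by default).  The first fixation exit
    inside the window is the response; a blink anywhere in the window asks
    for the trial to be repeated; an exit on a catch trial is a false
    positive and never reaches the adaptive procedure.
    """
    if response_window_ms is None:
        cond = getattr(trial, "condition", None)
        pres = getattr(cond, "presentation_ms", 500.0) if cond else 500.0
        grace = getattr(cond, "grace_ms", 500.0) if cond else 500.0
        response_window_ms = pres + grace
    if len(trace) == 0:
        return SaccadeVerdict(exited=False, correct=False)
    event = monitor_fixation(trace, geom, t_start=0.0, t_end=response_window_ms)
    if event.status == "blink":
        return SaccadeVerdict(exited=False, correct=False, blink=True)
    if event.status == "held":
        return SaccadeVerdict(exited=False, correct=False)
    beta = saccade_direction(event.sample, geom)
    if getattr(trial, "is_catch", False):
        return SaccadeVerdict(
            exited=True, correct=False, beta_g=beta,
            exit_time=event.sample.t, false_positive=True,
        )
    err = circular_distance(beta, float(trial.meridian_deg))
    return SaccadeVerdict(
        exited=True,
        correct=err <= CONE_HALFWIDTH_DEG,
        beta_g=beta,
        angular_error=err,
        exit_time=event.sample.t,
    )
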