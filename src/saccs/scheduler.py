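"""Trial scheduling and the closed measurement loop.

One session tests a single (eccentricity, spatial frequency) condition in one
response mode.  The schedule holds 120 target presentations — 30 per cardinal
meridian and 30 per grating orientation, jointly randomised — and, in the
saccadic mode, 12 catch trials without a target interleaved uniformly at
random (132 trials total).  Each meridian runs its own QUEST+ instance; catch
trials never touch the adaptive procedure.  A blink re-queues the interrupted
trial and re-randomises the order of the remaining ones.

The saccadic mode records both the gaze-based verdict (which drives QUEST+)
and the keyboard 4AFC answer (logged as an additional channel); the
non-saccadic mode records keyboard answers only and has no catch trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gaze as gz
from . import quest as qp
from .gaze import DEFAULT_GEOMETRY, ScreenGeometry
from .observer import ObserverModel

__all__ = [
    "SF_SETS",
    "MERIDIANS",
    "ORIENTATIONS",
    "KEY_PAIRS",
    "ConditionSpec",
    "TrialRecord",
    "TrialSchedule",
    "SessionLog",
    "build_schedule",
    "run_session",
    "build_study",
    "run_study",
    "conditions_for_participant",
]

#: Spatial frequencies tested per eccentricity level (cycles per degree):
#: the common set 0.8–4.3 everywhere, 7.2 added at the macular level (6.5°),
#: 7.2 and 10.7 added at the central level (2.0°).
SF_SETS = {
    2.0: (0.8, 1.4, 2.2, 4.3, 7.2, 10.7),
    6.5: (0.8, 1.4, 2.2, 4.3, 7.2),
    11.0: (0.8, 1.4, 2.2, 4.3),
}

MERIDIANS = (0, 90, 180, 270)
ORIENTATIONS = (45, 90, 135, 180)

#: 4AFC keyboard mapping: orientation -> accepted number-pad key pair.
KEY_PAIRS = {45: (1, 9), 90: (2, 8), 135: (3, 7), 180: (4, 6)}

N_TARGETS = 120
N_CATCH = 12
PER_MERIDIAN = N_TARGETS // len(MERIDIANS)


@dataclass(frozen=True)
class ConditionSpec:
    """One tested condition: eccentricity, spatial frequency and response mode."""

    eccentricity_deg: float
    spatial_freq_cpd: float
    mode: str = "saccadic"  # "saccadic" | "non-saccadic"
    stimulus_diameter_deg: float = 1.4
    presentation_ms: float = 500.0
    grace_ms: float = 500.0
    fixation_ms_range: tuple = (500.0, 650.0)

    def __post_init__(self) -> None:
        if self.eccentricity_deg not in SF_SETS:
            raise ValueError(
                f"eccentricity must be one of {sorted(SF_SETS)}, "
                f"got {self.eccentricity_deg}"
            )
        allowed = SF_SETS[self.eccentricity_deg]
        if self.spatial_freq_cpd not in allowed:
            raise ValueError(
                f"spatial frequency {self.spatial_freq_cpd} not tested at "
                f"{self.eccentricity_deg}° (allowed: {allowed})"
            )
        if self.mode not in ("saccadic", "non-saccadic"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def response_window_ms(self) -> float:
        return self.presentation_ms + self.grace_ms


@dataclass
class TrialRecord:
    """One planned or completed presentation."""

    trial_id: int
    condition: ConditionSpec
    meridian_deg: int
    orientation_deg: int
    is_catch: bool = False
    contrast: float | None = None
    fixation_ms: float | None = None
    saccade_correct: bool | None = None
    keyboard_correct: bool | None = None
    beta_g_deg: float | None = None
    exit_time_ms: float | None = None
    false_positive: bool = False
    status: str = "pending"  # pending | done | repeated


@dataclass
class TrialSchedule:
    trials: list
    seed: int
    mode: str

    def __len__(self) -> int:
        return len(self.trials)


def _balanced_margin_table(rng: np.random.Generator, n_transfers: int = 60) -> np.ndarray:
    """Random 4x4 non-negative integer table with every row and column sum 30.

    Exact joint balance (120/16 = 7.5 per cell) is impossible, so start from a
    near-uniform table — 7 everywhere plus two random permutation matrices —
    and apply random 2x2 transfers (+1/−1 on the corners of a random
    rectangle), which preserve all margins.
    """
    table = np.full((4, 4), 7, dtype=int)
    for _ in range(2):
        table[np.arange(4), rng.permutation(4)] += 1
    for _ in range(n_transfers):
        i1, i2 = rng.choice(4, size=2, replace=False)
        j1, j2 = rng.choice(4, size=2, replace=False)
        if table[i1, j1] > 0 and table[i2, j2] > 0:
            table[i1, j1] -= 1
            table[i2, j2] -= 1
            table[i1, j2] += 1
            table[i2, j1] += 1
    return table


def build_schedule(cond: ConditionSpec, seed: int) -> TrialSchedule:
    """Randomised balanced schedule for one session.

    120 targets with 30 per meridian and 30 per orientation (joint cell
    counts random), fully shuffled; the saccadic mode interleaves 12 catch
    trials at uniformly random positions.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    table = _balanced_margin_table(rng)
    targets = [
        (MERIDIANS[i], ORIENTATIONS[j])
        for i in range(4)
        for j in range(4)
        for _ in range(table[i, j])
    ]
    order = rng.permutation(len(targets))
    trials = [
        TrialRecord(
            trial_id=k,
            condition=cond,
            meridian_deg=targets[idx][0],
            orientation_deg=targets[idx][1],
        )
        for k, idx in enumerate(order)
    ]
    if cond.mode == "saccadic":
        # catch trials mimic real ones (random meridian/orientation labels for
        # the sham workflow) but carry no target
        for _ in range(N_CATCH):
            pos = int(rng.integers(0, len(trials) + 1))
            trials.insert(
                pos,
                TrialRecord(
                    trial_id=-1,
                    condition=cond,
                    meridian_deg=int(rng.choice(MERIDIANS)),
                    orientation_deg=int(rng.choice(ORIENTATIONS)),
                    is_catch=True,
                ),
            )
        for k, tr in enumerate(trials):
            tr.trial_id = k
    return TrialSchedule(trials=trials, seed=seed, mode=cond.mode)


@dataclass
class SessionLog:
    """Completed session: per-attempt rows plus the final QUEST+ states."""

    condition: ConditionSpec
    seed: int
    rows: pd.DataFrame
    quest_states: dict  # meridian -> QuestState
    aborted: bool = False

    def false_positive_rate(self) -> float:
        catch = self.rows[(self.rows["is_catch"]) & (self.rows["status"] == "done")]
        if len(catch) == 0:
            return float("nan")
        return float(catch["false_positive"].mean())


def _row(trial: TrialRecord) -> dict:
    return {
        "trial_id": trial.trial_id,
        "meridian_deg": trial.meridian_deg,
        "orientation_deg": trial.orientation_deg,
        "is_catch": trial.is_catch,
        "contrast": trial.contrast,
        "fixation_ms": trial.fixation_ms,
        "saccade_correct": trial.saccade_correct,
        "keyboard_correct": trial.keyboard_correct,
        "beta_g_deg": trial.beta_g_deg,
        "exit_time_ms": trial.exit_time_ms,
        "false_positive": trial.false_positive,
        "status": trial.status,
    }


def run_session(
    cond: ConditionSpec,
    observer: ObserverModel,
    seed: int,
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    keep_traces: bool = False,
    max_attempts: int | None = None,
) -> SessionLog:
    """Run one closed-loop session against a (simulated) observer.

    Per trial: draw the fixation duration, ask the meridian's QUEST+ instance
    for the next contrast (targets only), obtain the observer's gaze trace
    and keyboard answer, score the gaze, and update the driving QUEST+
    instance — the saccade verdict in saccadic mode, the 4AFC correctness in
    non-saccadic mode.  Blink-interrupted trials are re-queued with the
    remaining order re-randomised and do not update QUEST+.
    """
    rng = np.random.default_rng(seed)
    schedule = build_schedule(cond, int(rng.integers(0, 2**31 - 1)))
    gamma_fixed = 0.0 if cond.mode == "saccadic" else 0.25
    states = {
        mer: qp.init_state(qp.default_grid(gamma_fixed=gamma_fixed),
                           location_label=f"meridian_{mer}")
        for mer in MERIDIANS
    }
    pending = list(schedule.trials)
    rows: list[dict] = []
    traces: list = []
    if max_attempts is None:
        max_attempts = 20 * len(pending)
    attempts = 0
    i = 0
    aborted = False
    while i < len(pending):
        attempts += 1
        if attempts > max_attempts:
            aborted = True
            break
        trial = pending[i]
        trial.fixation_ms = float(rng.uniform(*cond.fixation_ms_range))
        if not trial.is_catch:
            trial.contrast = qp.next_stimulus(states[trial.meridian_deg]).c_linear
        try:
            outcome = observer.simulate_trial(
                meridian_deg=trial.meridian_deg,
                eccentricity=cond.eccentricity_deg,
                sf_cpd=cond.spatial_freq_cpd,
                contrast=trial.contrast,
                is_catch=trial.is_catch,
                presentation_ms=cond.presentation_ms,
                response_window_ms=cond.response_window_ms,
                rng=rng,
                geom=geom,
            )
        except Exception:
            aborted = True
            trial.status = "failed"
            rows.append(_row(trial))
            break
        verdict = gz.score_trial(outcome.trace, trial, geom,
                                 response_window_ms=cond.response_window_ms)
        if verdict.blink:
            # re-queue this trial's parameters and reshuffle what remains
            trial.status = "repeated"
            rows.append(_row(trial))
            remaining = pending[i + 1:] + [
                TrialRecord(
                    trial_id=trial.trial_id,
                    condition=cond,
                    meridian_deg=trial.meridian_deg,
                    orientation_deg=trial.orientation_deg,
                    is_catch=trial.is_catch,
                )
            ]
            order = rng.permutation(len(remaining))
            pending = pending[: i + 1] + [remaining[k] for k in order]
            i += 1
            continue
        trial.saccade_correct = verdict.correct
        trial.beta_g_deg = verdict.beta_g
        trial.exit_time_ms = verdict.exit_time
        trial.false_positive = verdict.false_positive
        trial.keyboard_correct = outcome.keyboard_correct
        trial.status = "done"
        if not trial.is_catch:
            driving = (
                verdict.correct if cond.mode == "saccadic"
                else outcome.keyboard_correct
            )
            states[trial.meridian_deg] = qp.update(
                states[trial.meridian_deg],
                qp.ContrastValue(trial.contrast),
                bool(driving),
            )
        rows.append(_row(trial))
        if keep_traces:
            traces.append(outcome.trace)
        i += 1

    log = SessionLog(
        condition=cond,
        seed=seed,
        rows=pd.DataFrame(rows),
        quest_states=states,
        aborted=aborted,
    )
    if keep_traces:
        log.traces = traces  # type: ignore[attr-defined]
    return log


# ---------------------------------------------------------------------------
# Study-level orchestration
# ---------------------------------------------------------------------------

def conditions_for_participant() -> list:
    """The 15 (eccentricity, spatial frequency) combinations of the design."""
    return [
        (ecc, sf) for ecc in sorted(SF_SETS) for sf in SF_SETS[ecc]
    ]


def build_study(n_participants: int = 12, seed: int = 0) -> pd.DataFrame:
    """Manifest of every session in a full study.

    participants x 15 eccentricity-frequency conditions x both modes, with a
    per-session seed derived deterministically from the master seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for ecc, sf in conditions_for_participant():
            for mode in ("saccadic", "non-saccadic"):
                rows.append(
                    {
                        "participant": p,
                        "eccentricity_deg": ecc,
                        "spatial_freq_cpd": sf,
                        "mode": mode,
                        "session_seed": int(rng.integers(0, 2**31 - 1)),
                    }
                )
    return pd.DataFrame(rows)


def run_study(
    manifest: pd.DataFrame,
    observer_for: "ObserverModel | callable",
    geom: ScreenGeometry = DEFAULT_GEOMETRY,
    progress: bool = False,
) -> pd.DataFrame:
    """Run every session of a manifest; returns the concatenated trial log.

    ``observer_for`` is either one ObserverModel shared by all participants or
    a callable ``participant_index -> ObserverModel``.
    """
    logs = []
    for _, s in manifest.iterrows():
        obs = observer_for(int(s["participant"])) if callable(observer_for) else observer_for
        cond = ConditionSpec(
            eccentricity_deg=float(s["eccentricity_deg"]),
            spatial_freq_cpd=float(s["spatial_freq_cpd"]),
            mode=str(s["mode"]),
        )
        log = run_session(cond, obs, int(s["session_seed"]), geom=geom)
        df = log.rows
        df.insert(0, "participant", int(s["participant"]))
        df.insert(1, "mode", cond.mode)
        df.insert(2, "eccentricity_deg", cond.eccentricity_deg)
        df.insert(3, "spatial_freq_cpd", cond.spatial_freq_cpd)
        logs.append(df)
    return pd.concat(logs, ignore_index=True)
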