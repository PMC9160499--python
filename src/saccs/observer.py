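"""Synthetic participant and eye tracker for closed-loop testing.

The observer owns a ground-truth contrast sensitivity function per
visual-field direction and eccentricity; detection of a stimulus of given
contrast is Bernoulli with probability from the cumulative Weibull whose
threshold is read off that CSF (guess rate 0 for the saccade channel, 0.25
for 4AFC keyboard answers).  On detection the observer launches a saccade
toward the target meridian after a contrast-dependent latency

    latency = base + gain * exp(-contrast / scale) + Gaussian noise,

so near-threshold stimuli draw slow saccades that can outlast the 500 ms
presentation limit — the mechanism through which the saccade channel can read
lower sensitivity than the keyboard channels.  Fixational jitter stays well
inside the 1° fixation radius; on catch trials a rare large fixational
excursion (default per-trial probability 0.043) escapes the radius in a
uniformly random direction and registers as a false positive.  Blinks appear
as runs of invalid samples.  Everything is reproducible under a seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .csf import CsfParams, invert_csf_to_threshold
from .gaze import DEFAULT_GEOMETRY, GazeTrace, ScreenGeometry
from .psychometric import PsychometricParams, slope_to_width, weibull_prob

__all__ = ["ObserverModel", "TrialOutcome", "default_observer"]

MERIDIANS = (0.0, 90.0, 180.0, 270.0)
ECCENTRICITIES = (2.0, 6.5, 11.0)

# Ground-truth CSF shape: peak log10 sensitivity per (meridian, eccentricity)
# in the screen frame (0° temporal, 90° inferior, 180° nasal, 270° superior
# for the tested right eye): horizontal > superior > inferior, decaying with
# eccentricity — the anisotropy expected in the parafoveal field.  Peak
# frequency drops toward the periphery; bandwidth held common.
_PEAK_LOG_CS = {
    (0.0, 2.0): 1.69, (180.0, 2.0): 1.68, (270.0, 2.0): 1.61, (90.0, 2.0): 1.57,
    (0.0, 6.5): 1.55, (180.0, 6.5): 1.57, (270.0, 6.5): 1.49, (90.0, 6.5): 1.42,
    (0.0, 11.0): 1.53, (180.0, 11.0): 1.48, (270.0, 11.0): 1.36, (90.0, 11.0): 1.28,
}
_PEAK_SF = {2.0: 2.4, 6.5: 1.6, 11.0: 1.1}
_CSF_BETA = 2.2


def _default_csf_table() -> dict:
    return {
        (mer, ecc): CsfParams(
            gamma_max=10.0 ** _PEAK_LOG_CS[(mer, ecc)],
            sf_max=_PEAK_SF[ecc],
            beta=_CSF_BETA,
        )
        for mer in MERIDIANS
        for ecc in ECCENTRICITIES
    }


@dataclass(frozen=True)
class TrialOutcome:
    """Everything the simulated participant produced for one trial."""

    detected: bool
    latency_ms: float | None
    trace: GazeTrace
    keyboard_correct: bool
    blink: bool


@dataclass(frozen=True)
class ObserverModel:
    """Generative model of a participant plus eye tracker.

    Latency units are milliseconds; contrasts are linear proportions; the
    per-trial ``fp_rate`` and ``blink_rate`` are probabilities.
    """

    csf_table: dict = field(default_factory=_default_csf_table)
    true_slope: float = 3.0
    lapse: float = 0.02
    guess_4afc: float = 0.25
    latency_base_ms: float = 200.0
    latency_gain_ms: float = 400.0
    latency_contrast_scale: float = 0.1
    latency_sd_ms: float = 50.0
    fp_rate: float = 0.043
    blink_rate: float = 0.02
    saccade_dir_sd_deg: float = 5.0
    fixation_jitter_sd_deg: float = 0.12
    sample_rate_hz: float = 1000.0
    fixed_threshold_m: float | None = None

    def __post_init__(self) -> None:
        for name in ("lapse", "guess_4afc", "fp_rate", "blink_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("latency_base_ms", "latency_gain_ms", "latency_contrast_scale",
                     "true_slope", "sample_rate_hz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    # -- ground truth -----------------------------------------------------
    def true_threshold(self, meridian_deg: float, eccentricity: float,
                       sf_cpd: float) -> float:
        """Ground-truth log-contrast threshold m for one location/frequency."""
        if self.fixed_threshold_m is not None:
            return self.fixed_threshold_m
        key = (float(meridian_deg), float(eccentricity))
        if key not in self.csf_table:
            raise KeyError(f"no ground-truth CSF for meridian/eccentricity {key}")
        return invert_csf_to_threshold(sf_cpd, self.csf_table[key])

    def true_params(self, meridian_deg: float, eccentricity: float, sf_cpd: float,
                    guess: float = 0.0) -> PsychometricParams:
        return PsychometricParams(
            m=self.true_threshold(meridian_deg, eccentricity, sf_cpd),
            w=slope_to_width(self.true_slope),
            gamma=guess,
            lam=self.lapse,
        )

    def detect_probability(self, meridian_deg: float, eccentricity: float,
                           sf_cpd: float, contrast: float,
                           guess: float = 0.0) -> float:
        """Psi(contrast) at the location's true threshold (guess per channel)."""
        return float(
            weibull_prob(contrast,
                         self.true_params(meridian_deg, eccentricity, sf_cpd, guess))
        )

    # -- response generation ----------------------------------------------
    def draw_latency(self, contrast: float, rng: np.random.Generator) -> float:
        lat = (
            self.latency_base_ms
            + self.latency_gain_ms * math.exp(-contrast / self.latency_contrast_scale)
            + rng.normal(0.0, self.latency_sd_ms)
        )
        return max(lat, 80.0)  # physiological floor

    def answer_4afc(self, perceived: bool, rng: np.random.Generator) -> bool:
        """Keyboard answer: correct if perceived (minus lapses), else a 1-in-4 guess."""
        if perceived:
            return bool(rng.random() >= self.lapse)
        return bool(rng.random() < self.guess_4afc)

    def generate_gaze_trace(
        self,
        *,
        detected: bool,
        latency_ms: float | None,
        meridian_deg: float,
        eccentricity: float,
        duration_ms: float,
        is_catch: bool,
        blink: bool,
        rng: np.random.Generator,
        geom: ScreenGeometry = DEFAULT_GEOMETRY,
    ) -> GazeTrace:
        """Emit a 1 kHz gaze trace for one trial.

        Fixational jitter is white Gaussian around the centre.  A detected
        target launches a straight saccade toward the meridian (angular noise
        sigma = ``saccade_dir_sd_deg``) at ``latency_ms``, covering the
        target eccentricity in ~40 ms.  Catch trials escape fixation in a
        uniformly random direction with probability ``fp_rate``.  A blink is
        a ~120 ms run of invalid samples at a random time.
        """
        dt = 1000.0 / self.sample_rate_hz
        n = int(round(duration_ms / dt)) + 1
        t = np.arange(n) * dt
        ppd = geom.pixels_per_degree
        sigma = self.fixation_jitter_sd_deg * ppd
        x = geom.center_x + rng.normal(0.0, sigma, n)
        y = geom.center_y + rng.normal(0.0, sigma, n)
        valid = np.ones(n, dtype=bool)

        onset = None
        direction = None
        amplitude_deg = None
        if is_catch:
            if rng.random() < self.fp_rate:
                onset = rng.uniform(50.0, max(duration_ms - 100.0, 51.0))
                direction = rng.uniform(0.0, 360.0)
                amplitude_deg = rng.uniform(1.5, 3.0)
        elif detected and latency_ms is not None:
            onset = latency_ms
            direction = meridian_deg + rng.normal(0.0, self.saccade_dir_sd_deg)
            amplitude_deg = eccentricity

        if onset is not None and onset < duration_ms:
            theta = math.radians(direction)
            progress = np.clip((t - onset) / 40.0, 0.0, 1.0)  # 40 ms flight
            r = progress * amplitude_deg * ppd
            x = x + r * math.cos(theta)
            y = y + r * math.sin(theta)

        if blink:
            b0 = rng.uniform(0.0, max(duration_ms - 120.0, 1.0))
            valid[(t >= b0) & (t <= b0 + 120.0)] = False

        return GazeTrace(t_ms=t, x_px=x, y_px=y, valid=valid)

    def simulate_trial(
        self,
        *,
        meridian_deg: float,
        eccentricity: float,
        sf_cpd: float,
        contrast: float | None,
        is_catch: bool,
        presentation_ms: float,
        response_window_ms: float,
        rng: np.random.Generator,
        geom: ScreenGeometry = DEFAULT_GEOMETRY,
    ) -> TrialOutcome:
        """Resolve one trial: detection, saccade latency, gaze trace, 4AFC answer.

        A detected stimulus yields a saccade only when its latency falls
        within the presentation limit — a stimulus that has already vanished
        no longer triggers the reflexive movement.  The keyboard answer uses
        the perceptual detection regardless of saccade timing.
        """
        blink = bool(rng.random() < self.blink_rate)
        if is_catch or contrast is None:
            trace = self.generate_gaze_trace(
                detected=False, latency_ms=None, meridian_deg=meridian_deg,
                eccentricity=eccentricity, duration_ms=response_window_ms,
                is_catch=True, blink=blink, rng=rng, geom=geom,
            )
            keyboard = bool(rng.random() < self.guess_4afc)
            return TrialOutcome(detected=False, latency_ms=None, trace=trace,
                                keyboard_correct=keyboard, blink=blink)

        p_detect = self.detect_probability(meridian_deg, eccentricity, sf_cpd,
                                           contrast, guess=0.0)
        detected = bool(rng.random() < p_detect)
        latency = self.draw_latency(contrast, rng) if detected else None
        saccade_launched = detected and latency is not None and latency <= presentation_ms
        trace = self.generate_gaze_trace(
            detected=saccade_launched, latency_ms=latency,
            meridian_deg=meridian_deg, eccentricity=eccentricity,
            duration_ms=response_window_ms, is_catch=False, blink=blink,
            rng=rng, geom=geom,
        )
        keyboard = self.answer_4afc(detected, rng)
        return TrialOutcome(detected=detected, latency_ms=latency, trace=trace,
                            keyboard_correct=keyboard, blink=blink)

    # -- configuration ----------------------------------------------------
    @classmethod
    def on_grid(cls, m: float, slope: float, lapse: float = 0.02,
                **overrides) -> "ObserverModel":
        """An idealised observer sitting exactly on a QUEST+ grid cell.

        Threshold and slope are fixed (no CSF), saccade latency is fast and
        contrast-independent, and blinks/false positives are off — suitable
        for parameter-recovery checks of the estimation machinery.
        """
        kwargs = dict(
            fixed_threshold_m=m, true_slope=slope, lapse=lapse,
            latency_base_ms=180.0, latency_gain_ms=1e-6,
            latency_sd_ms=20.0, fp_rate=0.0, blink_rate=0.0,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    def with_(self, **changes) -> "ObserverModel":
        return replace(self, **changes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "csf_table": {
                    f"{mer:g}:{ecc:g}": p.to_dict()
                    for (mer, ecc), p in self.csf_table.items()
                },
                "true_slope": self.true_slope,
                "lapse": self.lapse,
                "guess_4afc": self.guess_4afc,
                "latency_base_ms": self.latency_base_ms,
                "latency_gain_ms": self.latency_gain_ms,
                "latency_contrast_scale": self.latency_contrast_scale,
                "latency_sd_ms": self.latency_sd_ms,
                "fp_rate": self.fp_rate,
                "blink_rate": self.blink_rate,
                "saccade_dir_sd_deg": self.saccade_dir_sd_deg,
                "fixation_jitter_sd_deg": self.fixation_jitter_sd_deg,
                "sample_rate_hz": self.sample_rate_hz,
                "fixed_threshold_m": self.fixed_threshold_m,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ObserverModel":
        d = json.loads(text)
        d.pop("format_version", None)
        table = {}
        for key, pd_ in d.pop("csf_table").items():
            mer, ecc = key.split(":")
            table[(float(mer), float(ecc))] = CsfParams.from_dict(pd_)
        return cls(csf_table=table, **d)


def default_observer() -> ObserverModel:
    """The standard simulated participant (field-anisotropic CSF, 4.3% catch
    false positives, contrast-dependent saccade latency)."""
    return ObserverModel()


def cohort_observer(participant: int, master_seed: int = 0) -> ObserverModel:
    """A participant drawn from a simulated cohort.

    Individuals share the template CSF shape but differ in overall
    sensitivity (peak log10 CS shifted by N(0, 0.15) across the whole field),
    carry small location-specific deviations (N(0, 0.05)), a jittered peak
    frequency (±10%) and their own psychometric slope — the between-subject
    structure a twelve-participant cohort would show.  Deterministic in
    (participant, master_seed).
    """
    rng = np.random.default_rng([master_seed & 0x7FFFFFFF, participant])
    overall = rng.normal(0.0, 0.15)
    table = {}
    for key, p in _default_csf_table().items():
        local = rng.normal(0.0, 0.05)
        table[key] = CsfParams(
            gamma_max=10.0 ** (math.log10(p.gamma_max) + overall + local),
            sf_max=p.sf_max * 10.0 ** rng.normal(0.0, 0.04),
            beta=p.beta,
        )
    slope = float(np.clip(rng.normal(3.0, 0.5), 1.5, 5.5))
    return ObserverModel(csf_table=table, true_slope=slope)
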