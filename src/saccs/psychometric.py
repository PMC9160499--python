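"""Cumulative-Weibull psychometric function and the threshold → sensitivity chain.

The detection probability of a contrast stimulus is modelled as a cumulative
Weibull in log-contrast space,

    Psi(x; m, w, gamma, lam)
        = gamma + (1 - lam - gamma) * (1 - exp(log(0.5) * exp(c (log x - m) / w)))

where ``m`` is the threshold (the 50% point of the gamma = lam = 0 curve),
``w`` is the width between the 5% and 95% points of that base curve, ``gamma``
the lower asymptote (guess rate) and ``lam`` the lapse rate.  The constant
``c = log(-log 0.05) - log(-log 0.95)`` makes ``w`` exactly that 5%–95% span.
All logarithms here are natural; only the final sensitivity report uses log10.

Contrast is carried as a linear Michelson proportion in (0, 1]; percent forms
appear only at I/O boundaries.  The contrast threshold is ``CT = exp(m)``,
contrast sensitivity ``CS = 1/CT`` and the reported quantity ``log10(CS)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PsychometricParams",
    "ContrastValue",
    "SensitivityValue",
    "weibull_c_constant",
    "weibull_prob",
    "width_to_slope",
    "slope_to_width",
    "threshold_to_cs",
    "cs_to_threshold",
]

#: Width constant: log(-log 0.05) - log(-log 0.95), natural logs.
_C = math.log(-math.log(0.05)) - math.log(-math.log(0.95))


def weibull_c_constant() -> float:
    """Return ``c = log(-log 0.05) - log(-log 0.95)`` (natural logs, ≈ 4.067)."""
    return _C


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of the cumulative Weibull in log-contrast space.

    Attributes
    ----------
    m : float
        Threshold, log-contrast units (natural log of the linear contrast at
        which the base gamma = lam = 0 curve crosses 0.5).
    w : float
        Width between the 5% and 95% points of the base curve, log-contrast
        units.  Must be positive.
    gamma : float
        Lower asymptote (guess rate): 0 for yes/no saccade scoring, 0.25 for
        a four-alternative forced choice.
    lam : float
        Lapse rate (deficit of the upper asymptote).
    """

    m: float
    w: float
    gamma: float = 0.0
    lam: float = 0.0

    def __post_init__(self) -> None:
        if not self.w > 0:
            raise ValueError(f"width w must be positive, got {self.w}")
        if not (0.0 <= self.lam < 1.0):
            raise ValueError(f"lapse rate must lie in [0, 1), got {self.lam}")
        if not (0.0 <= self.gamma < 1.0 - self.lam):
            raise ValueError(
                f"guess rate must lie in [0, 1 - lam), got gamma={self.gamma} lam={self.lam}"
            )

    @property
    def slope(self) -> float:
        """Slope ``s = c / w`` of the cumulative Weibull."""
        return width_to_slope(self.w)

    def to_dict(self) -> dict:
        return {"m": self.m, "w": self.w, "gamma": self.gamma, "lam": self.lam}

    @classmethod
    def from_dict(cls, d: dict) -> "PsychometricParams":
        return cls(m=d["m"], w=d["w"], gamma=d["gamma"], lam=d["lam"])


@dataclass(frozen=True)
class ContrastValue:
    """A Michelson contrast as a linear proportion in (0, 1]."""

    c_linear: float

    def __post_init__(self) -> None:
        if not (0.0 < self.c_linear <= 1.0):
            raise ValueError(
                f"contrast must be a proportion in (0, 1], got {self.c_linear}"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.c_linear

    @property
    def log(self) -> float:
        """Natural log of the linear contrast (the Weibull's x-axis)."""
        return math.log(self.c_linear)

    @classmethod
    def from_percent(cls, pct: float) -> "ContrastValue":
        return cls(pct / 100.0)

    @classmethod
    def from_log(cls, log_c: float) -> "ContrastValue":
        return cls(math.exp(log_c))


@dataclass(frozen=True)
class SensitivityValue:
    """Linear contrast sensitivity ``cs = 1/CT`` and its log10."""

    cs: float
    log_cs: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.log_cs is None:
            object.__setattr__(self, "log_cs", math.log10(self.cs))
        elif not math.isclose(self.log_cs, math.log10(self.cs), abs_tol=1e-12):
            raise ValueError("log_cs inconsistent with cs")


def weibull_prob(x, p: PsychometricParams):
    """Evaluate the cumulative Weibull Psi at contrast ``x``.

    Parameters
    ----------
    x : ContrastValue, float or array of floats
        Stimulus contrast(s) as linear proportions.  Scalars and arrays of
        positive linear contrast are accepted alongside :class:`ContrastValue`.
    p : PsychometricParams

    Returns
    -------
    float or ndarray
        Psi in [gamma, 1 - lam], strictly increasing in x whenever
        gamma + lam < 1.
    """
    if isinstance(x, ContrastValue):
        xv = x.c_linear
    else:
        xv = np.asarray(x, dtype=float)
        if np.any(xv <= 0):
            raise ValueError("contrast must be strictly positive")
    log_x = np.log(xv)
    base = 1.0 - np.exp(math.log(0.5) * np.exp(_C * (log_x - p.m) / p.w))
    out = p.gamma + (1.0 - p.lam - p.gamma) * base
    if np.ndim(out) == 0:
        return float(out)
    return out


def width_to_slope(w: float) -> float:
    """Convert the 5%–95% width ``w`` to the Weibull slope ``s = c / w``."""
    if not w > 0:
        raise ValueError(f"width must be positive, got {w}")
    return _C / w


def slope_to_width(s: float) -> float:
    """Inverse of :func:`width_to_slope`: ``w = c / s``."""
    if not s > 0:
        raise ValueError(f"slope must be positive, got {s}")
    return _C / s


def threshold_to_cs(m: float) -> SensitivityValue:
    """Convert a log-contrast threshold to contrast sensitivity.

    ``CT = exp(m)``, ``cs = 1/CT``, ``log_cs = log10(cs) = -m / ln 10``.
    A threshold above full contrast (``exp(m) > 1``) is physically a
    sensitivity below 1; it is still computed but flagged with a warning.
    """
    ct = math.exp(m)
    if ct > 1.0:
        warnings.warn(
            f"threshold exp(m) = {ct:.4g} exceeds full contrast; sensitivity < 1",
            stacklevel=2,
        )
    cs = 1.0 / ct
    return SensitivityValue(cs=cs, log_cs=-m / math.log(10.0))


def cs_to_threshold(cs: float) -> float:
    """Inverse of :func:`threshold_to_cs`: ``m = -ln(10) * log10(cs) = -ln(cs)``."""
    if not cs > 0:
        raise ValueError(f"sensitivity must be positive, got {cs}")
    return -math.log(cs)
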