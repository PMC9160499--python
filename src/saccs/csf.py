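"""Offline analysis chain: psychometric fits, sensitivity conversion, CSF fits.

Per (subject, mode, direction, eccentricity, spatial-frequency) cell the raw
material is a rate table — how often each tested contrast was presented and
how often it drew a correct response.  The cell is fitted with the cumulative
Weibull (binomial maximum likelihood; guess rate fixed by response mode, lapse
free within [0, 0.1]), the fitted threshold ``m`` becomes a contrast
sensitivity ``CS = 1/exp(m)``, and the per-frequency ``log10 CS`` values are
fitted with a log-parabola contrast sensitivity function

    S(f) = log10(gamma_max) - log10(2) * ((log10 f - log10 sf_max) / (beta/2))**2

with peak sensitivity ``gamma_max``, peak frequency ``sf_max`` (cycles/degree)
and bandwidth ``beta`` (full width at half of the peak sensitivity, measured
in log10-frequency units; no low-frequency truncation is applied).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .psychometric import PsychometricParams, threshold_to_cs, weibull_c_constant

__all__ = [
    "CsfParams",
    "csf_value",
    "invert_csf_to_threshold",
    "fit_psychometric",
    "fit_csf",
    "mean_csf",
    "rate_table",
]

_LOG2 = math.log10(2.0)


@dataclass(frozen=True)
class CsfParams:
    """Log-parabola CSF parameters.

    gamma_max : peak linear contrast sensitivity (> 0)
    sf_max    : peak spatial frequency, cycles per degree (> 0)
    beta      : bandwidth — full width at half of peak sensitivity, in
                log10-frequency units (> 0)
    """

    gamma_max: float
    sf_max: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.gamma_max > 0 and self.sf_max > 0 and self.beta > 0):
            raise ValueError("CSF parameters must all be positive")

    def to_dict(self) -> dict:
        return {"gamma_max": self.gamma_max, "sf_max": self.sf_max, "beta": self.beta}

    @classmethod
    def from_dict(cls, d: dict) -> "CsfParams":
        return cls(d["gamma_max"], d["sf_max"], d["beta"])


def csf_value(sf, p: CsfParams):
    """log10 contrast sensitivity of the log-parabola at frequency ``sf`` (cpd)."""
    sf = np.asarray(sf, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("spatial frequency must be positive")
    dev = (np.log10(sf) - math.log10(p.sf_max)) / (p.beta / 2.0)
    out = math.log10(p.gamma_max) - _LOG2 * dev**2
    return float(out) if np.ndim(out) == 0 else out


def invert_csf_to_threshold(sf: float, p: CsfParams) -> float:
    """Log-contrast detection threshold implied by a CSF: m = -ln(10)·S(sf)."""
    return -math.log(10.0) * csf_value(sf, p)


# ---------------------------------------------------------------------------
# Psychometric fitting
# ---------------------------------------------------------------------------

_GUESS_BY_MODE = {"saccade": 0.0, "keyboard": 0.25}
_LAPSE_MAX = 0.1


def _nll(theta: np.ndarray, log_x: np.ndarray, n: np.ndarray, k: np.ndarray,
         gamma: float) -> float:
    m, w, lam = theta
    c = weibull_c_constant()
    base = 1.0 - np.exp(np.log(0.5) * np.exp(c * (log_x - m) / w))
    p = gamma + (1.0 - lam - gamma) * base
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return float(-(k * np.log(p) + (n - k) * np.log(1.0 - p)).sum())


def fit_psychometric(table: pd.DataFrame, mode: str):
    """Maximum-likelihood Weibull fit of one rate table.

    Parameters
    ----------
    table : DataFrame with columns ``contrast`` (linear proportion), ``n``
        (presentations) and ``k`` (correct responses).  Duplicate contrast
        rows are pooled; at least two distinct contrasts must carry data.
    mode : "saccade" (guess rate 0, yes/no scoring) or "keyboard" (0.25, 4AFC).

    Returns
    -------
    (PsychometricParams, diagnostics dict) — diagnostics carry the negative
    log-likelihood, a convergence flag and a boundary-data flag.  All-correct
    or all-incorrect data are unidentifiable: the threshold is clamped to the
    edge of the sampled contrast range and flagged.
    """
    if mode not in _GUESS_BY_MODE:
        raise ValueError(f"mode must be one of {sorted(_GUESS_BY_MODE)}, got {mode!r}")
    gamma = _GUESS_BY_MODE[mode]
    df = (
        pd.DataFrame(
            {"contrast": table["contrast"], "n": table["n"], "k": table["k"]}
        )
        .groupby("contrast", as_index=False)
        .sum()
    )
    df = df[df["n"] > 0]
    if np.any(df["contrast"] <= 0):
        raise ValueError("contrasts must be positive proportions")
    if np.any(df["k"] > df["n"]) or np.any(df["k"] < 0):
        raise ValueError("need 0 <= k <= n in every row")
    if len(df) < 2:
        raise ValueError("need data at >= 2 distinct contrast levels")

    log_x = np.log(df["contrast"].to_numpy(float))
    n = df["n"].to_numpy(float)
    k = df["k"].to_numpy(float)

    lo, hi = log_x.min(), log_x.max()
    boundary = False
    rate = k.sum() / n.sum()
    chance_band = gamma + 0.02 * (1 - gamma)
    if np.all(k >= n) or rate >= 0.995:
        boundary = True  # everything seen: threshold below the sampled range
        m_clamp = lo
    elif np.all(k <= n * gamma + 1e-9) or rate <= chance_band:
        boundary = True  # nothing seen: threshold above the sampled range
        m_clamp = hi
    if boundary:
        warnings.warn(
            "degenerate rate table (all-correct or at-chance); threshold "
            "clamped to the sampled contrast range", stacklevel=2,
        )
        params = PsychometricParams(m=float(m_clamp), w=1.0, gamma=gamma, lam=0.0)
        return params, {"nll": _nll(np.array([m_clamp, 1.0, 0.0]), log_x, n, k, gamma),
                        "converged": False, "boundary": True}

    span = max(hi - lo, 1.0)
    bounds = [(lo - 2.0, hi + 2.0), (0.05, 8.0 * span), (0.0, _LAPSE_MAX)]
    starts = [
        (m0, w0, 0.02)
        for m0 in np.linspace(lo, hi, 5)
        for w0 in (0.5, 1.0, 2.0, 4.0)
    ]
    best = None
    for s0 in starts:
        res = optimize.minimize(
            _nll, x0=np.array(s0), args=(log_x, n, k, gamma),
            method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    m, w, lam = best.x
    params = PsychometricParams(m=float(m), w=float(w), gamma=gamma, lam=float(lam))
    return params, {"nll": float(best.fun), "converged": bool(best.success),
                    "boundary": False}


def rate_table(trials: pd.DataFrame, response_col: str) -> pd.DataFrame:
    """Collapse a trial log into a rate table (contrast, n, k).

    ``trials`` must carry a ``contrast`` column and a boolean-ish response
    column; catch trials (NaN contrast) are ignored.
    """
    df = trials.dropna(subset=["contrast"])
    g = df.groupby("contrast")[response_col]
    out = pd.DataFrame({"n": g.size(), "k": g.sum().astype(float)}).reset_index()
    return out


# ---------------------------------------------------------------------------
# CSF fitting
# ---------------------------------------------------------------------------

def _csf_residuals(theta: np.ndarray, log_sf: np.ndarray, log_cs: np.ndarray):
    u, v, beta = theta  # u = log10 gamma_max, v = log10 sf_max
    return u - _LOG2 * ((log_sf - v) / (beta / 2.0)) ** 2 - log_cs


def fit_csf(points) -> CsfParams:
    """Least-squares log-parabola fit to (spatial frequency, log10 CS) points.

    Accepts an iterable of (sf, log_cs) pairs or a DataFrame with columns
    ``sf`` and ``log_cs``.  Needs >= 3 distinct frequencies.  The search is a
    deterministic multistart over bounded parameters: sf_max within
    [min SF / 2, max SF * 2], beta in (0, 4], gamma_max in [1, 1e4].
    """
    if isinstance(points, pd.DataFrame):
        sf = points["sf"].to_numpy(float)
        cs = points["log_cs"].to_numpy(float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (sf, log_cs) pairs")
        sf, cs = arr[:, 0], arr[:, 1]
    if np.unique(sf).size < 3:
        raise ValueError("need >= 3 distinct spatial frequencies to fit a CSF")
    if np.any(sf <= 0):
        raise ValueError("spatial frequencies must be positive")
    log_sf = np.log10(sf)
    if np.ptp(cs) < 1e-12:
        warnings.warn("flat log CS data; bandwidth pinned at its bound", stacklevel=2)

    lb = np.array([0.0, math.log10(sf.min() / 2.0), 1e-3])
    ub = np.array([4.0, math.log10(sf.max() * 2.0), 4.0])
    v_starts = np.linspace(lb[1], ub[1], 4)
    best = None
    for v0 in v_starts:
        for b0 in (1.0, 2.5):
            x0 = np.clip(np.array([max(cs.max(), 0.0), v0, b0]), lb, ub)
            res = optimize.least_squares(
                _csf_residuals, x0=x0, args=(log_sf, cs), bounds=(lb, ub),
            )
            if best is None or res.cost < best.cost - 1e-15:
                best = res
    u, v, beta = best.x
    return CsfParams(gamma_max=10.0**u, sf_max=10.0**v, beta=float(beta))


def mean_csf(points: pd.DataFrame, group_cols=None) -> "CsfParams | pd.DataFrame":
    """Fit the cross-subject mean CSF.

    ``points`` needs columns ``subject``, ``sf``, ``log_cs`` (plus any
    grouping columns).  log10 CS is averaged across subjects per frequency,
    then the log-parabola is fitted to the means.  With ``group_cols`` a
    DataFrame of fitted parameters per group is returned; otherwise a single
    :class:`CsfParams`.  Subjects missing a frequency are excluded from that
    frequency's mean with a warning.
    """
    required = {"subject", "sf", "log_cs"}
    if not required <= set(points.columns):
        raise ValueError(f"points must have columns {sorted(required)}")

    def _fit_one(df: pd.DataFrame) -> CsfParams:
        counts = df.groupby("sf")["subject"].nunique()
        if counts.nunique() > 1:
            warnings.warn(
                "unequal subject counts across frequencies; missing cells "
                "dropped from their frequency's mean", stacklevel=3,
            )
        means = df.groupby("sf", as_index=False)["log_cs"].mean()
        return fit_csf(means.rename(columns={"log_cs": "log_cs"}))

    if group_cols:
        rows = []
        for key, df in points.groupby(list(group_cols)):
            key = key if isinstance(key, tuple) else (key,)
            fit = _fit_one(df)
            rows.append(dict(zip(group_cols, key)) | fit.to_dict())
        return pd.DataFrame(rows)
    return _fit_one(points)


def threshold_chain(m: float) -> dict:
    """Convenience: threshold m → {ct, cs, log_cs} on reporting scales."""
    s = threshold_to_cs(m)
    return {"ct": math.exp(m), "cs": s.cs, "log_cs": s.log_cs}
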