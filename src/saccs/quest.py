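"""QUEST+ Bayesian adaptive procedure over a (threshold, slope) grid.

One independent instance runs per visual-field direction.  The engine keeps a
posterior probability mass over a discrete grid of Weibull thresholds and
slopes, updates it by Bayes' rule after each binary outcome, and places the
next stimulus at the candidate contrast minimising the expected Shannon
entropy of the posterior, with outcome probabilities marginalised over the
current posterior.  Guess and lapse rates are fixed per response mode, not
estimated: only threshold and slope carry grids.

Defaults follow the measurement design: 15 contrast levels geometrically
spaced from 0.024% to 66% serve both as the threshold grid (in natural-log
contrast) and as the stimulus domain, slopes run 0.5 to 5.5 in steps of 0.5,
the prior is uniform, and stopping is a fixed trial budget (30 per direction),
never an entropy-convergence rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .psychometric import ContrastValue, weibull_c_constant

__all__ = [
    "CONTRAST_LEVELS",
    "SLOPE_LEVELS",
    "ParameterGrid",
    "QuestState",
    "default_grid",
    "init_state",
    "outcome_likelihood",
    "update",
    "next_stimulus",
    "estimate_threshold",
    "posterior_entropy",
    "threshold_marginal",
]

#: The 15 testable contrast levels (linear proportions), geometric from
#: 0.00024 (~0.024%) to 0.66 (66%).
CONTRAST_LEVELS = tuple(np.geomspace(0.00024, 0.66, 15).tolist())

#: Slope grid 0.5, 1.0, ..., 5.5.
SLOPE_LEVELS = tuple((0.5 * np.arange(1, 12)).tolist())


@dataclass(frozen=True)
class ParameterGrid:
    """Discrete Weibull parameter space for one QUEST+ instance.

    ``thresholds`` are natural-log contrasts (strictly increasing);
    ``slopes`` are Weibull slopes ``s`` with width ``w = c/s``.
    ``gamma_fixed`` is 0 for saccade (yes/no) scoring and 0.25 for the 4AFC
    keyboard mode; ``lam_fixed`` defaults to a conventional 2% lapse.
    """

    thresholds: tuple = tuple(np.log(CONTRAST_LEVELS).tolist())
    slopes: tuple = SLOPE_LEVELS
    gamma_fixed: float = 0.0
    lam_fixed: float = 0.02

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        s = np.asarray(self.slopes, dtype=float)
        if t.size == 0 or s.size == 0:
            raise ValueError("parameter grids must be non-empty")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if s.size > 1 and not np.all(np.diff(s) > 0):
            raise ValueError("slopes must be strictly increasing")
        if not (0.0 <= self.gamma_fixed < 1.0 - self.lam_fixed):
            raise ValueError("gamma_fixed must lie in [0, 1 - lam_fixed)")

    @property
    def shape(self) -> tuple:
        return (len(self.thresholds), len(self.slopes))


def default_grid(gamma_fixed: float = 0.0, lam_fixed: float = 0.02) -> ParameterGrid:
    """The standard 15 x 11 grid with mode-appropriate fixed asymptotes."""
    return ParameterGrid(gamma_fixed=gamma_fixed, lam_fixed=lam_fixed)


def _likelihood_correct(grid: ParameterGrid, stimuli: np.ndarray) -> np.ndarray:
    """P(correct | stimulus, cell) for every stimulus x grid cell.

    Returns an array of shape (n_stimuli, n_thresholds, n_slopes).  The
    per-cell width is w = c / slope (mirror of the width→slope relation).
    """
    c = weibull_c_constant()
    log_x = np.log(np.asarray(stimuli, dtype=float))[:, None, None]
    m = np.asarray(grid.thresholds, dtype=float)[None, :, None]
    s = np.asarray(grid.slopes, dtype=float)[None, None, :]
    # c * (log x - m) / w with w = c/s collapses to s * (log x - m)
    base = 1.0 - np.exp(np.log(0.5) * np.exp(s * (log_x - m)))
    return grid.gamma_fixed + (1.0 - grid.lam_fixed - grid.gamma_fixed) * base


@dataclass(frozen=True)
class QuestState:
    """Posterior state of one QUEST+ instance (immutable; updates return new states)."""

    grid: ParameterGrid
    posterior: np.ndarray  # shape (n_thresholds, n_slopes), sums to 1
    stimulus_domain: tuple = CONTRAST_LEVELS
    trial_count: int = 0
    location_label: str = ""
    # cached P(correct | stimulus, cell); derived, not part of identity
    _lik: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        post = np.asarray(self.posterior, dtype=float)
        if post.shape != self.grid.shape:
            raise ValueError(
                f"posterior shape {post.shape} does not match grid {self.grid.shape}"
            )
        if np.any(post < 0) or abs(post.sum() - 1.0) > 1e-12:
            raise ValueError("posterior must be non-negative and sum to 1")
        object.__setattr__(self, "posterior", post)
        if self._lik is None:
            object.__setattr__(
                self,
                "_lik",
                _likelihood_correct(self.grid, np.asarray(self.stimulus_domain)),
            )

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format_version": 1,
                "thresholds": list(self.grid.thresholds),
                "slopes": list(self.grid.slopes),
                "gamma_fixed": self.grid.gamma_fixed,
                "lam_fixed": self.grid.lam_fixed,
                "stimulus_domain": list(self.stimulus_domain),
                "posterior": self.posterior.ravel().tolist(),
                "trial_count": self.trial_count,
                "location_label": self.location_label,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "QuestState":
        d = json.loads(text)
        grid = ParameterGrid(
            thresholds=tuple(d["thresholds"]),
            slopes=tuple(d["slopes"]),
            gamma_fixed=d["gamma_fixed"],
            lam_fixed=d["lam_fixed"],
        )
        post = np.asarray(d["posterior"], dtype=float).reshape(grid.shape)
        return cls(
            grid=grid,
            posterior=post,
            stimulus_domain=tuple(d["stimulus_domain"]),
            trial_count=d["trial_count"],
            location_label=d.get("location_label", ""),
        )


def init_state(
    grid: ParameterGrid,
    prior: np.ndarray | None = None,
    stimulus_domain=None,
    location_label: str = "",
) -> QuestState:
    """Create a fresh QUEST+ state with a uniform (or supplied) prior.

    A supplied prior is validated against the grid shape and renormalised.
    """
    shape = grid.shape
    if prior is None:
        post = np.full(shape, 1.0 / (shape[0] * shape[1]))
    else:
        post = np.asarray(prior, dtype=float)
        if post.shape != shape:
            raise ValueError(f"prior shape {post.shape} does not match grid {shape}")
        if np.any(post < 0) or post.sum() <= 0:
            raise ValueError("prior must be non-negative with positive mass")
        post = post / post.sum()
    domain = tuple(stimulus_domain) if stimulus_domain is not None else tuple(
        np.exp(np.asarray(grid.thresholds)).tolist()
    )
    return QuestState(
        grid=grid, posterior=post, stimulus_domain=domain,
        trial_count=0, location_label=location_label,
    )


def outcome_likelihood(
    state: QuestState, stimulus: ContrastValue, i_threshold: int, j_slope: int,
    correct: bool,
) -> float:
    """P(outcome | stimulus, grid cell) under the fixed-asymptote Weibull."""
    p = _likelihood_correct(state.grid, np.array([stimulus.c_linear]))[
        0, i_threshold, j_slope
    ]
    return float(p if correct else 1.0 - p)


def update(state: QuestState, stimulus: ContrastValue, correct: bool) -> QuestState:
    """Bayes update of the posterior after one binary outcome.

    posterior' ∝ posterior × P(outcome | stimulus, cell), renormalised.
    """
    p_correct = _likelihood_correct(state.grid, np.array([stimulus.c_linear]))[0]
    lik = p_correct if correct else 1.0 - p_correct
    unnorm = state.posterior * lik
    total = unnorm.sum()
    if total <= 0 or not np.isfinite(total):
        raise FloatingPointError(
            "posterior mass vanished during update (numerical degeneracy)"
        )
    return replace(
        state,
        posterior=unnorm / total,
        trial_count=state.trial_count + 1,
        _lik=state._lik,
    )


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def posterior_entropy(state: QuestState) -> float:
    """Shannon entropy (nats) of the joint posterior."""
    return _entropy(state.posterior.ravel())


def threshold_marginal(state: QuestState) -> np.ndarray:
    """Marginal posterior mass over the threshold grid."""
    return state.posterior.sum(axis=1)


def next_stimulus(state: QuestState) -> ContrastValue:
    """Choose the stimulus minimising expected posterior entropy.

    For each candidate contrast the two outcome branches (correct/incorrect)
    are weighted by their marginal probability under the current posterior;
    the candidate with the lowest expected entropy wins, ties going to the
    lowest contrast (the stimulus domain is stored in increasing order).
    """
    if len(state.stimulus_domain) == 0:
        raise ValueError("stimulus domain is empty")
    post = state.posterior  # (T, S)
    lik = state._lik  # (X, T, S)
    joint_c = lik * post[None, :, :]  # unnormalised posterior if correct
    p_c = joint_c.sum(axis=(1, 2))  # P(correct | x)
    joint_i = (1.0 - lik) * post[None, :, :]
    p_i = joint_i.sum(axis=(1, 2))

    expected = np.empty(len(state.stimulus_domain))
    for k in range(len(state.stimulus_domain)):
        h_c = _entropy(joint_c[k].ravel() / p_c[k]) if p_c[k] > 0 else 0.0
        h_i = _entropy(joint_i[k].ravel() / p_i[k]) if p_i[k] > 0 else 0.0
        expected[k] = p_c[k] * h_c + p_i[k] * h_i
    # lowest-contrast tie-break: argmin returns the first minimum and the
    # domain is sorted increasing, but guard against unsorted custom domains
    best = np.flatnonzero(expected <= expected.min() + 1e-12)
    k = best[np.argmin(np.asarray(state.stimulus_domain)[best])]
    return ContrastValue(float(state.stimulus_domain[k]))


def estimate_threshold(state: QuestState) -> float:
    """Posterior mean of the threshold marginal (log-contrast units)."""
    marg = threshold_marginal(state)
    return float(np.dot(marg, np.asarray(state.grid.thresholds)))
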