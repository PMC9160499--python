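"""Method-agreement analytics across the three response channels.

Every tested cell (subject, direction, eccentricity, spatial frequency) can
yield up to three log10 CS values: saccade-based responses in saccadic
measurements, keyboard responses in the same saccadic measurements, and
keyboard responses in separate non-saccadic measurements.  This module pairs
those values, computes Pearson correlations and Bland–Altman agreement
statistics (bias = mean paired difference, limits of agreement =
bias ± 1.96 · SD of the differences), and assembles the summary bundle:
triplet table, pairwise agreement, per-location sensitivity summaries and the
catch-trial false-positive rate.  Omnibus cohort statistics are left to
standard downstream routines; the tidy tables are the interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import csf as csf_mod
from .gaze import MERIDIAN_LABELS
from .psychometric import threshold_to_cs

__all__ = [
    "CHANNELS",
    "pearson_r",
    "bland_altman",
    "fit_study_channels",
    "build_report",
    "ReportBundle",
]

#: The three response channels, in reporting order.
CHANNELS = ("saccade_saccadic", "keyboard_saccadic", "keyboard_nonsaccadic")

#: Channel -> (mode, trial-log response column, psychometric guess-rate mode)
_CHANNEL_SOURCE = {
    "saccade_saccadic": ("saccadic", "saccade_correct", "saccade"),
    "keyboard_saccadic": ("saccadic", "keyboard_correct", "keyboard"),
    "keyboard_nonsaccadic": ("non-saccadic", "keyboard_correct", "keyboard"),
}


def pearson_r(x, y) -> tuple:
    """Pearson product-moment correlation of paired values; returns (r, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if x.size < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r = stats.pearsonr(x, y).statistic
    return float(r), int(x.size)


def bland_altman(x, y) -> dict:
    """Bland–Altman agreement of two paired measurement series.

    Returns bias = mean(x − y), the sample SD of the differences (ddof=1 when
    n > 1) and the 95% limits of agreement bias ± 1.96·SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need paired 1-D series with n >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "bias": bias,
        "sd_diff": sd,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "n": int(d.size),
    }


def fit_study_channels(study_log: pd.DataFrame) -> pd.DataFrame:
    """Fit every (participant, channel, direction, eccentricity, SF) cell.

    Expects the concatenated trial log of :func:`saccs.scheduler.run_study`.
    Returns a tidy frame with the fitted threshold and log10 CS per cell;
    cells whose fit is degenerate are flagged, not dropped.
    """
    rows = []
    done = study_log[study_log["status"] == "done"]
    for channel, (mode, col, fit_mode) in _CHANNEL_SOURCE.items():
        sub = done[(done["mode"] == mode) & (~done["is_catch"])]
        group_cols = ["participant", "eccentricity_deg", "spatial_freq_cpd",
                      "meridian_deg"]
        for key, cell in sub.groupby(group_cols):
            table = csf_mod.rate_table(cell, col)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                params, diag = csf_mod.fit_psychometric(table, fit_mode)
            sens = threshold_to_cs(params.m)
            rows.append(
                dict(zip(group_cols, key))
                | {
                    "channel": channel,
                    "m": params.m,
                    "w": params.w,
                    "lam": params.lam,
                    "log_cs": sens.log_cs,
                    "boundary": diag["boundary"],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ReportBundle:
    """Everything the comparison analysis produces, plus writers."""

    triplets: pd.DataFrame
    correlations: pd.DataFrame
    bland_altman: pd.DataFrame
    location_summary: pd.DataFrame
    false_positive_rate: float | None
    n_catch: int
    gaps: list

    def summary_dict(self) -> dict:
        return {
            "format_version": 1,
            "n_triplet_cells": int(len(self.triplets)),
            "correlations": self.correlations.to_dict(orient="records"),
            "bland_altman": self.bland_altman.to_dict(orient="records"),
            "false_positive_rate": self.false_positive_rate,
            "n_catch_trials": self.n_catch,
            "gaps": self.gaps,
        }

    def write(self, outdir, seed=None) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = f"# saccs report v1 seed={seed}\n"
        for name, df in (
            ("triplets", self.triplets),
            ("correlations", self.correlations),
            ("bland_altman", self.bland_altman),
            ("location_summary", self.location_summary),
        ):
            path = outdir / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary_dict() | {"seed": seed}, fh, indent=2)


def build_report(study_log: pd.DataFrame, fits: pd.DataFrame | None = None) -> ReportBundle:
    """Assemble the full agreement report from a study trial log.

    ``fits`` may be supplied (output of :func:`fit_study_channels`) to avoid
    refitting.  Channels missing from the log yield a partial report with the
    gaps listed explicitly.
    """
    if fits is None:
        fits = fit_study_channels(study_log)
    ok = fits[~fits["boundary"]] if "boundary" in fits else fits
    cell_cols = ["participant", "eccentricity_deg", "spatial_freq_cpd", "meridian_deg"]
    wide = ok.pivot_table(index=cell_cols, columns="channel", values="log_cs")
    gaps = [ch for ch in CHANNELS if ch not in wide.columns]
    triplet_cols = [ch for ch in CHANNELS if ch in wide.columns]
    triplets = wide.dropna(subset=triplet_cols).reset_index()

    corr_rows, ba_rows = [], []
    for i in range(len(triplet_cols)):
        for j in range(i + 1, len(triplet_cols)):
            a, b = triplet_cols[i], triplet_cols[j]
            x, y = triplets[a].to_numpy(), triplets[b].to_numpy()
            if x.size >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
                r, n = pearson_r(x, y)
                corr_rows.append({"pair": f"{a}_vs_{b}", "r": r, "n": n})
            if x.size >= 2:
                ba = bland_altman(x, y)
                ba_rows.append({"pair": f"{a}_vs_{b}"} | ba)

    # per (direction, eccentricity) sensitivity summary of the saccade channel,
    # pooled over subjects and spatial frequencies
    summary_rows = []
    for ch in triplet_cols:
        for (mer, ecc), grp in ok[ok["channel"] == ch].groupby(
            ["meridian_deg", "eccentricity_deg"]
        ):
            v = grp["log_cs"].to_numpy()
            summary_rows.append(
                {
                    "channel": ch,
                    "meridian_deg": mer,
                    "direction": MERIDIAN_LABELS.get(int(mer), str(mer)),
                    "eccentricity_deg": ecc,
                    "median_log_cs": float(np.median(v)),
                    "mean_log_cs": float(v.mean()),
                    "sd_log_cs": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                    "n": int(v.size),
                }
            )

    catch = study_log[(study_log["is_catch"]) & (study_log["status"] == "done")]
    n_catch = int(len(catch))
    fp_rate = float(catch["false_positive"].mean()) if n_catch else None

    return ReportBundle(
        triplets=triplets,
        correlations=pd.DataFrame(corr_rows),
        bland_altman=pd.DataFrame(ba_rows),
        location_summary=pd.DataFrame(summary_rows),
        false_positive_rate=fp_rate,
        n_catch=n_catch,
        gaps=gaps,
    )
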