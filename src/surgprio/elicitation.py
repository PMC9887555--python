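"""Aggregation of per-expert VAS scores into quality-of-life estimates.

Experts rate each procedure/health-state on a visual analogue scale from 0
(worst imaginable health) to 100 (best imaginable health), calibrated against
GBD anchor states, so utility = VAS / 100 and utility = 1 - disability weight
for GBD-derived states.  Per Delphi round the panel is summarised by median
and interquartile range (the feedback shown between rounds); the final
quality-of-life estimate of a procedure/state is the mean of the final-round
individual scores with a t-based confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoundSummary",
    "QoLEstimate",
    "vas_to_qol",
    "qol_from_disability_weight",
    "round_summary",
    "finalize_estimate",
    "pool_panels",
    "aggregate_final_round",
    "pooled_estimates",
]

SCORE_COLUMNS = ["panel", "round", "expert_id", "procedure_id", "state", "vas"]


@dataclass(frozen=True)
class RoundSummary:
    """Panel feedback for one procedure/state/round (VAS scale)."""

    median: float
    iqr_low: float
    iqr_high: float
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class QoLEstimate:
    """Aggregated utility for one procedure/state/panel.

    ``q_se``, ``ci_low`` and ``ci_high`` are NaN when only a single score is
    available (SE undefined); the CI is truncated to [0, 1].
    """

    procedure_id: str
    state: str
    panel: str
    q_mean: float
    q_sd: float
    q_se: float
    ci_low: float
    ci_high: float
    n: int


def vas_to_qol(v):
    """Map VAS (0-100) to utility (0-1); linear with calibrated endpoints."""
    arr = np.asarray(v, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("VAS scores must lie in [0, 100]")
    out = arr / 100.0
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def qol_from_disability_weight(dw):
    """Utility from a GBD disability weight: q = 1 - dw."""
    arr = np.asarray(dw, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("disability weights must lie in [0, 1]")
    out = 1.0 - arr
    return float(out) if np.isscalar(dw) or arr.ndim == 0 else out


def _as_vas_array(scores) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        for col in ("panel", "round", "procedure_id", "state"):
            if col in scores.columns and scores[col].nunique() > 1:
                raise ValueError(f"scores mix multiple values of '{col}'")
        vals = scores["vas"].to_numpy(float)
    else:
        vals = np.asarray(scores, dtype=float)
    if vals.size == 0:
        raise ValueError("empty score set")
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("VAS scores must lie in [0, 100]")
    return vals


def round_summary(scores) -> RoundSummary:
    """Median/IQR feedback plus mean and sample SD for one panel cell.

    Quantiles use linear interpolation (type 7), matching the default of the
    usual statistical environments.
    """
    vals = _as_vas_array(scores)
    q1, med, q3 = np.percentile(vals, [25, 50, 75])  # type-7 interpolation
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RoundSummary(median=float(med), iqr_low=float(q1),
                        iqr_high=float(q3), mean=float(np.mean(vals)),
                        sd=sd, n=int(vals.size))


def finalize_estimate(final_scores, procedure_id: str = "", state: str = "",
                      panel: str = "") -> QoLEstimate:
    """Final QoL estimate: mean of final-round scores on the utility scale.

    CI is ``mean ± t_{n-1, 0.975} * se`` truncated to [0, 1]; with n < 2 the
    SE and CI are returned as NaN but the mean is still reported.
    """
    vals = _as_vas_array(final_scores) / 100.0
    n = int(vals.size)
    q_mean = float(np.mean(vals))
    if n < 2:
        return QoLEstimate(procedure_id, state, panel, q_mean, 0.0,
                           np.nan, np.nan, np.nan, n)
    q_sd = float(np.std(vals, ddof=1))
    q_se = q_sd / np.sqrt(n)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    lo = max(q_mean - tcrit * q_se, 0.0)
    hi = min(q_mean + tcrit * q_se, 1.0)
    return QoLEstimate(procedure_id, state, panel, q_mean, q_sd, q_se,
                       lo, hi, n)


def pool_panels(scores_a, scores_b, procedure_id: str = "",
                state: str = "") -> QoLEstimate:
    """Pool two panels by concatenating individual expert scores.

    Every expert gets equal weight, so the pooled mean is the expert-count
    weighted average of the two panel means.  An empty second panel degrades
    to ``finalize_estimate`` of the first.
    """
    if isinstance(scores_a, pd.DataFrame) and isinstance(scores_b,
                                                         pd.DataFrame):
        for col in ("procedure_id", "state"):
            va = set(scores_a[col].unique())
            vb = set(scores_b[col].unique())
            if va != vb:
                raise ValueError(f"panel {col} mismatch: {va} vs {vb}")
    a = np.asarray(scores_a["vas"] if isinstance(scores_a, pd.DataFrame)
                   else scores_a, dtype=float)
    b = np.asarray(scores_b["vas"] if isinstance(scores_b, pd.DataFrame)
                   else scores_b, dtype=float)
    if b.size == 0:
        import warnings
        warnings.warn("second panel empty; pooled estimate equals panel A",
                      stacklevel=2)
        combined = a
    else:
        combined = np.concatenate([a, b])
    return finalize_estimate(combined, procedure_id, state, panel="pooled")


def aggregate_final_round(scores: pd.DataFrame,
                          final_round: int | None = None) -> pd.DataFrame:
    """Per-(panel, procedure, state) QoL estimates from final-round scores.

    Returns a tidy frame with columns procedure_id, state, panel, q_mean,
    q_sd, q_se, ci_low, ci_high, n.
    """
    if final_round is None:
        final_round = int(scores["round"].max())
    final = scores[scores["round"] == final_round]
    rows = []
    for (panel, pid, state), grp in final.groupby(
            ["panel", "procedure_id", "state"], sort=True):
        est = finalize_estimate(grp["vas"].to_numpy(float), pid, state, panel)
        rows.append(est.__dict__)
    return pd.DataFrame(rows)


def pooled_estimates(scores: pd.DataFrame, panel_a: str, panel_b: str,
                     final_round: int | None = None) -> pd.DataFrame:
    """Pooled per-(procedure, state) estimates across two panels."""
    if final_round is None:
        final_round = int(scores["round"].max())
    final = scores[scores["round"] == final_round]
    rows = []
    for (pid, state), grp in final.groupby(["procedure_id", "state"],
                                           sort=True):
        a = grp.loc[grp["panel"] == panel_a, "vas"].to_numpy(float)
        b = grp.loc[grp["panel"] == panel_b, "vas"].to_numpy(float)
        rows.append(pool_panels(a, b, pid, state).__dict__)
    return pd.DataFrame(rows)
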