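"""Urgency rankings from DALY/month results and their robustness.

Rank 1 is the most urgent procedure (largest DALY/month of delay).  Two
rankings — e.g. one built from the original panel's utilities and one from
the pooled utilities of both panels — are compared procedure by procedure
(rank shifts, largest urgency change) and globally via Spearman's rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .decision_model import UrgencyResult

__all__ = ["RankingComparison", "rank_procedures", "spearman",
           "compare_rankings"]


@dataclass(frozen=True)
class RankingComparison:
    """Joined rank table plus Spearman's rho between two urgency schemes.

    ``table`` has one row per procedure: delta_a, delta_b (DALY/month under
    each scheme), rank_a, rank_b and rank_shift = rank_b - rank_a (positive
    means the procedure became less urgent under scheme B).
    """

    table: pd.DataFrame
    rho: float
    n: int
    max_shift_procedure: str
    max_abs_delta_change: float


def _to_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        df = results[["procedure_id", "daly_per_month"]].copy()
    else:
        df = pd.DataFrame([{"procedure_id": r.procedure_id,
                            "daly_per_month": r.daly_per_month}
                           for r in results])
    if df.empty:
        raise ValueError("no urgency results given")
    if df["procedure_id"].duplicated().any():
        dupes = df.loc[df["procedure_id"].duplicated(), "procedure_id"]
        raise ValueError(f"duplicate procedure ids: {sorted(set(dupes))}")
    if not np.isfinite(df["daly_per_month"]).all():
        raise ValueError("non-finite DALY/month values")
    return df


def rank_procedures(results) -> pd.DataFrame:
    """Descending rank by DALY/month; ties get average ranks.

    For display determinism the table is sorted by (rank, procedure_id).
    """
    df = _to_frame(results)
    df["rank"] = df["daly_per_month"].rank(ascending=False, method="average")
    return (df.sort_values(["rank", "procedure_id"])
              .reset_index(drop=True))


def spearman(ranks_a: Sequence[float], ranks_b: Sequence[float]) -> float:
    """Spearman's rho as the Pearson correlation of the rank vectors."""
    a = np.asarray(ranks_a, dtype=float)
    b = np.asarray(ranks_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rank vectors must be 1-D and of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 ranks")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant rank vector; rho undefined")
    return float(stats.pearsonr(a, b)[0])


def compare_rankings(results_a, results_b) -> RankingComparison:
    """Compare two urgency rankings over the same procedure set."""
    ra = rank_procedures(results_a).rename(
        columns={"daly_per_month": "delta_a", "rank": "rank_a"})
    rb = rank_procedures(results_b).rename(
        columns={"daly_per_month": "delta_b", "rank": "rank_b"})
    only_a = set(ra["procedure_id"]) - set(rb["procedure_id"])
    only_b = set(rb["procedure_id"]) - set(ra["procedure_id"])
    if only_a or only_b:
        raise ValueError(
            f"procedure sets differ; only in A: {sorted(only_a)}, "
            f"only in B: {sorted(only_b)}")
    df = ra.merge(rb, on="procedure_id")
    df["rank_shift"] = df["rank_b"] - df["rank_a"]
    rho = spearman(df["rank_a"], df["rank_b"])
    change = (df["delta_a"] - df["delta_b"]).abs()
    imax = int(change.idxmax())
    return RankingComparison(
        table=df.sort_values(["rank_a", "procedure_id"])
                .reset_index(drop=True),
        rho=rho, n=len(df),
        max_shift_procedure=str(df.loc[imax, "procedure_id"]),
        max_abs_delta_change=float(change.max()),
    )
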