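"""End-to-end study analysis chaining the library modules.

One call (`run_study_analysis`) reproduces the whole validation battery on a
generated two-panel study: aggregate final-round scores, compare panels
(Bland-Altman per state, score and consensus mixed models), rebuild the
urgency ranking with original-only vs pooled utilities and compare them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import elicitation, validation_stats, ranking
from .decision_model import ModelSettings, daly_per_month
from .synthetic_data import (LifeTable, PanelConfig, ProcedureTruth,
                             generate_life_table, generate_study,
                             study_emulation_preset)

__all__ = ["StudyAnalysis", "qol_params_for_panel", "urgency_table",
           "run_study_analysis"]

ORIGINAL = "original"
VALIDATION = "validation"


@dataclass
class StudyAnalysis:
    """All headline quantities of one study run."""

    seed: int
    truths: list[ProcedureTruth]
    scores: pd.DataFrame
    estimates: pd.DataFrame
    pooled: pd.DataFrame
    ba_pre: validation_stats.BlandAltmanResult
    ba_post: validation_stats.BlandAltmanResult
    score_model: validation_stats.MixedModelResult
    sd_model: validation_stats.MixedModelResult
    ranking_comparison: ranking.RankingComparison

    def headline(self) -> dict:
        return {
            "seed": self.seed,
            "ba_bias_pre": self.ba_pre.bias,
            "ba_loa_pre": [self.ba_pre.loa_low, self.ba_pre.loa_high],
            "ba_bias_post": self.ba_post.bias,
            "ba_loa_post": [self.ba_post.loa_low, self.ba_post.loa_high],
            "score_study_coefficient": self.score_model.study_coefficient,
            "sd_study_coefficient": self.sd_model.study_coefficient,
            "spearman_rho": self.ranking_comparison.rho,
            "max_shift_procedure":
                self.ranking_comparison.max_shift_procedure,
            "n_procedures": self.ranking_comparison.n,
        }


def qol_params_for_panel(truths: Sequence[ProcedureTruth],
                         estimates: pd.DataFrame, panel: str):
    """Per-procedure model params with utilities taken from one panel.

    GBD-derived procedures keep their fixed truth utilities; panel-rated
    procedures get the panel's aggregated ``q_mean`` per state.  ``panel``
    may be 'pooled' when ``estimates`` is a pooled table.
    """
    est = estimates[estimates["panel"] == panel] if "panel" in estimates \
        else estimates
    lookup = {(r["procedure_id"], r["state"]): r["q_mean"]
              for _, r in est.iterrows()}
    out = []
    for t in truths:
        if t.gbd_derived:
            out.append(t.params)
        else:
            q_pre = lookup[(t.procedure_id, "pre")]
            q_post = lookup[(t.procedure_id, "post")]
            out.append(t.params.replace_qol(q_pre, q_post))
    return out


def urgency_table(params_list, life_table: LifeTable,
                  delay_months: int = 1,
                  settings: ModelSettings = ModelSettings()) -> pd.DataFrame:
    """DALY/month of delay for every procedure (no PSA)."""
    rows = [{"procedure_id": p.procedure_id,
             "daly_per_month": daly_per_month(p, life_table, delay_months,
                                              settings)}
            for p in params_list]
    return pd.DataFrame(rows)


def run_study_analysis(seed: int,
                       truth_cfg: dict | None = None,
                       original: PanelConfig | None = None,
                       validation: PanelConfig | None = None,
                       life_table: LifeTable | None = None,
                       delay_months: int = 1,
                       settings: ModelSettings = ModelSettings(),
                       ) -> StudyAnalysis:
    """Generate one study and run the full validation battery on it.

    Defaults to the study-emulation preset.  GBD-derived procedures are
    excluded from the panel-comparison statistics (both panels share those
    fixed weights) but included in the rankings.
    """
    truths, scores = generate_study(seed, truth_cfg, original, validation)
    life_table = life_table or generate_life_table()
    gbd_ids = {t.procedure_id for t in truths if t.gbd_derived}

    estimates = elicitation.aggregate_final_round(scores)
    pooled = elicitation.pooled_estimates(scores, ORIGINAL, VALIDATION)

    panel_rated = estimates[~estimates["procedure_id"].isin(gbd_ids)]
    ba = {}
    for state in ("pre", "post"):
        sub = panel_rated[panel_rated["state"] == state]
        wide = sub.pivot(index="procedure_id", columns="panel",
                         values="q_mean")
        ba[state] = validation_stats.bland_altman(wide[ORIGINAL],
                                                  wide[VALIDATION])

    score_tab = validation_stats.scores_to_model_table(
        scores, ORIGINAL, VALIDATION, exclude=gbd_ids)
    score_fit = validation_stats.fit_random_intercept_model(score_tab,
                                                            "score")
    sd_tab = validation_stats.sds_to_model_table(
        scores, ORIGINAL, VALIDATION, exclude=gbd_ids)
    sd_fit = validation_stats.fit_random_intercept_model(sd_tab, "sd")

    params_orig = qol_params_for_panel(truths, estimates, ORIGINAL)
    params_pooled = qol_params_for_panel(truths, pooled, "pooled")
    urg_orig = urgency_table(params_orig, life_table, delay_months, settings)
    urg_pooled = urgency_table(params_pooled, life_table, delay_months,
                               settings)
    comparison = ranking.compare_rankings(urg_orig, urg_pooled)

    return StudyAnalysis(seed=seed, truths=truths, scores=scores,
                         estimates=estimates, pooled=pooled,
                         ba_pre=ba["pre"], ba_post=ba["post"],
                         score_model=score_fit, sd_model=sd_fit,
                         ranking_comparison=comparison)
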