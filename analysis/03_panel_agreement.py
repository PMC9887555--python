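"""Compare the two panels: agreement, overall shift, consensus.

Bland-Altman per state on the per-procedure mean utilities, then the two
random-intercept models — individual utilities (overall panel difference)
and per-cell SDs (consensus difference) — with residual diagnostics.
GBD-derived procedures are excluded: both panels share those fixed weights.
"""

import json
from pathlib import Path

import pandas as pd

from surgprio import elicitation, validation_stats as vs

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scores = pd.read_csv(RESULTS / "data" / "scores.csv")
    truths = pd.read_csv(RESULTS / "data" / "truths.csv")
    gbd = set(truths.loc[truths["gbd_derived"], "procedure_id"])

    estimates = elicitation.aggregate_final_round(scores)
    keep = estimates[~estimates["procedure_id"].isin(gbd)]

    report = {}
    points = []
    for state in ("pre", "post"):
        wide = (keep[keep["state"] == state]
                .pivot(index="procedure_id", columns="panel",
                       values="q_mean"))
        ba = vs.bland_altman(wide["original"], wide["validation"])
        report[f"bland_altman_{state}"] = {
            "bias": ba.bias, "loa_low": ba.loa_low, "loa_high": ba.loa_high,
            "diff_min": ba.diff_min, "diff_max": ba.diff_max,
            "n_pairs": ba.n_pairs}
        points.append(pd.DataFrame({"state": state,
                                    "procedure_id": wide.index,
                                    "mean": ba.means, "diff": ba.diffs}))
        print(f"Bland-Altman {state}: bias {ba.bias:+.3f}, "
              f"LoA ({ba.loa_low:+.3f}, {ba.loa_high:+.3f}), "
              f"n={ba.n_pairs}")
    pd.concat(points).to_csv(RESULTS / "bland_altman_points.csv",
                             index=False)

    for kind, builder in (("score", vs.scores_to_model_table),
                          ("sd", vs.sds_to_model_table)):
        tab = builder(scores, "original", "validation", exclude=gbd)
        fit = vs.fit_random_intercept_model(tab, kind)
        diag = vs.residual_diagnostics(fit)
        coef = fit.coefficients.loc["study"]
        report[f"{kind}_model"] = {
            "coefficients": fit.coefficients.reset_index()
                               .to_dict(orient="records"),
            "var_random": fit.var_random,
            "var_residual": fit.var_residual,
            "random_intercept_sd":
                float(fit.random_intercepts.std(ddof=1)),
            "shapiro_p": diag.shapiro_p,
            "scale_location_slope": diag.scale_location_slope}
        print(f"{kind} model: study coefficient {coef['estimate']:+.4f} "
              f"(95% CI {coef['ci_low']:+.4f} to {coef['ci_high']:+.4f}), "
              f"Shapiro p={diag.shapiro_p:.3f}")

    (RESULTS / "panel_agreement.json").write_text(
        json.dumps(report, indent=2))
    print(f"report -> {RESULTS / 'panel_agreement.json'}")


if __name__ == "__main__":
    main()
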