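"""Aggregate expert VAS scores into quality-of-life estimates.

Per procedure/state: the panel mean of the final-round scores on the utility
scale with its SD and t-based 95% CI, for each panel separately and pooled
across both panels (equal weight per expert).
"""

from pathlib import Path

import pandas as pd

from surgprio import elicitation

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    scores = pd.read_csv(RESULTS / "data" / "scores.csv")
    estimates = elicitation.aggregate_final_round(scores)
    pooled = elicitation.pooled_estimates(scores, "original", "validation")

    estimates.to_csv(RESULTS / "qol_estimates.csv", index=False)
    pooled.to_csv(RESULTS / "qol_pooled.csv", index=False)

    wide = estimates.pivot_table(index="state", columns="panel",
                                 values="q_mean")
    print("mean utility by state and panel:")
    print(wide.round(3).to_string())
    diff = wide["validation"] - wide["original"]
    print(f"validation - original: pre {diff['pre']:+.3f}, "
          f"post {diff['post']:+.3f}")
    print(f"wrote {len(estimates)} panel estimates and {len(pooled)} "
          f"pooled estimates")


if __name__ == "__main__":
    main()
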