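"""Agreement and consensus analyses between the two expert panels.

Three instruments compare the validation panel against the original panel:

* Bland-Altman analysis of the per-procedure mean utilities (bias, 1.96-SD
  limits of agreement, observed extreme differences), run separately for the
  pre- and postoperative state;
* a random-intercept linear model ``response ~ study + state + (1 |
  procedure)`` fitted by REML, once on individual final-round expert
  utilities (the overall panel difference) and once on per-cell score SDs
  (the consensus difference — a lower SD means higher consensus);
* residual diagnostics (normality, homoscedasticity) for those fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "BlandAltmanResult",
    "MixedModelResult",
    "DiagnosticsReport",
    "ConvergenceError",
    "bland_altman",
    "fit_random_intercept_model",
    "residual_diagnostics",
    "scores_to_model_table",
    "sds_to_model_table",
]


class ConvergenceError(RuntimeError):
    """Mixed-model fit failed to converge; no silent fallback is attempted."""


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias and limits of agreement of validation-minus-original differences."""

    bias: float
    loa_low: float
    loa_high: float
    diff_min: float
    diff_max: float
    sd_diff: float
    n_pairs: int
    means: np.ndarray = field(repr=False, default=None)  # plot x-coordinates
    diffs: np.ndarray = field(repr=False, default=None)  # plot y-coordinates


@dataclass(frozen=True)
class MixedModelResult:
    """REML fit of ``response ~ study + state + (1 | procedure)``.

    ``coefficients`` is a frame indexed by fixed-effect name with columns
    estimate, se, ci_low, ci_high (normal-approximation CIs);
    ``random_intercepts`` maps procedure to its predicted intercept deviation.
    """

    coefficients: pd.DataFrame
    random_intercepts: pd.Series
    var_random: float
    var_residual: float
    fit_method: str
    fitted: np.ndarray = field(repr=False, default=None)
    residuals: np.ndarray = field(repr=False, default=None)

    @property
    def study_coefficient(self) -> float:
        return float(self.coefficients.loc["study", "estimate"])


@dataclass(frozen=True)
class DiagnosticsReport:
    """Residual diagnostics for a fitted model."""

    fitted: np.ndarray
    residuals: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray
    shapiro_stat: float
    shapiro_p: float
    scale_location_slope: float
    normality_tested: bool


def bland_altman(original, validation) -> BlandAltmanResult:
    """Bland-Altman agreement of paired per-procedure utilities.

    Differences are validation minus original; the limits of agreement are
    ``bias ± 1.96 * sd(differences)``; the 'maximum and minimum expected
    difference' is reported as the observed extreme differences.
    """
    a = np.asarray(original, dtype=float)
    b = np.asarray(validation, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("original and validation must be 1-D, equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs (SD undefined otherwise)")
    diffs = b - a
    means = 0.5 * (a + b)
    bias = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd,
                             diff_min=float(np.min(diffs)),
                             diff_max=float(np.max(diffs)),
                             sd_diff=sd, n_pairs=int(a.size),
                             means=means, diffs=diffs)


def scores_to_model_table(scores: pd.DataFrame, original_panel: str,
                          validation_panel: str,
                          exclude: set[str] | None = None,
                          final_round: int | None = None) -> pd.DataFrame:
    """Long table of individual final-round utilities for the score model.

    ``exclude`` drops procedures (typically the GBD-derived ones, which are
    identical in both panels and carry no between-panel information).
    """
    if final_round is None:
        final_round = int(scores["round"].max())
    df = scores[scores["round"] == final_round].copy()
    if exclude:
        df = df[~df["procedure_id"].isin(exclude)]
    df = df[df["panel"].isin([original_panel, validation_panel])]
    out = pd.DataFrame({
        "response": df["vas"].to_numpy(float) / 100.0,
        "study": (df["panel"] == validation_panel).astype(int).to_numpy(),
        "state": (df["state"] == "post").astype(int).to_numpy(),
        "procedure": df["procedure_id"].to_numpy(),
    })
    return out.reset_index(drop=True)


def sds_to_model_table(scores: pd.DataFrame, original_panel: str,
                       validation_panel: str,
                       exclude: set[str] | None = None,
                       final_round: int | None = None,
                       scale: str = "utility") -> pd.DataFrame:
    """Per-(study, state, procedure) score SDs for the consensus model.

    ``scale`` is 'utility' (default) or 'vas'; the study coefficient then
    carries the corresponding units.
    """
    if scale not in ("utility", "vas"):
        raise ValueError("scale must be 'utility' or 'vas'")
    if final_round is None:
        final_round = int(scores["round"].max())
    df = scores[scores["round"] == final_round].copy()
    if exclude:
        df = df[~df["procedure_id"].isin(exclude)]
    df = df[df["panel"].isin([original_panel, validation_panel])]
    grouped = (df.groupby(["panel", "procedure_id", "state"])["vas"]
                 .std(ddof=1).reset_index(name="sd_vas"))
    factor = 100.0 if scale == "utility" else 1.0
    return pd.DataFrame({
        "response": grouped["sd_vas"].to_numpy(float) / factor,
        "study": (grouped["panel"] == validation_panel).astype(int)
                  .to_numpy(),
        "state": (grouped["state"] == "post").astype(int).to_numpy(),
        "procedure": grouped["procedure_id"].to_numpy(),
    })


def fit_random_intercept_model(table: pd.DataFrame,
                               response_kind: str = "score",
                               ) -> MixedModelResult:
    """REML fit of ``response ~ study + state`` with a procedure intercept.

    ``table`` must have columns response, study (0 = original,
    1 = validation), state (0 = pre, 1 = post) and procedure.
    ``response_kind`` is a label ('score' or 'sd') recorded with the fit.
    """
    required = {"response", "study", "state", "procedure"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"model table missing columns: {sorted(missing)}")
    if table["procedure"].nunique() < 2:
        raise ValueError("need at least 2 procedures for a random intercept")
    if table["study"].nunique() < 2:
        raise ValueError("both study levels must be present")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("response ~ study + state", data=table,
                            groups=table["procedure"])
        fit = None
        for method in ("bfgs", "powell", "nm", "cg"):
            try:
                cand = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if not cand.converged:
                continue
            if fit is None or cand.llf > fit.llf:
                fit = cand
    if fit is None:
        raise ConvergenceError("random-intercept model did not converge "
                               "with any optimiser")

    names = {"Intercept": "intercept", "study": "study", "state": "state"}
    rows = []
    for raw, name in names.items():
        est = float(fit.params[raw])
        se = float(fit.bse[raw])
        rows.append({"term": name, "estimate": est, "se": se,
                     "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se})
    coefs = pd.DataFrame(rows).set_index("term")
    var_random = float(np.asarray(fit.cov_re)[0, 0])
    try:
        re = pd.Series({g: float(v.iloc[0]) for g, v in
                        fit.random_effects.items()},
                       name="random_intercept")
    except (np.linalg.LinAlgError, ValueError):
        # BLUPs shrink to zero as the intercept variance vanishes
        if var_random > 1e-8:
            raise ConvergenceError(
                "random-effect prediction failed with non-degenerate "
                "intercept variance") from None
        re = pd.Series({g: 0.0 for g in table["procedure"].unique()},
                       name="random_intercept")
    return MixedModelResult(
        coefficients=coefs,
        random_intercepts=re.sort_index(),
        var_random=var_random,
        var_residual=float(fit.scale),
        fit_method=f"REML ({response_kind} model)",
        fitted=np.asarray(fit.fittedvalues, dtype=float),
        residuals=np.asarray(fit.resid, dtype=float),
    )


def residual_diagnostics(fit: MixedModelResult) -> DiagnosticsReport:
    """Normality and homoscedasticity checks on a model's residuals.

    Returns residual-vs-fitted pairs, normal-quantile pairs, the
    Shapiro-Wilk test, and the slope of sqrt(|standardised residual|)
    against fitted values (positive slope = variance grows with the mean).
    """
    resid = np.asarray(fit.residuals, dtype=float)
    fitted = np.asarray(fit.fitted, dtype=float)
    n = resid.size
    order = np.argsort(resid)
    qq_sample = resid[order]
    qq_theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)

    if n >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # zero-range residuals
            sw_stat, sw_p = stats.shapiro(resid)
        tested = True
    else:
        sw_stat, sw_p, tested = np.nan, np.nan, False

    sd = resid.std(ddof=1) if n > 1 else 0.0
    if sd > 0 and np.ptp(fitted) > 0:
        z = np.sqrt(np.abs(resid / sd))
        slope = float(np.polyfit(fitted, z, 1)[0])
    else:
        slope = 0.0
    return DiagnosticsReport(fitted=fitted, residuals=resid,
                             qq_theoretical=qq_theoretical,
                             qq_sample=qq_sample,
                             shapiro_stat=float(sw_stat),
                             shapiro_p=float(sw_p),
                             scale_location_slope=slope,
                             normality_tested=tested)
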