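"""Agreement statistics: Bland-Altman, mixed models, residual diagnostics."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from surgprio.validation_stats import (bland_altman,
                                       fit_random_intercept_model,
                                       residual_diagnostics,
                                       scores_to_model_table,
                                       sds_to_model_table)


class TestBlandAltman:
    def test_perfect_agreement(self):
        res = bland_altman([0.4, 0.6, 0.8], [0.4, 0.6, 0.8])
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_hand_computed_two_pairs(self):
        res = bland_altman([0.5, 0.7], [0.4, 0.5])  # diffs -0.1, -0.2
        assert res.bias == pytest.approx(-0.15)
        assert res.sd_diff == pytest.approx(0.070711, abs=1e-5)
        assert res.loa_low == pytest.approx(-0.2886, abs=1e-4)
        assert res.loa_high == pytest.approx(-0.0114, abs=1e-4)
        assert (res.diff_min, res.diff_max) == \
            (pytest.approx(-0.2), pytest.approx(-0.1))

    def test_swap_negates(self):
        a = np.array([0.5, 0.6, 0.8, 0.9])
        b = np.array([0.45, 0.5, 0.75, 0.7])
        r1, r2 = bland_altman(a, b), bland_altman(b, a)
        assert r2.bias == pytest.approx(-r1.bias)
        assert r2.loa_low == pytest.approx(-r1.loa_high)
        assert r2.loa_high == pytest.approx(-r1.loa_low)
        assert r2.diff_min == pytest.approx(-r1.diff_max)

    def test_single_pair_raises(self):
        with pytest.raises(ValueError):
            bland_altman([0.5], [0.4])


def balanced_table(delta=0.0, state_effect=0.1, noise_sd=0.0, n_expert=4,
                   n_proc=5, seed=0, proc_offsets=None):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_proc):
        base = 0.5 + 0.05 * p + (proc_offsets[p] if proc_offsets else 0.0)
        for study in (0, 1):
            for state in (0, 1):
                for _ in range(n_expert):
                    rows.append({
                        "response": base + delta * study
                        + state_effect * state
                        + rng.normal(0, noise_sd),
                        "study": study, "state": state,
                        "procedure": f"P{p}"})
    return pd.DataFrame(rows)


class TestMixedModel:
    def test_noiseless_recovery(self):
        fit = fit_random_intercept_model(balanced_table(delta=-0.11))
        assert fit.study_coefficient == pytest.approx(-0.11, abs=1e-8)

    def test_balanced_design_equals_difference_of_means(self):
        """Oracle: on a balanced design the REML fixed effect for study is
        exactly the validation-minus-original mean difference."""
        tab = balanced_table(delta=-0.08, noise_sd=0.05, seed=3)
        fit = fit_random_intercept_model(tab)
        oracle = tab.loc[tab.study == 1, "response"].mean() \
            - tab.loc[tab.study == 0, "response"].mean()
        assert fit.study_coefficient == pytest.approx(oracle, abs=1e-8)

    def test_invariant_to_per_procedure_constants(self):
        tab = balanced_table(delta=-0.1, noise_sd=0.03, seed=5)
        fit1 = fit_random_intercept_model(tab)
        shifted = tab.copy()
        offsets = {f"P{p}": 0.2 * p for p in range(5)}
        shifted["response"] += shifted["procedure"].map(offsets)
        fit2 = fit_random_intercept_model(shifted)
        assert fit2.study_coefficient == pytest.approx(
            fit1.study_coefficient, abs=1e-6)

    def test_random_intercepts_track_heterogeneity(self):
        quiet = fit_random_intercept_model(
            balanced_table(noise_sd=0.02, seed=1))
        offsets = list(np.linspace(-0.15, 0.15, 5))
        hetero = fit_random_intercept_model(
            balanced_table(noise_sd=0.02, seed=1, proc_offsets=offsets))
        assert hetero.random_intercepts.std(ddof=1) > \
            quiet.random_intercepts.std(ddof=1)
        assert len(hetero.random_intercepts) == 5

    def test_ci_brackets_estimate(self):
        fit = fit_random_intercept_model(
            balanced_table(delta=-0.1, noise_sd=0.05, seed=2))
        for _, row in fit.coefficients.iterrows():
            assert row["ci_low"] <= row["estimate"] <= row["ci_high"]
        assert fit.var_random >= 0 and fit.var_residual >= 0

    def test_single_study_level_raises(self):
        tab = balanced_table()
        with pytest.raises(ValueError):
            fit_random_intercept_model(tab[tab.study == 0])


class TestModelTables:
    def test_score_table_codes_and_excludes(self):
        scores = pd.DataFrame({
            "panel": ["original", "validation"] * 4,
            "round": [2] * 8,
            "expert_id": [f"e{i}" for i in range(8)],
            "procedure_id": ["A", "A", "A", "A", "B", "B", "B", "B"],
            "state": ["pre", "pre", "post", "post"] * 2,
            "vas": [80, 70, 90, 85, 60, 50, 75, 65],
        })
        tab = scores_to_model_table(scores, "original", "validation",
                                    exclude={"B"})
        assert set(tab["procedure"]) == {"A"}
        assert set(tab["study"]) == {0, 1}
        assert tab["response"].max() <= 1.0

    def test_sd_table_scales(self):
        scores = pd.DataFrame({
            "panel": ["original"] * 4,
            "round": [2] * 4,
            "expert_id": list("abcd"),
            "procedure_id": ["A"] * 4,
            "state": ["pre"] * 4,
            "vas": [60.0, 70.0, 80.0, 90.0],
        })
        sd_vas = np.std([60, 70, 80, 90], ddof=1)
        util = sds_to_model_table(scores, "original", "validation")
        vas = sds_to_model_table(scores, "original", "validation",
                                 scale="vas")
        assert util["response"].iloc[0] == pytest.approx(sd_vas / 100)
        assert vas["response"].iloc[0] == pytest.approx(sd_vas)


class TestDiagnostics:
    @staticmethod
    def fake_fit(fitted, residuals):
        return SimpleNamespace(fitted=np.asarray(fitted, float),
                               residuals=np.asarray(residuals, float))

    def test_zero_residuals_flat_scale_location(self):
        diag = residual_diagnostics(
            self.fake_fit([0.2, 0.4, 0.6, 0.8], [0.0, 0.0, 0.0, 0.0]))
        assert diag.scale_location_slope == 0.0

    def test_gaussian_residuals_pass_shapiro(self):
        """Calibration: standard-normal residuals rarely rejected."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            resid = rng.standard_normal(500)
            diag = residual_diagnostics(
                self.fake_fit(rng.uniform(0, 1, 500), resid))
            hits += diag.shapiro_p > 0.05
        assert hits >= 90

    def test_heteroscedastic_residuals_positive_slope(self):
        rng = np.random.default_rng(0)
        fitted = np.linspace(0.1, 1.0, 400)
        resid = rng.normal(0, fitted)  # SD grows with the mean
        diag = residual_diagnostics(self.fake_fit(fitted, resid))
        assert diag.scale_location_slope > 0

    def test_tiny_sample_flagged(self):
        diag = residual_diagnostics(self.fake_fit([0.1, 0.2], [0.01, -0.01]))
        assert not diag.normality_tested
        assert np.isnan(diag.shapiro_p)
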