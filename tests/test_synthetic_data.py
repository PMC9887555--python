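"""Generator contracts: determinism, panel structure, clipping, life table."""

import numpy as np
import pandas as pd
import pytest

from surgprio.synthetic_data import (LifeTable, PanelConfig, TruthConfig,
                                     generate_life_table,
                                     generate_panel_scores,
                                     generate_procedure_truth,
                                     generate_study,
                                     study_emulation_preset,
                                     truths_to_frame)


class TestProcedureTruth:
    @pytest.mark.parametrize("n_proc,n_gbd", [(43, 9), (1, 0), (5, 5)])
    def test_counts_and_flags(self, n_proc, n_gbd):
        truths = generate_procedure_truth(n_proc, n_gbd, seed=1)
        assert len(truths) == n_proc
        assert sum(t.gbd_derived for t in truths) == n_gbd

    def test_qol_ordering_default(self):
        for t in generate_procedure_truth(30, 0, seed=3):
            assert 0.0 <= t.true_q_pre <= t.true_q_post <= 1.0

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            generate_procedure_truth(0, 0, seed=1)
        with pytest.raises(ValueError):
            generate_procedure_truth(5, 6, seed=1)

    def test_daly_span_order_of_magnitude(self, default_life_table):
        from surgprio.decision_model import daly_per_month
        truths = generate_procedure_truth(43, 9, seed=1)
        vals = np.array([daly_per_month(t.params, default_life_table)
                         for t in truths])
        pos = vals[vals > 0]
        assert pos.max() / pos.min() > 10.0


class TestPanelScores:
    def test_determinism_byte_identical(self, small_truths, quiet_panel,
                                        tmp_path):
        paths = []
        for i in (1, 2):
            df = generate_panel_scores(small_truths, quiet_panel)
            p = tmp_path / f"scores{i}.csv"
            df.to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_zero_noise_reproduces_truth(self, small_truths):
        cfg = PanelConfig(name="p", n_experts=5, expert_sd=1e-12,
                          tau_shift=0.0, round2_shrinkage=0.5, seed=0)
        df = generate_panel_scores(small_truths, cfg)
        truth = {(t.procedure_id, "pre"): t.true_q_pre for t in small_truths}
        truth.update({(t.procedure_id, "post"): t.true_q_post
                      for t in small_truths})
        final = df[df["round"] == 2]
        for _, r in final.iterrows():
            assert r["vas"] == pytest.approx(
                100 * truth[(r["procedure_id"], r["state"])], abs=1e-6)

    def test_full_shrinkage_collapses_to_round1_median(self, small_truths):
        cfg = PanelConfig(name="p", n_experts=7, expert_sd=0.1,
                          round2_shrinkage=1.0, round2_noise_sd=0.0, seed=5)
        df = generate_panel_scores(small_truths, cfg)
        non_gbd = {t.procedure_id for t in small_truths if not t.gbd_derived}
        for (pid, state), grp in df[df["procedure_id"].isin(non_gbd)].groupby(
                ["procedure_id", "state"]):
            r1 = grp[grp["round"] == 1]["vas"]
            r2 = grp[grp["round"] == 2]["vas"]
            assert np.allclose(r2, np.median(r1))

    def test_gbd_zero_dispersion_and_panel_identity(self, small_truths):
        _, orig, val = study_emulation_preset()
        a = generate_panel_scores(small_truths, orig)
        b = generate_panel_scores(small_truths, val)
        gbd = {t.procedure_id for t in small_truths if t.gbd_derived}
        for df in (a, b):
            sub = df[df["procedure_id"].isin(gbd)]
            assert (sub.groupby(["procedure_id", "state"])["vas"]
                    .std(ddof=1) == 0).all()
        ma = a[a["procedure_id"].isin(gbd)].groupby(
            ["procedure_id", "state"])["vas"].mean()
        mb = b[b["procedure_id"].isin(gbd)].groupby(
            ["procedure_id", "state"])["vas"].mean()
        pd.testing.assert_series_equal(ma, mb)

    def test_scores_clipped(self, small_truths):
        cfg = PanelConfig(name="p", n_experts=20, expert_sd=0.5, seed=2)
        df = generate_panel_scores(small_truths, cfg)
        assert df["vas"].between(0, 100).all()

    def test_empty_truths_raise(self, quiet_panel):
        with pytest.raises(ValueError):
            generate_panel_scores([], quiet_panel)

    def test_final_means_unbiased(self):
        """Mean error of final-round panel means stays below expert_sd/10."""
        truths = generate_procedure_truth(4, 0, seed=3)
        truth = {(t.procedure_id, "pre"): t.true_q_pre for t in truths}
        truth.update({(t.procedure_id, "post"): t.true_q_post
                      for t in truths})
        errs = []
        for seed in range(100):
            cfg = PanelConfig(name="p", n_experts=10, expert_sd=0.08,
                              round2_shrinkage=0.5, seed=seed)
            df = generate_panel_scores(truths, cfg)
            final = df[df["round"] == 2]
            means = final.groupby(["procedure_id", "state"])["vas"].mean()
            errs.extend(means[key] / 100 - truth[key]
                        for key in means.index)
        assert abs(np.mean(errs)) < 0.08 / 10


class TestPreset:
    def test_panel_sizes(self):
        _, orig, val = study_emulation_preset()
        assert (orig.n_experts, val.n_experts) == (18, 15)

    def test_encoded_effects(self):
        _, orig, val = study_emulation_preset()
        assert val.expert_sd - orig.expert_sd == pytest.approx(0.06)
        assert (val.shift_pre + val.shift_post) / 2 == pytest.approx(-0.11)

    def test_realized_overall_difference(self):
        """Validation-minus-original final-round mean ~ -0.11 utility."""
        diffs = []
        for seed in range(1, 6):
            truths, scores = generate_study(seed)
            gbd = {t.procedure_id for t in truths if t.gbd_derived}
            fin = scores[(scores["round"] == 2)
                         & ~scores["procedure_id"].isin(gbd)]
            m = fin.groupby("panel")["vas"].mean() / 100
            diffs.append(m["validation"] - m["original"])
        assert np.mean(diffs) == pytest.approx(-0.11, abs=0.02)


class TestLifeTable:
    def test_closed_form(self):
        lt = generate_life_table(a=1e-4, b=0.09, max_age=100)
        expected = 1 - np.exp(-1e-4 * np.exp(0.09 * 60) / 12)
        assert lt.monthly_p(60) == pytest.approx(expected, rel=1e-12)

    def test_zero_hazard_limit(self):
        lt = generate_life_table(a=1e-300, b=0.0)
        assert lt.monthly_p(50) == pytest.approx(0.0, abs=1e-290)

    def test_absorbing_cap(self):
        lt = generate_life_table(max_age=100)
        assert lt.monthly_p(100) == 1.0
        assert lt.monthly_p(150) == 1.0

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            generate_life_table(a=0.0)
        with pytest.raises(ValueError):
            generate_life_table(max_age=130)

    def test_roundtrip(self, default_life_table):
        df = default_life_table.to_frame()
        lt = LifeTable.from_frame(df)
        assert np.array_equal(lt.p_month, default_life_table.p_month)


def test_study_determinism():
    t1, s1 = generate_study(42)
    t2, s2 = generate_study(42)
    assert truths_to_frame(t1).equals(truths_to_frame(t2))
    pd.testing.assert_frame_equal(s1, s2)
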