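"""Synthetic study generator: procedure truths, life tables, expert panels.

The raw expert scores behind the two-hospital elicitation studies are not
public, so every analysis in this package runs against synthetic data with the
same statistical structure: two expert panels score the pre- and postoperative
health state of each panel-rated procedure on a 0-100 VAS over two Delphi
rounds, while a minority of procedures carry fixed GBD-derived weights that
are identical in both panels.  The ``study_emulation_preset`` encodes the
observed between-panel effects (a systematic downward shift of the validation
panel, inflated expert dispersion, and procedure-level heterogeneity of the
shift) as generative parameters, so that the validation battery can be run as
a parameter-recovery exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ProcedureParams",
    "ProcedureTruth",
    "TruthConfig",
    "PanelConfig",
    "LifeTable",
    "generate_procedure_truth",
    "generate_panel_scores",
    "generate_life_table",
    "study_emulation_preset",
    "truths_to_frame",
    "truths_from_frame",
]

STATES = ("pre", "post")


@dataclass(frozen=True)
class ProcedureParams:
    """Decision-model inputs for one procedure (an 'average patient').

    ``q_pre``/``q_post`` are utilities in [0, 1]; ``p_wait_death`` is the
    monthly probability of disease-related death while waiting;
    ``p_periop_death`` is the one-off probability of death at surgery;
    ``s_long`` is the long-term post-surgery survival fraction over
    ``horizon_years`` (converted internally to a constant excess hazard).
    """

    procedure_id: str
    age0: float
    q_pre: float
    q_post: float
    p_wait_death: float
    p_periop_death: float
    s_long: float
    horizon_years: float = 5.0

    def __post_init__(self) -> None:
        for name in ("q_pre", "q_post", "p_wait_death", "p_periop_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.s_long <= 1.0:
            raise ValueError(f"s_long={self.s_long} outside (0, 1]")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be positive")

    def replace_qol(self, q_pre: float, q_post: float) -> "ProcedureParams":
        """Same procedure with different utility inputs."""
        d = asdict(self)
        d.update(q_pre=q_pre, q_post=q_post)
        return ProcedureParams(**d)


@dataclass(frozen=True)
class ProcedureTruth:
    """Ground truth for one synthetic procedure.

    ``gbd_derived`` marks procedures whose utilities come from fixed GBD
    disability weights rather than panel elicitation; both panels receive the
    identical value for them.
    """

    procedure_id: str
    true_q_pre: float
    true_q_post: float
    gbd_derived: bool
    params: ProcedureParams


@dataclass(frozen=True)
class TruthConfig:
    """Generation ranges for procedure truths.

    Defaults emulate a mix of semi-elective oncological, cardiothoracic and
    vascular procedures: substantial preoperative health loss, a clear but
    partial postoperative recovery, and survival parameters wide enough that
    urgency (DALY/month of delay) spans more than an order of magnitude.
    """

    q_pre_range: tuple[float, float] = (0.45, 0.80)
    q_gain_range: tuple[float, float] = (0.08, 0.20)
    q_post_cap: float = 0.92
    age_range: tuple[float, float] = (50.0, 75.0)
    p_wait_log10_range: tuple[float, float] = (-3.0, float(np.log10(0.05)))
    p_periop_range: tuple[float, float] = (0.005, 0.05)
    s_long_range: tuple[float, float] = (0.30, 0.95)
    horizon_years: float = 5.0
    enforce_order: bool = True  # true_q_pre <= true_q_post

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


@dataclass(frozen=True)
class PanelConfig:
    """Generative description of one expert panel.

    ``shift_pre``/``shift_post`` are panel-level mean offsets on the utility
    scale, ``expert_sd`` the between-expert dispersion of *final-round* scores,
    ``tau_shift`` the SD of a procedure-level random component of the shift,
    and ``round2_shrinkage`` the fraction by which round-2 scores are pulled
    toward the round-1 panel median.
    """

    name: str
    n_experts: int
    shift_pre: float = 0.0
    shift_post: float = 0.0
    expert_sd: float = 0.10
    tau_shift: float = 0.0
    round2_shrinkage: float = 0.5
    seed: int = 0
    round2_noise_sd: float | None = None  # override for degenerate setups

    def __post_init__(self) -> None:
        if self.n_experts < 2:
            raise ValueError("n_experts must be >= 2")
        if self.expert_sd < 0:
            raise ValueError("expert_sd must be >= 0")
        if not 0.0 <= self.round2_shrinkage <= 1.0:
            raise ValueError("round2_shrinkage must be in [0, 1]")
        if self.tau_shift < 0:
            raise ValueError("tau_shift must be >= 0")

    def shift(self, state: str) -> float:
        return self.shift_pre if state == "pre" else self.shift_post

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=False)


class LifeTable:
    """Monthly background death probability per integer year of age.

    Built from a Gompertz hazard ``h(age) = a * exp(b * age)`` per year; the
    monthly probability is ``1 - exp(-h/12)``, capped at 1 at ``max_age`` so
    the cohort model cannot outlive the table.
    """

    def __init__(self, ages: np.ndarray, p_month: np.ndarray) -> None:
        ages = np.asarray(ages, dtype=float)
        p_month = np.asarray(p_month, dtype=float)
        if ages.shape != p_month.shape or ages.ndim != 1:
            raise ValueError("ages and p_month must be 1-D and equal length")
        if np.any((p_month < 0) | (p_month > 1)):
            raise ValueError("monthly probabilities must lie in [0, 1]")
        self.ages = ages
        self.p_month = p_month

    def monthly_p(self, age: float) -> float:
        """Monthly background death probability at (fractional) age."""
        idx = min(int(np.floor(age)) - int(self.ages[0]), len(self.ages) - 1)
        idx = max(idx, 0)
        return float(self.p_month[idx])

    def monthly_p_vector(self, ages: np.ndarray) -> np.ndarray:
        idx = np.clip(np.floor(ages).astype(int) - int(self.ages[0]),
                      0, len(self.ages) - 1)
        return self.p_month[idx]

    @property
    def max_age(self) -> float:
        return float(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages.astype(int),
                             "p_month": self.p_month})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        return cls(df["age"].to_numpy(float), df["p_month"].to_numpy(float))


def generate_life_table(a: float = 1e-4, b: float = 0.092,
                        max_age: int = 100) -> LifeTable:
    """Gompertz life table with baseline hazard ``a``/yr and slope ``b``/yr."""
    if a <= 0:
        raise ValueError("baseline hazard a must be > 0")
    if b < 0:
        raise ValueError("Gompertz slope b must be >= 0")
    if max_age > 120:
        raise ValueError("max_age must be <= 120")
    ages = np.arange(0, max_age + 1, dtype=float)
    p = 1.0 - np.exp(-a * np.exp(b * ages) / 12.0)
    p[-1] = 1.0  # absorbing cap at the end of the table
    return LifeTable(ages, p)


def generate_procedure_truth(n_proc: int, n_gbd: int, seed: int,
                             config: TruthConfig | None = None,
                             ) -> list[ProcedureTruth]:
    """Draw ``n_proc`` procedure truths, ``n_gbd`` of them GBD-derived."""
    if n_proc < 1:
        raise ValueError("n_proc must be >= 1")
    if not 0 <= n_gbd <= n_proc:
        raise ValueError("n_gbd must satisfy 0 <= n_gbd <= n_proc")
    cfg = config or TruthConfig()
    rng = np.random.default_rng(seed)

    gbd_flags = np.zeros(n_proc, dtype=bool)
    gbd_flags[rng.choice(n_proc, size=n_gbd, replace=False)] = True

    truths: list[ProcedureTruth] = []
    width = max(2, len(str(n_proc)))
    for i in range(n_proc):
        q_pre = rng.uniform(*cfg.q_pre_range)
        gain = rng.uniform(*cfg.q_gain_range)
        q_post = min(q_pre + gain, cfg.q_post_cap)
        if not cfg.enforce_order:
            if rng.random() < 0.5:
                q_pre, q_post = q_post, q_pre
        pid = f"P{i + 1:0{width}d}"
        params = ProcedureParams(
            procedure_id=pid,
            age0=float(np.floor(rng.uniform(*cfg.age_range))),
            q_pre=q_pre,
            q_post=q_post,
            p_wait_death=float(10.0 ** rng.uniform(*cfg.p_wait_log10_range)),
            p_periop_death=float(rng.uniform(*cfg.p_periop_range)),
            s_long=float(rng.uniform(*cfg.s_long_range)),
            horizon_years=cfg.horizon_years,
        )
        truths.append(ProcedureTruth(pid, q_pre, q_post, bool(gbd_flags[i]),
                                     params))
    return truths


def _final_round_noise_sds(cfg: PanelConfig) -> tuple[float, float]:
    # Round-1 dispersion is inflated so that after shrinking toward the
    # round-1 median the final-round dispersion comes out at expert_sd.
    gamma = cfg.round2_shrinkage
    sd1 = cfg.expert_sd / (1.0 - gamma / 2.0)
    if cfg.round2_noise_sd is not None:
        sd2 = cfg.round2_noise_sd
    else:
        sd2 = float(np.sqrt(max(cfg.expert_sd ** 2
                                - (1.0 - gamma) ** 2 * sd1 ** 2, 0.0)))
    return sd1, sd2


def generate_panel_scores(truths: Sequence[ProcedureTruth],
                          cfg: PanelConfig) -> pd.DataFrame:
    """Two-round VAS scores for one panel over all procedures.

    Panel-rated procedures: round-1 scores are Gaussian around
    ``truth + shift + delta_proc`` (utility scale, then x100, clipped to
    [0, 100]); round-2 scores are pulled toward the round-1 panel median by
    ``round2_shrinkage`` plus residual noise.  GBD-derived procedures emit the
    fixed weight for every expert in both rounds (zero dispersion).
    """
    if len(truths) == 0:
        raise ValueError("truths must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    sd1, sd2 = _final_round_noise_sds(cfg)
    gamma = cfg.round2_shrinkage
    experts = [f"{cfg.name}_e{j + 1:02d}" for j in range(cfg.n_experts)]

    rows: list[dict] = []
    for truth in truths:
        delta = rng.normal(0.0, cfg.tau_shift) if cfg.tau_shift > 0 else 0.0
        for state in STATES:
            q_true = truth.true_q_pre if state == "pre" else truth.true_q_post
            if truth.gbd_derived:
                vas_fixed = float(np.clip(100.0 * q_true, 0.0, 100.0))
                for rnd in (1, 2):
                    rows += [{"panel": cfg.name, "round": rnd,
                              "expert_id": e,
                              "procedure_id": truth.procedure_id,
                              "state": state, "vas": vas_fixed}
                             for e in experts]
                continue
            target = q_true + cfg.shift(state) + delta
            r1 = 100.0 * (target + rng.normal(0.0, sd1, cfg.n_experts))
            r1 = np.clip(r1, 0.0, 100.0)
            med1 = float(np.median(r1))
            r2 = r1 + gamma * (med1 - r1)
            r2 = r2 + 100.0 * rng.normal(0.0, sd2, cfg.n_experts)
            r2 = np.clip(r2, 0.0, 100.0)
            for rnd, vals in ((1, r1), (2, r2)):
                rows += [{"panel": cfg.name, "round": rnd, "expert_id": e,
                          "procedure_id": truth.procedure_id,
                          "state": state, "vas": float(v)}
                         for e, v in zip(experts, vals)]
    df = pd.DataFrame(rows)
    df["round"] = df["round"].astype(int)
    return df


def study_emulation_preset() -> tuple[dict, PanelConfig, PanelConfig]:
    """Generative configuration emulating the two-hospital study.

    43 procedures of which 9 carry fixed GBD weights; an 18-expert original
    panel and a 15-expert validation panel whose scores sit systematically
    lower (-0.14 preoperative, -0.08 postoperative on the utility scale) with
    inflated dispersion (0.16 vs 0.10) and procedure-level shift heterogeneity
    of SD 0.06.
    """
    truth_cfg = {"n_proc": 43, "n_gbd": 9, "config": TruthConfig()}
    original = PanelConfig(name="original", n_experts=18,
                           shift_pre=0.0, shift_post=0.0,
                           expert_sd=0.10, tau_shift=0.0,
                           round2_shrinkage=0.5)
    validation = PanelConfig(name="validation", n_experts=15,
                             shift_pre=-0.14, shift_post=-0.08,
                             expert_sd=0.16, tau_shift=0.06,
                             round2_shrinkage=0.5)
    return truth_cfg, original, validation


def generate_study(seed: int, truth_cfg: dict | None = None,
                   original: PanelConfig | None = None,
                   validation: PanelConfig | None = None,
                   ) -> tuple[list[ProcedureTruth], pd.DataFrame]:
    """Full two-panel study: truths plus a combined score table.

    Panel seeds are derived from ``seed`` so one integer reproduces the whole
    study; explicit ``PanelConfig.seed`` values are overridden.
    """
    if truth_cfg is None or original is None or validation is None:
        p_truth, p_orig, p_val = study_emulation_preset()
        truth_cfg = truth_cfg or p_truth
        original = original or p_orig
        validation = validation or p_val
    ss = np.random.SeedSequence(seed).spawn(3)
    truth_seed = int(ss[0].generate_state(1)[0] % (2 ** 31))
    truths = generate_procedure_truth(truth_cfg["n_proc"], truth_cfg["n_gbd"],
                                      truth_seed,
                                      truth_cfg.get("config"))
    frames = []
    for cfg, sub in ((original, ss[1]), (validation, ss[2])):
        panel_seed = int(sub.generate_state(1)[0] % (2 ** 31))
        cfg = PanelConfig(**{**asdict(cfg), "seed": panel_seed})
        frames.append(generate_panel_scores(truths, cfg))
    return truths, pd.concat(frames, ignore_index=True)


def truths_to_frame(truths: Sequence[ProcedureTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        row = {"procedure_id": t.procedure_id, "true_q_pre": t.true_q_pre,
               "true_q_post": t.true_q_post, "gbd_derived": t.gbd_derived}
        row.update({k: v for k, v in asdict(t.params).items()
                    if k != "procedure_id"})
        rows.append(row)
    return pd.DataFrame(rows)


def truths_from_frame(df: pd.DataFrame) -> list[ProcedureTruth]:
    out = []
    for _, r in df.iterrows():
        params = ProcedureParams(
            procedure_id=r["procedure_id"], age0=float(r["age0"]),
            q_pre=float(r["q_pre"]), q_post=float(r["q_post"]),
            p_wait_death=float(r["p_wait_death"]),
            p_periop_death=float(r["p_periop_death"]),
            s_long=float(r["s_long"]),
            horizon_years=float(r["horizon_years"]),
        )
        out.append(ProcedureTruth(r["procedure_id"], float(r["true_q_pre"]),
                                  float(r["true_q_post"]),
                                  bool(r["gbd_derived"]), params))
    return out
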