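"""Cohort state-transition model for health loss per month of surgical delay.

Three states: Preop (waiting for surgery), Postop (operated) and Dead.  The
cohort starts in Preop at the decision age; during each month of delay it
faces disease-related waiting mortality on top of background mortality.  At
the surgery cycle a one-off perioperative death probability applies and the
survivors move to Postop, where background mortality is augmented by a
constant excess hazard calibrated to the long-term post-surgery survival
fraction.  QALYs accrue each monthly cycle at the state utility (cycle-start
occupancy); the urgency measure is

    DALY/month = (QALY(no delay) - QALY(delay d months)) / d

i.e. the expected QALY loss per month that surgery is postponed.  Parameter
uncertainty is propagated by probabilistic sensitivity analysis with
moment-matched Beta distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_data import LifeTable, ProcedureParams

__all__ = [
    "ModelSettings",
    "CohortTrace",
    "UrgencyResult",
    "survival_to_monthly_hazard",
    "run_cohort",
    "daly_per_month",
    "psa",
]


@dataclass(frozen=True)
class ModelSettings:
    """Numerical settings for the cohort simulation.

    The horizon is a hard cap at ``max_age`` (life-table support); the run
    stops earlier once the living fraction drops below ``min_alive``.
    ``max_cycles`` truncates the horizon explicitly (mainly for toy cases).
    Discounting and half-cycle correction default off.
    """

    max_age: float = 100.0
    min_alive: float = 1e-9
    max_cycles: int | None = None
    discount_rate_annual: float = 0.0
    half_cycle_correction: bool = False


@dataclass
class CohortTrace:
    """Per-cycle state occupancy (cycle-start) and accumulated QALYs."""

    cycles: np.ndarray
    preop: np.ndarray
    postop: np.ndarray
    dead: np.ndarray
    qaly_total: float

    @property
    def occupancy(self) -> np.ndarray:
        return np.column_stack([self.preop, self.postop, self.dead])


@dataclass(frozen=True)
class UrgencyResult:
    """DALY/month of delay for one procedure, with optional PSA interval."""

    procedure_id: str
    daly_per_month: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_samples: int = 0
    seed: int | None = None


def survival_to_monthly_hazard(s: float, years: float) -> float:
    """Constant monthly excess hazard implying survival ``s`` over ``years``."""
    if s <= 0:
        raise ValueError("survival fraction must be > 0")
    if s > 1:
        raise ValueError("survival fraction must be <= 1")
    if years <= 0:
        raise ValueError("years must be > 0")
    return -np.log(s) / (12.0 * years)


def _n_cycles(params: ProcedureParams, settings: ModelSettings) -> int:
    n = int(np.ceil((settings.max_age - params.age0) * 12.0))
    if settings.max_cycles is not None:
        n = min(n, settings.max_cycles)
    return max(n, 0)


def run_cohort(params: ProcedureParams, life_table: LifeTable,
               delay_months: int = 0,
               settings: ModelSettings = ModelSettings()) -> CohortTrace:
    """Simulate the cohort with surgery delayed by ``delay_months`` cycles.

    Waiting deaths combine disease and background mortality as independent
    competing risks on the probability scale; postoperative mortality adds
    the excess hazard to the background hazard.
    """
    if not (isinstance(delay_months, (int, np.integer))
            and delay_months >= 0):
        raise ValueError("delay_months must be a non-negative integer")
    d = int(delay_months)
    T = _n_cycles(params, settings)
    ages = params.age0 + np.arange(T) / 12.0
    p_bg = life_table.monthly_p_vector(ages)
    with np.errstate(divide="ignore"):
        h_bg = -np.log1p(-np.clip(p_bg, 0.0, 1.0 - 1e-300))
    h_ex = survival_to_monthly_hazard(params.s_long, params.horizon_years)

    p_die_pre = 1.0 - (1.0 - params.p_wait_death) * (1.0 - p_bg)
    p_die_post = 1.0 - np.exp(-(h_bg + h_ex))

    preop = np.zeros(T)
    postop = np.zeros(T)
    alive = 1.0
    for t in range(T):
        if t == d:
            alive *= (1.0 - params.p_periop_death)  # surgery at cycle start
        if t < d:
            preop[t] = alive
            alive *= (1.0 - p_die_pre[t])
        else:
            postop[t] = alive
            alive *= (1.0 - p_die_post[t])
        if alive < settings.min_alive:
            T = t + 1
            preop, postop = preop[:T], postop[:T]
            break
    dead = 1.0 - preop - postop

    occ_q = preop * params.q_pre + postop * params.q_post
    if settings.half_cycle_correction:
        occ_end = np.empty_like(occ_q)
        occ_end[:-1] = occ_q[1:]
        occ_end[-1] = occ_q[-1]
        occ_q = 0.5 * (occ_q + occ_end)
    if settings.discount_rate_annual > 0.0:
        occ_q = occ_q / (1.0 + settings.discount_rate_annual) ** (
            np.arange(len(occ_q)) / 12.0)
    qaly = float(np.sum(occ_q) / 12.0)
    return CohortTrace(np.arange(T), preop, postop, dead, qaly)


def daly_per_month(params: ProcedureParams, life_table: LifeTable,
                   delay_months: int = 1,
                   settings: ModelSettings = ModelSettings()) -> float:
    """Expected QALY loss per month of delay (delay d vs immediate surgery)."""
    if not (isinstance(delay_months, (int, np.integer)) and delay_months >= 1):
        raise ValueError("delay_months must be an integer >= 1")
    q0 = run_cohort(params, life_table, 0, settings).qaly_total
    qd = run_cohort(params, life_table, int(delay_months), settings).qaly_total
    return (q0 - qd) / float(delay_months)


def _beta_moment_match(mean: float, se: float, name: str) -> tuple[float,
                                                                   float]:
    if se < 0:
        raise ValueError(f"{name}: SE must be >= 0")
    var = se ** 2
    if var >= mean * (1.0 - mean):
        raise ValueError(
            f"{name}: SE {se} too large for mean {mean} "
            "(Beta moment matching infeasible)")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def psa(params: ProcedureParams, life_table: LifeTable,
        uncertainty: dict[str, float], n_samples: int = 1000,
        seed: int = 0, delay_months: int = 1,
        settings: ModelSettings = ModelSettings()) -> UrgencyResult:
    """Probabilistic sensitivity analysis of DALY/month.

    ``uncertainty`` maps parameter names (q_pre, q_post, p_wait_death,
    p_periop_death, s_long) to standard errors; each uncertain parameter is
    drawn from a Beta distribution matched to (mean, SE) by the method of
    moments (degenerate at SE = 0).  The point estimate is computed at the
    mean parameters; the interval is the 2.5-97.5 percentile range of the
    per-draw DALY/month values.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    allowed = {"q_pre", "q_post", "p_wait_death", "p_periop_death", "s_long"}
    unknown = set(uncertainty) - allowed
    if unknown:
        raise ValueError(f"unknown uncertain parameters: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    point = daly_per_month(params, life_table, delay_months, settings)

    draws = {}
    for name in sorted(allowed):
        mean = getattr(params, name)
        se = float(uncertainty.get(name, 0.0))
        if se == 0.0:
            draws[name] = np.full(n_samples, mean)
        else:
            a, b = _beta_moment_match(mean, se, name)
            draws[name] = rng.beta(a, b, n_samples)
    # s_long = 0 is outside the parameter space (infinite hazard)
    draws["s_long"] = np.clip(draws["s_long"], 1e-12, 1.0)

    values = np.empty(n_samples)
    base = {f: getattr(params, f) for f in (
        "procedure_id", "age0", "horizon_years")}
    for i in range(n_samples):
        p_i = ProcedureParams(**base,
                              **{k: float(draws[k][i]) for k in sorted(allowed)})
        values[i] = daly_per_month(p_i, life_table, delay_months, settings)
    lo, hi = np.percentile(values, [2.5, 97.5])
    return UrgencyResult(params.procedure_id, point, float(lo), float(hi),
                         n_samples, seed)
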