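# Methods

## Decision model

A monthly-cycle cohort state-transition model with states Preop, Postop,
Dead.  Per procedure the inputs are: age at decision `age0`; utilities
`q_pre`, `q_post` in [0, 1]; monthly disease-related waiting mortality
`p_wait_death`; one-off perioperative mortality `p_periop_death`; long-term
post-surgery survival fraction `s_long` over `horizon_years` (default 5),
converted to a constant monthly excess hazard `−ln(s_long)/(12·horizon)`;
and a background life table (monthly death probability per integer age,
Gompertz by default: `a·exp(b·age)` per year with `a = 1e−4`,
`b = 0.092` — a plausible adult mortality curve with ≈2.5 %/yr hazard at
age 60).

Transitions: while waiting (cycles `t < d`), death probability per cycle is
`1 − (1 − p_wait)(1 − p_bg)` (independent competing risks on the
probability scale); at cycle `d` the surviving cohort undergoes surgery and
loses fraction `p_periop_death`; after surgery, the monthly death
probability is `1 − exp(−(h_bg + h_excess))` (hazards add — the standard
competing-hazard approximation at monthly resolution).  QALYs accrue at
cycle-start occupancy (`q/12` per cycle); the urgency measure is
`Δ = (QALY(0) − QALY(d))/d`, default `d = 1` month.  The simulation stops
at age 100 (life-table support) or when the living fraction falls below
1e−9.  Discounting and half-cycle correction exist as settings and default
off.  Note `Δ` can be slightly negative: when `q_post − q_pre` is small,
postponing an operation that carries upfront perioperative mortality buys
a little utility — that is genuine model behaviour, not an error.

The per-procedure parameter set is intentionally isolated in one type
(`ProcedureParams`) so the mapping to any richer transition structure (e.g.
a separate disease-progression pathway) can be swapped without touching the
analyses.

Parameter uncertainty is propagated by PSA: each uncertain parameter gets a
Beta distribution matched to (mean, SE) by method of moments (degenerate at
SE = 0, error if the SE is infeasible for the mean), `n_samples` draws
(default 1000), a 2.5–97.5 percentile interval, and a point estimate at the
mean parameters.  All draws flow from one seed.

## Elicitation

Utilities map linearly from the calibrated VAS (`q = v/100`) and from GBD
disability weights (`q = 1 − dw`).  Round feedback is the median and IQR
(type-7 linear-interpolation quantiles — the default of the common
statistical environments; no convention was fixed by the study design).
The final estimate of a procedure/state is the mean of final-round
individual scores; its CI uses the t distribution (panels of 15–18 make
the normal approximation materially too narrow) and is truncated to
[0, 1].  Pooling two panels concatenates individual expert scores (equal
weight per expert); pooling by averaging panel means is a deliberate
non-default alternative.

## Synthetic-study generator

What it emulates: 43 procedures, 9 of which carry fixed GBD-derived weights
identical in both panels (they are excluded from panel-comparison
statistics — they carry no between-panel information — and included in
rankings); an 18-expert original panel and a 15-expert validation panel;
two Delphi rounds where round 2 shrinks toward the round-1 panel median by
γ = 0.5.

Expert noise is Gaussian on the VAS scale, clipped to [0, 100].  The preset
specifies the *final-round* dispersion (0.10 original, 0.16 validation, on
the utility scale); round-1 dispersion is inflated to
`expert_sd/(1 − γ/2)` and the round-2 residual noise is set to
`sqrt(expert_sd² − (1−γ)²·sd1²)` so the final dispersion comes out at the
specified value (the small variance contribution of the shared round-1
median is neglected).  The validation panel's shift is −0.14 (pre) and
−0.08 (post) plus a procedure-level random component with SD
τ = 0.06, chosen so the SD of paired panel differences ≈ 0.075, i.e. a
limits-of-agreement half-width of ≈ 1.96 × 0.075 ≈ 0.145.

Truth ranges: preoperative utility U(0.45, 0.80), postoperative gain
U(0.08, 0.20) capped at 0.92; age U(50, 75); monthly waiting mortality
log-uniform over (0.001, 0.05); perioperative mortality U(0.005, 0.05);
5-year survival U(0.30, 0.95).  These are clinically plausible for
semi-elective oncological/cardiovascular surgery, give DALY/month spanning
more than an order of magnitude (so the ranking is informative), and keep
the clipping bias negligible: with the validation panel's shifted means and
inflated round-1 dispersion, scores near the VAS floor/ceiling would
otherwise be clipped asymmetrically and bias the realized panel difference.
Residual clipping moves the realized 10-seed mean effects by ≲ 0.008
utility, within the Monte-Carlo noise of the recovery checks.

What it does **not** emulate: expert dropout between rounds, free-text
argument exchange, correlation of one expert's errors across procedures,
non-Gaussian (e.g. end-digit-preference) scoring, and any systematic
difference in *survival* parameters between hospitals.  Passing recovery
tests therefore shows the statistical pipeline is correct and the ranking
is robust to the modelled kind of panel disagreement — not that real
panels behave this way.

## Validation statistics

Bland–Altman: differences are validation − original per procedure/state on
panel-mean utilities; bias = mean difference; limits of agreement
bias ± 1.96·SD; the "maximum/minimum expected difference" is reported as
the observed extreme differences (a prediction-interval reading of that
phrase is possible; the observed extremes are the more conservative,
assumption-free choice).

Mixed models: `response ~ study + state + (1 | procedure)` by REML via
statsmodels MixedLM, study coded original = 0 / validation = 1, state
pre = 0 / post = 1.  The score model uses individual final-round expert
utilities (not panel means; a panel-mean variant is a config option).  The
SD model uses per-(study, state, procedure) sample SDs, by default on the
utility scale (a VAS-scale option exists).  Several optimisers are tried
(bfgs, powell, nm, cg) and the converged fit with the best REML likelihood
is kept; if none converges the fit fails loudly.  When the random-intercept
variance is estimated at zero, BLUPs are reported as exact zeros (their
limit) rather than failing on the singular covariance.  Fixed-effect CIs
are normal-approximation (±1.96·SE).  Diagnostics: Shapiro–Wilk on
residuals, normal-quantile pairs, and the slope of √|standardised
residual| on fitted values as the homoscedasticity indicator.

Ranking: rank 1 = most urgent (largest DALY/month); ties take average
ranks (and are ordered by procedure id for display determinism);
Spearman's ρ is the Pearson correlation of the rank vectors.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; panel and truth seeds are
derived from one study seed via seed sequences, so identical configurations
give byte-identical CSVs.  The recovery analyses average over ten
independent study replicates (per-seed SD of the score-model study
coefficient is ≈ 0.015, so 10-seed means are stable to ≈ 0.005); a full
10-replicate battery runs in well under a minute on one core.  PSA examples
use 300–1000 draws.

## Known limitations

* The three-state structure folds all waiting risk into mortality; disease
  progression to inoperability or to a worse operable state is not
  modelled.
* Utilities enter as point estimates per state; no age- or time-dependence
  of `q_pre`/`q_post`.
* The Gompertz life table is a single-sex, single-cohort abstraction; use
  a national table for applied work (any CSV with `age, p_month` loads).
* The SD-model response (sample SDs) is heteroscedastic by construction at
  small panel sizes; the REML fit treats it as Gaussian, as in the
  standard analysis this package implements.
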