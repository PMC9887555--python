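# surgprio

Urgency ranking of semi-elective surgery when operating-room capacity is
scarce, driven by expert-elicited quality of life and a cohort
state-transition model — plus the validation battery that asks whether the
ranking survives replacing one hospital's quality-of-life estimates with
another's.

## The problem

When surgical capacity collapses (as during the Covid-19 waves), hospitals
must decide which semi-elective procedures — cancer resections, valve
replacements, transplantations — to do first.  A utilitarian answer is to
rank procedures by the expected health lost per month that surgery is
postponed:

```
Δ = (QALY(no delay) − QALY(delay of d months)) / d     [DALY per month]
```

QALYs come from a monthly-cycle Markov cohort model with three states,
**Preop → Postop → Dead**: while waiting, an average patient faces
disease-specific mortality `p_wait` on top of background (life-table)
mortality and lives at utility `q_pre`; at surgery a one-off perioperative
mortality `p_periop` applies; afterwards the patient lives at utility
`q_post` under background mortality plus a constant excess hazard calibrated
to the long-term survival fraction `s_long` over a fixed horizon.

The utilities `q_pre`, `q_post` are the soft input: where no Global Burden
of Disease weight exists (utility = 1 − disability weight), they are
elicited from expert panels on a calibrated 0–100 visual analogue scale in a
two-round Delphi procedure.  Panels differ between hospitals, so the package
ships the full between-panel validation battery:

* **Bland–Altman analysis** of per-procedure mean utilities (bias, 1.96·SD
  limits of agreement), per health state;
* **random-intercept mixed models** `response ~ study + state +
  (1 | procedure)` fitted by REML, on individual expert utilities (overall
  panel shift) and on per-cell score SDs (consensus difference);
* **ranking robustness**: Spearman's ρ between the DALY/month ranking under
  original-only vs pooled utilities, with per-procedure rank shifts.

Real expert scores from such studies are typically not shareable, so a
first-class synthetic generator (`surgprio.synthetic_data`) emulates the
whole design — two panels (18 and 15 experts), 43 procedures (9 with fixed
GBD weights), two Delphi rounds with shrinkage toward the round-1 median — 
and a `study2023` preset encodes a validation panel that scores
systematically lower (−0.14 pre, −0.08 post on the utility scale) with
inflated dispersion (0.16 vs 0.10) and procedure-level shift heterogeneity
(SD 0.06).  Every analysis then becomes a parameter-recovery exercise.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
preset and write their tables under `results/`:

```bash
python analysis/01_simulate_study.py
python analysis/02_aggregate_qol.py
python analysis/03_panel_agreement.py
python analysis/04_urgency_ranking.py
```

which prints (seed 1):

```
Bland-Altman pre: bias -0.108, LoA (-0.299, +0.082), n=34
Bland-Altman post: bias -0.065, LoA (-0.234, +0.105), n=34
score model: study coefficient -0.0865 (95% CI -0.0976 to -0.0754), ...
sd model: study coefficient +0.0536 (95% CI +0.0461 to +0.0611), ...
Spearman rho (original vs pooled QoL): 0.9912 over 43 procedures
largest urgency change: P07 (0.1967 -> 0.2135 DALY/month, rank 6 -> 4)
PSA for P07: 0.197 (0.180-0.213) DALY/month, n=1000
```

Read: on this draw the validation panel scores ~0.09 utility lower overall
(negative study coefficient) and agrees less (positive SD-model
coefficient, i.e. larger between-expert SDs), yet the urgency ranking is
almost unchanged (ρ = 0.991) — the ranking is driven mainly by survival
parameters, and a roughly constant utility shift cancels in the
pre-vs-post comparison.  Single-seed values scatter around the generative
parameters; averaging over seeds (see below) recovers them.

The same steps are available as a CLI:

```bash
surgprio simulate --seed 1 --out results/data
surgprio run-all  --seed 1 --out results/run
```

## Layout

```
src/surgprio/        library: synthetic_data, elicitation, decision_model,
                     validation_stats, ranking, pipeline, cli
analysis/            numbered narrative drivers over the library
tests/               pytest suite (unit, property and recovery tests)
scripts/acceptance.py  headline-statistic reproduction
docs/methods.md      model, assumptions, numerical choices, limitations
```
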