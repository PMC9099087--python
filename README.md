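# trialcea

Within-trial cost-utility analysis of a two-arm surgical randomized trial,
built as a reusable, tested pipeline. The motivating setting is the
comparison of two procedures for symptomatic haemorrhoids — stapled
haemorrhoidectomy (**SH**) versus a modified ligation procedure for prolapsed
haemorrhoids (**MLPPH**) — with a binary six-month outcome (cured vs
improvement), per-patient direct medical costs in EUR, EQ-5D-3L quality-of-life
measurements at six scheduled visits, and ordinal symptom scores (HSS 0–15,
Wexner 0–20, VAS 0–10). The package is aimed at health-economics and
biostatistics practitioners who want the full analytic chain of such a trial —
comparative statistics, QALY computation, decision modelling, and uncertainty
analysis — as composable, seedable library functions rather than point-and-click
software.

## What it computes

- **Comparative trial statistics** (`trialcea.comparative_stats`): Pearson χ²
  (no continuity correction) and Fisher's exact test on 2×2 tables; odds
  ratios (MLPPH vs SH) with Woolf confidence intervals
  exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) and Haldane–Anscombe handling of zero
  cells; Mann–Whitney U (exact for small tie-free samples, tie-corrected
  normal approximation otherwise); Student/Welch t tests from raw data or
  printed summaries; and the equivalence-trial sample size
  n = (z₁₋α/₂ + z₍₁₊power₎/₂)² (p₁q₁ + p₂q₂) / Δ², validated by a
  zero-true-difference CI-containment simulation.
- **Utilities and QALYs** (`trialcea.utility_qaly`): EQ-5D-3L indexing under a
  pluggable value set (shipped default: the Japanese time trade-off tariff,
  full health = 1, worst state 33333 = −0.111) and QALYs as the trapezoidal
  area under the utility trajectory, QALY = ∫ u(t) dt over the 6-month
  (182/365-year) horizon.
- **Decision tree** (`trialcea.cea_tree`): a two-strategy tree whose chance
  nodes split into cure/improvement branches; exact rollback
  E[C] = p·C_cure + (1−p)·C_improve; incremental analysis
  ΔC, ΔE, ICER = ΔC/ΔE with cost-effectiveness-plane quadrant/dominance
  labels; per-patient cost-effectiveness ratios (mean of ratios); and net
  monetary benefit NMB = λ·E − C.
- **Sensitivity analysis** (`trialcea.sensitivity_psa`): one-way (±20%)
  tornado re-evaluation of the ICER per parameter; probabilistic sensitivity
  analysis drawing gamma-distributed costs and beta-distributed utilities and
  probabilities (method of moments) with tree rollback per draw; CE-plane
  export; and the cost-effectiveness acceptability curve (probability each
  strategy has the highest NMB as a function of willingness to pay).
- **Synthetic cohorts** (`trialcea.trial_data`): a seeded patient-level
  generator calibrated to the trial's published summaries, plus cohort CSV
  I/O with strict validation.
- **CLI** (`trialcea` console script): `simulate`, `analyze`, `cea`, `psa`,
  `ceac` subcommands producing CSV/JSON results bundles with a reproducibility
  manifest.

## Worked example

```python
>>> import trialcea as tc
>>> r = tc.pearson_chi2(tc.ContingencyTable2x2.from_events(46, 66, 58, 64))
>>> round(r.statistic, 3), round(r.p_value, 3)
(8.894, 0.003)
>>> out = tc.evaluate_tree(tc.default_model())
>>> inc = tc.incremental_analysis(out["SH"], out["MLPPH"])
>>> round(inc.delta_cost, 2), round(inc.delta_effect, 5), inc.quadrant
(-577.73, 0.00479, 'dominant')
```

The first call tests the 6-month cure rates (46/66 vs 58/64): χ² = 8.894 on
1 d.f., p = 0.003 — the ligation procedure cures significantly more patients.
The second rolls back the calibrated decision tree: MLPPH costs 577.73 EUR
less per patient and yields 0.00479 more QALYs over six months, i.e. it
*dominates* SH (cheaper and more effective; the raw ICER ≈ −120 612 EUR/QALY
is negative and is reported with an explicit dominance flag).

Generating and analysing a synthetic cohort end to end:

```sh
trialcea simulate --out cohort.csv --seed 7
trialcea analyze --cohort cohort.csv --out results/ --seed 7
```

writes the comparative tables, QALY and CER summaries, the within-trial
incremental analysis, the tornado table, 1000 PSA draws with the CE plane and
CEAC, and a manifest with checksums of every output.

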