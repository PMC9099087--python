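# Methods

This note documents the statistical models, the calibration of the defaults,
the numerical choices, and the limitations of the `trialcea` pipeline. It is
the package's own account of its science; every number quoted here is either
a configured input or something the test suite / acceptance script computes.

## Study design being emulated

A two-arm, 1:1 randomized comparison of stapled haemorrhoidectomy (SH,
n = 66) against a modified ligation procedure for prolapsed haemorrhoids
(MLPPH, n = 64), stratified by haemorrhoid grade (II/III/IV), with a binary
six-month outcome (cured vs improvement), per-patient direct medical cost in
EUR, EQ-5D-3L measured at baseline and days 1, 7, 21 and months 3, 6, and
ordinal scores (HSS at baseline/months 1, 3, 6; Wexner likewise; VAS at
days 0, 1, 3, 7, 14). Visit times are encoded in days — 0, 1, 7, 21, 91, 182
— using 30.4375 days/month, and converted to years with 365 days/year. The
follow-up horizon is therefore 182/365 ≈ 0.4986 years.

## Comparative statistics

- **Pearson χ²** uses the closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) with
  df = 1 and *no* Yates continuity correction: the uncorrected statistic is
  what reproduces the trial's cure-rate χ² of 8.894 from the 46/66 vs 58/64
  counts. scipy supplies the χ²₁ tail probability.
- **Odds ratios** are directed MLPPH-relative-to-SH, i.e. (c/d)/(a/b) with
  rows (SH; MLPPH) and first column = event. Confidence intervals are Woolf
  (log-scale normal). A single zero cell triggers the Haldane–Anscombe +0.5
  correction and sets a `continuity_corrected` flag — mirroring how a
  zero-event complication row should be reported with a caveat rather than a
  bare number; two zero cells on a diagonal leave the OR undefined (error).
- **Mann–Whitney U** uses exact enumeration when both samples have ≤ 10
  observations and no ties, and the tie-corrected normal approximation
  *without* continuity correction otherwise (so identical samples give
  p = 1 exactly). If every pooled observation is tied the test is degenerate
  and returns U = nm/2, p = 1.
- **t tests** default to the pooled (Student) variant, with Welch available;
  a summary-statistics variant supports printed tables.
- **Equivalence sample size.** For margin Δ, type-I error α, power 1−β and
  anticipated proportions p₁, p₂, the per-arm n is the normal-approximation
  solution of "the two-sided (1−α) Wald CI for the difference lies entirely
  in (−Δ, Δ) with probability ≥ power when the true difference is zero":

      n = (z₁₋α/₂ + z₍₁₊power₎/₂)² · (p₁(1−p₁) + p₂(1−p₂)) / Δ².

  With Δ = 0.23, α = 0.05, power = 0.90, p₁ = 0.91, p₂ = 0.68 this yields
  n = 74 per arm. The companion simulation draws both arms from one common
  proportion p\* chosen so 2p\*(1−p\*) equals the formula's variance term
  (p\* ≈ 0.817 here) — this checks the formula under its own variance
  assumption, which is the only well-posed reading of a "zero true
  difference" design built from two unequal anticipated proportions. At
  n = 74 the simulated CI-containment frequency is ≈ 0.90 as designed.

## EQ-5D-3L indexing and QALYs

The shipped value set is the Japanese time trade-off tariff (Tsuchiya et
al. 2002), stored as `valuesets/jp_tto.csv` in additive-decrement form: index
= 1 − 0.152·[any problem] − Σ per-dimension level decrements. Full health
(11111) indexes to 1.0 and the worst state (33333) to −0.111; the additive
form guarantees monotonicity in every dimension. Any tariff with the same
structure can be substituted (`ValueSet3L.from_csv`), and a degenerate
constant tariff is supported for testing.

QALYs are the trapezoidal integral of the indexed utility trajectory over
time in years — linear interpolation between visits, no extrapolation past
the last visit, trajectory anchored at the pre-randomization baseline
(t = 0). No discounting or half-cycle correction is applied over the
six-month horizon.

Patient-level cost-effectiveness ratios are the **mean of per-patient
cost/QALY ratios**, not the ratio of arm means; the two differ under
patient-level heterogeneity (Jensen), and the mean-of-ratios convention is
what arm-level CER summaries with their own standard deviations imply.

## Decision tree and its calibration

Each strategy's chance node splits into cure/improvement with probability
p_cure; rollback is the exact expectation. The default model is calibrated
as follows:

- p_cure: the observed 46/66 (SH) and 58/64 (MLPPH).
- Branch costs: 1608.975 / 1770.675 EUR (SH cure / improvement) and
  1076.275 / 1118.625 EUR (MLPPH), the midpoints of the ±20% one-way
  sensitivity ranges; the rolled-back expected costs (1657.98, 1080.25 EUR)
  agree with the observed arm means to within rounding.
- Branch effects: the improvement branch is fixed at 0.40 QALYs for both
  strategies (the midpoint of its reported ±20% band); each cure-branch
  effect is then the unique value making the strategy's expected effect equal
  its observed arm mean QALYs (0.40766 SH, 0.41245 MLPPH), giving ≈ 0.41099
  and ≈ 0.41374. The reported one-way utility ranges are only printed to two
  decimals, so any base inside the rounding-consistent interval is
  admissible; the arm-mean-consistency constraint pins it down.

Sign convention: ΔC and ΔE are comparator − reference (MLPPH − SH), so a
cheaper, more effective comparator gives ΔC < 0, ΔE > 0 — the "dominant"
quadrant — and a negative ICER, which is reported raw but flagged
(`dominance=True`). A zero ΔE leaves the ICER undefined (`icer=None`);
boundary cases resolve by weak dominance. Note that an ICER computed from
independently rounded arm summaries is numerically delicate: with
ΔE ≈ 0.005, a 0.01-EUR rounding of ΔC moves the ICER by ≈ 2 EUR/QALY, which
is why the pipeline treats the quadrant/NMB decision rules, not a specific
ICER digit string, as the meaningful output.

## Sensitivity analysis

**One-way (tornado).** Each of the ten model parameters (per strategy: two
branch costs, two branch effects, and the improvement probability) is moved
to ×0.8 and ×1.2 of base with everything else held fixed, the tree is
re-rolled and the ICER recorded; bars are ranked by |ICER_high − ICER_low|.
Probabilities are clipped to [0, 1] with a flag. The high/low input ratio is
1.2/0.8 = 1.5 for every unclipped parameter.

**Probabilistic (PSA).** Every uncertain parameter is drawn independently per
iteration (default 1000): costs from gamma distributions with shape (m/s)²
and scale s²/m, utilities and probabilities from beta distributions by method
of moments (feasibility: s² < m(1−m)). Defaults attach the arm-level cost
standard deviations (279.72 / 248.01 EUR) to both branch costs of the arm,
the arm-level QALY standard deviations (0.02307 / 0.01691) to both branch
effects, and binomial standard errors at the arm sizes to the cure
probabilities. No correlation structure is imposed — draws are independent
within and across strategies. Degenerate (sd = 0) parameters are point
masses, which makes the base case a strict special case of the PSA.

The CEAC reports, per willingness-to-pay threshold (default grid: 0–50 000
EUR/QALY in steps of 500, always including 8732), the fraction of iterations
in which each strategy attains the highest net monetary benefit; NMB ties are
credited to the reference strategy (immaterial for continuous draws), so the
two curves sum to one. Under the default calibration the comparator's
acceptance probability stays above one half over the entire grid — the
dominance pattern is insensitive to the threshold.

## Synthetic cohort generator

The generator emulates the trial's *marginal* structure per arm:

- outcomes ~ Bernoulli(cure probability); grades i.i.d. from the pooled
  grade distribution (32/70/28 out of 130);
- costs ~ gamma by method of moments around the arm mean/sd (positive and
  right-skewed, matching the PSA's own distributional assumption); optionally
  outcome-conditional cost means;
- ordinal scores: Poisson draws around per-visit means, clipped to the
  instrument range;
- EQ-5D-3L responses: per visit, a target utility is drawn from a normal
  truncated to the representable range [−0.111, 1] whose location parameter
  is root-solved so the *truncated* mean equals the configured visit mean;
  the target is then randomized-rounded between the two bracketing achievable
  utilities with probabilities that preserve it in expectation, and a state
  attaining the chosen utility is picked uniformly.

The two-stage utility scheme exists because the achievable-utility grid is
very uneven — in particular there is a 0.196 gap between full health (1.0)
and the best imperfect state (0.804) under the Japanese tariff. Nearest-state
snapping across that gap would bias visit means by up to ~0.01, visibly
distorting QALY calibration; the randomized rounding makes the per-visit mean
estimator exactly unbiased (at the price of some extra, honestly reported,
dispersion). Default per-visit utility means are anchored at the published
baseline (0.79 / 0.77) and day-1 (0.65 / 0.69) values; the remaining visits
(SH: 0.74, 0.80, 0.8255, 0.85; MLPPH: 0.75, 0.81, 0.8335, 0.86) are chosen so
the trapezoid of the mean trajectory equals the published arm QALYs (0.40766
/ 0.41245) and utilities recover above baseline by month 3.

What the generator does **not** emulate: within-patient correlation of
utilities across visits (draws are independent given the visit means, so
individual trajectories are noisier than real ones while arm means and QALY
means are correct); cost–outcome and cost–utility dependence (off by
default); grade-conditional effect sizes; and any missing-data mechanism
(the emulated trial had complete follow-up). Passing parameter-recovery tests
therefore validates the marginal calibration, not patient-level joint
structure.

## Numerical choices and problem sizes

- Seeding: `numpy.random.default_rng` throughout; a config/CLI seed fully
  determines every cohort, PSA and simulation. Re-running with the same seed
  reproduces outputs byte-for-byte.
- The truncated-normal location calibration uses Brent root-finding with
  bracket expansion; gamma/beta fits are closed-form method of moments.
- Parameter-recovery tests run at 5000 patients/arm, the PSA acceptance test
  at 1000 iterations, the equivalence coverage simulation at 10 000 trials,
  and the quadrant/NMB consistency property at 1000 random models — sizes at
  which Monte-Carlo error (3 s.e. bands) is small relative to the quantities
  checked while the whole suite runs in a few seconds.
- Exact Mann–Whitney enumeration is limited to both samples ≤ 10 (tie-free);
  beyond that the tie-corrected asymptotic test is used.

## Known limitations

- The decision tree is a single-period, two-strategy, two-branch model; no
  Markov extension, discounting, or half-cycle correction (appropriate for a
  six-month horizon, not beyond).
- Beta-distributed utilities cannot represent states valued below 0; for
  this trial all branch effects are well inside (0, 1) QALYs so the
  constraint never binds.
- The Wald-CI equivalence machinery is asymptotic; at small n or extreme
  proportions an exact or score-interval variant would be preferable.
- Arm-summary calibration inherits the rounding of published two-decimal
  inputs; quantities formed as ratios of small differences (the ICER) are
  reported with that caveat and interpreted through dominance/NMB logic.
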