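# Methods

## Scientific setting

`quantherit` estimates narrow-sense heritability (h²) of a quantitative
phenotype — the motivating case is fasting plasma triglyceride concentration
in two-generation family cohorts — as a *function of where in the population
distribution the phenotype lies*. Classical familial regression assumes one
slope: offspring on parent (β_OP), offspring on midparent (β_OM), or sib on
co-sib (β_FS). Here each slope is instead estimated at every percentile of
the dependent member's distribution by quantile regression, converted to h²,
and tested for constancy. A rising h²(τ) curve ("quantile-dependent
expressivity") means genetic effects are larger in people with high phenotype
values — which can masquerade as gene–environment or gene–drug interaction in
studies that shift the phenotype distribution.

## Pipeline

1. **Input** — tab-delimited pedigree (`individual_id, father_id, mother_id,
   sex, cohort`) and longitudinal exam (`individual_id, exam_index, age,
   value, on_lipid_meds`) tables, validated for referential integrity and
   acyclic parentage.
2. **Eligibility** — exams under age 16 or taken on lipid-lowering medication
   are excluded. The medication criterion is applied at the *exam* level by
   default (a subject's medicated exams are dropped, the rest kept); a strict
   subject-level mode (`medication_scope="subject"`) removes any ever-
   medicated subject entirely. Exam-level is the less destructive reading of
   a subject-level inclusion criterion applied to up to nine repeated exams.
3. **Adjustment** — per cohort, OLS of the (optionally log-transformed) value
   on `female, age, age², female×age, female×age²`, pooled over all exam
   records of the cohort; one model per cohort rather than per exam wave,
   since the age terms absorb between-exam aging. Each exam's adjusted value
   is residual + cohort grand mean (keeps concentration units so slopes are
   interpretable), and each individual's final value is the mean over their
   adjusted exams. Collinear covariate columns (e.g. in a single-sex cohort)
   are dropped with a warning.
4. **Pairs** — offspring-parent pairs weighted ½/½ when both parents are
   measured and 1 for a single measured parent; midparent pairs (parental
   mean) restricted to complete parent couples; all k(k−1) ordered full-sib
   pairs per sibship with per-pair weight 1/(k−1) so each sibling contributes
   total weight 1 as the dependent member ("equal weight to each sibling"
   admits two readings; a flat per-pair weight mode is available); spouse
   pairs, one per parental couple, give r_spouse. Degrees of freedom are
   Σk_i − 2 for offspring-parent-type sets and Σ(k_i − 1) for full-sib sets.
5. **Quantile process** — at each grid level τ (default 0.05, 0.06, …, 0.95;
   91 levels) the weighted check loss Σᵢ wᵢ ρ_τ(yᵢ − a − b·xᵢ) is minimised
   exactly. Per-level fits are independent; "simultaneous" inference comes
   from a bootstrap (default 1000 replicates; pair resampling by default,
   cluster/family resampling available because pairs within a family are
   dependent) that refits the whole process per replicate and yields the
   91×91 covariance of the slope process. Replicates with degenerate
   regressor values are redrawn (counted; >10% redraws aborts) so the
   replicate count stays fixed.
6. **Heritability** — Falconer conversions with assortative mating:
   h² = 2β_OP/(1+r_spouse); h² = β_OM; h² = (√(1+8·r_spouse·β_FS) − 1) /
   (2·r_spouse), the inverse of β_FS = h²/2 + r·h⁴/2, with the series limit
   2β_FS used for |r| < 1e-8. Standard errors by the delta method treating
   r_spouse as fixed (this reproduces, e.g., an offspring-parent SE of
   2×0.0074/1.15 ≈ 0.013). The full-sib delta-method SE is an approximation;
   no exact small-sample propagation is attempted.
7. **Trend tests** — discrete orthogonal polynomial contrasts of degree 1–3,
   built by QR-orthonormalisation of the Vandermonde basis on the actual grid
   (so non-uniform grids work), applied to the slope vector; variance
   c′Vc from the bootstrap covariance; t statistic referred to the pair set's
   pedigree degrees of freedom, two-sided p-values. The linear test also
   reports the least-squares slope of β(τ) on percentile (change per 1%).
   A 90th-vs-10th percentile difference contrast is reported alongside.

## Quantile-regression solver

The weighted check-loss minimisation is a linear program. It is solved by a
Mehrotra predictor-corrector interior-point iteration on the bounded-variable
dual, max c′d s.t. A d = (1−τ)A1, 0 ≤ d ≤ 1, where A is the transposed
row-scaled design and the equality multiplier converges to the regression
coefficients. With two parameters every Newton step is a closed-form 2×2
solve, so the iteration is implemented both as a numpy batch over all grid
levels and as a numba kernel (used when numba is importable; ~10 ms for a
91-level process on ~10³ pairs). Point fits finish with a vertex polish:
the LP optimum interpolates two data points, so the lines through the four
smallest-|residual| points are enumerated and the best kept, giving an exact
LP vertex. Tolerances: relative duality gap 1e-11 for point fits, 1e-8 for
bootstrap replicates (their slopes only feed an empirical covariance; errors
≪ 1e-4 are immaterial there), and polishing is skipped in replicates. Ties /
non-unique optima resolve to whichever candidate vertex attains the minimal
objective in the enumeration. A constant regressor raises a
`DegenerateDesignError` rather than returning an arbitrary slope.

## Synthetic cohorts

The generator emulates the study population without any access-restricted
data: per family a latent multivariate normal vector (father, mother, k
offspring) with corr(f,m) = ρ_spouse = 0.15, corr(parent,child) = ρ_po =
0.35, corr(sib,sib) = ρ_ss = 0.40, pushed through Φ and the inverse CDF of a
configurable margin (Gaussian copula). Quantile-dependent expressivity is
induced purely by margin nonlinearity: `null_config` (normal margin,
mean 2.4, SD 1.0 mmol/L) yields a flat slope process, `signature_config`
(lognormal, μ=0.6, σ=0.6 on the log scale — right-skewed with mean ≈ 2.2 and
SD ≈ 1.4 mmol/L, triglyceride-like) yields slopes that rise with τ on the raw
scale but are near-constant after log transformation. This is the simplest
generative mechanism consistent with the observed raw-vs-log contrast; it is
a test bed, not a claim about biology. Sibship sizes default to
{1: 0.35, 2: 0.34, 3: 0.19, 4: 0.08, 5: 0.04}, roughly the two-generation
cohort mix. Sex (−0.2 for female), age (+0.02/yr) effects are additive;
each of 3 exams (4 years apart) adds N(0, 0.3) noise; offspring ages uniform
on 25–55, parents offset +25 years; values floored at 1e-3 since
concentrations are positive. One seed determines everything.

What the generator does *not* emulate: genotypes, shared-environment
covariance distinct from the single sib-sib correlation, assortative-mating
dynamics, cohort effects beyond the label, missingness patterns, or
medication use. Passing recovery tests therefore shows the estimator chain
is correct under a Gaussian-copula world, not that real triglyceride data
meet those assumptions.

`oracle_quantile_slope` provides independent ground truth: it simulates pairs
directly from the latent model and minimises the sample mean check loss with
a derivative-free Nelder-Mead search — no code shared with the LP solver.

## Verification problem sizes

Closed-form heritability conversions are checked exactly against the
published slope/correlation values. Solver correctness is checked against an
independent `scipy.optimize.linprog` (HiGHS) solve and against statsmodels'
`QuantReg` on 200–300-point instances. Statistical behaviour is checked by
simulation: type-I error of the cubic trend test over 500 null cohorts
(300 families, 100 bootstrap replicates each, 19-level grid), and parameter
recovery/power on lognormal-margin cohorts of 3000 families (50 replicates
for the 90th–10th difference test, grids restricted to the levels under
test). Grid density was chosen per check because calibration and power of
the contrast tests do not depend on how finely the quantile axis is sampled;
the analysis default remains the 91-level grid.

## Known limitations

- No shared-environment decomposition: familial slopes conflate additive
  genetic and common-environment resemblance, so "h²" here is the familial
  upper bound the regression estimators define.
- No quantile-crossing correction or smoothing of the slope process; raw
  per-τ estimates are reported as is.
- Delta-method SEs for the full-sib conversion are first-order only.
- The bootstrap treats pairs as exchangeable by default; family resampling
  is available and recorded in `run_summary.json`, but the two can differ
  when sibships are large.
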