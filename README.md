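# quantherit

Quantile-specific narrow-sense heritability from family-structured phenotype
data.

## The problem

Familial regression estimates narrow-sense heritability (h²) of a
quantitative trait from a single regression slope: offspring on parent
(β_OP), offspring on midparent (β_OM), or sib on co-sib (β_FS), via the
Falconer relations

    h² = 2·β_OP / (1 + r_spouse)
    h² = β_OM
    h² = (√(1 + 8·r_spouse·β_FS) − 1) / (2·r_spouse)

where r_spouse is the phenotypic correlation between mates. A single slope,
however, assumes the genetic effect is the same for everyone. For
right-skewed traits such as fasting triglyceride concentrations, the
offspring–parent relationship is demonstrably steeper for offspring in the
upper tail of the distribution than in the lower tail — *quantile-dependent
expressivity*. When present, it can masquerade as gene–drug or
gene–environment interaction in any study design that shifts the phenotype
distribution.

`quantherit` quantifies this: it estimates β(τ) at every percentile τ of the
dependent member's distribution by weighted linear quantile regression
(exact LP solutions via an interior-point solver with vertex polishing),
attaches a bootstrap covariance to the whole slope process, converts slopes
to h²(τ), and tests whether the process is flat versus linear, quadratic or
cubic in τ using orthogonal polynomial contrasts. It is aimed at
quantitative-genetics and genetic-epidemiology researchers working with
two-generation pedigree data (or anyone who wants a calibrated test bed for
quantile-process inference on familial pairs).

Because real two-generation cohort data of this kind are access-restricted,
the package includes a first-class Gaussian-copula pedigree simulator with
controllable spouse / parent–offspring / sib–sib correlations and margins,
so every stage of the pipeline is testable end to end.

## Worked example

Simulate a 1000-family cohort with lognormal (triglyceride-like) margins and
constant latent familial correlations, then run the full analysis on
offspring–parent and full-sib pairs:

```bash
quantherit all --kind op,fs --boot 200 --seed 11 \
    --grid-min 0.05 --grid-max 0.95 --grid-step 0.05 --out demo
quantherit report --in demo
```

```
kind,transform,correlation,trad_slope,trad_se,trad_p,slope_per_percentile,...,diff_90_10,diff_90_10_se,diff_90_10_p
op,identity,0.281,0.2831,0.0213,1.3e-38,0.00524,...,0.4906,0.0528,3.6e-20
fs,identity,0.297,0.2969,0.0293,4.3e-23,0.00524,...,0.4152,0.0725,1.4e-08
# r_spouse = 0.0821
# seed = 11, n_boot = 200
```

Reading the offspring–parent row: the traditional (one-slope) analysis gives
β_OP = 0.283 ± 0.021, but the quantile analysis shows the slope *increases*
by 0.0052 ± 0.0005 per percentile of the offspring distribution (linear
trend p ≈ 2.5×10⁻²², with significant quadratic curvature), and the slope at
the 90th percentile exceeds the one at the 10th by 0.49 ± 0.05. The
accompanying `h2_curve.csv` carries the per-quantile conversion — here h²
rises from 0.25 ± 0.02 at the 10th percentile through 0.48 ± 0.03 at the
median to 1.16 ± 0.10 at the 90th (values above 1 flag that familial slopes
in the far tail overstate strictly additive heritability; see
`docs/methods.md`). Had the margins been normal (`null_config`), the same
pipeline reports a flat slope process and non-significant trend tests.

Outputs per run: `slopes.csv` (per-τ intercept/slope/SE), `h2_curve.csv`
(per-τ slope and h² with SEs), `trend_tests.json` (linear/quadratic/cubic
contrasts and the 90th−10th difference), `table1.csv` (the summary above),
and `run_summary.json` (every decision, seed and count needed to rerun the
analysis bit-identically).

The same analysis runs on real data with
`quantherit fit --pedigree ped.tsv --exams exams.tsv ...`; input dialects
are documented in `docs/methods.md`.

## Library use

```python
from quantherit import (RunConfig, run_pipeline, signature_config,
                        h2_from_op, fit_weighted_quantile)

res = run_pipeline(RunConfig(synthetic=signature_config(seed=1), seed=1,
                             kinds=("op",), n_boot=200))
print(res["table1"])
print(h2_from_op(beta_op=0.0837, se_beta=0.0074, r_spouse=0.15).h2)  # 0.1456
```

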