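# threshcurve

Quantitative total-bilirubin (TB) thresholds for liver failure in
hospitalized patients with chronic liver disease.

High TB marks failing liver function, but *how much* bilirubin signals
"liver failure" — and whether the same number can be used in cirrhosis and
in non-cirrhotic advanced fibrosis — is contested between ACLF (acute-on-
chronic liver failure) diagnostic frameworks. `threshcurve` implements, as
a reusable and fully tested pipeline, the quantitative analysis that
answers this with survival data: it maps TB at admission to
confounder-adjusted 28- and 90-day transplantation-free mortality and
derives two kinds of TB cutoff from the shape of that curve. It is aimed at
hepatology/biostatistics researchers who want to run the analysis on their
own cohort data or study its statistical behavior on synthetic cohorts with
a known ground truth.

## The method

For a cohort of hospitalized patients with cirrhosis or advanced fibrosis
(FIB-4 > 1.45), after excluding patients transplanted within 90 days:

1. **Cox models** — multivariable Cox proportional-hazards regression of
   90-day transplantation-free mortality on TB, continuous (HR per mg/dL)
   and in seven bins (≤2, 2–5, 5–8, 8–12, 12–16, 16–20, >20 mg/dL; lowest
   bin as reference), adjusted for age, sex, etiology, overt ascites, GI
   bleeding, bacterial infection, HE grade, INR, creatinine, ln ALT, and
   sodium; Efron tie handling; ordinal-bin trend test.
2. **TB–mortality correlation curve** — a binomial-logit GAM of
   death-by-horizon on a penalized cubic B-spline in TB plus the same
   confounders (smoothing weight chosen by AIC), turned into a curve by
   marginal standardization: for each TB value *t* on a 0–50 mg/dL grid,
   every patient's TB is set to *t* and the model-predicted risks are
   averaged,

   p̂(t) = n⁻¹ Σᵢ expit( s(t) + xᵢᵀβ̂ ).

3. **Cutoffs from the curve's acceleration** — a cubic smoothing spline is
   refit to the curve and differentiated twice. The TB at the *maximum* of
   this acceleration is the **mathematical cutoff** (where mortality growth
   speeds up fastest); a subsequent *minimum* marks the saturation point.
   The **clinical cutoff** is the smallest TB at which the adjusted 28-day
   curve reaches 15% mortality (the EASL-CLIF organ-failure anchor), found
   by root solving on the smoothed curve.

Because the cohort data the analysis was designed around are not public,
the package ships a synthetic-cohort generator with a configurable
TB → log-hazard link (S-shaped for cirrhosis-like cohorts, hinge-at-12 for
fibrosis-like ones), TB-bin-dependent complication rates, Weibull event
times and 90-day administrative censoring — so every stage can be tested
against a known generative truth (`true_curve`).

## Worked example

```python
import threshcurve as tc

cfg = tc.SimulationConfig.cirrhosis_like(seed=1)      # n=2592, S-shaped link
cohort = tc.generate_cohort(cfg)
analysis, report = tc.apply_exclusions(cohort)

cox = tc.TBCoxModel(analysis, exposure_mode="continuous").fit()
print(cox.summary(exposure_only=True).round(3))

gam90 = tc.AdjustedMortalityGAM(analysis, horizon=90).fit()
gam28 = tc.AdjustedMortalityGAM(analysis, horizon=28).fit()
c90, c28 = gam90.predict_curve(), gam28.predict_curve()

peak, valley = tc.find_inflections(tc.second_derivative(c90))
clinical = tc.clinical_cutoff(c28, level=0.15)
report = tc.summarize_cutoffs(
    analysis, c28, c90,
    {"mathematical": peak, "valley": valley, "clinical": clinical},
    group="cirrhosis",
)
print(report.to_frame().round(3))
```

prints (abridged)

```
term  coef  hazard_ratio  ci_lower  ci_upper   p
  tb 0.085         1.088     1.079     1.098 0.0

      cutoff  tb_mg_dl  exceed_fraction  adjusted_mortality28_at_cutoff  adjusted_mortality90_at_cutoff
mathematical    14.000            0.243                           0.088                           0.163
      valley    25.000            0.063                           0.359                           0.540
    clinical    16.306            0.209                           0.150                           0.241
```

Reading this: mortality risk rises 8.8% per mg/dL of TB after adjustment;
the fitted curve accelerates fastest at TB ≈ 14 mg/dL (24% of the cohort
above it) and saturates past ≈ 25 mg/dL; adjusted 28-day mortality crosses
the 15% anchor at TB ≈ 16.3 mg/dL — and the curve evaluated at that cutoff
reads exactly 15.0%, by construction of the root solver.

The same stages are scriptable from the shell:

```bash
threshcurve report examples/cirrhosis.yaml --outdir out/
threshcurve simulate --n 2592 --seed 1 --out cohort.csv
threshcurve curve cohort.csv --horizon 90 --out curve90.csv
```

## Layout

| module | contents |
| --- | --- |
| `threshcurve.simulate` | `SimulationConfig`, `TBLink`, `generate_cohort`, `true_curve` |
| `threshcurve.scores` | FIB-4, MELD, MELD-Na, CTP, TB bins |
| `threshcurve.filters` | inclusion check, group assignment, exclusion cascade |
| `threshcurve.cox` | `TBCoxModel` → `CoxResults` (lifelines backend) |
| `threshcurve.riskcurve` | `AdjustedMortalityGAM` → `GAMResults` → `RiskCurve` |
| `threshcurve.cutoffs` | acceleration curve, inflection search, clinical cutoff |
| `threshcurve.reporting` | bin summary tables, `run_pipeline`, artifact output |
| `threshcurve.cli` | `threshcurve` command (typer) |

See `docs/methods.md` for the statistical details, default parameters, and
known limitations.
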