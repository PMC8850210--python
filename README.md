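# fivmap

Does weighting a stroke patient's follow-up infarct volume (FIV) by *where*
the infarct sits strengthen its association with 90-day functional outcome?
`fivmap` is a tested, reusable pipeline for that question, aimed at
neuroimaging statisticians and stroke-outcome researchers. It covers the
whole chain on DWI-like data in a common atlas space:

1. **Segment** — label voxels whose intensity exceeds the mirrored
   contralateral voxel by ≥ 20% (infarct is hyperintense on trace DWI), with
   optional connected-component and morphological clean-up;
2. **Decompose** — split the lesion into sub-volumes by mRS-relevance class
   (high / moderate / low) using a 66-region parcellation and a relevance
   table;
3. **Map** — score each region's association with outcome by the
   Brunner–Munzel rank test of stochastic superiority
   p̂ = P(X < Y) + ½·P(X = Y) (X = mRS of spared, Y = of lesioned patients),
   and derive relevance classes from the z-map;
4. **Model** — fit the ten-model battery: binary logistic for favorable
   outcome (mRS ≤ 2) and proportional-odds ordinal regression for mRS shift,
   univariable on each volume and multivariable on the class volumes,
   unadjusted and covariate-adjusted; report odds ratios per 10 mL with Wald
   95% CIs, AIC = 2k − 2·log L, c-statistics (ROC AUC; all-discordant-pairs
   concordance for ordinal outcomes) and DeLong comparisons of correlated
   AUCs.

Because cohorts of this kind are not public, the package includes a
first-class synthetic generator: a mirror-symmetric 66-region parcellation
with a deep high-relevance core, lesions grown so that occupancy progresses
high → moderate → low with total volume, DWI-like intensities with exact
contrast control, and mRS outcomes from a proportional-odds latent model
`logit P(mRS ≤ k) = α_k + β_high·V_high + β_mod·V_mod + β_low·V_low + γ·x`.
See `docs/methods.md` for the full model description and defaults.

## Worked example

```python
from fivmap import CohortConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    cohort=CohortConfig(n_patients=252, seed=1),
    workdir="run1",
    adjusted="both",
)
bundle = run_pipeline(config)
t = bundle.model_table.set_index(["model", "predictor"])
for model, pred in [("model_1", "fiv_total"), ("model_2", "fiv_high"),
                    ("model_5", "fiv_high"), ("model_5", "fiv_mod")]:
    r = t.loc[(model, pred)]
    print(f"{model:8s} {pred:9s} OR/10mL {r.or_per_10mL:.2f} "
          f"({r.or_ci95_low:.2f}-{r.or_ci95_high:.2f})  AIC {r.aic:.0f}  c {r.c_statistic:.2f}")
print("DeLong total vs high p =", round(bundle.delong["p"], 3))
```

prints

```
model_1  fiv_total OR/10mL 0.88 (0.84-0.93)  AIC 306  c 0.79
model_2  fiv_high  OR/10mL 0.52 (0.44-0.62)  AIC 283  c 0.78
model_5  fiv_high  OR/10mL 0.58 (0.47-0.71)  AIC 284  c 0.79
model_5  fiv_mod   OR/10mL 0.95 (0.85-1.06)  AIC 284  c 0.79
DeLong total vs high p = 0.165
```

Read: per additional 10 mL of total FIV the odds of a favorable outcome
fall by ~12% (OR 0.88); per 10 mL of *high-relevance* FIV they fall by ~48%
(OR 0.52), and the high-relevance model has the lowest AIC. In the joint
model only the high-relevance volume stays significant (the moderate-volume
OR CI spans 1), yet by DeLong's test the high-relevance c-statistic is not
significantly better than total FIV's — location-weighting sharpens the
per-mL odds ratio without improving discrimination, which is exactly the
structural pattern the default generator encodes.

The same pipeline is scriptable from the shell:

```bash
fivmap simulate --out cohort/ --seed 1 --n 252
fivmap segment --in cohort/P0001_dwi.nii.gz --brain-mask cohort/parcellation.nii.gz \
       --threshold 0.20 --out P0001_lesion.nii.gz
fivmap decompose --lesion P0001_lesion.nii.gz --parcellation cohort/parcellation.nii.gz \
       --regions cohort/regions.tsv --relevance cohort/relevance.tsv --out P0001_sub.json
fivmap run --workdir run1 --seed 1
```

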