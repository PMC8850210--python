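# Methods

`fivmap` re-implements, as a tested and reusable pipeline, the analysis of
whether weighting follow-up infarct volume (FIV) by the mRS-relevance of the
infarcted location strengthens its association with 90-day functional
outcome after anterior large-vessel-occlusion stroke. Because clinical
follow-up DWI cohorts of this kind are not publicly available, the pipeline
ships a first-class synthetic-data generator and every statistical claim in
the test suite is made on synthetic cohorts whose generative structure is
known exactly.

## The analysis chain

1. **Segmentation.** On trace DWI, acute infarct is hyperintense. The coarse
   delineation labels a voxel infarct-positive when its intensity exceeds
   that of the homologous voxel mirrored across the midsagittal plane by at
   least 20% (inclusive: `(I_v − I_m)/I_m ≥ 0.20`). Only positive asymmetry
   counts — a signed-magnitude rule would label the healthy mirror voxel of
   every lesion voxel too. The denominator is the contralateral intensity,
   because contralateral tissue is the reference. Voxels whose mirror
   counterpart lies outside the brain or has zero intensity are skipped and
   counted. The midline is the grid mid-plane; data are assumed already
   atlas-aligned (registration is out of scope). `clean_mask` removes
   6-connected components below a size threshold and can optionally fill
   enclosed holes and apply one binary closing; both morphology steps are
   off by default so that `min_cluster_voxels=1` is the identity.

2. **Relevance decomposition.** A 66-region parcellation and a region →
   {high, moderate, low, unclassified} relevance table split the lesion into
   class sub-volumes. Every lesion voxel is attributed to exactly one class
   (label 0 → unclassified), so
   `n_high + n_mod + n_low + n_unclassified = n_total` holds exactly in voxel
   counts for every mask. Volumes are voxel count × voxel volume / 1000 (mL).
   Because the literature disagrees on whether "total FIV" includes tissue
   outside the labelled regions, results report both `fiv_total` and the
   classified-only total.

3. **Region lesion–symptom mapping.** For each region, patients lesioned in
   the region are compared with spared patients on their 90-day mRS with the
   Brunner–Munzel test. The estimate is the stochastic superiority
   p̂ = P(X < Y) + ½P(X = Y) with X the mRS of a spared and Y of a lesioned
   patient, computed from pooled mid-ranks; the studentised statistic uses
   the rank-based variance with Satterthwaite-type degrees of freedom and is
   mapped to the standard-normal scale by quantile transform so z-scores
   from regions with different df are comparable. Orientation is fixed:
   positive z means lesioned patients fare worse. The test is run at region
   level (66 tests) because every downstream use (relevance classes) is
   regional. Regions with fewer than `min_group = 5` patients in either arm
   are flagged non-evaluable — the rank test is unstable below that.
   Complete-separation regions get signed-infinite z by convention and
   classify as high. No multiple-testing correction is applied by default.
   Relevance classes derive from z tertiles (ties broken by ascending region
   id) or from user-supplied absolute thresholds; a pre-existing relevance
   table can equally be supplied externally, which is the pipeline default
   since published classifications typically are inherited from prior work.

4. **Outcome models.** Ten models: binary logistic for favorable outcome
   (mRS ≤ 2) on total / high / moderate / low FIV univariably (1–4) and the
   three class volumes jointly (5), then the same five specifications as
   proportional-odds ordinal fits of the full mRS (6–10). Each exists
   unadjusted and adjusted for age, sex, diabetes, atrial fibrillation,
   prior stroke or pre-stroke mRS > 0, treatment allocation, occlusion site
   (dummy-coded, M1 reference), onset-to-treatment time and collateral
   score (entered as a linear 0–3 ordinal). Adjusted estimates come from
   one joint model per roster row. Fits are maximum likelihood via
   statsmodels (`Logit`, `OrderedModel`), Newton first with a BFGS
   fallback; non-convergence and separation raise, never pass silently.
   Missing data are handled complete-case with logged exclusion counts.
   Coefficients are reported in the favorable direction and odds ratios per
   10 mL (`OR = exp(10·β)`), with Wald 95% CIs transformed from the
   coefficient scale (the CI method is a package choice; profile-likelihood
   CIs would also be defensible).

5. **Model scoring.** AIC = 2k − 2·loglik with k the number of estimated
   parameters. The binary c-statistic is the Mann–Whitney rank estimator of
   the ROC AUC with half credit for ties. The ordinal c-statistic is
   all-discordant-pairs concordance: the probability that of two subjects
   with different mRS levels the worse one has the higher risk score,
   computed as the n_k·n_l-weighted average of level-pair AUCs (an exact
   identity). Note that averaging the K−1 *cumulative* dichotomy AUCs with
   weights n_below·n_above is **not** the same statistic — a level pair
   (k, l) crosses l − k thresholds, which yields a distance-weighted
   concordance; the plain concordance form is used because it reduces
   exactly to the binary AUC at K = 2 and admits a brute-force oracle.
   Correlated binary-model AUCs are compared with DeLong's test (structural
   components from mid-rank placements; zero-variance differences return
   p = 1 with a degeneracy flag). Ordinal c-statistics are compared by a
   paired subject bootstrap, since DeLong is defined for binary labels.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
neuroanatomy:

* **Geometry.** The brain is a mirror-symmetric ellipsoid (semi-axes 45% of
  the grid extent) on a default 48³ grid of 3 mm voxels (~1150 mL; the
  tests use a coarser 32³/4 mm grid). Each hemisphere is split into three
  radial distance bands around a deep anchor near the midline — high
  relevance innermost (10% of hemisphere volume, echoing the small deep
  structures like internal capsule and lentiform nucleus that dominate mRS
  relevance), moderate next (to 30%), low outermost. Each band is cut into
  11 Voronoi regions seeded at random band voxels; the right hemisphere is
  the mirror image with ids offset by 33, so homologous regions have
  identical voxel counts by construction.
* **Lesions.** 6-connected flood fill from a random seed voxel in a
  high-relevance region of one hemisphere, consuming frontier voxels in
  strict relevance order (high before moderate before low) and, within a
  class, preferring voxels nearer the seed up to a uniform jitter
  (`lesion_roughness_mm`, default 4 mm), giving compact blobs with a mildly
  irregular surface. Because the relevance bands are radially contiguous
  with thickness much greater than one voxel step, a connected lesion
  cannot touch the low band without containing moderate tissue: the
  occupancy ordering (low > 0 ⇒ mod > 0 ⇒ high > 0) holds for every lesion
  by construction, and small lesions are purely high-relevant. Total-volume
  targets are log-normal (median ≈ 49 mL, log-sd 1.1, clipped to 95% of one
  hemisphere), chosen so the per-mRS volume distributions are ordered and a
  realistic minority of patients (~35% / ~10%) show moderate / low
  occupancy.
* **Intensities.** Uniform baseline 100 inside the brain with multiplicative
  Gaussian noise (default sd 5%). By default the noise field is generated on
  one hemisphere and mirrored, so noise alone never crosses the asymmetry
  threshold and segmentation correctness is exactly testable; an
  independent-noise mode exists for robustness checks. Lesion voxels are
  elevated by exactly (1 + contrast), default 0.30, relative to their mirror
  counterparts.
* **Outcomes.** mRS is drawn from a proportional-odds latent model
  `logit P(mRS ≤ k) = α_k + β_high·V_high + β_mod·V_mod + β_low·V_low + γ·x`
  with volumes in mL and negative β harmful. Defaults: β_high = −0.05/mL
  (≈ OR 0.61 per 10 mL), β_mod = β_low = 0 — so the headline multivariable
  pattern (only the high-relevance volume truly matters, univariable
  associations for every class arising through volume correlation) is a
  structural property of the defaults. Covariate effects default to a small
  age effect (−0.02/yr, centred), a treatment benefit (+0.6 for EVT) and a
  collateral-score gradient (+0.25/point). The cut-points
  (−0.698, 0.889, 2.090, 2.858, 3.589, 3.976) were calibrated once by
  simulation under these defaults so the marginal favorable rate is ≈53%, a
  convenience anchor rather than a claim. Covariate distributions use
  typical trial-population anchors (age 66 ± 14 truncated to [18, 95],
  diabetes 16%, atrial fibrillation 44%, prior stroke or pre-stroke
  disability 19%, EVT 52%, occlusion ICA-T/M1/M2 = 22/72/6%,
  onset-to-treatment 195 ± 98 min, collateral score 0–3 with probabilities
  0.10/0.25/0.40/0.25).
* **Reproducibility.** All randomness descends from a single root seed via
  named SHA-256-derived substreams per stage, so identical configurations
  give bit-identical cohorts, and partial re-runs of individual stages from
  persisted intermediates match the one-shot run.

## What passing tests do and do not show

The generator's mirror symmetry, uniform baseline, and exactly enforced
contrast make segmentation exactness provable; real DWI has bias fields,
asymmetric anatomy, registration error and hemorrhage, none of which are
modelled, so Dice = 1 on symmetric-noise fixtures says nothing about
clinical segmentation accuracy. Likewise the proportional-odds generator
matches the fitted model family by design, so parameter recovery and CI
coverage validate the estimation machinery, not the biological adequacy of
proportional odds. Statistical properties checked at scaled-down problem
sizes (32³ grids, 100–200 replicates) are stated as such in the tests.

## Numerical choices and edge cases

* Segmentation threshold comparison is `≥` (boundary inclusive); voxels with
  undefined mirror reference are excluded and counted.
* Brunner–Munzel with zero rank variance (all tied or complete separation)
  returns signed infinity and a degeneracy flag instead of raising; batch
  mapping never throws on degenerate regions.
* Logistic/ordinal optimizers use gradient tolerances of 1e-10 / 1e-8;
  ordinal fits report favorable-direction coefficients by negating the
  statsmodels threshold parameterisation.
* Tertile classification puts ⌈n/3⌉ regions in high; ties broken by region
  id ascending; infinite z sorts above all finite z.
* DeLong with zero variance of the AUC difference (e.g. identical scores)
  returns z = 0, p = 1, flagged degenerate.

## Known limitations

No registration, no hemorrhage or hemicraniectomy handling, no hemispheric
dominance, no voxel-level spatial inference (cluster/TFCE), no multiple
imputation, and no claim that the synthetic anatomy resembles real vascular
territories. The ordinal-model c-statistic comparison uses a bootstrap
because a DeLong-type variance for ordinal concordance is not defined here.
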