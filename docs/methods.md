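# Methods

## Kinetic maps

Breast DCE protocols with high spatial but low temporal resolution sample
three timepoints: pre-contrast `S0`, early post-contrast `S1` (nominally
2.5 min after injection) and late post-contrast `S2` (nominally 7.5 min).
Two voxel-wise summaries capture the enhancement-curve shape without a
pharmacokinetic model:

- `PE = 100 (S1 − S0) / S0` (percent; negative values preserved),
- `SER = (S1 − S0) / (S2 − S0)` (dimensionless; >1 washout, ≈1 plateau,
  <1 persistent uptake).

PE is undefined (excluded, not clamped) where `S0 ≤ 0`. SER validity
requires both `S1 − S0 > noise_floor` (the voxel genuinely enhances) and
`|S2 − S0| > noise_floor` (the denominator is resolvable). Without this
gate, near-zero denominators in unenhancing stroma produce unbounded
ratios that dominate band means; the acquisition literature does not fix a
convention here, so the gate is explicit, configurable, and recorded in the
output provenance. `noise_floor` defaults to 0 intensity units; phantom
analyses set it to 3× the simulated intensity noise SD. An optional SER cap
exists but is off by default. Whether non-enhancing voxels should enter SER
band averages at all is a policy choice, controlled by the validity mask
and flagged in configuration.

Curve classification (washout / plateau / persistent / non-enhancing) uses
a plateau band of SER ∈ [0.9, 1.1] and an enhancement floor of PE = 10%.

## Segmentation

**Tumor.** Voxels with PE ≥ 70% on the first post-contrast image, the
established empirical criterion matching radiological assessment. The
comparison is inclusive (≥) — the boundary convention is unstated in the
clinical criterion and had to be fixed. Candidates are restricted to the
breast support region (in air the baseline signal is pure noise and PE is
meaningless), and the largest 26-connected component is kept by default —
the targeted lesions are single masses; `all` and `seeded` policies cover
multifocal cases.

**Breast support.** By default a 3-class Otsu partition of the
pre-contrast volume (air | suppressed fat | gland); everything above the
lowest boundary is breast. An externally supplied mask is accepted and
preferred on real data.

**Fibroglandular tissue.** Fuzzy C-means on pre-contrast intensities of
breast voxels: standard alternating updates
(`u_ik ∝ (1/d_ik²)^(1/(m−1))` normalised per voxel; centroids are
`u^m`-weighted means), k-means++-style seeded initialisation, deterministic
given the seed. Defaults: 2 clusters, fuzzifier m = 2.0, tolerance 1e-5 on
the maximum centroid shift, ≤300 iterations, 3 reinitialisations on
centroid collapse. The objective is non-increasing across iterations (a
property test asserts this on every run), and at m → 1⁺ the partition
agrees with hard k-means. Whether the original tool clustered pre- or
post-contrast intensities, and with how many clusters, is not documented;
both are configurable and logged. The highest-intensity centroid is
labelled fibroglandular (fat is dark on fat-suppressed T1 imaging);
centroid ties break deterministically toward the lower cluster index.
Tumor voxels are always removed from the stromal mask.

## Proximity map and distance bands

Distances are center-to-center voxel distances in mm with anisotropic
spacing, computed by the exact Euclidean distance transform
(`scipy.ndimage.distance_transform_edt` with `sampling=spacing`); no
sub-voxel surface model is attempted. Tumor voxels carry distance 0 and are
excluded from banding.

Bands are half-open `[lo, hi)` in 5-mm steps over 0–40 mm: d = 5.0 mm
belongs to 5–10, d ≥ 40 mm is ignored entirely. A voxel contributes to a
band when it is fibroglandular, channel-valid and non-tumor; PE and SER
therefore have separate voxel counts per band. A band mean is defined only
when its count is positive.

The **global** summary is the *unweighted* mean of the defined band means
over the seven 5–40 mm bands — each shell counts equally regardless of its
voxel count, so thin distal shells are not swamped by bulky proximal ones;
a voxel-weighted variant is available behind a flag. The **periphery**
summary is the 0–5 mm band, excluded from the global value. The exclusion
of the periphery happens at aggregation time, not by erosion of the
fibroglandular mask (an erosion-based partial-volume correction is a known
omission, listed under limitations). Measurable **stromal size** is the
fibroglandular voxel count within 0–40 mm times the voxel volume (cm³).

The band aggregator takes any registered scalar volume, so maps other than
PE/SER (e.g. ADC) can be banded unchanged; no diffusion modelling is
included.

## Digital phantom

The phantom emulates a sagittal fat-suppressed breast acquisition: an
80×80×44 grid at 1.5×1.5×2.0 mm (≈2 mm slices) holding an ellipsoidal
tumor (9 mm radii) with washout kinetics (PE 120%, SER 1.8), a stromal
shell out to 42 mm whose noiseless fields are linear in distance d —
PE(d) = 30 − 0.399·d percent and SER(d) = 0.60 + 0.0022·d — a 6-mm
adipose rim (PE 3%, S0 = 60), and air (S0 = 5) outside the breast surface.
The radial gradients reproduce the qualitative stromal pattern the method
is designed to measure: enhancement decaying away from the tumor with a
weak opposing SER trend. Post-contrast volumes are back-computed from the
target fields (`S1 = S0(1 + PE/100)`, `S2 = S0(1 + PE/(100·SER))`), so the
kinetic maps invert them exactly; ground-truth band means are the
noiseless field averaged per band. Tumor PE is far above the 70% threshold
so segmentation recovers the true mask on noiseless data.

Noise is additive Gaussian on all three volumes (SD = σ × stromal S0),
chosen over Rician for analytic tractability in the high-SNR regime of
breast imaging at these field strengths. What the phantom does **not**
emulate: real breast anatomy (ducts, Cooper ligaments, heterogeneous
gland), coil/bias fields, motion, partial-volume mixing at tissue
interfaces. Passing phantom tests therefore demonstrates correctness of
the computational chain, not robustness to anatomical complexity.

## Cohort simulator

Per-subject band-mean PE at the seven 5–40 mm band midpoints follows a
linear mixed model: fixed intercept 25% and slope −0.399 %/mm, subject
random intercept SD 5%, random slope SD 0.1 %/mm, residual SD 2% —
magnitudes consistent with the stromal measurements the method produces.
Subject-level predictors: global SER ~ Normal(0.7, 0.15); tumor volume
log-normal with median 16.5 cm³ and IQR ≈ 5.8–43 cm³ (matching reported
cohort tumor-size distributions). Survival is exponential with log hazard
linear in mean-centred predictors (centring only rescales the baseline
hazard; Cox coefficients are unchanged); censoring is uniform over a
120-month follow-up. Baseline hazards were calibrated once so censoring is
≈30%: 0.040 events/month for the heavy-tailed volume predictor, 0.027
otherwise. All-censored draws are resampled with a logged seed advance and
fail after 5 attempts.

## Statistics

- **Radial trend:** `value ~ distance` with per-subject random intercepts
  and slopes, fitted by REML (the ML/REML choice is not externally
  constrained; REML is the unbiased-variance default). If the
  random-effects covariance is singular the model falls back to a random
  intercept only, recorded in `fallback_`; a single subject reduces to
  OLS. With a two-level group factor the model becomes
  `value ~ group * distance` and per-group slopes plus their difference
  (with CI and p) are reported. Residual QQ data are exposed because mixed
  models on band means commonly show mild non-normality; no corrective
  transform is applied by default.
- **5-year status:** recurrent if the event occurred at ≤60 months;
  non-recurrent if followed event-free to ≥60 months; censored earlier →
  unclassifiable and excluded, guarding group comparisons against
  differential follow-up. The exclusion treatment is an inference from the
  way such cohorts shrink when classified, documented as an assumption.
- **Rank tests:** Wilcoxon–Mann–Whitney (unpaired) and Wilcoxon
  signed-rank (paired), two-sided; exact null distributions (by
  enumeration) below total n = 25 and normal approximation beyond.
  Hodges–Lehmann estimates are the median of pairwise differences
  (unpaired) or Walsh averages (paired); CIs invert the test via order
  statistics at exact (small n) or normal-approximation indices, matching
  the convention of R's `wilcox.test(conf.int=TRUE)`, against which they
  are frozen-oracle tested. All-tied inputs return p = 1, HL = 0, flagged.
- **Cox models:** single-predictor partial likelihood with Efron tie
  handling (the tie method is not externally constrained; Efron is the
  accurate default), via lifelines. Reported: HR per unit, Wald 95% CI,
  likelihood-ratio p — deliberately the mixed convention in which the CI
  and p can disagree near the boundary. Proportional hazards are checked
  by the scaled Schoenfeld residual test (rank time transform); undefined
  below 3 events. A sensitivity refit adds measurable stromal size as a
  covariate and reports the change in the predictor HR; |r| > 0.99
  collinearity is flagged instead of fitted.
- Significance is two-sided α = 0.05 throughout; no multiplicity
  correction is applied across the battery, matching the analysis design
  this package validates.

## Validation design and problem sizes

`scripts/acceptance.py` and the heavier tests recover known parameters
from simulation: the radial slope from 200 replicates of 50-subject
cohorts (bias within 2 Monte-Carlo SEs, ~95% CI coverage), the volume HR
(1.017/cm³, recovered within ±0.005 — the heavy-tailed predictor makes
this log-HR very well identified) and the global-SER HR (0.058/unit) at
n = 2000 with ≈30% censoring, and a 3.91-point paired shift via the HL
estimator at n = 2000 pairs (within 5%). The single-cohort log-HR for the
SER effect has an irreducible sampling SD ≈ 0.17 at these design values,
so its check is on the relative error of the log hazard. Phantom-based
suites use the default grid (≈0.28 M voxels) or a 40×40×24 coarse variant;
distance-transform exactness is asserted against a brute-force oracle on
twenty ≤12×12×6 grids.

## Known limitations

- No registration/motion correction: the three volumes are assumed
  co-registered (affine consistency is checked, nothing is corrected).
- No partial-volume (erosion) correction at the tumor boundary; the 0–5 mm
  periphery band is the most exposed to this.
- Center-to-center distances slightly overestimate distance-to-surface by
  up to ~half a voxel.
- The 5-year rule discards subjects censored before 60 months rather than
  modelling them; the Cox analyses do not have this limitation.
- Pathology class and SBR grade are treated as continuous covariates where
  used, an unusual but deliberate coding choice carried over from the
  analysis design this package validates.
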