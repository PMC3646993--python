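# stromaprox

Quantitative mapping of contrast enhancement in the **normal-appearing
stroma around breast tumors** on dynamic contrast-enhanced MRI (DCE-MRI),
with the survival statistics used to relate those measurements to
recurrence-free survival (RFS) after neoadjuvant chemotherapy.

Malignant breast tumors co-opt their surrounding stroma: angiogenesis,
immune infiltration and matrix remodelling extend beyond the visible lesion
margin. `stromaprox` measures this halo on standard clinical three-timepoint
breast DCE-MRI (pre-contrast `S0`, early post-contrast `S1` ≈ 2.5 min, late
post-contrast `S2` ≈ 7.5 min) and is aimed at imaging researchers studying
peritumoral tissue as a prognostic marker.

## Method

Per voxel, two kinetic summaries:

- **Percent enhancement** — `PE = 100 · (S1 − S0) / S0`
- **Signal enhancement ratio** — `SER = (S1 − S0) / (S2 − S0)`
  (SER > 1: washout, the malignant archetype; SER ≈ 1: plateau;
  0 < SER < 1: persistent benign-type uptake)

The spatial analysis then proceeds in four stages:

1. **Tumor mask** — voxels with PE ≥ 70% on the first post-contrast image
   (largest 26-connected component by default).
2. **Fibroglandular mask** — fuzzy C-means clustering of pre-contrast
   intensities inside the breast separates glandular from adipose tissue;
   on fat-suppressed T1 imaging the brightest cluster is glandular. Tumor
   voxels are removed: only normal-appearing stroma remains.
3. **Proximity map** — for every non-tumor voxel, the 3-D Euclidean
   distance (mm, anisotropic voxel spacing respected) to the nearest tumor
   voxel.
4. **Distance bands** — mean PE and SER in 5-mm shells from 0 to 40 mm.
   The 0–5 mm band is the *tumor periphery*; the *global* value is the
   unweighted average of the seven band means over 5–40 mm.

Cohort-level statistics: a linear mixed-effects model of band means against
radial distance (random intercept + slope per subject, REML) for the radial
trend; Wilcoxon rank tests with Hodges–Lehmann (pseudo-)median differences
and exact test-inversion CIs for group/visit comparisons under a 5-year
recurrence-status rule; and single-predictor Cox proportional-hazards
models (Efron ties, Wald CIs, likelihood-ratio p, scaled Schoenfeld PH
check) for RFS.

Because no cohort images are distributed, the package ships a digital
phantom (tumor + stromal shell + fat + air with exactly invertible
kinetics) and a cohort simulator that reproduce the statistical structure
the analysis assumes, with known ground truth at every stage.

## Worked example

```python
import numpy as np
from stromaprox import (
    PhantomSpec, generate_phantom, compute_enhancement_maps, band_statistics,
)

series, truth = generate_phantom(PhantomSpec(noise_sigma=0.02, seed=3))
maps = compute_enhancement_maps(series, noise_floor=18.0)  # 3 sigma
profile = band_statistics(
    truth.proximity, maps.pe, truth.masks.fibroglandular,
    validity_mask=maps.pe_valid,
)
for (lo, hi), m, n in zip(profile.band_edges, profile.band_mean, profile.band_count):
    print(f"[{lo:4.0f},{hi:4.0f}) mm  PE = {m:6.2f} %  ({n} voxels)")
print(f"periphery PE = {profile.periphery_mean:.2f} %")
print(f"global PE    = {profile.global_mean:.2f} %")
```

prints

```
[   0,   5) mm  PE =  28.85 %  (1568 voxels)
[   5,  10) mm  PE =  27.02 %  (3544 voxels)
[  10,  15) mm  PE =  25.04 %  (6272 voxels)
[  15,  20) mm  PE =  23.04 %  (9504 voxels)
[  20,  25) mm  PE =  21.02 %  (13592 voxels)
[  25,  30) mm  PE =  19.05 %  (17760 voxels)
[  30,  35) mm  PE =  17.07 %  (23856 voxels)
[  35,  40) mm  PE =  15.09 %  (28808 voxels)
periphery PE = 28.85 %
global PE    = 21.05 %
```

The phantom's stromal PE decays at −0.399 %/mm from 30% at the tumor edge;
the recovered band means follow that gradient (≈ 27% in the 5–10 mm band
down to ≈ 15% at 35–40 mm), the periphery band sits highest, and the global
value averages the seven 5–40 mm bands. The same call aggregates SER or any
other registered scalar map.

A command-line interface wraps the pipeline:

```bash
stromaprox simulate --out phantom/ --seed 3 --noise-sigma 0.02
stromaprox map --s0 phantom/s0.nii.gz --s1 phantom/s1.nii.gz \
               --s2 phantom/s2.nii.gz --out run/ --noise-floor 18
stromaprox stats --cohort subjects.csv --model cox --predictor global_ser \
               --out cox.json
```

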