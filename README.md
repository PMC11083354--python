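# nichecontact

Quantifies how glioblastomas relate spatially to the brain's adult
neurogenic zones — the subventricular zone (SVZ) along the lateral
ventricles and the subgranular zone (SGZ) of the hippocampal dentate gyrus —
plus the cortex, and runs the survival and association statistics that such
contact measurements feed. It is written for neuro-oncology imaging groups
who have co-registered, already-segmented label volumes (a BraTS-style tumor
segmentation and binary zone masks on a common 1 mm grid) and want fully
automated, reproducible contact metrics instead of subjective readings.

## What it computes

For each patient, on the largest connected tumor component (multifocal
tumors are analysed through their main lesion):

- center of mass **c** of the tumor core (contrast-enhancing tumor +
  necrosis), in world mm;
- minimal Euclidean distance d(c, Z) = min over zone voxels z of ‖c − z‖
  for each zone Z;
- relative tumor fraction |T ∩ Z| / |T| (percent, voxel counts) per zone;
- binary contact, defined as fraction > 0%.

Downstream statistics:

- **Maximally selected rank statistics**: for a continuous covariate x
  (e.g. SVZ distance), every observed value μ within quantile bounds
  (ε₁, ε₂) = (0.1, 0.9) is a candidate cutpoint; the standardized two-group
  log-rank statistic Z(μ) = (O − E)/√V compares x ≤ μ vs x > μ, and
  μ* = argmax |Z(μ)|. Because the maximum is selected over many correlated
  splits, the p-value is Monte-Carlo adjusted by permuting x across
  subjects: p = (1 + #{M_b ≥ M_obs}) / (B + 1).
- **Cox proportional-hazards models** (Efron ties, via lifelines): model A
  with zone fractions, model B with zone distances, kept separate because a
  collinearity screen (Pearson |r| ≥ 0.7) flags fraction-distance pairs.
- **Association tests**: 2×2 contingency chi-square with a clamped Yates
  continuity correction, Σ (max(|O−E| − min(0.5, |O−E|), 0))² / E on 1 df;
  Mann-Whitney U with midrank ties; Kaplan-Meier medians with log-rank
  comparison.

Because real MRI and clinical data of this kind are not shareable, the
package ships a synthetic cohort generator (`nichecontact.synthetic_cohort`)
that produces 3D label phantoms with controlled tumor-zone geometry and
clinical tables with survival drawn from an explicit Weibull
proportional-hazards model, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from nichecontact import (GeometryConfig, make_zone_masks, make_tumor,
                          quantify_patient, maxstat_test,
                          simulate_clinical_cohort)

geo = GeometryConfig()                       # 96 mm³ phantom, 1 mm voxels
zones = make_zone_masks(geo)
seg, truth = make_tumor(geo, zones, target_dist_svz_mm=14.0, seed=11)
rec = quantify_patient("P0", seg, zones)
print(f"distance to SVZ: {rec.dist_svz_mm:.2f} mm, "
      f"SVZ fraction: {rec.frac_svz_pct:.2f}%")

clinical, spatial, _ = simulate_clinical_cohort(n=177, seed=42,
                                                target_censored=12)
df = clinical.merge(spatial, on="patient_id")
res = maxstat_test(df.dist_svz_mm, df.os_months, df.event, B=999, seed=42)
print(f"optimal cutpoint: {res.cutpoint:.2f} mm, "
      f"max |Z| = {res.max_stat:.2f}, adjusted p = {res.p_adjusted:.3f}")
```

prints

```
distance to SVZ: 13.96 mm, SVZ fraction: 0.00%
optimal cutpoint: 10.13 mm, max |Z| = 1.64, adjusted p = 0.673
```

The tumor placed to sit 14 mm from the SVZ is measured at 13.96 mm (within
one voxel diagonal), with no overlap, hence no contact. On the simulated
177-patient cohort the cutpoint scan selects 10.13 mm; the adjusted p of
0.67 is honest about multiplicity — the cohort's distance effect is a
smooth log-linear hazard (HR 0.97 per mm), not a step, so no single
cutpoint separates survival sharply.

The `analysis/` directory holds numbered drivers that run the full
pipeline on synthetic data — simulation, quantification, cutpoint search,
Cox models, association tables — writing outputs under `results/`.

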