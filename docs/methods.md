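# Methods

## Spatial quantification

All volumes of one patient must share a grid (shape and affine); mismatches
are rejected before any metric is computed. The tumor segmentation uses
BraTS-style integer codes (1 = necrosis, 2 = edema, 4 = enhancing tumor by
default, configurable — segmentation tools name the subregions but integer
codes vary between pipelines). The *tumor core* is enhancing + necrosis; it
is both the center-of-mass mask and the default denominator of the zone
fractions. The denominator is configurable (`core` or `core+edema`) because
"whole tumor" is ambiguous in practice; all shipped analyses use `core`,
keeping fraction and center-of-mass definitions consistent.

Connected components use 26-connectivity by default; components are ordered
by size descending with lexicographic tie-break so selection is
deterministic. The minimal component size filter defaults to 1 voxel —
multifocal satellites are often tiny, and a size floor would silently
unflag them. All metrics are computed on the largest component only; a
patient is multifocal when more than one component passes the filter.

Distances are point-to-voxel-center: the minimum over zone voxels of the
Euclidean distance from the core's center of mass to the voxel center, in
world mm through the affine. This matches a zone *delineation* at voxel
resolution and has an exact brute-force oracle (exhaustive enumeration),
which the test suite exercises on random grids up to 32³ including
anisotropic spacings. Distance is deliberately measured from the center of
mass, not the enhancing edge, so a tumor can overlap a zone (fraction > 0)
while its center-of-mass distance stays positive; contact is defined purely
by fraction > 0.

Degenerate inputs: empty tumor mask, empty zone mask, or an empty core in
the main component are errors, not silent zeros.

## Maximally selected rank statistics

Candidates are the distinct observed covariate values μ with
ε₁ ≤ mean(x ≤ μ) ≤ ε₂, defaults (0.1, 0.9) — the conventional bounds that
keep both groups away from degeneracy. Each split is scored by the
standardized log-rank statistic with hypergeometric variance; tied event
times reduce the risk set simultaneously. The selected cutpoint is the
smallest candidate attaining max |Z| (deterministic tie-break).

The adjusted p-value is a permutation test: covariate values are permuted
across subjects B times (default 9999), the maximal statistic recomputed,
and p = (1 + #{M_b ≥ M_obs})/(B + 1). This add-one estimator is exact in
level under exchangeability; B = 999 is used in the calibration tests to
keep runtimes modest. Subjects are canonically re-ordered before drawing
permutations, so the p-value is invariant to input row order given a seed.

The scan is O(events × candidates) per permutation: O − E is a linear
functional of group membership with log-rank (martingale-residual) scores
δᵢ − Λ̂(tᵢ), accumulated over candidates by cumulative sums, while the
variance's per-risk-set group sizes come from a 2D histogram over
(risk-set index, candidate bin). Permutations are processed in small blocks
(default 16) — on a 177-subject cohort with ~150 candidates a B = 999
adjustment takes about half a second on one CPU. The vectorized scan is
tested for exact agreement (1e-10) with the direct per-split statistic and
against hand-computed risk-set tables; the statistic's square is checked
against an independent log-rank implementation.

## Synthetic cohorts

The generator emulates the study conditions: 177 patients, ~72% SVZ
contact, ~30% SGZ contact, ~90% cortex contact, ~30.5% preoperative
seizures, ~11% preoperative multifocality (~33% in total), median overall
survival ≈ 8 months, 12 subjects administratively censored.

**Covariates.** Age ~ Normal(64, 11) truncated to [18, 90] (reported
group-wise mean ages are mutually inconsistent; 64 is the working target);
KPS from a categorical law on 40–100 with median 80; resection
Bernoulli(0.60); MGMT methylated 0.39 / not evaluated 0.028; Ki-67
>30% 0.40 / <30% 0.32 / not evaluated 0.28. Seizure probability is logistic
in contact: logit p = −0.39 + 0.30·cortex − 1.03·SVZ, encoding the observed
directionality (cortex-contacting tumors seize more, SVZ-contacting fewer);
the coefficients are configuration, not claims about mechanism.

**Survival.** Weibull proportional hazards with inverse-transform sampling:
T = λ(−log U · e^(−η))^(1/k), centred linear predictor
η = β_age(age − 65) + β_res·resection + β_kps(KPS − 80) +
β_dist(d_SVZ − 10) + β_mf·multifocal, with default hazard ratios 1.06/yr,
0.24, 0.99/pt, 0.97/mm and 1.51 — the signs and magnitudes of the
established predictors. Baseline k = 1.1; λ = 5.5 months was calibrated
once so the default cohort's median OS is ≈ 8 months (8.0 ± 1.0 over 30
seeds). Censoring is administrative at a single horizon (default 54
months); `tune_censoring_horizon` places the horizon between order
statistics to hit an exact censored count (12 of 177 in the default
conditions). The distance entering the hazard is the *measured*
center-of-mass distance, the same covariate the analysis uses.

**Tabular layer.** For statistical recovery experiments the spatial
summaries are drawn directly: contact flags Bernoulli per zone; for contact
patients the fraction decreases roughly linearly in distance with
multiplicative log-normal noise (σ = 0.25), always strictly positive;
non-contact patients have zero fraction and larger distance. This
construction reproduces the strong negative fraction-distance correlation
(r ≈ −0.8) that forces separate Cox models, and keeps the contact ⇔
fraction > 0 identity exact.

**Volume layer.** The phantom is a 96³ grid at 1 mm: brain ellipsoid with a
3 mm cortical shell, a 2 mm SVZ ribbon around a ventricle ellipsoid, and
two bilateral SGZ blobs placed lateral-inferior to the ribbon with a 4 mm
clearance (dentate gyrus proxies adjacent to the temporal ventricle, as in
real anatomy). Main lesions are spheroids along an outward ray from an SVZ
anchor voxel; the long semiaxis is chosen so the inner end does or does not
reach the SVZ and the outer end does or does not reach the cortex,
realizing drawn contact flags constructively (SVZ and SGZ flags are strict,
with retries; rare infeasible draws re-sample geometry). Satellite lesions
(1–3 small enhancing spheres, kept clear of the main lesion) realize
preoperative multifocality. Realized metrics — center of mass, distances,
fractions, core voxel count — are recorded per patient in `truth.yaml`; the
generator-measurer agreement test requires the quantifier to reproduce them
after a NIfTI round trip (distances within one voxel diagonal, fractions
within 0.5 points, contact flags exactly; in practice agreement is exact to
float precision).

**Cutpoint-recovery probe.** `simulate_step_cohort` is a purpose-built
probe, not a cohort emulation: x ~ Uniform(4, 24) mm with an exponential
hazard twice as large for x ≤ 14 mm, administratively censored at 15 months
(~30% censoring). The step sits at the covariate median so the two groups
are balanced — the configuration in which the log-rank comparison carries
maximal information and localization error reflects the statistic itself
rather than group imbalance.

What the synthetic data do **not** emulate: MRI intensities, registration
or segmentation errors, anatomical variability of the zones, correlated
covariates (age and KPS are drawn independently), non-proportional hazards,
or informative censoring. Passing tests therefore demonstrate correctness
of the measurement and inference machinery under a known generating model,
not robustness to real-data artifacts.

## Statistical conventions

- **Chi-square**: 2×2 contingency tests use a *clamped* Yates correction —
  each |O − E| is shrunk by min(0.5, |O − E|) before squaring, so
  near-independent tables yield statistic exactly 0 and p = 1. When every
  cell deviates by ≥ 0.5 this equals the classical Yates formula, which the
  tests verify against scipy. MGMT and Ki-67 tests run on evaluated
  categories only.
- **Mann-Whitney U**: scipy's implementation (midranks; exact null for
  small tie-free samples, otherwise normal approximation with tie-corrected
  variance and continuity correction), verified against exact-enumeration
  and permutation oracles. An all-identical comparison reports p = 1 with a
  warning.
- **Cox models**: lifelines, Efron ties. Rows with unknown resection or
  unevaluated MGMT are excluded from models using those covariates — no
  imputation scheme is assumed. Resection is binary (any resection vs
  biopsy), KPS numeric 10–100, MGMT binary methylated. Non-convergence is
  raised, never swallowed.
- **Kaplan-Meier medians** are the earliest time with S(t) ≤ 0.5, undefined
  (None) when the curve never crosses 0.5.
- A generic two-sample Welch t test is exposed alongside the association
  tests for completeness but is not part of the contact summary pipeline,
  which uses chi-square, Mann-Whitney and log-rank throughout.

## Problem sizes in the shipped checks

The test suite and acceptance script run entirely on synthetic data at
sizes chosen to make their Monte-Carlo assertions statistically meaningful
on a single CPU: 100 random instances for the spatial oracles, 200 null
repeats at B = 999 for the level of the adjusted cutpoint test (binomial
99% band), 100 seeds for the ±2 mm step-localization rate and for Cox CI
coverage at n = 500, and a 50-patient volume cohort for generator-measurer
agreement.

## Known limitations

- The phantom's zones are smooth ellipsoid derivatives; real SVZ/SGZ atlas
  masks are thin, folded and noisy, so fraction values near 0% (the regime
  of the smallest published cutpoints) are under-represented.
- The constructive lesion placement realizes contact flags but not a target
  *distribution* of fractions or distances; cohort-level geometry summaries
  are emergent, not controlled.
- The Monte-Carlo adjustment assumes exchangeability of the covariate
  across subjects under the null; covariate-dependent censoring would
  break it.
- Cutpoint selection reports observed covariate values; between-value
  resolution is limited by the cohort's covariate spacing.
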