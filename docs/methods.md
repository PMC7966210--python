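# Methods

## The measurement model

ASPECTS quantifies early ischemic change on non-contrast CT (NCCT) of the
brain: ten regions per hemisphere — four deep structures (caudate nucleus CN,
internal capsule IC, insula INS, lentiform nucleus LN) and six cortical
middle-cerebral-artery territories (M1–M6) — are each scored normal or
affected, and the score is 10 minus the number of affected regions.

`autoaspects` automates the reading as a density measurement:

1. **Probabilistic atlas.** Each region/hemisphere is a scalar likelihood
   map w(x) ∈ [0, 1] on a shared grid (20 maps). The maps are fuzzy, not a
   hard segmentation: no per-voxel normalization across regions is imposed,
   and adjacent regions may share support voxels.
2. **HU inclusion window.** Voxels below 10 HU (CSF, chronic infarcts) or
   above 55 HU (calcification, bone) are excluded from every regional
   measurement. Bounds are inclusive: 10 HU and 55 HU are kept, 9.99 and
   55.01 are not.
3. **Weighted regional mean.** For region r on side s,
   μ(r, s) = Σᵢ wᵢ·HUᵢ / Σᵢ wᵢ over support voxels (w > 0) passing the
   window. A region whose support is entirely excluded has no mean; by
   default this is a hard error, and a tolerant mode flags the region
   unmeasurable instead (it then never counts as affected).
4. **Relative difference.** d(r) = 100 · (μ_contra − μ_affected) / μ_contra,
   in percent, positive when the affected side is hypodense. The healthy
   (contralateral) side is the denominator so the thresholds read as
   minimum detectable relative hypodensities.
5. **Hemisphere detection.** S(side) = Σ_r max(0, d_r(side)) summed over the
   10 regions; the side with larger S is called affected, exact ties go to
   the left. The margin S(winner) − S(loser) is reported. The detected side
   can be overridden (clinically the affected side is usually known).
6. **Classification and score.** Region r is affected iff d(r) ≥ t(r); the
   boundary is inclusive so a threshold acts as a minimum effect size.
   Score = 10 − #affected.

Default thresholds are the specificity-constrained optimized values: 5.6%
for the central group (CN/IC/INS/LN), 4.7% for the cortical group (M1–M6)
in `grouped` mode, and 4.9% for all regions in `single` mode. A
`per_region` mode accepts an explicit 10-entry map.

Regional means are computed in 3D over the full region volume (no per-slice
convention), and the relative difference always uses the contralateral mean
as denominator; both are deliberate fixed conventions of this
implementation.

## Registration

Scoring operates in atlas space. `identity` mode (default, and the phantom
path) asserts the volume is already on the atlas grid. `affine` mode
estimates a similarity transform (translation, small rotation, isotropic
scale): translation and scale are initialized from the first and second
moments of the brain-tissue mask (voxels in the 10–55 HU window) against
the atlas brain box, then refined by maximizing the Dice overlap between
the forward-transformed atlas box and the tissue mask with Nelder–Mead from
a deterministic start. The fit assumes the head is fully inside the field
of view — a tissue box clipped by the grid edge leaves the similarity
underdetermined along the clipped axes. Atlas resampling is trilinear with
weights clipped back to [0, 1]; the identity transform reproduces the maps
bit-exactly, and integer-voxel translations are exact at interior voxels.

## Synthetic atlas and CT phantoms

No public NCCT dataset with regional ratings exists for this task, so the
package ships generators whose defaults define the test conditions.

**Atlas.** Ten spherical blobs per hemisphere on a 5×2 lattice of cells in
the sagittal plane; each blob has a hard core (w = 1) and a linear ramp to
0 over a `margin` of 2 voxels (a margin of 0 gives hard binary maps for
closed-form tests). Cores are pairwise disjoint by construction; the seed
jitters centers within cells (±1 voxel). Right maps are exact mirror images
of left maps across the mid-sagittal plane (array axis 0); with an odd
left–right dimension the central column carries zero weight. Grids below
roughly 48×48×24 cannot hold ten disjoint cores at the default margin and
raise a sizing error. The ramp profile is a convenience for exercising the
fuzzy-mean code path, not a model of any vendor atlas.

**Phantoms.** Background parenchyma is N(35, 1.5²) HU everywhere (no air,
no skull — measurements only read region supports). A lesion in region r at
relative drop δ% subtracts 35 · (δ/100) · w(x), so hard-weight voxels carry
the full drop and the measured relative difference equals δ exactly in the
noise-free limit; with fractional weights the measured difference is
attenuated by Σw²/Σw (≈ 0.78 for the default atlas), which is intentional —
partial-volume-like dilution at region borders. Contamination replaces a
fraction of each region's support voxels with CSF-like U[0, 9] HU or
calcification-like U[60, 100] HU values; both lie outside the inclusion
window, so they must not move any regional mean, and they never alter
ground truth. All lesions of one phantom lie on a single hemisphere.

**Cohorts.** Per patient: affected-region count uniform on 0..10, side
Bernoulli(0.5), per-region drop uniform on 2–15%, contamination fractions
0.05 + 0.05. The drop range is a simulation choice (no published effect-size
distribution for early ischemic hypodensity exists), and under these
defaults the affected and normal relative-difference distributions barely
overlap: fitted thresholds therefore generalize with held-out specificity
near 1.0 rather than hovering at the 90% training floor. Passing tests
consequently demonstrate correctness of the machinery (floor satisfied on
training data, no degradation on held-out data), not the clinical
operating point of real NCCT, where noise, registration error and anatomy
compress the separation.

## Threshold training

Observations are (patient, region) rows with the measured relative
difference and a binary reference status. The train/test split samples
patients (never regions) within strata, rounding the per-stratum train
count to the target fraction (deviation ≤ 1 patient per stratum);
single-patient strata go wholly to one side with a warning, so the realized
overall fraction can drift from the target. ROC candidate thresholds are
the distinct observed differences plus ∓∞ sentinels; AUC uses the
Mann–Whitney midrank formulation, and its 95% CI a seeded patient-level
(cluster) bootstrap, 2000 replicates by default, because the 10 regions of
a patient are correlated. Threshold selection maximizes sensitivity subject
to specificity ≥ the floor (default 0.90, applied before any rounding),
with ties broken by higher specificity and then by smaller threshold;
candidates here exclude the infinite sentinels, since "classify nothing"
is not a usable operating point — this keeps the infeasibility error
(reporting the maximum achievable specificity) meaningful. Grouped fitting
optimizes the central and cortical pools separately; single fitting pools
all regions.

## Agreement statistics

Confusion counts treat "affected" as positive; sensitivity, specificity and
accuracy are reported as integer percentages rounded half away from zero
(711/798 → 89, 353/622 → 57). Trichotomized agreement bands the score into
0–4 / 5–7 / 8–10 and counts patients whose bands match. ICC(1,1) — one-way
random effects, absolute agreement, single rater — is computed from the
ANOVA mean squares, ICC = (MSB − MSW)/(MSB + (k−1)·MSW), with 95% CI from
the F-distribution bounds FL = F/F₀.₉₇₅;n−1,n(k−1) and
FU = F·F₀.₉₇₅;n(k−1),n−1, bound = (F• − 1)/(F• + k − 1). Bland–Altman
reports the mean paired difference and limits of agreement
mean ± 1.96·SD (SD with n−1); published intervals of this width around a
small mean at large n are limits of agreement, not a CI of the mean, and
are interpreted as such here.

## Numerical choices and degenerate inputs

- Exact threshold ties classify as affected (inclusive ≥).
- Hemisphere ties (S_left = S_right) resolve to left, deterministically.
- Weighted means skip w = 0 voxels before HU testing, so the excluded-voxel
  count refers to support voxels only.
- All generators and resampling procedures take explicit integer seeds;
  identical seeds reproduce volumes, cohorts, splits and bootstrap CIs
  bit-for-bit.
- Zero-variance rating data makes ICC undefined (error), except the exact
  pred == ref case which reports ICC 1 by convention.
- Problem sizes used by the shipped validation runs: 64×64×32 voxel grids,
  400-patient cohorts for threshold training, 100 phantoms for hemisphere
  detection, n = 2000 for ICC recovery — sizes at which every Monte Carlo
  check is stable at its stated tolerance.

## Known limitations

- No CT physics: noise is i.i.d. Gaussian (no streaks, beam hardening or
  slice-thickness partial volume), and phantoms have no skull or CSF spaces
  beyond the injected contamination voxels.
- The affine registration is a documented stand-in for an unpublished
  vendor fitting step; it handles similarity transforms of a fully
  contained head, nothing deformable.
- The hemisphere-detection rule (sum of positive relative differences) is
  this package's own deterministic definition of "the more hypodense side".
- Synthetic validation bounds software correctness, not clinical accuracy;
  the printed-count reproductions check the statistics pipeline against
  published summaries, and the ICCs of the original study cannot be
  recomputed without the per-patient clinical ratings.
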