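# Methods

`airwayct` quantifies two CT biomarkers of smoking-related airway disease
from low-dose chest CT — airway wall thickness at a fixed internal lumen
diameter (AWT_3.5) and recalibrated lung densitometry (Perc15, %LAA−950) —
and links them to airflow limitation with ordinary least squares. Because
screening-cohort CT data are not redistributable, the package ships two
synthetic-data generators that define its study conditions: a digital CT
phantom of airway trees in parenchyma, and a simulated heavy-smoker cohort.
This note records the models, the tunable parameters, the numerical
choices, and what the synthetic conditions do and do not establish about
real data.

## Airway wall measurement

### Model

An airway cross-section perpendicular to the local centerline direction is
probed with `n_rays` (default 32) radial HU profiles sampled by trilinear
interpolation at `ray_step_mm` (default 0.1 mm) out to `ray_len_mm`
(default 5 mm). On each ray:

1. **Inner (lumen) border.** Detection uses the classical half-maximum
   rule against the observed ray peak: the first rising crossing of
   `(hu − hu_air)/(hu_peak − hu_air) = 0.5`. Referencing the *observed*
   peak rather than the nominal wall density matters for sub-millimetre
   walls: at the protocol blur a 0.4 mm wall's peak reaches only ~50% of
   the true wall density, so a crossing defined against the nominal density
   would often not exist at all.
2. **Wall center.** The wall-center radius `m` is the midpoint of the
   rising half-crossing and the falling half-crossing toward the
   parenchyma baseline. For a blurred wall the two crossings are biased in
   opposite directions by the overlap of the two edges, so their midpoint
   is a stable estimate of the wall midline. Rays whose outer side is
   occluded (no visible parenchyma) borrow the section's median half-width.
3. **Refined inner radius.** `r_inner = m − ∫₀^m ñ(r) dr` with
   `ñ = clip((hu − hu_air)/(W − hu_air), −0.5, 1)` and `W` the wall
   reference density. For a symmetric blur kernel, the wall-side mass lost
   before the true edge equals the lumen-side mass gained after it, so
   this partial-volume integral recovers the sharp edge position for any
   blur width. The raw half-maximum crossing is biased inward by roughly
   0.1–0.25 mm for 0.4–0.6 mm walls at protocol blur — enough to push a
   true 3.5 mm lumen out of the 3.5 ± 0.25 mm selection band — which is
   why the refinement, not the crossing, provides the radius.
4. **Integral-based wall thickness.** With the baseline `b(r)` equal to
   the lumen air density before the wall peak and the local parenchyma
   density (median HU of the distal 1 mm of the ray) after it,

   `AWT_ray = Δr · Σ clip((hu − b)/(W − b), −0.5, 1)`

   over the window `[r_inner − w, r_peak + w]` (default `w` = 2 mm). The
   integral of a blurred wall equals the integral of the sharp wall, so
   the estimate is robust to the reconstruction kernel and to
   partial-volume effects that make edge-to-edge calipers overestimate
   thin walls.
5. **Outer-border detectability.** A ray is *assessed* when the profile
   descends below `P + f_out · (W − P)` (default `f_out` = 0.5) within
   `d_max` = 2 mm beyond the wall peak, i.e. when no adjacent tissue of
   wall-like density blocks the outer border, and when the local
   parenchyma estimate itself is at least 200 HU below the wall reference
   (otherwise the ray sees no parenchyma at all).

Per section: internal diameter = 2 × mean inner radius over rays with an
inner border (the mean-radius convention, not the equal-area diameter —
for an elliptical lumen they differ); APF = assessed rays / all rays; AWT
= mean thickness over assessed rays. Sections keep only if at least half
the rays yield an inner border. Locations with internal diameter within
`3.5 ± 0.25` mm and APF ≥ 0.25 enter the analysis; per-lobe and whole-lung
AWT are APF-weighted means, the whole lung using the symmetric five-lobe
formula `Σ(AWT_lobe · APF_lobe)/Σ APF_lobe`.

### Numerical choices

* **Wall reference density `W`**: default 0 HU (soft tissue ≈ water). A
  per-section "robust peak" estimate (95th percentile of ray peaks) is
  available (`hu_wall_ref="auto"`), but at protocol blur the observed peak
  of a sub-millimetre wall underestimates the true density by up to a
  factor of two, which would inflate the HU-integral thickness by the same
  factor; a fixed soft-tissue reference keeps the integral calibrated.
  A global calibration drift of ±25 HU changes the thickness by ~2.5%
  (≤0.02 mm), and the densitometry path removes such drift anyway.
* **Clip bounds `(−0.5, 1)`**: the upper bound caps the integrand at the
  wall density; the lower bound admits symmetric negative excursions so
  zero-mean image noise cancels instead of rectifying into a positive
  thickness bias (with a zero floor, low-dose vs high-dose scans acquire a
  small but systematic thickness offset). Noise-free profiles never fall
  below their baselines, so the bounds do not affect clean-profile
  results.
* **Bifurcation exclusion**: positions within 2 mm of a branching end of
  a branch are skipped; perpendicular planes are ill-defined there.
* **Sampling**: positions equally spaced along the centerline at
  `centerline_step_mm` (default 1 mm), endpoints inclusive.
* **Defaults are the protocol constants**: target diameter 3.5 mm,
  tolerance ±0.25 mm, inclusion threshold APF ≥ 0.25, −950 HU LAA
  threshold, 15th percentile.

### Centerline extraction

Centerlines come either from phantom ground truth or from the label
volume: the lumen mask (trachea + airway labels) is skeletonized
(3-D thinning), the skeleton graph decomposed into arcs between junction
clusters and endpoints, leaf spurs shorter than 2 mm pruned and
pass-through junctions re-merged, and generations assigned by
breadth-first depth from the trachea-top root (trachea = generation 0).
Voxel chains are smoothed (5-point moving average) and resampled at
0.5 mm. One degeneracy is handled explicitly: 3-D thinning can fully erode
a tube whose axis lies exactly between voxel centers; in that case the
mask is re-skeletonized after a half-voxel in-plane shift and the skeleton
shifted back.

## Densitometry

HU values are recalibrated by shifting the entire scan so the mean HU in
the (2-voxel-eroded) trachea mask equals −1000; erosion keeps
partial-volume wall voxels out of the air estimate. Perc15 is the 15th
percentile (linear interpolation between order statistics, the "type 7"
convention) of lung voxels with the airway lumen, dilated by one voxel,
excluded before the denominator is formed. %LAA−950 is the percentage of
those voxels below −950 HU; its natural log is reported with values below
0.1% floored to 0.1% so emphysema-free subjects remain finite. Lung volume
is voxel count × voxel volume.

## The digital phantom

The phantom realizes the acquisition geometry of a low-dose screening
protocol: in-plane pixel spacing = FOV/matrix (0.59–0.68 mm at 300–350 mm
FOV and a 512 matrix), 1 mm slices at 0.7 mm increments, soft-kernel blur
modeled as an isotropic in-plane Gaussian PSF (default FWHM 0.7 mm) plus
boxcar slice-thickness averaging, and additive Gaussian noise (defaults:
25 HU low dose, 10 HU high dose — plausible for ~20 mAs vs diagnostic
exposure; only the ordering matters to the tests).

Rendering is done on a supersampled grid (fine spacing ≤ ~0.18 mm,
reduced automatically for large scenes), the PSF applied there, and the
acquisition grid read out by decimation. This mimics how the scanner's
continuous PSF-blurred signal is sampled by reconstruction; composing
directly on the acquisition grid would let a 0.6 mm wall vanish entirely
between 0.68 mm voxel centers.

Tissue densities: lumen/trachea air −1000 HU, wall 0 HU, parenchyma
−880 HU with a smooth ±15 HU texture field (correlation length 1.5 mm),
emphysema −980 HU, outside-lung background +20 HU. The texture serves two
purposes: real parenchyma is not uniform, and a continuous density
distribution keeps the percentile ground truth strictly monotone in the
emphysema fraction. Emphysema is placed as spheres of radius 2–6 mm
(coherent low-attenuation areas, like centrilobular disease) from a fixed
placement stream, so a larger target fraction strictly extends the blob
set of a smaller one. An `adjacent_vessel` is a wall-density collar
subtending an exact angular fraction of the outer perimeter, so the
occluded fraction in APF experiments is known by construction.

The five-lobe tree template arranges a trachea, main bronchi and a
bronchus intermedius, then one monopodial path per lobe with a short stub
sibling at every junction (so each internal node bifurcates). Per
generation, lumen diameters default to 12, 9, 7, 5.6, 4.5, **3.5**, 2.8,
2.2 mm (generations 0–7; wall thickness = 0.18 × diameter), placing the
3.5 mm caliber at generation 5. Representative branch lengths per
generation form a dome peaking at that generation: a one-path-per-lobe
tree cannot carry the 2^g branches of a real dichotomous tree, so the
representative length stands in for the abundance of measurable airways —
rising branch count × falling detectability — which in real lungs
concentrates assessable wall perimeter around the 3.5 mm caliber. The
lung region is an analytic elliptic cylinder wrapped around the tree
(volume known in closed form), partitioned into lobes by nearest lobe
path.

## The simulated cohort

One row per subject. Structure:

* `log AWT_3.5 ~ Normal(log 0.57, 0.385)` and
  `Perc15 ~ Normal(−920, 17.0)`, bivariate with correlation ρ = 0.13.
  The log-scale and HU-scale SDs are recovered from printed interquartile
  ranges via `IQR = 2·z(0.75)·SD`. ρ is **an assumption**: no correlation
  is printed anywhere, so it is derived from the univariate regression
  slope of log-AWT on Perc15 (0.003 per HU) and the two SDs.
* `FEV1%pred = β₀ + β₁·logAWT + β₂·Perc15 + ε`, with β₁ = −31.28 %pred
  per log-mm and β₂ = 0.342 %pred per HU; β₀ is solved so the mean is
  98.2 at the covariate means, and `sd(ε)` (≈15.1) so the total SD is
  19.7. With these inputs the sequential variance decomposition of a
  simulated cohort lands near 33% for log-AWT and 8% for Perc15 without
  any further tuning.
* Symptoms (chronic mucus hypersecretion, cough, dyspnea, wheezing) are
  Bernoulli with logistic probability in log-AWT; the slope (default 1.3
  per log-mm, a free parameter chosen to reproduce a ~0.1 mm median AWT
  gap between symptomatic and asymptomatic subjects) and the intercepts
  are solved numerically (Gauss–Hermite expectation + bisection) to match
  the target prevalences (29.7/32.7/28.4/25.3%).
* Pack-years are log-normal with median 34.0 and quartiles (28.0, 45.6)
  (the printed IQR is right-skewed); current smoking is Bernoulli(0.591);
  age is Normal(59.4, 5.2).
* %LAA−950 is a fixed monotone log-linear map of Perc15 (lower Perc15 →
  more LAA), giving a log-normal marginal with median 2.5% and quartiles
  (1.3, 4.3). FEV1 (L) and FEV1/FVC are descriptive affine transforms of
  FEV1%pred calibrated to means 3.45 L and 70.0%.

## Statistics

Descriptives are mean ± SD or median (Q1–Q3) for flagged skewed columns
and percentages for booleans. Group contrasts: Mann–Whitney U (exact p
for group sizes ≤ 20, normal approximation with continuity correction
above), Student's t, chi-square on 2×2 counts, Wilcoxon signed-rank for
paired lobe contrasts. Regression is OLS with natural-log transforms for
AWT and %LAA (the log base affects coefficients, not p-values or R²); the
multivariable entry gate (univariate p < 0.05) is provided as a helper the
caller may override. Variance explained is reported under **both**
conventions, labelled: sequential R² increments in the stated term order
(they sum exactly to the full-model R²; AWT entered first is the headline)
and squared semi-partial correlations from the full model. No
multiple-testing correction is applied (working α = 0.05). Bland–Altman
agreement: bias = mean difference, limits = bias ± 1.96 SD, with a
one-sample t-test of the differences.

## What the synthetic conditions establish — and what they do not

Passing tests establish that the measurement chain is *internally
correct*: thickness recovery within ≤0.1 mm median error on walls
0.4–0.9 mm at protocol blur and noise, blur-robustness over FWHM
0.5–1.0 mm, exact APF bookkeeping under known occlusion, densitometry
that matches sort-based oracles and is invariant to calibration drift,
and regressions that recover their generating coefficients at nominal
rates. They do not establish performance on real lungs: the phantom has
straight circular branches, piecewise-constant tissue densities, Gaussian
noise and blur, no cardiac or respiratory motion, no mucus, no
reconstruction artifacts; the cohort simulator encodes the target
population's first and second moments and one structural equation, not
the unknown full joint distribution. Problem sizes (tube length 30–60 mm,
a 150 mm FOV / 220-matrix tree, 8 dose pairs, 40 regression seeds) were
chosen so the full suite runs comfortably on a single CPU while leaving
the per-quantity Monte-Carlo error well below the tolerances being
checked.

## Known limitations

* Generations are topological (depth from the trachea), not anatomical
  airway naming; stub siblings in the phantom occupy one generation each.
* The skeleton-based extractor is validated on phantom trees with clean
  labels; heavily noisy lumen segmentations would need stronger pruning.
* The inner-radius refinement assumes an approximately symmetric blur
  kernel and a wall that is locally straight at the blur scale; residual
  diameter bias is ≤0.1 mm for the calibers studied, and is a systematic
  (not random) error shared by all subjects.
* The −0.5 clip floor is a compromise: fully unbounded integrands would
  be noise-unbiased but sensitive to dark structures (emphysema) abutting
  the wall window.
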