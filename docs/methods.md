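# Methods

This document specifies the forward model, the estimators, the figures of
merit, and the simulation machinery implemented in `mewpdq`, together with
every default parameter, its units, and the reasoning behind the main
numerical choices.

## 1. Problem statement

A patient treated with Thorium-227 also carries its decay product
Radium-223. Both isotopes emit photons over overlapping energy ranges, so
planar/SPECT measurements in any energy window contain *crosstalk*: counts
from both isotopes. The clinical quantity of interest is the mean activity
concentration of each isotope in a small set of volumes of interest (VOIs)
— background soft tissue, pelvic bone, gut, and a bone lesion — at
count levels far too low for artifact-free voxel reconstruction.

`mewpdq` implements a projection-domain estimator (MEW-PDQ): the regional
uptake of both isotopes is estimated jointly, by maximum likelihood, directly
from the multi-energy-window projection data, without reconstructing images.

## 2. Forward model

### 2.1 Emissions and detector energy response

Each isotope is a line spectrum (bundled TSV data): Th-227 and the Ra-223
chain in secular equilibrium, photon energies in keV with absolute
intensities (photons per decay). The detector has Gaussian energy response
with FWHM = 9.8% of 140 keV scaled as sqrt(E/140) (NaI behavior). The
probability that a photon of line *l* is recorded in energy window *w* is
the Gaussian mass of the line inside the window; per isotope and window
these sum to an *effective window weight*. Four acquisition windows are
used by default (keV, half-open):

| window | range | role |
|---|---|---|
| 1 | [74, 94) | shared X-ray region (both isotopes) |
| 2 | [140, 168) | low-intensity region |
| 3 | [216, 256) | Th-227 236 keV photopeak |
| 4 | [256, 288) | Ra-223 chain ~270 keV region |

The spectral separation between windows 3 and 4 is what makes the joint
two-isotope problem well conditioned; window 1 alone leaves the isotopes
nearly unidentifiable (CRLB-NSD in the hundreds of percent, see
`examples/window_design_study.py`).

### 2.2 Geometry and physics

The scanner is a parallel-hole system rotating around the patient axis:

* `n_angles` views over 360° (60 at reference scale, 24 at desk scale);
* acquisition time 1800 s total;
* intrinsic resolution 3.9 mm FWHM;
* collimator resolution slope 1.26 mm FWHM per cm distance
  (from the modeled system's published ~13.2 mm system FWHM at 10 cm and
  3.9 mm intrinsic: sqrt(13.2² − 3.9²)/10);
* orbit radius 150 mm (a body-contour orbit for a pelvis);
* attenuation from a three-class (air / soft tissue / bone) map scaled
  per effective window energy using a bundled mass-attenuation table;
  bone density 1.40 g/cm³ (whole pelvic bone: spongiosa-dominated average,
  not cortical);
* a broad-Gaussian scatter surrogate per window (scatter-to-primary
  fractions 0.3 / 0.2 / 0.15 / 0.1, 60 mm FWHM in the detector plane);
* stray-radiation background: Poisson with window-block-constant mean,
  0.1 counts/bin per 10 min in window 3, other windows scaled by width;
* Poisson counting noise.

The projector applies, per view: in-plane rotation into the detector
frame, depth-dependent attenuation (precomputed per window), summation
into a small number of depth groups each blurred with its Gaussian
detector response, the scatter surrogate, and the sensitivity x time
scale. Every stage is linear with an **exact adjoint**: the rotation is a
sparse matrix whose transpose is the adjoint, and the blurs are symmetric
Toeplitz matrices (self-adjoint). The rotation is implemented in
*push-forward (splat)* form — each voxel distributes its content over the
four detector-frame pixels around its rotated position with bilinear
weights summing to one — so expected counts per view are conserved
exactly for content inside the field of view. (The gather form fails this
by up to 27% for a point source, which is why it is not used.)

Not modeled (documented generator limits): septal penetration, lead
X-rays, detector backscatter, dead time, depth-dependent scatter shape,
energy-dependent intrinsic efficiency, organ-specific kinetics.

### 2.3 Count-level calibration

The sensitivity scale is calibrated once per study so the standard
phantom produces `target_total_counts = 2e5` expected *signal* counts
(all windows, both isotopes, stray background excluded) over the full
acquisition — the low-count regime the method targets. The calibrated
scale is then held fixed for every patient and condition in that study,
as a physical scanner's would be.

## 3. Regional system matrix and estimator

For K VOIs, the regional system matrix of isotope *i* is M x K: column
*k* holds the expected counts in every (window, view, pixel) bin per unit
activity concentration (1 Bq/mL) filling VOI *k*, computed noise-free
with the projector. The composite model for the 2K-vector
λ = (λ^Th, λ^Ra) is

    E[g] = H λ + ψ,   H = [H^Th  H^Ra],

with ψ the stray-noise means. Counts are independent Poisson.

The estimator is multiplicative EM on the composite vector:

    λ_k ← λ_k · [ Σ_m H_mk g_m / ((Hλ)_m + ψ_m) ] / Σ_m H_mk

run for a fixed 1000 iterations by default (an optional relative-change
tolerance enables early stopping). The log-likelihood is non-decreasing
every iteration (asserted in tests); bins with near-zero model mean are
guarded (they contribute zero when the measured count is zero). The flat
initialization matches the stray-corrected total count.

## 4. Figures of merit and the CRLB

For n noise realizations of one patient (truth λ, estimates λ̂):

* NB = (mean λ̂ − λ)/λ, NSD = std(λ̂)/λ (population 1/n convention),
  NRMSE = rms(λ̂ − λ)/λ, so NRMSE² = NB² + NSD² exactly.

For a patient population with one realization each and per-patient
normalized error e_p:

* ensemble NB = |mean_p e_p| (signed errors may cancel; a nonzero value
  indicates population-level systematic bias),
* ensemble NRMSE = sqrt(mean_p e_p²).

The Poisson Fisher information is F_ab = Σ_m H_ma H_mb / ((Hλ)_m + ψ_m),
optionally restricted to a subset of windows; the CRLB-derived NSD is
sqrt((F⁻¹)_aa)/λ_a — the precision floor of unbiased estimators, used
both as an efficiency benchmark and to quantify window information gain.

## 5. Phantoms and virtual imaging trials

The digital pelvic phantom places an elliptical soft-tissue body, a bone
structure, a gut region, and a spherical bone lesion (default diameter
33.75 mm) on an isotropic grid (reference 1.105 mm voxels; desk profile
5.89 mm). Default uptake ratios background:bone:gut:lesion are
12:30:100:300 (Th) and 2:5:25:20 (Ra), scaled to 11 MBq total Th-227 and
a 5:1 Th:Ra activity ratio. The body spans the axial field of view by
design (patients extend beyond it), so axial truncation is expected.

Variability machinery:

* *lumpy heterogeneity*: Gaussian-lump textures within a region,
  mean-preserving by construction, with a linear mixture knob between the
  homogeneous and fully heterogeneous maps;
* *virtual imaging trial (VIT) population*: lesion diameter ~
  N(33.75, 12.64²) mm truncated at 10 mm, lesion center uniform within
  bone (with containment), per-region uptakes ~ N(mean, (10% mean)²)
  truncated at 0, body scale log-normal (σ = 0.08);
* *rigid misregistration*: in-plane shifts and rotation about the patient
  axis applied to activity and attenuation while VOI labels stay fixed
  (emulating stale CT segmentation); transforms that would clip the body
  transaxially raise an error.

When the truth is not piecewise constant (heterogeneity,
misregistration), projections are simulated in voxel mode from the
actual maps; the estimator still uses the VOI-basis matrix, which is the
realistic mismatch being studied.

## 6. Baselines

* **DOSEM**: dual-isotope OSEM voxel reconstruction (both isotope maps
  updated against the same multi-window data; default 16 iterations x 6
  subsets, no post-filter; reconstruction confined to the attenuating
  support), followed by VOI voxel means. The protocol is a documented
  convention, configurable.
* **GTM**: geometric-transfer-matrix partial-volume correction. The K x K
  per-isotope transfer matrix is measured through the same
  reconstruction pipeline on noiseless unit-VOI projections and inverted
  on the DOSEM VOI means.

Both baselines share the projector with the estimator — comparisons are
matched-model by construction.

## 7. Desk-scale profile and runtime

The default study profile (`desk_config()`) targets a single CPU:
48 x 48 x 24 grid at 5.89 mm, 24 views, 1000 EM iterations, 25
realizations for single-patient studies, 96 VIT patients. With it,
building a system matrix takes ~1 s and one 1000-iteration estimate ~2 s.

The reconstruction baselines cost about two orders of magnitude more per
patient than the projection-domain estimator (one DOSEM run plus eight
per-VOI calibration reconstructions for GTM, ~25 s/patient). The VIT
therefore runs the baselines on a documented leading subsample
(`n_baseline_patients`, default 12) of the same patient list, while the
estimator runs on all patients. The baseline lesion biases being measured
are large (tens of percent) relative to their subsample standard error,
so the subsample does not change directional comparisons; the subsample
size is recorded in every result table.

## 8. Statistical caveats on trial-level figures

Two trial-level figures deserve care when reproducing them:

* **Ensemble NB of the Ra-223 lesion.** At the calibrated count level the
  per-patient Ra-lesion error has NSD ~25% at the mean lesion diameter
  and 90–200% for the small-diameter tail of the VIT population (the
  CRLB-derived floor itself is ~200% at 15 mm). The ensemble-NB
  estimator therefore has a standard error of roughly
  ensemble-NRMSE/√n_patients — several percent at n = 96 — and small
  nonnegativity-induced skew is possible for near-uninformative lesions.
  Values of a few percent for this cell are measurement noise as much as
  estimator property; seed-to-seed variation of the same magnitude is
  expected.
* **Empirical NSD vs CRLB with ~50 realizations.** The sampling error of
  an NSD estimate is ~NSD/√(2n) ≈ 10% relative at n = 50, so
  empirical-to-bound ratios for individual cells scatter by about that
  much around their true values even for an efficient estimator.
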