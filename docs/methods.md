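# Methods

## The partition model

Selective internal radiation therapy (SIRT) delivers ⁹⁰Y-labelled resin
microspheres to liver tumors through the hepatic artery. ⁹⁰Y is a pure β
emitter (half-life 2.67 d, mean β energy 0.927 MeV) and the microspheres
are a permanent implant, so the absorbed dose to a compartment that traps
initial activity A₀ (GBq) in mass m (kg) is

    D [Gy] = k · A₀ / m .

`sirtdose` pins k = 49.67 Gy·kg/GBq, the canonical resin-microsphere
value; integrating the total number of decays from the physical constants
above gives 49.43, i.e. the pinned value is consistent within half a
percent, and k is exposed as a parameter (`dose_constant`) for
sensitivity analysis.

The body is divided into four compartments: tumor, in-target normal liver
(parenchyma supplied by the treated artery), out-target normal liver, and
the lungs, which receive activity through arteriovenous shunting. The
lungs take the lung-shunt fraction (LSF) of the injection; the remaining
(1 − LSF) splits among the three liver partitions proportionally to their
imaging counts C·V (mean VOI concentration × VOI volume). Only count
*ratios* enter, so no camera calibration is needed. Tissue density is
1.0 kg/L for tumor and liver, 0.3 kg/L for aerated lung; the standalone
lung mass defaults to the 3.3 L population-average CT lung volume
× 0.3 kg/L = 0.99 kg.

The LSF itself is measured on conjugate anterior/posterior planar
scintigrams of the ⁹⁹ᵐTc-MAA planning scan as

    LSF = TC_lung / (TC_lung + TC_liver),

with TC the geometric mean of the anterior and posterior ROI counts. The
geometric mean is the standard conjugate-view estimator (it cancels the
first-order depth dependence of attenuation); whether a specific clinic
sums or geometric-means the two views is rarely reported, so the
combination rule is a documented choice here. On post-treatment ⁹⁰Y
PET/CT, which covers a single bed position, total lung counts are
extrapolated as (mean basal-lung concentration) × (lung volume); the
extrapolation is exact for uniform lung activity and its bias equals the
basal-vs-whole-lung concentration difference otherwise.

## Activity planning

The partition-model plan inverts the dose equation. The required activity
delivers 120 Gy to the tumor; tolerance activities cap the injection so
the lungs stay < 20 Gy and the in-target normal liver < 70 Gy — or the
out-target normal liver < 30 Gy when the in-target partition is too small
to be the relevant organ at risk. The clinical criterion for "too small"
is qualitative; we implement it as an explicit caller flag plus an
automatic volume cutoff (in-target < 10% of total liver volume,
configurable), and the plan records which limit was applied. When a
tolerance binds, the plan is capped rather than rejected (treatments do
proceed at reduced activity) and reports the reduction fraction.
A measured LSF above 0.2 excludes the patient from treatment.

The empirical comparator is the BSA method for resin spheres,
A [GBq] = (BSA − 0.2) + V_tumor/V_liver with DuBois–DuBois
BSA = 0.007184·W^0.425·H^0.725, followed by the package-insert shunt
reduction: no reduction below LSF 0.10, 20% for [0.10, 0.15), 40% for
[0.15, 0.20), exclusion at ≥ 0.20. Only the 40% maximum and the 0.2
exclusion are universally printed; the intermediate bands follow the
manufacturer convention.

## The synthetic-data generator

No public imaging cohort exists for this workflow, so every stage runs on
seeded digital phantoms: four disjoint axis-aligned ellipsoids on a
96×96×96 grid at 4 mm isotropic spacing (384 mm field of view; geometry
is specified in millimetres, so resolution changes resample the same
anatomy). Default volumes are ~408 mL tumor, ~760 mL in-target liver,
~188 mL out-target liver and ~1.36 L lungs — a bulky but realistic
hepatic tumor load. Axes follow x: left→right, y: anterior→posterior,
z: caudal→cranial; planar projection integrates along y.

Acquisition is emulated as: Gaussian point-spread blur (FWHM 12 mm for
SPECT, 6 mm for PET), Poisson counts at `noise_scale` = 50 expected
counts per unit activity (≈10⁵ counts in a tumor VOI, typical for
quantitative emission imaging), and for PET a partial axial field of view
covering the caudal 40% of the lung extent. The lung concentration is
rescaled at build time so the lung holds exactly `lsf_true` of the
phantom activity.

The MAA-vs-microsphere discrepancy has no accepted quantitative model; it
is emulated phenomenologically with two knobs whose defaults reproduce
the *direction and rough size* of the clinically reported paired
differences: the MAA map scales the tumor concentration by 0.73 (mean) of
the microsphere value, and the MAA shunt is the microsphere LSF plus a
non-negative excess (mean 0.042), giving cohort means near 0.06 (MAA)
vs 0.018 (microsphere). Cohort draws use truncated normals: tumor-to-
normal uptake ratio 4.0 ± 1.0, microsphere LSF 0.018 ± 0.020 on
[0.001, 0.19], injected activity 2.1 ± 0.9 GBq on [0.5, 4].

Progression-free survival is exponential with a dose-switched mean:
286 days when the true tumor dose exceeds 200 Gy, 92 days otherwise,
censored at a 400-day horizon — the simplest outcome model matching the
two reported group means. All randomness flows from one integer seed via
`numpy.random.SeedSequence.spawn`, so a cohort is a pure function of
(n, params, seed).

What the generator does **not** emulate: collimator/scatter physics,
reconstruction artefacts (TOF, PSF recovery), respiratory motion,
registration error between modalities, manual ROI variability (VOIs come
from the label grid, i.e. perfect delineation), multiple discrete tumors,
and any biological dose–response beyond the threshold switch. Passing
tests therefore demonstrate the *self-consistency* of the dosimetry chain
and its behaviour under controlled blur/noise/shunt conditions, not
clinical accuracy on real scanners.

## Numerical choices

* Apportionment conserves activity exactly: the float residue of the
  proportional split is folded into the largest liver share.
* A compartment with zero activity fraction has an unbounded tolerance
  activity, returned as the `UNBOUNDED` (`inf`) sentinel.
* Dose-group dichotomization is strict (`dose > threshold` is "high").
* The Kaplan–Meier median is the first time S(t) ≤ 0.5, `None` when the
  curve never reaches it; "mean ± SE" summaries are the restricted mean
  over the observed horizon with a Greenwood-based standard error.
* Planar ROIs are label projections dilated by 3 pixels (12 mm) to
  capture resolution spill-out, the analogue of generously drawn manual
  ROIs. Planar attenuation is off by default (μ = 0) and exposed for
  sensitivity studies.
* PET lung extrapolation in the phantom pipeline uses the label-grid lung
  volume (the CT-segmentation analogue); the 3.3 L population constant is
  the default only where no per-case volume exists, since phantom lungs
  are not 3.3 L and the constant would inject a volume bias extraneous to
  what is being tested.
* Blur uses zero-padding (`mode="constant"`); compartments sit away from
  the grid edge, so total counts are conserved to < 0.1%.

## Problem sizes

The test suite and analysis scripts run full-resolution phantoms
(96³ × 4 mm): one rendered case costs ~0.3 s, so the 100-replicate
modality-bias suite and the 100-replicate log-rank power study each finish
in well under two minutes. The demonstration cohort is 23 cases.

## Known limitations

* Statistical power of the log-rank comparison at the study's size
  (n = 22 split 14/8, exponential means 286/92 d, censoring at 400 d) is
  ≈0.69, so roughly three in ten such cohorts will *not* reach p < 0.05
  — consistent with the marginal p observed at that size clinically.
* The MAA/microsphere discrepancy model is a stand-in with the right
  direction, not an estimate of particle physiology.
* Voxel-wise dosimetry, dose–volume histograms, partial-volume
  correction and multi-tumor reporting are out of scope.
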