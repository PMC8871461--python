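# Methods

`octagree` implements a semi-automated quantification pipeline for three OCT
biomarkers on paired spectral-domain OCT B-scans — one acquired with enhanced
depth imaging (EDI) and one without — together with the statistical agreement
analysis between the two acquisition modes. Because no clinical scans ship
with the package, a synthetic B-scan generator with exhaustive ground truth
provides the data for every simulation study and test.

## The measurement problem

EDI shifts the OCT zero-delay line toward the choroid, improving deep-tissue
visibility at some cost to inner-retina contrast. Choroidal biomarkers are
normally quantified on EDI scans and retinal biomarkers on conventional
scans; if the two modes agree, a single EDI scan suffices for both. The
package quantifies, per scan:

- **HF** — hyperreflective foci: solitary bright dots < 30 µm without
  shadowing, counted between the posterior RNFL boundary and the external
  limiting membrane (ELM) in the central 3 mm.
- **EZR** — ellipsoid-zone reflectivity ratio: the EZ peak reflectivity
  divided by the RPE peak reflectivity (the brightest band), averaged over
  longitudinal reflectance profiles sampled every 200 µm across the central
  3 mm (16 positions for the 3000 µm / 200 µm geometry).
- **CVI** — choroidal vascularity index: luminal (dark) area divided by
  total choroidal area in the central 3 mm after local binarisation.

and, per cohort, the agreement analysis: Lilliefors-corrected KS normality
gate on the paired differences, paired t-test or Wilcoxon signed-rank test,
two-way absolute-agreement single-measures ICC(A,1) with an F-based 95% CI,
and Bland–Altman limits of agreement (parametric `mean ± 1.96·SD`, or
non-parametric with a median centre and Harrell–Davis 2.5/97.5% quantiles).

## Pipeline order (fixed)

1. rigid integer-translation registration of the pair by normalized
   cross-correlation (search radius 5 px by default; ties broken by smallest
   shift magnitude, then Δrow, then Δcol);
2. histogram matching of the conventional scan to the EDI scan. The EDI
   image is the reference because every ROI is outlined there. The monotone
   gray-level map is estimated on the registered overlap region only, so
   non-overlapping border content cannot bias the normalisation;
3. ROI definition on the EDI image — central 3 mm window
   (`round(3000/lateral_scale)` columns around the fovea; truncation at the
   image border is an error, never a silent clip), HF band
   (RNFL-posterior ≤ depth < ELM) and choroidal band
   (choroid-anterior ≤ depth < choroid–scleral interface) from the supplied
   layer model;
4. transfer of all masks to the conventional frame by the registered shift
   (dropped border pixels are counted; > 5% loss raises a diagnostic);
5. quantification of HF, EZR and CVI on each mode.

Layer curves come from ground truth in synthetic mode or from a
user-supplied segmentation file for real data; automatic layer segmentation
is out of scope, as is sub-pixel or non-rigid registration (the clinical
acquisition uses the device's follow-up referencing, so residual
misalignment is a few pixels of pure translation).

## Detector and estimator choices

**HF.** The spot counter follows the published denoise → local-contrast
enhancement → spot-count recipe. Denoising is a median filter on a
cross-shaped (plus) 3×3 footprint: it removes isolated speckle outliers but
preserves near-pixel-width, axially elongated foci that a full square median
erases. Enhancement is sliding-window local mean/std normalisation (window
63 px) with the statistics restricted to the detection band — a masked,
untiled variant of adaptive contrast enhancement chosen over tiled CLAHE
because it is exactly translation-equivariant and the masked statistics keep
the bright EZ/RPE complex just below the ELM from suppressing foci near the
band's lower edge. Pixels of the normalised image above `z_threshold = 3.5`
(with a 1.0 display-unit floor on the local σ so noise-free scenes are
well-defined) form candidate components; components are sized by their
half-maximum support, converted to an equivalent diameter with the geometric
mean of the axial and lateral scales (foci are near-isotropic), and
discarded if ≥ 30 µm or touching the band border. All knobs live in
`HFParams`.

**EZR.** Profiles are per-depth means over a 3-column lateral window; each
peak is the maximum within ±30 µm of its segmentation prior (an error if the
two search windows would overlap). Ratios are computed on the exported 8-bit
log-display intensities — not back-transformed to linear — because the
clinical protocol quantifies exported display images. Per-position ratios
above 1 are kept (speckle can locally raise EZ above RPE); only non-positive
RPE peaks exclude a position.

**CVI.** Niblack-style local threshold `T = m − k·s` (window 51 px,
`k = 0.05`) where `m` and `s` are computed from choroidal-ROI pixels only,
so the bright RPE above and sclera below never contaminate the window
statistics; pixels below `T` are luminal (lumens are hyporeflective — the
polarity is stated explicitly since protocols often leave it implicit).
Because the threshold is relative to local statistics, the CVI is invariant
under monotone affine rescaling of the ROI intensities; a uniform ROI
produces a degenerate threshold and is flagged, not rejected.

**Statistics.** The paired design calls for the signed-rank test (the
"rank-sum" name that circulates for this analysis denotes an unpaired test;
the paired analogue is implemented and the discrepancy noted here). The
implementation drops zero differences, uses mid-ranks for ties, enumerates
the exact tie-aware null distribution by dynamic programming for n ≤ 25 and
uses a tie- and continuity-corrected normal approximation beyond. ICC form
is a genuinely open choice; ICC(A,1) (two-way, absolute agreement, single
measures) is the default because the scientific question is
interchangeability of modes, and ICC(C,1) is available as an option. No
multiple-testing correction is applied across the nine biomarker × subgroup
comparisons by default (a Holm option exists), matching how such agreement
tables are conventionally reported.

## The synthetic generator

The generator emulates a foveal B-scan in the 8-bit log-display domain:
seven interface curves (ILM, RNFL-posterior, ELM, EZ-centre, RPE-centre,
choroid-anterior, choroid–scleral) share a smooth seeded undulation and
enclose constant-reflectivity bands; vessel lumens are dark ellipses packed
into the choroid until a target luminal fraction is realised inside the
central-3-mm choroidal ROI (realised fraction within ±0.02 of the target, and
recorded exactly from the mask); foci are Gaussian bumps (diameter 16–28 µm,
≥ 40 µm apart, placed sequentially so the first *k* foci of a scene are
identical whether *k* or *k+1* are requested); intraretinal cysts are dark
ellipses whose columns attenuate all deeper signal multiplicatively in the
display domain (so EZ and RPE peaks scale together and their ratio is
preserved — matching the empirical finding that edema leaves EZR and CVI
agreement intact).

Defaults describe the study conditions: 512×320 px at 3.9 µm/px axial and
11 µm/px lateral (the 3 mm ROI is 273 columns), 60 eyes per cohort with
round(0.567·n) edema eyes (34/26 at n = 60), 20–120 foci per eye, luminal
fractions in {0.60, 0.65, 0.70, 0.75}, EZ/RPE band ratios in [0.60, 0.95],
inter-mode shifts up to ±3 px, and SNR scores in (30.5, 35] so simulated
cohorts represent the post-exclusion sample (the > 30 quality gate is tested
with explicitly constructed low-SNR records).

**Speckle** is gamma-distributed multiplicative noise on the
back-transformed linear intensities (shape `1/contrast²`, default contrast
0.3), applied after the log-display transform as its additive equivalent and
clipped to 8 bits. The field is generated once per scene on a canvas shared
by both mode crops: the two acquisitions image the same scatterer
configuration seconds apart, and 50-frame averaging removes most
acquisition-specific noise, so speckle is treated as a tissue property.
Independent per-acquisition Gaussian noise is available
(`acq_noise_sigma`) but defaults to 0 for the same reason.

**Mode rendering.** The EDI rendering multiplies display intensities below
the RPE band by a depth-increasing gain (default up to 1.25×) and compresses
inner-retina contrast about the background level (default factor 0.85); the
conventional rendering attenuates sub-RPE intensities with depth (default
down to 0.8×). These defaults are a qualitative stand-in: the clinical
literature reports the EDI/conventional contrast difference only
descriptively, so the magnitudes are configurable and make no quantitative
claim. For cohort simulations `ModeEffect.null()` renders both modes
identically (the zero-mode-effect condition), and `ModeEffect.hf_only(12)`
adds Poisson-mean-12 EDI-only foci in edema eyes with otherwise neutral
rendering — the "HF-only mode effect" used to reproduce the study's
agreement pattern.

## What the simulations do and do not show

With the default qualitative mode-rendering difference active, global
histogram matching cannot perfectly undo region-specific contrast changes,
and small systematic residuals remain in the paired differences (of order
0.03 in EZR, 0.004 in CVI on 8-eye demonstrations) even though the ICCs stay
high — an honest reminder that a monotone global intensity map is only an
approximation to the physical mode difference. The agreement simulations
therefore follow the two defined conditions: the null condition (identical
rendering) calibrates the false-positive side, and the HF-only condition
tests that an edema-confined effect of ~12 foci is detected in the
macular-edema subgroup while EZR and CVI remain null.

Passing tests show that the *pipeline* recovers known ground truth under
speckle, cysts, inter-mode shifts and rendering differences of the modelled
kind. They do not certify performance on clinical scans: real OCT speckle is
correlated with tissue microstructure, layer boundaries are curved and
pathological in ways the smooth undulation model is not, real foci and
vessel walls have softer contrast, and real segmentations carry errors.
The generator also places all foci inside the central-3-mm detection band,
so recall/precision statements are per-ROI, not per-whole-scan.

## Numerical conventions and degenerate inputs

- Row 0 is the vitreous; depth increases downward; all ranges are 0-based
  and half-open. Masks live in pixel space; physical units are attached only
  at input/output boundaries.
- Identical `(SceneSpec, seed)` reproduce bit-identical images and ground
  truth (per-purpose child RNG streams from one `SeedSequence`).
- Registration of a constant image is rejected (correlation undefined);
  crossing layer curves are rejected as invalid segmentations; a
  zero-thickness HF band yields count 0 while a zero-thickness choroid is an
  error; all-zero paired differences give p = 1 with a flag; constant
  nonzero differences leave the t-statistic undefined (NaN p, flagged);
  subgroups with n < 5 omit the ICC with a flag; n = 3 subgroups skip the
  normality table and stay on the distribution-free branch.
- ICC at the boundary (zero residual variance) returns a collapsed CI with
  a degeneracy flag rather than dividing by zero.

## Problem sizes used by the shipped studies

Unit tests use 10–30 seeded scans per property; the acceptance-level suite
uses 50 scans per biomarker recovery study, 100 registration trials, 100
random ICC tables, 10,000 draws for Bland–Altman coverage, and 20 replicate
60-eye cohorts per agreement condition. `scripts/acceptance.py` reruns the
recovery studies at 50 scans, the registration study at 100 trials, and one
60-eye agreement study, writing every headline number to JSON.
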