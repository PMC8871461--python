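# octagree

Semi-automated quantification of retinal and choroidal OCT biomarkers on
paired spectral-domain OCT B-scans — with and without enhanced depth imaging
(EDI) — and the statistical agreement analysis between the two acquisition
modes.

EDI shifts the OCT zero-delay line toward the choroid to improve deep-tissue
visibility, at some cost to inner-retina contrast. Choroidal biomarkers are
traditionally measured on EDI scans and retinal biomarkers on conventional
scans. If both modes give interchangeable measurements, a *single* EDI
B-scan suffices for a comprehensive biomarker panel — saving acquisition
time and avoiding co-registration artifacts. `octagree` is for researchers
who want to quantify that interchangeability, and for anyone who needs a
tested, scriptable implementation of the three biomarkers themselves.

## Biomarkers

For each B-scan, within the central 3 mm around the fovea:

- **Hyperreflective foci (HF)** — solitary bright dots with equivalent
  diameter < 30 µm, counted between the posterior RNFL boundary and the
  external limiting membrane:
  denoise → local-contrast enhancement → spot counting.
- **Ellipsoid-zone reflectivity ratio (EZR)** — longitudinal reflectance
  profiles every 200 µm (16 positions for the 3 mm / 200 µm geometry);
  per position the ratio of the EZ peak to the RPE peak (the most
  hyperreflective band), EZR = mean over positions.
- **Choroidal vascularity index (CVI)** — the full-thickness choroidal ROI
  is binarised by a Niblack-style local threshold `T = m − k·s` computed
  from ROI pixels only; CVI = luminal (dark) area / total area.

For each cohort of paired scans, per biomarker and subgroup (overall, with
and without macular edema): a Lilliefors-corrected Kolmogorov–Smirnov
normality gate on the paired differences; paired *t*-test (normal branch) or
exact tie-aware Wilcoxon signed-rank test (non-normal branch); two-way
absolute-agreement single-measures intraclass correlation ICC(A,1),

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE)),

with its F-based 95% CI; and Bland–Altman limits of agreement — parametric
`mean(d) ± 1.96·SD(d)` or non-parametric (median centre, Harrell–Davis
2.5/97.5% quantiles).

Because clinical OCT data cannot ship with the package, a synthetic B-scan
generator (`octagree.synth`) produces paired EDI/conventional scans with
full ground truth: layered retina, choroid with dark vessel lumens at a
known luminal fraction, injectable sub-30 µm foci, intraretinal cysts with
sub-cyst attenuation, shared tissue-linked speckle, and a configurable
EDI-vs-conventional rendering difference. See `docs/methods.md` for the
model and its limitations.

## Worked example

Quantify one synthetic eye in both modes, then run a 60-eye simulated
agreement study with an edema-confined EDI effect on foci:

```python
from octagree import synth
from octagree.pipeline import record_from_synthetic, quantify_eye, run_cohort

spec = synth.SceneSpec(n_foci=40, n_cysts=2, mode_shift=(2, 3), seed=7)
edi, conv, gt = synth.generate_pair(spec)
rec = record_from_synthetic((edi, conv), gt, synth.EyeRecordMeta(
    "demo", "DR", True, 33.0, 32.0, spec.fovea_x))
without, with_, reg = quantify_eye(rec)
print("estimated shift:", reg.shift)
print("without EDI:", without)
print("with EDI:   ", with_)

cohort = synth.render_cohort(60, seed=1, mode_effect=synth.ModeEffect.hf_only(12.0))
report = run_cohort([record_from_synthetic(*r) for r in cohort])
print(report.agreement[["biomarker", "subgroup", "n",
                        "mean_difference", "p_value", "icc"]].to_string(index=False))
```

prints

```
estimated shift: (2, 3)
without EDI: BiomarkerTriplet(hf_count=44, ezr=0.8473056016180434, cvi=0.6993699802818256)
with EDI:    BiomarkerTriplet(hf_count=40, ezr=0.8463485715798699, cvi=0.6952820660799307)
                               biomarker   subgroup  n  mean_difference  p_value      icc
                Hyperreflective foci (n)    Overall 60         6.816667 0.000000 0.955316
                Hyperreflective foci (n)    With ME 34        12.029412 0.000000 0.927145
                Hyperreflective foci (n) Without ME 26         0.000000 1.000000 1.000000
Ellipsoid zone reflectivity ratio (a.u.)    Overall 60         0.000194 0.141480 0.999944
Ellipsoid zone reflectivity ratio (a.u.)    With ME 34         0.000341 0.132679 0.999899
Ellipsoid zone reflectivity ratio (a.u.) Without ME 26         0.000000 1.000000 1.000000
      Choroidal vascularity index (a.u.)    Overall 60        -0.000002 0.500000 1.000000
      Choroidal vascularity index (a.u.)    With ME 34        -0.000003 0.500000 1.000000
      Choroidal vascularity index (a.u.) Without ME 26         0.000000 1.000000 1.000000
```

The single-eye truth was 40 foci, EZR 0.850 and luminal fraction 0.702; the
pipeline recovers 40–44 foci, EZR ≈ 0.847 and CVI ≈ 0.70 in both modes after
registration (the true inter-mode shift was (2, 3) px). In the cohort, the
injected mode effect — on average 12 extra EDI-only foci in the 34 edema
eyes — shows up exactly where it was planted: the HF mean difference is
+12.0 with p < 0.001 in the macular-edema subgroup, while EZR and CVI
differences stay at ~0 with p > 0.05 and ICCs near 1, so the two modes are
interchangeable for the outer-retina and choroidal biomarkers.

## Command line

```bash
octagree simulate --n-eyes 60 --seed 1 --out cohort/      # TIFF pairs + ground truth + manifest
octagree quantify --manifest cohort/manifest.csv --out results/
octagree agree    --differences results/differences.csv --out results/
octagree all      --n-eyes 60 --seed 1 --out results/     # in-memory end-to-end
```

`quantify` writes `agreement.csv` (biomarker × subgroup table),
`differences.csv` (per eye), `bland_altman.csv` (plot-ready limits of
agreement) and `exclusions.csv` (eyes failing the SNR > 30 quality gate).
A YAML/JSON file passed via `--params` overrides any `SceneSpec` default.

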