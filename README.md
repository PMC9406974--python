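# strokeperf

Automated perfusion post-processing for acute ischemic stroke, end to end:
from a raw 4D perfusion series (CT perfusion or DSC-MRI) to
rCBF / rCBV / MTT / Tmax maps, ischemic-core and penumbra volumes,
DEFUSE3 thrombectomy eligibility, and between-package agreement
statistics — validated on synthetic digital perfusion phantoms with exact
ground truth.

## What it does

- **phantom** — generates head-sized 4D phantoms whose voxel curves follow
  gamma-variate-AIF ⊛ exponential-residue kinetics, with planted core
  (low CBF / low ADC) and penumbra (delayed Tmax) lesions, an arterial
  voxel plug, matching ADC maps, and exact ground-truth maps and masks.
- **signal** — translation motion correction, Gaussian smoothing, brain
  masking, and signal→concentration conversion (baseline subtraction for
  CTP, log-ratio for DSC-MRI) with automatic pre-bolus baseline detection.
- **aif** — automatic arterial-input-function detection (tall/early/narrow
  voxel scoring) and optional gamma-variate fitting.
- **deconv** — truncated-SVD deconvolution (standard Toeplitz or
  delay-insensitive block-circulant) and the four perfusion maps.
- **lesion** — core (rCBF < 30 % of reference, or ADC < 620×10⁻⁶ mm²/s),
  penumbra (Tmax > 6 s), mismatch volume/ratio, and DEFUSE3 triage
  (ICV < 70 mL, ratio > 1.8, mismatch > 15 mL). All thresholds are
  user-definable.
- **agreement** — ICC(2,1) with F-based CI and interpretation bands,
  Bland–Altman limits of agreement with CIs, paired Wilcoxon signed-rank
  (exact by enumeration up to n = 25), and triage concordance with
  70-mL subgroups.

## CLI

```bash
# generate a phantom (spec JSON optional; defaults are sensible)
strokeperf phantom --spec spec.json --out phantom/

# process one CTP case (NIfTI series + JSON sidecar with frame_times/modality)
strokeperf process-ctp --series phantom/series.nii.gz \
    --sidecar phantom/series.json --out run/

# MRI: PWI series plus ADC volume
strokeperf process-mri --series pwi.nii.gz --sidecar pwi.json \
    --adc adc.nii.gz --out run/

# DEFUSE3 triage from volumes
strokeperf triage --icv 74 --pv 164

# between-package agreement for a paired cohort
# (CSVs with columns case_id, icv, pv; volumes in mL)
strokeperf compare --a rapid.csv --b other.csv --out report/
```

Exit codes: 0 success, 2 validation error, 1 runtime error. Every run
embeds a provenance block (software version, config SHA-256, seed) in its
output JSON.

Pipeline options (SVD threshold, circulant mode, smoothing FWHM,
thresholds, scaling constants, seed) live in a strict JSON config; see
`strokeperf.io.PipelineConfig`.

## Notes on defaults

- The SVD truncation default (10 % of the largest singular value) is a
  noise-robustness setting and carries the well-known low bias of
  truncated-SVD flow estimates; for noiseless synthetic data use a small
  threshold (e.g. 0.01) to recover parameters near-exactly.
- Scaling constants default to k_av = 1, ρ = 1.04 g/mL, H_sv = 0.25,
  H_lv = 0.45 and are fully configurable.
- The phantom's discrete residue preserves both the exponential's peak
  (flow) and area (flow·MTT) on the coarse frame grid, so CBF, CBV, MTT
  and Tmax are all exactly recoverable from noiseless data.
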