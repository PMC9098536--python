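# gliomet

VOI-based multiparametric MRI analysis for differentiating **glioblastoma
(GB)** from **solitary brain metastasis (BM)**.

On conventional MRI a glioblastoma and a single brain metastasis can look
nearly identical — ring-enhancing, centrally necrotic, surrounded by edema —
yet their biology differs in ways that advanced MRI can measure. GB grows
infiltratively (tumor cells in the peritumoral edema, neoangiogenesis with a
largely intact blood–brain barrier); BM grows expansively with leaky,
systemic-type capillaries and purely vasogenic edema. Three quantitative
biomarkers capture this:

* **mean lesional ADC** (apparent diffusion coefficient, mm²/s) from
  multi-b DWI — lower in GB (higher cellularity);
* **maximum perilesional rCBV** (relative cerebral blood volume) within
  5 mm of the enhancing tumor — higher in GB (infiltrative edema);
* **PSR** (percentage signal recovery) of the lesion's DSC perfusion
  curve — higher in GB (preserved blood–brain barrier limits leakage).

`gliomet` implements the full quantitative chain for this three-marker
model, plus synthetic digital phantoms and study-parameterized synthetic
cohorts so that every stage is testable without patient data. It is aimed at
researchers who want a reproducible, scriptable reference implementation of
the VOI-based GB-vs-BM workflow.

## The model

**DSC perfusion.** The T2\*-weighted signal during a gadolinium bolus is
converted to concentration, ΔR2\*(t) = −ln(S(t)/S₀)/TE, with S₀ the mean of
the pre-bolus baseline frames. Tissue and arterial curves are related by the
indicator-dilution convolution C_t = CBF · (C_a ⊛ R), with residue
R(t) = e^(−t/MTT); `gliomet` inverts it by **block-circulant SVD**
deconvolution (zero-padded circulant system, singular values below a
configurable fraction of the largest zeroed, CBF = peak of the recovered
residue curve). CBV is the ratio of integrated tissue to arterial
concentration, and **rCBV** normalizes CBV to contralateral
normal-appearing white matter. The perfusion curve of the lesion VOI is
summarized by peak height PH = S₀ − S_min and residual drop SR = S₀ − S_end,
giving

```
PSR = 100 − 100·SR/PH  =  100·(S_end − S_min)/(S₀ − S_min)
```

i.e. the fraction of the first-pass signal drop recovered by the end of the
acquisition.

**Diffusion.** ADC is fit per voxel by ordinary least squares of ln S(b)
against b (b = 0, 500, 1000 s/mm²): ADC = −slope.

**VOIs.** Three volumes of interest: the enhancing lesion excluding
cystic/necrotic degeneration; the perilesional edema ring within 5 mm
(physical distance, anisotropy-aware distance transform) of the enhancing
tumor; and the residual (distal) edema. Each is projected on the ADC and
rCBV maps for min/mean/max statistics.

**Statistics.** Per-feature Welch t tests, empirical ROC curves
(AUC = Mann–Whitney statistic) with Youden-optimal cutoffs, a
maximum-likelihood logistic combination of the three biomarkers, and the
three-threshold decision rule

> perilesional rCBV max > 1.37 **and** PSR > 75 % **and**
> mean lesional ADC < 1.0×10⁻³ mm²/s ⇒ GB

(strict inequalities; AND/OR/majority combination configurable). The
closed-form binormal AUC Φ(Δμ/√(σ₁²+σ₂²)) serves as the analytic oracle.

## Worked example

A GB-like digital phantom (lesional ADC 0.71×10⁻³ mm²/s, perilesional rCBV
2.63, PSR 84.6 % — the GB group means) with 1 % signal noise, pushed through
the full imaging chain:

```python
import dataclasses
import pandas as pd
from gliomet import (
    build_phantom, gb_like_phantom_spec, fit_adc_map, normalize_rcbv,
    apply_decision_rule, default_decision_rule,
)
from gliomet.perfusion import arterial_input_curve, cbv_map
from gliomet.voi import extract_case_features

case = build_phantom(gb_like_phantom_spec(noise_sd=1.0, seed=0))

aif = arterial_input_curve(case.dsc, case.masks["arterial"])
adc = fit_adc_map(case.dwi)
rcbv = normalize_rcbv(cbv_map(case.dsc, aif), case.masks["reference"])
enhancing = dataclasses.replace(
    case.masks["lesion"],
    voxels=case.masks["lesion"].voxels | case.masks["necrotic_core"].voxels,
    label="enhancing",
)
feats = extract_case_features(
    adc, rcbv, case.dsc,
    enhancing=enhancing, edema=case.masks["edema"],
    necrotic=case.masks["necrotic_core"],
)
print(f"lesion ADC mean        {feats.lesion_adc_mean * 1e3:.3f} x10-3 mm^2/s")
print(f"perilesional rCBV max  {feats.perilesional_rcbv_max:.2f}")
print(f"PSR                    {feats.psr_percent:.1f} %")
row = pd.DataFrame([feats.to_dict()])
print("decision rule          ->", apply_decision_rule(row, default_decision_rule())[0])
```

prints

```
lesion ADC mean        0.712 x10-3 mm^2/s
perilesional rCBV max  2.73
PSR                    84.6 %
decision rule          -> GB
```

The recovered ADC and PSR match the phantom truth; the rCBV maximum sits
slightly above the region truth of 2.63 because a VOI *maximum* over ~10⁴
noisy voxels is upward-biased — exactly the behavior the statistic has on
real maps. All three criteria fire and the rule calls the case GB.

The same workflow is available from the shell:

```bash
gliomet simulate-cohort --seed 2 --out out/      # 20 GB + 21 BM feature CSV
gliomet analyze-cohort out/cohort_features.csv --seed 2 --out out/
gliomet simulate-phantom --kind GB --seed 0 --out out/
gliomet extract-features out/phantom_gb --out out/
gliomet phantom-roundtrip --out out/
gliomet replicate --seed 1 --out out/
```

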