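# Methods

This note documents the models implemented in `gliomet`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## DSC perfusion model

The dynamic susceptibility contrast series is modeled with the standard
indicator-dilution relations. Signal and concentration are linked through
ΔR2\*(t) = −ln(S(t)/S₀)/TE; the proportionality constant between ΔR2\* and
molar concentration is scanner-specific and never needed, so concentrations
are carried in ΔR2\* units (s⁻¹) throughout and all derived quantities
(CBV, rCBV, CBF ratios) are dimensionless or relative. Voxels with
non-positive signal are marked invalid (NaN) and excluded from maps rather
than raising; signal above baseline maps to negative ΔR2\* and is retained
in the curves (clipped to zero only before CBV integration, so blood
volumes stay non-negative while the deconvolution system remains unbiased).

**Deconvolution.** C_t = Δt·(C_a ⊛ F·R) is solved on a zero-padded
block-circulant system (padding to the next power of two of at least
`pad_factor`·n samples, default 2, so the circular convolution reproduces
the causal linear one). For a circulant matrix the singular values are the
moduli of its eigenvalues — the DFT of the padded, Δt-scaled AIF — so the
thresholded SVD pseudo-inverse is applied exactly in the Fourier domain;
a dense-matrix SVD cross-check is part of the test suite. CBF is the peak
of the recovered F·R curve, clipped at zero.

* `sv_threshold_fraction` (default **0.10**): singular values below this
  fraction of the largest are zeroed. 0.10 is a conventional operating
  point for noisy clinical data. The threshold is noise regularization and
  nothing else: on noiseless synthetic curves it should be near zero, and
  the oracle tests use 1e-3, at which CBF recovery on forward-simulated
  curves is exact to ~1e-6. At 0.10 the same noiseless curves are
  recovered with ~10 % median CBF error — the cost of regularizing data
  that needs none.

**CBV and rCBV.** CBV = ∫C_t dt / ∫C_a dt by the trapezoid rule over the
full acquisition window; rCBV normalizes the CBV map by its mean over a
reference mask (contralateral normal-appearing white matter), making the
reference mean exactly 1. "Corrected rCBV" in this package means exactly
this normalization; contrast-leakage (Boxerman-type) correction is out of
scope, and consequently tissues with incomplete signal recovery carry a
persistent concentration tail that contributes to their integrated CBV
(see the phantom section for how ground truth handles this).

**PSR.** One perfusion curve per lesion: the VOI-mean signal curve (not a
voxel-wise average of PSRs). With S₀ the baseline mean, S_min the
post-baseline minimum and S_end the mean of the last `end_window` frames
(default 5), PH = S₀ − S_min, SR = S₀ − S_end and
PSR = 100 − 100·SR/PH = 100·(S_end − S_min)/(S₀ − S_min). Reading SR as the
*residual* drop at the end plateau and PH as the bolus peak height is the
interpretation under which the formula reproduces the standard
percentage-signal-recovery quantity and the expected GB > BM ordering.
If PH is below the noise floor (2× the baseline standard deviation) there
is no detectable bolus; PSR is reported as 100 with a `no_bolus` flag
rather than raising. PSR may exceed 100 (T1-dominant leakage overshoot).

## Diffusion model

ADC is fit per voxel by unweighted ordinary least squares of ln S(b) on b;
with three b-values the difference from signal-weighted fitting (available
via `weighted=True`) is negligible, and the unweighted fit matches how
scanner consoles generate ADC maps. ADC is carried in mm²/s internally; the
×10⁻³ display convention is applied only in CSV output and converted back
on read. Voxels with any non-positive signal are invalid (NaN).

## VOI construction

* Lesion VOI = enhancing mask minus necrotic/cystic core (an empty result
  is an error: "lesion fully necrotic").
* Perilesional ring = voxels within `width_mm` (default 5 mm) Euclidean
  distance of the lesion, via `scipy.ndimage.distance_transform_edt` with
  the voxel spacing as sampling, so the 5 mm is physical and anisotropic
  grids (e.g. 5 mm slices) dilate correctly. The transform measures to the
  nearest lesion voxel *center*, which overestimates the distance to the
  lesion surface by a sub-voxel amount; a quarter-voxel offset
  (`width + 0.25·min(spacing)`) compensates, bringing dilated voxel counts
  within ~2 % of continuum shell volumes (uncorrected they run ~5 % low, a
  half-voxel offset ~10 % high). By default the ring is intersected with
  the edema mask (the study's ring lay within FLAIR-hyperintense edema);
  `restrict_to_edema=False` yields the bare geometric shell.
* Residual edema = edema minus lesion minus ring (may be empty; flagged,
  features for that region left undefined).

Masks and maps must share the grid exactly — a strict shape check stands in
for co-registration, which is out of scope (phantoms are generated
pre-aligned). Segmentation masks are inputs, never computed.

## Statistical stage

* **t tests**: Welch by default — the group SDs are strongly unequal
  (e.g. perilesional rCBV max 0.64 vs 1.72) — with the pooled variant
  available. Both-groups-zero-variance with equal means returns t = 0,
  p = 1; with unequal means it is undefined and raises. No multiple-testing
  correction by default (raw p-values are reported); Bonferroni can be
  applied downstream if desired.
* **ROC**: empirical curve over all distinct cutoffs; AUC is the
  Mann–Whitney statistic (ties half credit), invariant under strictly
  monotone transforms. The optimal cutoff maximizes Youden's
  J = sensitivity + specificity − 1; near-ties (1e-12) resolve toward the
  cutoff nearest the pooled median, stabilizing plateaus.
* **Combination**: features are standardized and combined by a
  maximum-likelihood logistic fit (deterministic convex problem); the
  combined score is the linear predictor. Under perfect separation the ML
  fit diverges, so the Fisher-discriminant (LDA) direction on the pooled
  covariance is used and a warning logged. "Maximum-likelihood model of
  combining classifiers" admits several readings; the logistic ML linear
  combiner is the closest standard construction and is documented as an
  interpretation.
* **Decision rule**: perilesional rCBV max > 1.37, PSR > 75 %, lesional
  mean ADC < 1.0×10⁻³ mm²/s, combined conjunctively by default (the
  phrasing of the source rule is conjunctive but unverifiable; `any` and
  `majority` modes are available and reported by the replication pipeline).
  Inequalities are strict — boundary values do not satisfy a criterion.
  GB is the positive class everywhere; cases with missing rule features
  are labeled undetermined and excluded (but counted) in confusion metrics.
* `binormal_auc` = Φ(|Δμ|/√(σ₁²+σ₂²)) is the analytic oracle for all ROC
  estimators; bootstrap AUC CIs use seeded case resampling (2000 resamples
  for study-sized cohorts, capped at 200 for the 2×10⁵-case replication
  cohorts where the CI is already ±0.1 points).

## Synthetic cohorts

Case-level cohorts draw each feature from a per-group Gaussian with the
reference study's group means and SDs (20 GB / 21 BM by default; 13
features across lesion, perilesional ring and residual edema). Features are
sampled **independently** — the study reports no covariances — with an
optional user-supplied correlation matrix applied as a Gaussian copula for
sensitivity analysis. ADC draws are truncated at zero by redraw (a redraw
probability of ~1.6 % for the GB lesional ADC, which shifts that mean by
~+2 %; distributional tests therefore compare against truncated-normal
moments). PSR is not truncated: values above 100 % are physical.

Two printed rows of the source table are internally inconsistent with its
own text (the lesional "rCBV max" row carries percent-scale values and the
"PSR" row carries rCBV-scale values); the only dimensionally consistent
assignment — PSR 71.14 (13.84) vs 84.59 (13.30) %, lesional rCBV max
4.62 (2.78) vs 4.89 (2.88) — is used. The resulting lesional rCBV mean
(9.71) exceeding its max (4.62) is an inconsistency of the source data,
retained as printed; neither quantity enters the decision rule.

What independence does and does not show: the single-feature AUCs and
operating points depend only on the marginals and reproduce the published
values closely (binormal AUCs 85.9 / 78.0 / 75.8 % vs published
88 / 78 / 74 %). The combined AUC under independence is Φ(√Σaᵢ²) ≈ 93.3 %
vs the published 95 %, and the conjunctive rule's patient-level
sensitivity/specificity (95 %/86 % in the study) is *not* reproducible from
marginals at all — under independence the conjunction's sensitivity is
~47 %. The replication report states this explicitly rather than treating
it as a target.

## Digital phantoms

The phantom is a deliberately minimal geometry: concentric spheres
(necrotic core ⊂ enhancing lesion ⊂ edema) centered in a regular grid
(default 64³ voxels at 1 mm isotropic; radii 4 / 10 / 20 mm, chosen so both
a 5 mm ring and residual edema exist), plus 3 mm arterial and reference
spheres outside the edema. Each region carries one ground-truth tissue
state (CBF, MTT, PSR, ADC, S₀), so regions are homogeneous and VOI
statistics have exact expectations.

* **AIF**: gamma-variate bolus C_a(t) = A·(t−t₀)^α·e^(−(t−t₀)/β) with
  α = 3, β = 1.5 s, arrival t₀ = 10·TR — a typical first-pass shape that
  fits comfortably inside the 50-frame window with 8 pre-bolus frames
  (protocol: TR/TE = 1.49 s/40 ms, ≥5 baseline frames). Default amplitude
  3.3 gives an arterial peak ΔR2\* ≈ 15 s⁻¹ (~45 % signal drop at TE 40 ms).
* **Tissue curves**: rectangle-rule discrete causal convolution
  C_t = CBF·Δt·(C_a ⊛ R), R = e^(−t/MTT) — exactly the system the
  block-circulant deconvolution inverts, so noiseless CBF recovery is a
  sharp test. The flip side: the rectangle-rule time integral of R
  overestimates MTT by ~Δt/2·R(0) (≈20 % at MTT = 4 s, Δt = 1.49 s), so the
  central-volume identity CBV = CBF·MTT holds numerically only for fine
  temporal sampling; it is verified at Δt = 0.1 s, where it agrees to ~1 %.
* **PSR mechanism**: a logistic recovery-offset ramp L(t) (time constant
  2·Δt, centered at the bolus peak, exactly zero before bolus arrival so
  baseline frames equal S₀) is added to the concentration; its amplitude is
  calibrated by Brent root-finding so the summarized PSR of the noiseless
  curve equals the requested target (to ~1e-9 pp). The source quantifies
  only the measured PSR, not a leakage mechanism; a monotone post-bolus
  offset is the minimal model with a single calibratable parameter.
* **Ground-truth rCBV**: the recovery ramp leaves a persistent
  concentration tail that inflates the integrated CBV (no leakage
  correction exists in the package by design). A region's stored rCBV truth
  is therefore the *model-consistent* value — the ratio of its noiseless
  integrated concentration to the reference region's — and the GB-like /
  BM-like builders calibrate each region's CBF by root-finding so this
  model-consistent rCBV hits the group-mean targets (2.63 / 1.21
  perilesional, etc.). Against real data this means the phantom's "rCBV"
  plays the role of the uncorrected rCBV a leakage-naive pipeline measures.
* **Noise**: additive Gaussian on signal magnitude, seeded. Rician noise,
  realistic anatomy, motion and multi-coil effects are not modeled — at the
  simulated SNRs (noise 1–2 % of S₀) the Gaussian approximation is
  adequate and keeps the oracle math exact. Passing phantom tests therefore
  demonstrates correctness of the quantitative chain, not robustness to
  clinical artifacts.
* **DWI**: S_b = S₀·e^(−b·ADC) per region plus the same noise model.

Determinism: every generator is driven by `numpy.random.default_rng(seed)`;
identical (spec, seed) reproduce outputs bit for bit, and every CSV/report
embeds the tool version, seed and a config hash (output paths excluded from
the hash, so relocating a run does not change its fingerprint).

## Problem sizes and run times

Distributional checks use 10⁵ cases per group (moments) and 2×10⁵ per group
(ROC/AUC convergence and the replication pipeline, where the Monte-Carlo SE
of an AUC is ~0.1 points); the deconvolution oracle uses 200 forward
simulations over CBF ∈ [0.2, 3], MTT ∈ [2, 12] s at protocol timing;
image-domain tests use 48³–64³ phantoms. The full test suite runs in about
half a minute and the acceptance script in a few minutes on one CPU.

## Known limitations

* Feature independence in cohorts is an assumption, not an estimate; joint
  statistics (combined AUC, rule sensitivity/specificity) are
  independence-bound approximations.
* No AIF auto-selection: an arterial mask (or the phantom's arterial
  region) must be supplied.
* No leakage correction, delay/dispersion correction, registration,
  IVIM/kurtosis/tensor diffusion, or tumor segmentation.
* The Youden cutoff for lesional ADC on large synthetic cohorts converges
  to the equal-density crossing of the two (truncated) Gaussians,
  ≈0.90×10⁻³ mm²/s — close to, but not identical with, the published
  1.0×10⁻³ operating point chosen on the 41-patient sample.
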