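"""Synthetic data generation: digital DSC/DWI phantoms and feature cohorts.

Two generators make the whole pipeline testable without patient data:

* **Voxel-level phantoms** — concentric spherical geometry (necrotic core
  inside an enhancing lesion inside FLAIR-hyperintense edema) plus small
  arterial and contralateral reference spheres, on a regular grid. Each
  region carries ground-truth perfusion (CBF, MTT, PSR) and diffusion (ADC)
  values; the DSC signal is assembled from a gamma-variate arterial input
  function convolved with an exponential residue, with a calibrated
  post-bolus recovery ramp so the summarized PSR of the noiseless curve hits
  the requested target, and the DWI volumes are mono-exponential in b.
  Additive Gaussian noise on the signal magnitude, seeded.

* **Case-level cohorts** — per-feature Gaussians for the GB and BM groups
  parameterized by the reference study's group means and standard
  deviations (20 GB / 21 BM cases), sampled independently per feature (an
  optional correlation matrix applies a Gaussian copula for sensitivity
  analysis). ADC draws are truncated at zero by redrawing.

Ground-truth rCBV note: the recovery ramp that realizes PSR < 100 leaves a
persistent concentration tail which contributes to the integrated CBV (no
leakage correction is applied anywhere in the package), so a region's stored
rCBV truth is the model-consistent value — the ratio of noiseless integrated
concentrations against the reference region. The GB-like/BM-like phantom
builders calibrate each region's CBF by root-finding so that this
model-consistent rCBV equals the requested target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core import AcquisitionParams, ConcentrationCurve, DscSeries, ParametricMap, RegionMask
from .diffusion import DwiStack
from .perfusion import summarize_perfusion_curve
from .voi import FEATURE_NAMES

__all__ = [
    "CohortSpec",
    "RegionTruth",
    "PhantomSpec",
    "PhantomCase",
    "PhantomTruth",
    "default_cohort_spec",
    "sample_feature_cohort",
    "gamma_variate_aif",
    "default_aif",
    "dsc_signal_from_truth",
    "calibrate_cbf_for_rcbv",
    "build_phantom",
    "gb_like_phantom_spec",
    "bm_like_phantom_spec",
]

logger = logging.getLogger(__name__)

GROUPS = ("GB", "BM")

#: Group-wise feature Gaussians (mean, SD) from the reference study cohort.
#: ADC in mm^2/s, rCBV dimensionless, PSR in percent. "edema_*" rows are the
#: residual (distal) edema VOI.
TABLE1_FEATURES: dict[str, dict[str, tuple[float, float]]] = {
    "perilesional_adc_min": {"BM": (1.28e-3, 0.29e-3), "GB": (1.25e-3, 0.28e-3)},
    "perilesional_adc_mean": {"BM": (1.50e-3, 0.24e-3), "GB": (1.43e-3, 0.31e-3)},
    "perilesional_rcbv_max": {"BM": (1.21, 0.64), "GB": (2.63, 1.72)},
    "perilesional_rcbv_mean": {"BM": (0.87, 0.22), "GB": (1.46, 1.08)},
    "edema_adc_min": {"BM": (1.44e-3, 0.34e-3), "GB": (1.36e-3, 0.34e-3)},
    "edema_adc_mean": {"BM": (1.57e-3, 0.30e-3), "GB": (1.52e-3, 0.36e-3)},
    "edema_rcbv_max": {"BM": (0.97, 0.90), "GB": (1.67, 1.54)},
    "edema_rcbv_mean": {"BM": (0.61, 0.56), "GB": (0.88, 0.70)},
    "lesion_adc_min": {"BM": (0.56e-3, 0.28e-3), "GB": (0.43e-3, 0.20e-3)},
    "lesion_adc_mean": {"BM": (1.13e-3, 0.21e-3), "GB": (0.71e-3, 0.33e-3)},
    "lesion_rcbv_mean": {"BM": (9.71, 3.53), "GB": (7.60, 4.12)},
    "lesion_rcbv_max": {"BM": (4.62, 2.78), "GB": (4.89, 2.88)},
    "psr_percent": {"BM": (71.14, 13.84), "GB": (84.59, 13.30)},
}


# ---------------------------------------------------------------------------
# Case-level feature cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Gaussian feature structure of a two-group (GB/BM) cohort.

    ``features`` maps a feature name (from the CaseFeatures schema) to
    ``{"GB": (mean, sd), "BM": (mean, sd)}``. ``correlation``, if given, is a
    feature-by-feature correlation matrix applied to both groups via a
    Gaussian copula (the study reports no covariances; independence is the
    default).
    """

    features: dict[str, dict[str, tuple[float, float]]]
    n_gb: int = 20
    n_bm: int = 21
    correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gb < 1 or self.n_bm < 1:
            raise ValueError("n_gb and n_bm must be >= 1")
        for name, groups in self.features.items():
            if name not in FEATURE_NAMES:
                raise ValueError(f"unknown feature name {name!r}")
            for g in GROUPS:
                if g not in groups:
                    raise ValueError(f"feature {name!r} missing group {g!r}")
                mean, sd = groups[g]
                if not np.isfinite(mean) or not np.isfinite(sd) or sd < 0:
                    raise ValueError(f"feature {name!r}, group {g!r}: invalid (mean, sd)")
        if self.correlation is not None:
            c = np.asarray(self.correlation, dtype=float)
            k = len(self.features)
            if c.shape != (k, k):
                raise ValueError("correlation must be square over the feature set")
            if not np.allclose(c, c.T) or np.any(np.diag(c) != 1.0):
                raise ValueError("correlation must be symmetric with unit diagonal")
            self.correlation = c

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.features)


def default_cohort_spec() -> CohortSpec:
    """The reference-study-parameterized cohort: 20 GB vs 21 BM cases."""
    return CohortSpec(features={k: dict(v) for k, v in TABLE1_FEATURES.items()})


def sample_feature_cohort(spec: CohortSpec, seed: int | None = None) -> pd.DataFrame:
    """Draw a case-level feature table from the cohort spec.

    Each feature is Gaussian per group (independently unless a correlation
    matrix is set). ADC features are truncated at zero by marginal redraw.
    Returns a DataFrame with columns ``case_id``, ``group`` and one column
    per feature, reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    names = spec.feature_names
    k = len(names)
    chol = None
    if spec.correlation is not None:
        chol = np.linalg.cholesky(spec.correlation)
    frames = []
    for group, n in (("GB", spec.n_gb), ("BM", spec.n_bm)):
        z = rng.standard_normal((n, k))
        if chol is not None:
            z = z @ chol.T
        means = np.array([spec.features[name][group][0] for name in names])
        sds = np.array([spec.features[name][group][1] for name in names])
        x = means + sds * z
        for j, name in enumerate(names):
            if "adc" not in name or sds[j] == 0:
                continue
            bad = x[:, j] <= 0
            while bad.any():  # truncate at 0 by redraw
                x[bad, j] = means[j] + sds[j] * rng.standard_normal(int(bad.sum()))
                bad = x[:, j] <= 0
        df = pd.DataFrame(x, columns=list(names))
        df.insert(0, "group", group)
        df.insert(0, "case_id", [f"{group}_{i:05d}" for i in range(n)])
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Voxel-level phantoms
# ---------------------------------------------------------------------------

def gamma_variate_aif(
    times: np.ndarray,
    t0: float,
    amplitude: float = 1.0,
    alpha: float = 3.0,
    beta: float = 1.5,
) -> np.ndarray:
    """Gamma-variate bolus: C(t) = A*(t-t0)^alpha * exp(-(t-t0)/beta), t > t0.

    Zero before bolus arrival ``t0``; peaks at ``t0 + alpha*beta``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be > 0")
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly ascending")
    dt_rel = times - t0
    curve = np.zeros_like(times)
    post = dt_rel > 0
    curve[post] = amplitude * dt_rel[post] ** alpha * np.exp(-dt_rel[post] / beta)
    return curve


def default_aif(
    acq: AcquisitionParams,
    amplitude: float = 3.3,
    alpha: float = 3.0,
    beta: float = 1.5,
    t0: float | None = None,
) -> ConcentrationCurve:
    """Default arterial input: bolus arriving at 10*TR, first-pass shaped.

    The default amplitude gives an arterial peak dR2* of ~15 1/s, i.e. a
    ~45% signal drop at TE = 40 ms — a typical first-pass magnitude.
    """
    times = acq.times
    if t0 is None:
        t0 = 10.0 * acq.tr_seconds
    values = gamma_variate_aif(times, t0=t0, amplitude=amplitude, alpha=alpha, beta=beta)
    return ConcentrationCurve(values=values, times=times)


def _tissue_concentration(cbf: float, mtt_seconds: float, aif: ConcentrationCurve) -> np.ndarray:
    """Rectangle-rule causal convolution C_t = cbf*dt*(AIF (*) R), R = exp(-t/mtt)."""
    n = aif.values.size
    lags = np.arange(n) * aif.dt
    residue = np.exp(-lags / mtt_seconds)
    return cbf * aif.dt * np.convolve(aif.values, residue)[:n]


def _recovery_gate(times: np.ndarray, t_arrival: float, t_peak: float, tau: float) -> np.ndarray:
    """Smooth 0->1 ramp: logistic centered at the bolus peak, exactly zero
    before bolus arrival (keeps baseline frames untouched)."""
    sig = 1.0 / (1.0 + np.exp(-(times - t_peak) / tau))
    sig0 = 1.0 / (1.0 + np.exp(-(t_arrival - t_peak) / tau))
    gate = np.where(times >= t_arrival, (sig - sig0) / (1.0 - sig0), 0.0)
    return np.clip(gate, 0.0, None)


def dsc_signal_from_truth(
    cbf: float,
    mtt_seconds: float,
    psr_percent: float | None,
    s0: float,
    aif: ConcentrationCurve,
    acq: AcquisitionParams,
    ramp_tau_seconds: float | None = None,
) -> np.ndarray:
    """Noiseless DSC signal for one tissue class with a known PSR.

    S(t) = s0*exp(-TE*(C_t(t) + L(t))) where C_t is the convolution of the
    AIF with an exponential residue, scaled by CBF, and L is a logistic
    recovery-offset ramp whose amplitude is calibrated by root-finding so
    that the summarized PSR of the output equals ``psr_percent`` (well
    within 1 percentage point). ``psr_percent=None`` disables the ramp
    (pure first-pass signal, L == 0). The pre-bolus frames equal s0 exactly.
    """
    if mtt_seconds <= 0:
        raise ValueError("mtt_seconds must be > 0")
    if cbf < 0:
        raise ValueError("cbf must be >= 0")
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    times = aif.times
    if times.size != acq.n_timepoints:
        raise ValueError("aif length must equal acq.n_timepoints")
    conc = _tissue_concentration(cbf, mtt_seconds, aif)
    c_peak = float(conc.max())
    if cbf == 0 or c_peak == 0:
        return np.full(times.size, float(s0))
    if psr_percent is None:
        return s0 * np.exp(-acq.te_seconds * conc)
    nz = np.nonzero(aif.values > 0)[0]
    t_arrival = float(times[nz[0] - 1]) if nz[0] > 0 else float(times[nz[0]])
    t_peak = float(times[int(np.argmax(conc))])
    tau = ramp_tau_seconds if ramp_tau_seconds is not None else 2.0 * aif.dt
    gate = _recovery_gate(times, t_arrival, t_peak, tau)

    def psr_of(amp: float) -> float:
        signal = s0 * np.exp(-acq.te_seconds * (conc + amp * gate))
        return summarize_perfusion_curve(signal, acq).psr_percent

    def objective(amp: float) -> float:
        return psr_of(amp) - psr_percent

    lo, hi = -2.0 * c_peak, 2.0 * c_peak
    for _ in range(60):
        if objective(lo) > 0 >= objective(hi):
            break
        lo *= 2.0
        hi *= 2.0
    else:
        raise RuntimeError("could not bracket the PSR recovery ramp amplitude")
    amp = brentq(objective, lo, hi, xtol=1e-10 * max(c_peak, 1.0))
    return s0 * np.exp(-acq.te_seconds * (conc + amp * gate))


def _measured_cbv(signal: np.ndarray, s0: float, aif: ConcentrationCurve, acq: AcquisitionParams) -> float:
    conc = -np.log(signal / s0) / acq.te_seconds
    num = float(np.trapezoid(np.clip(conc, 0.0, None), aif.times))
    den = float(np.trapezoid(np.clip(aif.values, 0.0, None), aif.times))
    return num / den


def calibrate_cbf_for_rcbv(
    target_rcbv: float,
    mtt_seconds: float,
    psr_percent: float,
    reference: "RegionTruth",
    aif: ConcentrationCurve,
    acq: AcquisitionParams,
    s0: float = 100.0,
) -> float:
    """CBF such that the model-consistent rCBV of the region hits the target.

    The measured CBV includes the PSR recovery-ramp tail, so the mapping
    from CBF to rCBV is solved numerically (monotone; Brent's method).
    """
    if target_rcbv <= 0:
        raise ValueError("target_rcbv must be > 0")
    ref_signal = dsc_signal_from_truth(
        reference.cbf, reference.mtt_seconds, reference.psr_percent, s0, aif, acq
    )
    ref_cbv = _measured_cbv(ref_signal, s0, aif, acq)

    def f(cbf: float) -> float:
        sig = dsc_signal_from_truth(cbf, mtt_seconds, psr_percent, s0, aif, acq)
        return _measured_cbv(sig, s0, aif, acq) / ref_cbv - target_rcbv

    lo, hi = 1e-6, max(4.0 * reference.cbf * target_rcbv, 0.5)
    for _ in range(60):
        if f(hi) > 0:
            break
        hi *= 2.0
    return float(brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


@dataclass(frozen=True)
class RegionTruth:
    """Ground-truth tissue values of one phantom region."""

    cbf: float
    mtt_seconds: float
    psr_percent: float
    adc_mm2_per_s: float
    s0: float = 100.0

    def __post_init__(self) -> None:
        for name in ("mtt_seconds", "adc_mm2_per_s", "s0"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive")
        if not np.isfinite(self.cbf) or self.cbf < 0:
            raise ValueError("cbf must be finite and >= 0")
        if not np.isfinite(self.psr_percent):
            raise ValueError("psr_percent must be finite")


@dataclass
class PhantomSpec:
    """Geometry, ground truth and noise of a spherical digital phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_radius_mm: float = 10.0
    necrotic_core_radius_mm: float = 4.0
    edema_radius_mm: float = 20.0
    region_truth: dict[str, RegionTruth] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0
    aif_amplitude: float = 3.3
    small_region_radius_mm: float = 3.0  # arterial / reference spheres

    def __post_init__(self) -> None:
        if not (
            self.necrotic_core_radius_mm < self.lesion_radius_mm < self.edema_radius_mm
        ):
            raise ValueError("require necrotic_core_radius < lesion_radius < edema_radius")
        if self.edema_radius_mm - self.lesion_radius_mm <= 5.0:
            raise ValueError(
                "edema_radius_mm - lesion_radius_mm must exceed 5 mm "
                "(both a 5 mm ring and residual edema must exist)"
            )
        if self.necrotic_core_radius_mm < 0 or self.noise_sd < 0:
            raise ValueError("radii and noise_sd must be >= 0")
        required = {"lesion", "edema", "reference"}
        missing = required - set(self.region_truth)
        if missing:
            raise ValueError(f"region_truth missing regions: {sorted(missing)}")


@dataclass
class PhantomTruth:
    adc_map: ParametricMap
    rcbv_map: ParametricMap
    region_scalars: dict[str, dict[str, float]]


@dataclass
class PhantomCase:
    dsc: DscSeries
    dwi: DwiStack
    masks: dict[str, RegionMask]
    truth: PhantomTruth
    aif: ConcentrationCurve
    spec: PhantomSpec
    acq: AcquisitionParams


# region ids in the phantom label volume; 4 is the arterial region
_REGION_IDS = {
    "background": 0,
    "necrotic_core": 1,
    "lesion": 2,
    "edema": 3,
    "arterial": 4,
    "reference": 5,
}
_TISSUE_REGIONS = ("background", "necrotic_core", "lesion", "edema", "reference")


def build_phantom(spec: PhantomSpec, acq: AcquisitionParams | None = None) -> PhantomCase:
    """Assemble a phantom case: DSC series, DWI stack, masks and truths.

    Spherical concentric geometry centered in the grid; arterial and
    reference spheres sit on the x axis outside the edema. The DSC signal is
    region-constant (plus seeded Gaussian noise), the arterial region
    carries the AIF, and the stored rCBV truth is the ratio of noiseless
    integrated concentrations against the reference region (identically 1
    there by definition).
    """
    acq = acq or AcquisitionParams()
    shape = tuple(int(s) for s in spec.grid_shape)
    spacing = np.asarray(spec.spacing_mm, dtype=float)

    centre = (np.asarray(shape) - 1) / 2.0 * spacing
    axes = [np.arange(n) * d for n, d in zip(shape, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    r_centre = np.sqrt(sum((c - c0) ** 2 for c, c0 in zip(coords, centre)))

    offset = spec.edema_radius_mm + spec.small_region_radius_mm + 1.0
    half_extent_x = (shape[0] - 1) / 2.0 * spacing[0]
    if offset + spec.small_region_radius_mm > half_extent_x:
        raise ValueError("grid too small for arterial/reference regions outside the edema")

    def sphere_at(dx_mm: float, radius: float) -> np.ndarray:
        c0 = centre.copy()
        c0[0] += dx_mm
        r = np.sqrt(sum((c - cc) ** 2 for c, cc in zip(coords, c0)))
        return r <= radius

    necrotic = r_centre <= spec.necrotic_core_radius_mm
    lesion = (r_centre <= spec.lesion_radius_mm) & ~necrotic
    edema = (r_centre <= spec.edema_radius_mm) & ~necrotic & ~lesion
    arterial = sphere_at(+offset, spec.small_region_radius_mm)
    reference = sphere_at(-offset, spec.small_region_radius_mm)

    region_id = np.zeros(shape, dtype=np.int8)
    for rid, mask in ((1, necrotic), (2, lesion), (3, edema), (4, arterial), (5, reference)):
        region_id[mask] = rid

    truths = dict(spec.region_truth)
    truths.setdefault("necrotic_core", RegionTruth(
        cbf=0.02, mtt_seconds=4.0, psr_percent=100.0, adc_mm2_per_s=2.4e-3,
        s0=truths["reference"].s0,
    ))
    truths.setdefault("background", truths["reference"])
    truths.setdefault("arterial", RegionTruth(
        cbf=1.0, mtt_seconds=4.0, psr_percent=100.0, adc_mm2_per_s=3.0e-3,
        s0=truths["reference"].s0,
    ))

    aif = default_aif(acq, amplitude=spec.aif_amplitude)
    curves = np.empty((6, acq.n_timepoints))
    for name in _TISSUE_REGIONS:
        t = truths[name]
        curves[_REGION_IDS[name]] = dsc_signal_from_truth(
            t.cbf, t.mtt_seconds, t.psr_percent, t.s0, aif, acq
        )
    art = truths["arterial"]
    curves[_REGION_IDS["arterial"]] = art.s0 * np.exp(-acq.te_seconds * aif.values)

    rng = np.random.default_rng(spec.seed)
    dsc_signal = curves[region_id]
    if spec.noise_sd > 0:
        dsc_signal = dsc_signal + rng.normal(0.0, spec.noise_sd, dsc_signal.shape)
        dsc_signal = np.clip(dsc_signal, 1e-6, None)
    dsc = DscSeries(signal=dsc_signal, times=acq.times, acq=acq)

    region_order = sorted(_REGION_IDS, key=_REGION_IDS.get)
    adc_by_region = np.array([truths[n].adc_mm2_per_s for n in region_order])
    s0_by_region = np.array([truths[n].s0 for n in region_order])
    dwi_vols = np.empty((len(acq.b_values),) + shape)
    for i, b in enumerate(acq.b_values):
        vals = s0_by_region * np.exp(-b * adc_by_region)
        dwi_vols[i] = vals[region_id]
        if spec.noise_sd > 0:
            dwi_vols[i] = np.clip(
                dwi_vols[i] + rng.normal(0.0, spec.noise_sd, shape), 1e-6, None
            )
    dwi = DwiStack(volumes=dwi_vols, b_values=acq.b_values, spacing_mm=tuple(spacing))

    # model-consistent truths: integrate the noiseless region concentrations
    ref_cbv = _measured_cbv(
        curves[_REGION_IDS["reference"]], truths["reference"].s0, aif, acq
    )
    region_scalars: dict[str, dict[str, float]] = {}
    rcbv_by_region = np.zeros(6)
    for name in _TISSUE_REGIONS:
        t = truths[name]
        cbv = _measured_cbv(curves[_REGION_IDS[name]], t.s0, aif, acq)
        rcbv = cbv / ref_cbv
        rcbv_by_region[_REGION_IDS[name]] = rcbv
        region_scalars[name] = {
            "cbf": t.cbf, "mtt_seconds": t.mtt_seconds, "psr_percent": t.psr_percent,
            "adc_mm2_per_s": t.adc_mm2_per_s, "s0": t.s0, "cbv": cbv, "rcbv": rcbv,
        }
    rcbv_by_region[_REGION_IDS["arterial"]] = np.nan  # arterial region is not tissue

    adc_map = ParametricMap(adc_by_region[region_id], tuple(spacing), name="adc_truth")
    rcbv_map = ParametricMap(rcbv_by_region[region_id], tuple(spacing), name="rcbv_truth")

    masks = {
        "lesion": RegionMask(lesion, tuple(spacing), "lesion"),
        "necrotic_core": RegionMask(necrotic, tuple(spacing), "necrotic_core"),
        "edema": RegionMask(edema, tuple(spacing), "edema"),
        "arterial": RegionMask(arterial, tuple(spacing), "arterial"),
        "reference": RegionMask(reference, tuple(spacing), "reference"),
    }
    return PhantomCase(
        dsc=dsc, dwi=dwi, masks=masks,
        truth=PhantomTruth(adc_map=adc_map, rcbv_map=rcbv_map, region_scalars=region_scalars),
        aif=aif, spec=spec, acq=acq,
    )


def _group_phantom_spec(
    lesion_adc: float,
    lesion_psr: float,
    lesion_rcbv: float,
    edema_adc: float,
    edema_rcbv: float,
    noise_sd: float,
    seed: int,
    acq: AcquisitionParams,
) -> PhantomSpec:
    reference = RegionTruth(cbf=0.25, mtt_seconds=4.0, psr_percent=100.0, adc_mm2_per_s=0.78e-3)
    aif = default_aif(acq)
    lesion_cbf = calibrate_cbf_for_rcbv(lesion_rcbv, 4.0, lesion_psr, reference, aif, acq)
    edema_cbf = calibrate_cbf_for_rcbv(edema_rcbv, 4.0, 98.0, reference, aif, acq)
    return PhantomSpec(
        region_truth={
            "lesion": RegionTruth(lesion_cbf, 4.0, lesion_psr, lesion_adc),
            "edema": RegionTruth(edema_cbf, 4.0, 98.0, edema_adc),
            "reference": reference,
        },
        noise_sd=noise_sd,
        seed=seed,
    )


def gb_like_phantom_spec(
    noise_sd: float = 0.0, seed: int = 0, acq: AcquisitionParams | None = None
) -> PhantomSpec:
    """Phantom with GB group-mean truths: low lesional ADC, high perilesional
    rCBV, near-complete signal recovery (intact blood-brain barrier)."""
    acq = acq or AcquisitionParams()
    return _group_phantom_spec(
        lesion_adc=0.71e-3, lesion_psr=84.59, lesion_rcbv=4.89,
        edema_adc=1.43e-3, edema_rcbv=2.63,
        noise_sd=noise_sd, seed=seed, acq=acq,
    )


def bm_like_phantom_spec(
    noise_sd: float = 0.0, seed: int = 0, acq: AcquisitionParams | None = None
) -> PhantomSpec:
    """Phantom with BM group-mean truths: high lesional ADC, low perilesional
    rCBV, reduced signal recovery (leaky systemic-type capillaries)."""
    acq = acq or AcquisitionParams()
    return _group_phantom_spec(
        lesion_adc=1.13e-3, lesion_psr=71.14, lesion_rcbv=4.62,
        edema_adc=1.50e-3, edema_rcbv=1.21,
        noise_sd=noise_sd, seed=seed, acq=acq,
    )
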