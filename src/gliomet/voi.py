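"""VOI construction and per-case feature extraction.

Three volumes of interest drive the analysis:

* the enhancing lesion, with cystic/necrotic degeneration excluded;
* the perilesional edema ring, i.e. edema within a physical distance
  (default 5 mm) of the enhancing tumor boundary — built by thresholding a
  Euclidean distance transform scaled by the voxel spacing, so anisotropic
  grids dilate correctly in millimeters;
* residual edema: the remaining edema beyond the ring.

Each VOI is projected on the ADC and rCBV maps for order statistics, and the
lesion VOI additionally yields the PSR of its mean perfusion signal curve.
Masks and maps must share the grid exactly (images are assumed co-registered
upstream; a strict shape check stands in for registration QC).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields

import numpy as np
from scipy import ndimage

from .core import DscSeries, ParametricMap, RegionMask
from .perfusion import mean_curve_over_voi, summarize_perfusion_curve

__all__ = [
    "VoiStats",
    "CaseFeatures",
    "FEATURE_NAMES",
    "lesion_voi",
    "perilesional_ring",
    "residual_edema",
    "voi_statistics",
    "extract_case_features",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "lesion_adc_min",
    "lesion_adc_mean",
    "lesion_rcbv_mean",
    "lesion_rcbv_max",
    "perilesional_adc_min",
    "perilesional_adc_mean",
    "perilesional_rcbv_mean",
    "perilesional_rcbv_max",
    "edema_adc_min",
    "edema_adc_mean",
    "edema_rcbv_mean",
    "edema_rcbv_max",
    "psr_percent",
)


@dataclass
class VoiStats:
    min: float
    mean: float
    max: float
    n_voxels: int


@dataclass
class CaseFeatures:
    """One case's extracted biomarkers (ADC in mm^2/s; rCBV dimensionless).

    Regions without a usable VOI (e.g. no edema ring) carry NaN. "edema"
    fields refer to the residual-edema VOI, distal to the perilesional ring.
    """

    lesion_adc_min: float = math.nan
    lesion_adc_mean: float = math.nan
    lesion_rcbv_mean: float = math.nan
    lesion_rcbv_max: float = math.nan
    perilesional_adc_min: float = math.nan
    perilesional_adc_mean: float = math.nan
    perilesional_rcbv_mean: float = math.nan
    perilesional_rcbv_max: float = math.nan
    edema_adc_min: float = math.nan
    edema_adc_mean: float = math.nan
    edema_rcbv_mean: float = math.nan
    edema_rcbv_max: float = math.nan
    psr_percent: float = math.nan
    diagnosis: str = "unknown"

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _check_grids(*masks: RegionMask) -> None:
    shapes = {m.voxels.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError("masks must share the same grid")


def lesion_voi(enhancing: RegionMask, necrotic: RegionMask) -> RegionMask:
    """Enhancing tumor minus its necrotic/cystic core."""
    _check_grids(enhancing, necrotic)
    voxels = enhancing.voxels & ~necrotic.voxels
    if not voxels.any():
        raise ValueError("lesion fully necrotic: enhancing minus necrotic is empty")
    return RegionMask(voxels=voxels, spacing_mm=enhancing.spacing_mm, label="lesion")


def perilesional_ring(
    lesion: RegionMask,
    edema: RegionMask,
    width_mm: float = 5.0,
    restrict_to_edema: bool = True,
) -> RegionMask:
    """Edema within ``width_mm`` (Euclidean, in mm) of the enhancing tumor.

    The lesion is dilated by a physical-distance ball via a spacing-scaled
    distance transform; the lesion itself is excluded, and by default the
    result is intersected with the edema mask (set ``restrict_to_edema=False``
    to take the bare geometric shell).

    The distance transform measures to the nearest lesion voxel *center*,
    which overestimates the distance to the lesion surface by a fraction of
    a voxel on average; a quarter-voxel offset compensates so that dilated
    voxel counts track continuum volumes.
    """
    _check_grids(lesion, edema)
    if not lesion:
        raise ValueError("lesion mask is empty")
    dist = ndimage.distance_transform_edt(~lesion.voxels, sampling=lesion.spacing_mm)
    shell = (dist > 0) & (dist <= width_mm + 0.25 * min(lesion.spacing_mm))
    voxels = shell & edema.voxels if restrict_to_edema else shell
    if not voxels.any():
        logger.warning("perilesional ring is empty; features undefined for that region")
    return RegionMask(voxels=voxels, spacing_mm=lesion.spacing_mm, label="perilesional_ring")


def residual_edema(edema: RegionMask, lesion: RegionMask, ring: RegionMask) -> RegionMask:
    """Edema beyond the perilesional ring (edema minus lesion minus ring)."""
    _check_grids(edema, lesion, ring)
    voxels = edema.voxels & ~lesion.voxels & ~ring.voxels
    if not voxels.any():
        logger.warning("residual edema is empty; features undefined for that region")
    return RegionMask(voxels=voxels, spacing_mm=edema.spacing_mm, label="residual_edema")


def voi_statistics(pmap: ParametricMap, mask: RegionMask) -> VoiStats:
    """Min/mean/max over valid (finite) masked voxels."""
    if pmap.values.shape != mask.voxels.shape:
        raise ValueError("map and mask must share the grid")
    if not mask:
        raise ValueError(f"mask {mask.label!r} is empty")
    vals = pmap.values[mask.voxels]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no valid voxels in region {mask.label!r}")
    return VoiStats(
        min=float(vals.min()),
        mean=float(vals.mean()),
        max=float(vals.max()),
        n_voxels=int(vals.size),
    )


def extract_case_features(
    adc_map: ParametricMap,
    rcbv_map: ParametricMap,
    series: DscSeries,
    enhancing: RegionMask,
    edema: RegionMask | None = None,
    necrotic: RegionMask | None = None,
    ring_width_mm: float = 5.0,
    diagnosis: str = "unknown",
) -> CaseFeatures:
    """Build the three VOIs and extract the full per-case feature set.

    The lesion VOI excludes the necrotic core (if given); perilesional ring
    and residual edema require an edema mask — without one those fields stay
    NaN while lesion features and PSR are still computed.
    """
    if adc_map.values.shape != rcbv_map.values.shape or adc_map.values.shape != series.shape:
        raise ValueError("ADC map, rCBV map and DSC series must share the grid")
    if necrotic is None:
        necrotic = RegionMask(
            voxels=np.zeros_like(enhancing.voxels),
            spacing_mm=enhancing.spacing_mm,
            label="necrotic_core",
        )
    lesion = lesion_voi(enhancing, necrotic)
    feats = CaseFeatures(diagnosis=diagnosis)

    def _fill(prefix: str, mask: RegionMask) -> None:
        try:
            adc = voi_statistics(adc_map, mask)
            rcbv = voi_statistics(rcbv_map, mask)
        except ValueError as exc:
            logger.warning("region %s skipped: %s", prefix, exc)
            return
        setattr(feats, f"{prefix}_adc_min", adc.min)
        setattr(feats, f"{prefix}_adc_mean", adc.mean)
        setattr(feats, f"{prefix}_rcbv_mean", rcbv.mean)
        setattr(feats, f"{prefix}_rcbv_max", rcbv.max)

    _fill("lesion", lesion)
    if edema is not None and edema:
        ring = perilesional_ring(lesion, edema, width_mm=ring_width_mm)
        distal = residual_edema(edema, lesion, ring)
        if ring:
            _fill("perilesional", ring)
        if distal:
            _fill("edema", distal)
    summary = summarize_perfusion_curve(mean_curve_over_voi(series, lesion), series.acq)
    feats.psr_percent = summary.psr_percent
    return feats
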