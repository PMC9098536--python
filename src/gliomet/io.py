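"""File I/O: NIfTI volumes, feature/cohort CSVs and YAML configs.

Conventions:

* volumes are NIfTI-1 with the voxel spacing on the affine diagonal —
  4D float for DSC, one 3D float volume per b-value, uint8 (0/1) masks;
* tables are CSV with a commented metadata header line recording the tool
  version, seed and config hash, so every output is reproducible from its
  header;
* ADC columns are written in the conventional x10^-3 mm^2/s display units
  and converted back to mm^2/s on read (internal unit everywhere).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .core import AcquisitionParams, DscSeries, ParametricMap, RegionMask
from .diffusion import DwiStack

__all__ = [
    "save_volume",
    "load_volume",
    "save_phantom_images",
    "load_dsc_series",
    "load_dwi_stack",
    "load_mask",
    "write_table",
    "read_table",
    "config_hash",
]

ADC_DISPLAY_SCALE = 1e3  # mm^2/s -> x10^-3 mm^2/s display convention


def _affine(spacing_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_mm
    return aff


def save_volume(data: np.ndarray, spacing_mm, path: str | Path, dtype=np.float32) -> Path:
    """Write a 3D/4D array as NIfTI-1 with spacing on the affine diagonal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), _affine(spacing_mm))
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=float), spacing


def save_phantom_images(case, out_dir: str | Path) -> dict[str, Path]:
    """Write a phantom case as NIfTI files (DSC 4D, DWI per-b, uint8 masks,
    truth maps) plus a b-value table and a JSON acquisition sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spacing = case.dwi.spacing_mm
    paths = {"dsc": save_volume(case.dsc.signal, spacing, out / "dsc.nii")}
    for b, vol in zip(case.dwi.b_values, case.dwi.volumes):
        paths[f"dwi_b{int(b)}"] = save_volume(vol, spacing, out / f"dwi_b{int(b)}.nii")
    (out / "bvals.txt").write_text(" ".join(str(int(b)) for b in case.dwi.b_values) + "\n")
    for name, mask in case.masks.items():
        paths[f"mask_{name}"] = save_volume(
            mask.voxels.astype(np.uint8), spacing, out / f"mask_{name}.nii", dtype=np.uint8
        )
    paths["truth_adc"] = save_volume(case.truth.adc_map.values, spacing, out / "truth_adc.nii")
    paths["truth_rcbv"] = save_volume(case.truth.rcbv_map.values, spacing, out / "truth_rcbv.nii")
    acq = case.acq
    (out / "acquisition.json").write_text(json.dumps({
        "te_seconds": acq.te_seconds,
        "tr_seconds": acq.tr_seconds,
        "n_timepoints": acq.n_timepoints,
        "n_baseline": acq.n_baseline,
        "b_values": list(acq.b_values),
        "seed": case.spec.seed,
    }, indent=2) + "\n")
    return paths


def load_dsc_series(path: str | Path, acq: AcquisitionParams) -> DscSeries:
    data, _ = load_volume(path)
    return DscSeries(signal=data, times=acq.times, acq=acq)


def load_dwi_stack(paths, b_values, spacing_mm=None) -> DwiStack:
    vols, spacing = [], spacing_mm
    for p in paths:
        data, sp = load_volume(p)
        vols.append(data)
        spacing = spacing or sp
    return DwiStack(volumes=np.stack(vols), b_values=tuple(b_values), spacing_mm=spacing)


def load_mask(path: str | Path, label: str) -> RegionMask:
    data, spacing = load_volume(path)
    return RegionMask(voxels=data > 0.5, spacing_mm=spacing, label=label)


def _scale_adc_columns(df: pd.DataFrame, factor: float) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        if "adc" in col:
            df[col] = df[col] * factor
    return df


def write_table(
    df: pd.DataFrame, path: str | Path, seed: int | None = None, cfg_hash: str | None = None
) -> Path:
    """CSV with a metadata comment header; ADC columns in x10^-3 mm^2/s."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = f"# gliomet {__version__}"
    if seed is not None:
        meta += f" seed={seed}"
    if cfg_hash is not None:
        meta += f" config={cfg_hash}"
    with open(path, "w") as fh:
        fh.write(meta + "\n")
        _scale_adc_columns(df, ADC_DISPLAY_SCALE).to_csv(fh, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a gliomet CSV, converting ADC columns back to mm^2/s."""
    df = pd.read_csv(path, comment="#")
    return _scale_adc_columns(df, 1.0 / ADC_DISPLAY_SCALE)


def config_hash(config_dict: dict) -> str:
    """Short stable hash of a config mapping (sorted-key JSON, sha256)."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
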