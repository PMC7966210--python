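"""NIfTI volume I/O and JSON report serialization."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError
from .phantom import CTVolume
from .scorer import AspectsResult

REPORT_SCHEMA_VERSION = "1"


def read_volume(path: str | Path) -> CTVolume:
    """Read a scalar NIfTI-1 volume as HU.

    nibabel applies the scl_slope/scl_inter rescale when present, so raw
    stored values with slope 1 / intercept -1024 come back already shifted
    to the HU scale. Malformed files raise FormatError.
    """
    try:
        img = nib.load(str(path))
        data = img.get_fdata()  # applies scl_slope / scl_inter
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a scalar 3D volume, got shape {data.shape}")
    if not np.isfinite(data).all():
        raise FormatError(f"{path}: volume contains non-finite values")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CTVolume(voxels=data, voxel_spacing_mm=spacing)


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CTVolume as NIfTI-1 with a diagonal spacing affine."""
    affine = np.diag(list(volume.voxel_spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(volume.voxels, affine), str(path))


def config_hash(config: dict) -> str:
    """Short deterministic hash of a JSON-serializable config."""
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def aspects_result_to_dict(result: AspectsResult, config: dict | None = None) -> dict:
    """JSON-ready dict of an AspectsResult: floats at 4 decimals,
    deterministic key order."""
    regions = []
    for rr in result.region_results:
        meas = result.measurements.get((rr.region, result.affected_hemisphere))
        contra = result.measurements.get(
            (rr.region, result.affected_hemisphere.opposite)
        )
        regions.append(
            {
                "region": rr.region.value,
                "mean_hu_affected": None if meas is None else round(meas.weighted_mean_hu, 4),
                "mean_hu_contralateral": None
                if contra is None
                else round(contra.weighted_mean_hu, 4),
                "relative_diff_pct": None
                if rr.region in result.unmeasurable_regions
                else round(rr.relative_diff_pct, 4),
                "threshold_pct": round(rr.threshold_pct, 4),
                "affected": rr.affected,
            }
        )
    out = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "affected_hemisphere": result.affected_hemisphere.value,
        "hemisphere_overridden": result.hemisphere_overridden,
        "asymmetry_score": round(result.asymmetry_score, 4),
        "regions": regions,
        "affected_regions": [r.value for r in result.affected_regions],
        "unmeasurable_regions": [r.value for r in result.unmeasurable_regions],
        "score": result.score,
    }
    if config is not None:
        out["config_hash"] = config_hash(config)
    return out


def write_report(payload: dict, path: str | Path) -> None:
    """Write a JSON report with sorted keys (byte-deterministic)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
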