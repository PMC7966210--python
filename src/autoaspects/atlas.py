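"""Probabilistic ASPECTS atlas: per-region, per-hemisphere voxel weight maps.

The atlas assigns every voxel a likelihood of belonging to each of the 10
ASPECTS regions, separately per hemisphere (20 scalar maps in total). The
maps are fuzzy, not a hard segmentation: a region's mean CT density is later
computed as a weight-averaged Hounsfield value over its map. A synthetic
atlas builder places smooth mirror-symmetric blobs so the full measurement
pipeline can be exercised without clinical data.

Conventions
-----------
Array axis 0 is the left–right axis. The left hemisphere occupies voxel
columns ``x < X // 2``; the right hemisphere is the mirror image under
``np.flip(..., axis=0)``. With an odd first dimension the central column
carries zero weight in every map, so mirroring is exact and the hemispheres
never overlap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FormatError, SizingError
from .regions import ALL_REGIONS, Hemisphere, Region

ATLAS_FORMAT_VERSION = "1"


@dataclass
class ProbabilisticAtlas:
    """20 weight volumes (10 regions x 2 hemispheres) on a shared grid."""

    grid_shape: tuple[int, int, int]
    voxel_spacing_mm: tuple[float, float, float]
    weights: dict[tuple[Region, Hemisphere], np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if len(self.weights) != 2 * len(ALL_REGIONS):
            raise ValueError(f"expected 20 weight maps, got {len(self.weights)}")
        for (region, hemi), w in self.weights.items():
            if w.shape != self.grid_shape:
                raise ValueError(f"{region}/{hemi}: shape {w.shape} != grid {self.grid_shape}")
            if w.min() < 0 or w.max() > 1:
                raise ValueError(f"{region}/{hemi}: weights outside [0, 1]")
            if not (w > 0).any():
                raise ValueError(f"{region}/{hemi}: empty support")
        for region in ALL_REGIONS:
            left = self.weights[(region, Hemisphere.LEFT)]
            right = self.weights[(region, Hemisphere.RIGHT)]
            if (left * right).any():
                raise ValueError(f"{region}: left and right supports overlap")

    def support(self, region: Region, hemisphere: Hemisphere) -> np.ndarray:
        """Boolean mask of voxels with positive weight."""
        return self.weights[(region, hemisphere)] > 0

    def save(self, directory: str | Path) -> None:
        """Write 20 NIfTI volumes plus a JSON manifest to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        affine = np.diag(list(self.voxel_spacing_mm) + [1.0])
        for (region, hemi), w in self.weights.items():
            img = nib.Nifti1Image(np.asarray(w, dtype=np.float64), affine)
            nib.save(img, directory / f"{region.value}_{hemi.value}.nii.gz")
        manifest = {
            "version": ATLAS_FORMAT_VERSION,
            "grid_shape": list(self.grid_shape),
            "voxel_spacing_mm": list(self.voxel_spacing_mm),
            "regions": [r.value for r in ALL_REGIONS],
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "ProbabilisticAtlas":
        directory = Path(directory)
        manifest_path = directory / "manifest.json"
        if not manifest_path.exists():
            raise FormatError(f"no atlas manifest at {manifest_path}")
        manifest = json.loads(manifest_path.read_text())
        weights: dict[tuple[Region, Hemisphere], np.ndarray] = {}
        for name in manifest["regions"]:
            region = Region(name)
            for hemi in Hemisphere:
                path = directory / f"{region.value}_{hemi.value}.nii.gz"
                if not path.exists():
                    raise FormatError(f"missing atlas volume {path}")
                weights[(region, hemi)] = np.asarray(
                    nib.load(path).get_fdata(), dtype=np.float64
                )
        atlas = cls(
            grid_shape=tuple(manifest["grid_shape"]),
            voxel_spacing_mm=tuple(manifest["voxel_spacing_mm"]),
            weights=weights,
        )
        atlas.validate()
        return atlas


def mirror_region(
    atlas: ProbabilisticAtlas, region: Region, hemisphere: Hemisphere
) -> np.ndarray:
    """Weight map of the same region on the opposite hemisphere.

    Raises KeyError for a label not present in the atlas.
    """
    return atlas.weights[(Region(region), Hemisphere(hemisphere).opposite)]


def build_synthetic_atlas(
    grid_shape: tuple[int, int, int],
    seed: int,
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    margin: float = 2.0,
) -> ProbabilisticAtlas:
    """Build a mirror-symmetric synthetic atlas of smooth blob regions.

    Each of the 10 left-hemisphere regions is a sphere of weight 1 (the
    core) surrounded by a linear ramp of width ``margin`` voxels down to 0
    (``margin=0`` produces hard binary maps). Cores are placed on a lattice
    of cells so they are pairwise disjoint; the seed jitters the blob
    centers within their cells. Right-hemisphere maps are exact mirror
    images of the left maps across the mid-sagittal plane (axis 0).

    Raises SizingError when the grid cannot hold 10 disjoint cores per
    hemisphere at the requested margin.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or any(s < 16 for s in grid_shape):
        raise SizingError(f"grid {grid_shape} too small; every dimension must be >= 16")
    if margin < 0:
        raise ValueError("margin must be >= 0")

    nx, ny, nz = grid_shape
    half_x = nx // 2  # left hemisphere: x in [0, half_x)
    # lattice of 10 cells in the (y, z) plane; 5 cells along the longer axis
    if ny >= nz:
        cells_y, cells_z = 5, 2
    else:
        cells_y, cells_z = 2, 5
    cell_y = ny / cells_y
    cell_z = nz / cells_z
    half = min(half_x / 2.0, cell_y / 2.0, cell_z / 2.0)
    radius = half - margin - 1.0  # reserve 1 voxel for jitter
    if radius < 1.0:
        raise SizingError(
            f"grid {grid_shape} cannot hold 10 disjoint region cores per "
            f"hemisphere with margin {margin} (max core radius {radius:.2f})"
        )

    rng = np.random.default_rng(seed)
    xs = np.arange(nx, dtype=np.float64)
    ys = np.arange(ny, dtype=np.float64)
    zs = np.arange(nz, dtype=np.float64)

    weights: dict[tuple[Region, Hemisphere], np.ndarray] = {}
    for idx, region in enumerate(ALL_REGIONS):
        cy, cz = idx % cells_y, idx // cells_y
        jitter = rng.uniform(-1.0, 1.0, size=3)
        center = np.array(
            [
                half_x / 2.0 + jitter[0],
                (cy + 0.5) * cell_y + jitter[1],
                (cz + 0.5) * cell_z + jitter[2],
            ]
        )
        d = np.sqrt(
            (xs[:, None, None] - center[0]) ** 2
            + (ys[None, :, None] - center[1]) ** 2
            + (zs[None, None, :] - center[2]) ** 2
        )
        if margin > 0:
            left = np.clip((radius + margin - d) / margin, 0.0, 1.0)
        else:
            left = (d <= radius).astype(np.float64)
        left[half_x:, :, :] = 0.0  # support confined to the left hemisphere
        weights[(region, Hemisphere.LEFT)] = left
        weights[(region, Hemisphere.RIGHT)] = np.flip(left, axis=0).copy()

    atlas = ProbabilisticAtlas(
        grid_shape=grid_shape, voxel_spacing_mm=voxel_spacing_mm, weights=weights
    )
    atlas.validate()
    return atlas
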