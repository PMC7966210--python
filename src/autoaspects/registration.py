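"""Fitting the atlas grid to an input CT volume.

The scorer operates in atlas space, so a clinical volume must first be
brought onto the atlas grid. Two modes are supported:

``identity``
    The volume is already on the atlas grid (the phantom path; default).

``affine``
    A similarity transform (translation + rotation + isotropic scale) is
    estimated from intensity moments of the brain-tissue mask (voxels within
    the 10–55 HU parenchyma window), then refined by maximizing the overlap
    correlation between the transformed atlas brain-probability map and the
    volume's tissue mask with a derivative-free local search. This is a
    deliberately simple, deterministic fitting procedure; deformable
    registration is out of scope.

Transforms map atlas voxel coordinates to volume voxel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .atlas import ProbabilisticAtlas
from .errors import RegistrationError
from .phantom import CTVolume
from .scorer import HU_INCLUDE_MAX, HU_INCLUDE_MIN


@dataclass(frozen=True)
class AffineTransform:
    """x_volume = linear @ x_atlas + translation (voxel coordinates)."""

    linear: np.ndarray  # 3x3
    translation: np.ndarray  # 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=np.float64))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64)
        )
        if self.linear.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("AffineTransform needs a 3x3 linear part and a 3-vector")
        if abs(np.linalg.det(self.linear)) < 1e-8:
            raise RegistrationError("degenerate (non-invertible) linear part")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.linear, np.eye(3)) and np.allclose(self.translation, 0)

    def to_dict(self) -> dict:
        return {
            "linear": self.linear.tolist(),
            "translation": self.translation.tolist(),
        }


def brain_mask(volume: CTVolume) -> np.ndarray:
    """Brain-parenchyma mask: voxels within the HU inclusion window."""
    v = volume.voxels
    return (v >= HU_INCLUDE_MIN) & (v <= HU_INCLUDE_MAX)


def _mask_moments(mask: np.ndarray) -> tuple[float, np.ndarray, float]:
    """(total, centroid, rms radius) of a binary mask."""
    total = float(mask.sum())
    if total == 0:
        raise RegistrationError("empty brain-tissue mask")
    idx = np.argwhere(mask).astype(np.float64)
    centroid = idx.mean(axis=0)
    rms = float(np.sqrt(((idx - centroid) ** 2).sum(axis=1).mean()))
    return total, centroid, rms


def fit_atlas(
    volume: CTVolume,
    atlas: ProbabilisticAtlas,
    mode: str = "identity",
    refine: bool = True,
) -> AffineTransform:
    """Estimate the atlas-to-volume transform.

    ``identity`` returns the identity transform. ``affine`` initializes
    translation and isotropic scale from moments of the volume's tissue mask
    vs. the atlas brain box, then (optionally) refines translation, scale,
    and a small rotation by maximizing the Dice overlap between the
    forward-transformed atlas brain box and the volume's tissue mask
    (Nelder–Mead from a deterministic start).
    """
    if mode == "identity":
        return AffineTransform.identity()
    if mode != "affine":
        raise ValueError(f"unknown registration mode {mode!r}")

    mask = brain_mask(volume)
    _, vol_centroid, vol_rms = _mask_moments(mask)

    # the atlas "brain" is its full grid box (phantoms fill the grid with tissue)
    atlas_box = np.ones(atlas.grid_shape, dtype=bool)
    _, atl_centroid, atl_rms = _mask_moments(atlas_box)

    scale0 = vol_rms / atl_rms
    translation0 = vol_centroid - scale0 * atl_centroid

    if not refine:
        return AffineTransform(np.eye(3) * scale0, translation0)

    mask_f = mask.astype(np.float64)
    mask_sum = mask_f.sum()
    box_f = atlas_box.astype(np.float64)

    def objective(params: np.ndarray) -> float:
        tx, ty, tz, log_s, rx, ry, rz = params
        linear = float(np.exp(log_s)) * _small_rotation(rx, ry, rz)
        inv = np.linalg.inv(linear)
        t = np.array([tx, ty, tz])
        # push the atlas box into volume space: out[x] = box[inv(x - t)]
        pushed = ndimage.affine_transform(
            box_f, inv, offset=-inv @ t, output_shape=mask.shape, order=1, cval=0.0
        )
        dice = 2.0 * float((pushed * mask_f).sum()) / (float(pushed.sum()) + mask_sum)
        return -dice

    x0 = np.array(
        [translation0[0], translation0[1], translation0[2], np.log(scale0), 0, 0, 0]
    )
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": 150, "xatol": 1e-3, "fatol": 1e-7},
    )
    best = res.x if res.fun <= objective(x0) else x0
    tx, ty, tz, log_s, rx, ry, rz = best
    linear = float(np.exp(log_s)) * _small_rotation(rx, ry, rz)
    return AffineTransform(linear, np.array([tx, ty, tz]))


def _small_rotation(rx: float, ry: float, rz: float) -> np.ndarray:
    """Rotation matrix from Euler angles (radians), XYZ order."""
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    rot_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    rot_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rot_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rot_z @ rot_y @ rot_x


def resample_atlas(
    atlas: ProbabilisticAtlas,
    transform: AffineTransform,
    target_grid: tuple[int, int, int],
) -> ProbabilisticAtlas:
    """Resample every weight map onto the target grid through the transform.

    Trilinear interpolation; weights are clipped back to [0, 1]. The
    identity transform on the same grid returns bit-identical maps.
    """
    target_grid = tuple(int(s) for s in target_grid)
    if transform.is_identity and target_grid == atlas.grid_shape:
        weights = {k: w.copy() for k, w in atlas.weights.items()}
        return ProbabilisticAtlas(
            grid_shape=target_grid,
            voxel_spacing_mm=atlas.voxel_spacing_mm,
            weights=weights,
        )
    # output voxel x_vol samples the atlas at inv(linear) @ (x_vol - t)
    inv = np.linalg.inv(transform.linear)
    offset = -inv @ transform.translation
    weights = {}
    for key, w in atlas.weights.items():
        resampled = ndimage.affine_transform(
            w, inv, offset=offset, output_shape=target_grid, order=1, cval=0.0
        )
        weights[key] = np.clip(resampled, 0.0, 1.0)
    return ProbabilisticAtlas(
        grid_shape=target_grid,
        voxel_spacing_mm=atlas.voxel_spacing_mm,
        weights=weights,
    )
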