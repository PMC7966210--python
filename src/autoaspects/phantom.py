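"""Synthetic non-contrast CT phantoms with known region-level ground truth.

A phantom is a 3D Hounsfield-unit volume built on an atlas grid: normal
brain parenchyma (~35 HU) with additive Gaussian noise, optional ischemic
lesions expressed as a relative percentage drop of the mean HU in selected
regions of one hemisphere, and optional contaminating voxels that mimic
cerebrospinal fluid / old infarcts (< 10 HU) and calcification / bone
(> 55 HU). The contamination must be removed by the scorer's HU inclusion
window, so injecting it never changes a region's ground-truth status.

Lesion HU reduction is blended by the atlas weight: a voxel with weight w in
a region lesioned at d% has expected value ``background * (1 - w * d / 100)``,
so in hard-weight (w = 1) voxels the drop equals d exactly and the measured
relative difference recovers d in the noise-free limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import ProbabilisticAtlas
from .errors import SpecificationError
from .regions import ALL_REGIONS, Hemisphere, Region


@dataclass(frozen=True)
class LesionSpec:
    """A single simulated early-ischemic lesion."""

    region: Region
    hemisphere: Hemisphere
    relative_drop_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.relative_drop_pct < 100.0:
            raise SpecificationError(
                f"relative_drop_pct must be in [0, 100), got {self.relative_drop_pct}"
            )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic NCCT volume."""

    background_hu_mean: float = 35.0
    background_hu_sd: float = 1.5
    lesions: tuple[LesionSpec, ...] = ()
    csf_fraction: float = 0.0
    calcification_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lesions", tuple(self.lesions))
        if self.background_hu_sd < 0:
            raise SpecificationError("background_hu_sd must be >= 0")
        for frac in (self.csf_fraction, self.calcification_fraction):
            if not 0.0 <= frac < 1.0:
                raise SpecificationError("contamination fractions must lie in [0, 1)")
        sides = {les.hemisphere for les in self.lesions}
        if len(sides) > 1:
            raise SpecificationError("all lesions must lie on a single hemisphere")

    @property
    def lesioned_hemisphere(self) -> Hemisphere | None:
        return self.lesions[0].hemisphere if self.lesions else None


@dataclass
class CTVolume:
    """A 3D HU voxel grid with spacing metadata."""

    voxels: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise SpecificationError("CTVolume requires a 3D grid")
        if not np.isfinite(self.voxels).all():
            raise SpecificationError("CTVolume contains non-finite HU values")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)


@dataclass(frozen=True)
class GroundTruth:
    """Which regions are truly lesioned, and on which side."""

    hemisphere: Hemisphere | None
    status: dict[Region, bool] = field(default_factory=dict)  # True = affected

    @property
    def affected_regions(self) -> tuple[Region, ...]:
        return tuple(r for r in ALL_REGIONS if self.status[r])

    @property
    def true_score(self) -> int:
        return 10 - len(self.affected_regions)


def simulate_volume(
    atlas: ProbabilisticAtlas, spec: PhantomSpec
) -> tuple[CTVolume, GroundTruth]:
    """Render one phantom volume and its region-level ground truth.

    Deterministic for a fixed ``spec.seed``.
    """
    for les in spec.lesions:
        if (les.region, les.hemisphere) not in atlas.weights:
            raise SpecificationError(f"lesion region {les.region} not in atlas")

    rng = np.random.default_rng(spec.seed)
    vox = np.full(atlas.grid_shape, spec.background_hu_mean, dtype=np.float64)
    if spec.background_hu_sd > 0:
        vox += rng.normal(0.0, spec.background_hu_sd, size=atlas.grid_shape)

    for les in spec.lesions:
        w = atlas.weights[(les.region, les.hemisphere)]
        vox -= spec.background_hu_mean * (les.relative_drop_pct / 100.0) * w

    # contamination: per region support, replace a random voxel fraction
    for (region, hemi), w in atlas.weights.items():
        support = np.flatnonzero(w > 0)
        for frac, low, high in (
            (spec.csf_fraction, 0.0, 9.0),
            (spec.calcification_fraction, 60.0, 100.0),
        ):
            if frac <= 0:
                continue
            n_replace = int(round(frac * support.size))
            if n_replace == 0:
                continue
            chosen = rng.choice(support, size=n_replace, replace=False)
            vox.flat[chosen] = rng.uniform(low, high, size=n_replace)

    volume = CTVolume(voxels=vox, voxel_spacing_mm=atlas.voxel_spacing_mm)
    lesioned = {les.region for les in spec.lesions}
    truth = GroundTruth(
        hemisphere=spec.lesioned_hemisphere,
        status={r: r in lesioned for r in ALL_REGIONS},
    )
    return volume, truth


@dataclass(frozen=True)
class CohortSpec:
    """Distributional parameters for a simulated patient cohort.

    Defaults: the number of affected regions per patient is uniform on
    0..10, the affected side is a fair coin, and the per-region HU drop is
    uniform on 2–15%. Contamination fractions default to 5% CSF-like and
    5% calcification-like voxels per region so the exclusion rule is always
    exercised.
    """

    n_patients: int
    lesion_count_range: tuple[int, int] = (0, 10)
    drop_range_pct: tuple[float, float] = (2.0, 15.0)
    background_hu_mean: float = 35.0
    background_hu_sd: float = 1.5
    csf_fraction: float = 0.05
    calcification_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecificationError("n_patients must be >= 1")
        lo, hi = self.lesion_count_range
        if not (0 <= lo <= hi <= 10):
            raise SpecificationError("lesion_count_range must satisfy 0 <= lo <= hi <= 10")
        if not 0 <= self.drop_range_pct[0] <= self.drop_range_pct[1] < 100:
            raise SpecificationError("drop_range_pct must satisfy 0 <= lo <= hi < 100")


def simulate_cohort(
    atlas: ProbabilisticAtlas, spec: CohortSpec, seed: int
) -> list[tuple[CTVolume, GroundTruth]]:
    """Simulate a cohort of phantoms; deterministic per seed.

    Every patient gets a clinically affected side (even with zero lesions,
    matching the clinical situation where a side is known from symptoms);
    the returned ground truth carries that side.
    """
    rng = np.random.default_rng(seed)
    cohort: list[tuple[CTVolume, GroundTruth]] = []
    lo, hi = spec.lesion_count_range
    for _ in range(spec.n_patients):
        n_lesions = int(rng.integers(lo, hi + 1))
        side = Hemisphere.LEFT if rng.random() < 0.5 else Hemisphere.RIGHT
        regions = rng.choice(len(ALL_REGIONS), size=n_lesions, replace=False)
        lesions = tuple(
            LesionSpec(
                region=ALL_REGIONS[i],
                hemisphere=side,
                relative_drop_pct=float(rng.uniform(*spec.drop_range_pct)),
            )
            for i in regions
        )
        vol_seed = int(rng.integers(0, 2**31 - 1))
        volume, truth = simulate_volume(
            atlas,
            PhantomSpec(
                background_hu_mean=spec.background_hu_mean,
                background_hu_sd=spec.background_hu_sd,
                lesions=lesions,
                csf_fraction=spec.csf_fraction,
                calcification_fraction=spec.calcification_fraction,
                seed=vol_seed,
            ),
        )
        # zero-lesion patients still carry the clinically suspected side
        truth = GroundTruth(hemisphere=side, status=truth.status)
        cohort.append((volume, truth))
    return cohort
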