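"""Seeded 4D DCE phantoms with known enhancement kinetics.

Patient images cannot be redistributed, so every downstream stage is tested
against digital phantoms: a spherical tumor-suspicious lesion (TSL), a
perilesional shell directly adjacent to it (PLT) and normal-appearing
tissue (NAT) filling the rest of the grid.  Each compartment follows a
piecewise-linear enhancement trajectory — flat baseline, linear wash-in
ramp, linear wash-out ramp — scaled by a raw baseline intensity, with
optional i.i.d. additive Gaussian noise.  Because the downstream features
are themselves piecewise-linear fits, noiseless phantoms admit *exact*
recovery of the generating slopes and apex, which the test suite asserts.

The module also fabricates binary mask pairs with a closed-form DICE and
probability maps with a known maximum, as fixtures for the evaluation and
calibration stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .tic import DCESeries, TissueMask

__all__ = [
    "KineticSpec",
    "PhantomSpec",
    "default_phantom_spec",
    "generate_phantom",
    "generate_mask_pair",
    "generate_probability_map",
]

logger = logging.getLogger(__name__)

CURVE_TYPES = ("persistent", "plateau", "washout")


@dataclass(frozen=True)
class KineticSpec:
    """Piecewise-linear enhancement kinetics for one tissue compartment.

    The normalized trajectory is 1.0 up to ``onset_frame``, rises with
    ``wash_in_slope`` (normalized units per frame) until ``peak_frame``,
    then changes with ``wash_out_slope`` until the last frame.  Raw voxel
    intensity is the trajectory scaled by ``baseline_intensity``.
    ``curve_type`` names the enhancement archetype and must match the sign
    of the wash-out slope: persistent > 0, plateau ~ 0, washout < 0.
    """

    curve_type: str
    baseline_intensity: float
    onset_frame: int
    peak_frame: int
    wash_in_slope: float
    wash_out_slope: float
    n_frames: int

    #: |wash_out_slope| below this counts as plateau for the type check.
    _plateau_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.curve_type not in CURVE_TYPES:
            raise ValueError(f"unknown curve_type {self.curve_type!r}")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be > 0")
        if self.n_frames < 4:
            raise ValueError("n_frames must be >= 4")
        if not 0 <= self.onset_frame < self.peak_frame < self.n_frames:
            raise ValueError(
                "need 0 <= onset_frame < peak_frame < n_frames; got "
                f"{self.onset_frame}, {self.peak_frame}, {self.n_frames}"
            )
        if self.wash_in_slope <= 0:
            raise ValueError("wash_in_slope must be > 0")
        s = self.wash_out_slope
        expected = (
            "plateau"
            if abs(s) <= self._plateau_tol
            else ("persistent" if s > 0 else "washout")
        )
        if expected != self.curve_type:
            raise ValueError(
                f"curve_type {self.curve_type!r} inconsistent with "
                f"wash_out_slope {s:g} (expected {expected!r})"
            )

    @property
    def apex_value(self) -> float:
        """Normalized intensity at the peak frame (the true fitted maximum)."""
        return 1.0 + self.wash_in_slope * (self.peak_frame - self.onset_frame)

    def normalized_curve(self) -> np.ndarray:
        """The noiseless normalized trajectory, one value per frame."""
        frames = np.arange(self.n_frames, dtype=float)
        curve = np.ones(self.n_frames)
        rising = (frames > self.onset_frame) & (frames <= self.peak_frame)
        curve[rising] = 1.0 + self.wash_in_slope * (frames[rising] - self.onset_frame)
        falling = frames > self.peak_frame
        curve[falling] = self.apex_value + self.wash_out_slope * (
            frames[falling] - self.peak_frame
        )
        return curve

    def raw_curve(self) -> np.ndarray:
        return self.baseline_intensity * self.normalized_curve()


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, kinetics and noise of a synthetic DCE acquisition.

    The lesion is a sphere of ``lesion_radius`` voxels around
    ``lesion_center``; the perilesional shell extends ``rim_thickness``
    voxels beyond it and must fit inside the grid; all remaining voxels are
    normal-appearing tissue.  Identical spec + seed gives bit-identical
    volumes.
    """

    grid_shape: tuple[int, int, int] = (24, 24, 14)
    voxel_spacing: tuple[float, float, float] = (1.5, 1.5, 3.0)
    lesion_center: tuple[int, int, int] = (12, 12, 7)
    lesion_radius: float = 4.0
    rim_thickness: float = 2.0
    kinetics: dict[str, KineticSpec] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if self.lesion_radius <= 0 or self.rim_thickness < 1:
            raise ValueError("need lesion_radius > 0 and rim_thickness >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        outer = self.lesion_radius + self.rim_thickness
        for c, n in zip(self.lesion_center, self.grid_shape):
            if c - outer < 0 or c + outer > n - 1:
                raise ValueError(
                    f"lesion plus rim (radius {outer:g}) does not fit inside "
                    f"grid {self.grid_shape} at center {self.lesion_center}"
                )
        missing = [t for t in ("TSL", "PLT", "NAT") if t not in self.kinetics]
        if missing:
            raise ValueError(f"kinetics missing for tissues: {missing}")
        n_frames = {k.n_frames for k in self.kinetics.values()}
        if len(n_frames) != 1:
            raise ValueError("all compartments must share n_frames")

    @property
    def n_frames(self) -> int:
        return next(iter(self.kinetics.values())).n_frames


def default_phantom_spec(
    noise_sd: float = 0.0, seed: int = 0, n_frames: int = 30
) -> PhantomSpec:
    """A realistic default phantom mirroring the reported lesion kinetics.

    The lesion follows a fast wash-in / rapid-washout (type 3) curve with
    apex 4.2, the perilesional shell a plateau (type 2) with apex 2.2, and
    normal tissue a near-flat persistent (type 1) curve staying close to
    1.0 — the fitted-maximum triplet (4.2, 2.2, ~1.0) typical of a clearly
    discriminable clinically significant lesion.  Baseline intensity is 100
    raw units; the wash-in ramp runs from frame 1 (the last baseline frame
    under the default 2-frame baseline) to frame 9.
    """
    return PhantomSpec(
        kinetics={
            "TSL": KineticSpec("washout", 100.0, 1, 9, 0.40, -0.05, n_frames),
            "PLT": KineticSpec("plateau", 100.0, 1, 9, 0.15, 0.0, n_frames),
            "NAT": KineticSpec("persistent", 100.0, 1, 5, 0.02, 0.011, n_frames),
        },
        noise_sd=noise_sd,
        seed=seed,
    )


def _compartment_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    grids = np.ogrid[tuple(slice(0, n) for n in spec.grid_shape)]
    dist = np.sqrt(
        sum((g - c) ** 2 for g, c in zip(grids, spec.lesion_center))
    )
    tsl = dist <= spec.lesion_radius
    plt = (dist > spec.lesion_radius) & (
        dist <= spec.lesion_radius + spec.rim_thickness
    )
    nat = ~(tsl | plt)
    masks = {"TSL": tsl, "PLT": plt, "NAT": nat}
    for tissue, m in masks.items():
        if not m.any():
            raise ValueError(f"compartment {tissue} is empty for this geometry")
    return masks


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[DCESeries, TissueMask, dict[str, KineticSpec]]:
    """Build the 4D series, the tissue label mask and echo the ground truth.

    Every voxel of a compartment follows that compartment's noiseless raw
    trajectory, plus i.i.d. Gaussian noise of sd ``spec.noise_sd`` drawn
    from ``default_rng(spec.seed)``.
    """
    masks = _compartment_masks(spec)
    data = np.empty(spec.grid_shape + (spec.n_frames,), dtype=float)
    for tissue, mask in masks.items():
        data[mask] = spec.kinetics[tissue].raw_curve()
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data += rng.normal(0.0, spec.noise_sd, size=data.shape)
    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    label_map = {"TSL": 1, "PLT": 2, "NAT": 3}
    for tissue, code in label_map.items():
        labels[masks[tissue]] = code
    series = DCESeries(data, voxel_spacing=spec.voxel_spacing)
    logger.info(
        "phantom: grid=%s frames=%d voxels=%s",
        spec.grid_shape,
        spec.n_frames,
        {t: int(m.sum()) for t, m in masks.items()},
    )
    return series, TissueMask(labels, label_map), dict(spec.kinetics)


def generate_mask_pair(
    shape: tuple[int, int, int],
    overlap_fraction: float,
    seed: int = 0,
    n_voxels: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Two equal-size binary masks with a closed-form DICE.

    Both masks contain ``n_voxels`` voxels and share
    ``round(overlap_fraction * n_voxels)`` of them, placed at seeded random
    flat positions, so DICE = 2k / 2n = k/n exactly.  The construction
    counts |A|, |B| and |A ∩ B| are logged.
    """
    if not 0 <= overlap_fraction <= 1:
        raise ValueError(f"overlap_fraction {overlap_fraction} outside [0, 1]")
    total = int(np.prod(shape))
    k = int(round(overlap_fraction * n_voxels))
    needed = 2 * n_voxels - k
    if needed > total:
        raise ValueError(
            f"shape {shape} ({total} voxels) too small to place two "
            f"{n_voxels}-voxel masks with overlap {k} ({needed} needed)"
        )
    rng = np.random.default_rng(seed)
    flat = rng.permutation(total)[:needed]
    a = np.zeros(total, dtype=bool)
    b = np.zeros(total, dtype=bool)
    a[flat[:n_voxels]] = True
    b[flat[n_voxels - k : 2 * n_voxels - k]] = True
    logger.info("mask pair: |A|=%d |B|=%d |A∩B|=%d", n_voxels, n_voxels, k)
    return a.reshape(shape), b.reshape(shape)


def generate_probability_map(
    mask: np.ndarray,
    inside_level: float,
    outside_level: float,
    seed: int = 0,
) -> np.ndarray:
    """Voxelwise probability map whose maximum over ``mask`` is exact.

    Outside voxels draw uniformly from [0, outside_level); inside voxels
    draw from [outside_level, inside_level), except one deterministic
    lesion voxel pinned at exactly ``inside_level`` so the patient-level
    (max-voxel) prediction equals it by construction.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("mask is empty: nowhere to place the lesion signal")
    for name, level in (("inside_level", inside_level), ("outside_level", outside_level)):
        if not 0 <= level <= 1:
            raise ValueError(f"{name} {level} outside [0, 1]")
    if inside_level <= outside_level:
        raise ValueError(
            f"inside_level ({inside_level}) must exceed outside_level "
            f"({outside_level})"
        )
    rng = np.random.default_rng(seed)
    out = rng.uniform(0.0, outside_level, size=mask.shape)
    out[mask] = rng.uniform(outside_level, inside_level, size=int(mask.sum()))
    first_inside = tuple(np.argwhere(mask)[0])
    out[first_inside] = inside_level
    return out
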