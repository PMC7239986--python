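"""Digital striatal phantoms with ground-truth binding ratios.

A phantom is a 3-D volume on an MNI-like grid (default 91 x 109 x 91 voxels
at 2 mm isotropic) containing a brain ellipsoid at uniform background
intensity and one ellipsoid per striatal structure (left/right caudate and
putamen) whose noiseless intensity is ``background * (1 + r)`` for a
structure-specific true binding ratio ``r``.  Reconstruction smoothness is
emulated by an isotropic Gaussian point-spread function; reconstructed-image
noise by a post-blur Poisson draw.  Matched binary ROI masks (exact
structures, enlarged "big" putamen masks for hottest-voxels analysis, and a
reference region) are drawn on the unblurred geometry, so every quantified
SBR can be compared against a known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "VolumeImage",
    "ROIMask",
    "Ellipsoid",
    "PhantomSpec",
    "render_phantom",
    "default_phantom_spec",
]

_FWHM_TO_SIGMA = 1.0 / (8.0 * np.log(2.0)) ** 0.5  # sigma = FWHM / 2.3548

MASK_NAMES = (
    "putamen_L", "putamen_R", "caudate_L", "caudate_R",
    "big_putamen_L", "big_putamen_R", "reference",
)


@dataclass
class VolumeImage:
    """3-D scalar volume with isotropic voxel size in mm."""

    data: np.ndarray
    voxel_size: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not (self.voxel_size > 0):
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if np.any(self.data < 0):
            raise ValueError("volume intensities must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0


@dataclass
class ROIMask:
    """Binary region-of-interest mask on the same grid as its volume."""

    data: np.ndarray
    voxel_size: float = 2.0
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {self.data.shape}")
        if not self.data.any():
            raise ValueError(f"mask {self.name!r} is empty")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_ml(self) -> float:
        return self.n_voxels * self.voxel_size**3 / 1000.0


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in mm coordinates relative to the grid center."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be > 0, got {self.semi_axes}")

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(a * factor for a in self.semi_axes))


# Approximate MNI-space striatal geometry (mm, relative to grid center).
# Putamen ~4.9 ml per side; caudate head+body ~3.4 ml per side.
_DEFAULT_STRUCTURES = {
    "putamen_L": Ellipsoid((-26.0, 0.0, 2.0), (9.0, 13.0, 8.0)),
    "putamen_R": Ellipsoid((26.0, 0.0, 2.0), (9.0, 13.0, 8.0)),
    "caudate_L": Ellipsoid((-13.0, 16.0, 12.0), (5.0, 10.0, 8.0)),
    "caudate_R": Ellipsoid((13.0, 16.0, 12.0), (5.0, 10.0, 8.0)),
}

_DEFAULT_BRAIN = Ellipsoid((0.0, -4.0, 8.0), (70.0, 86.0, 66.0))

# Central exclusion standing in for thalamus / brain stem / ventricles.
_DEFAULT_CENTRAL_EXCLUSION = Ellipsoid((0.0, -12.0, 0.0), (18.0, 26.0, 30.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and degradation settings for one phantom.

    ``binding`` maps each structure name to its true binding ratio ``r``
    (noiseless structure intensity is ``background * (1 + r)``).
    ``psf_fwhm`` is the Gaussian point-spread FWHM in mm; ``noise_scale``
    the expected counts per background voxel for the Poisson emulation
    (0 disables noise).
    """

    shape: tuple[int, int, int] = (91, 109, 91)
    voxel_size: float = 2.0
    background: float = 100.0
    structures: dict[str, Ellipsoid] = field(
        default_factory=lambda: dict(_DEFAULT_STRUCTURES)
    )
    binding: dict[str, float] = field(
        default_factory=lambda: {n: 4.0 for n in _DEFAULT_STRUCTURES}
    )
    brain: Ellipsoid = _DEFAULT_BRAIN
    central_exclusion: Ellipsoid = _DEFAULT_CENTRAL_EXCLUSION
    big_putamen_factor: float = 2.0
    psf_fwhm: float = 7.0
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.background > 0):
            raise ValueError(f"background must be > 0, got {self.background}")
        if self.psf_fwhm < 0:
            raise ValueError(f"psf_fwhm must be >= 0, got {self.psf_fwhm}")
        if self.noise_scale < 0:
            raise ValueError(f"noise_scale must be >= 0, got {self.noise_scale}")
        if set(self.binding) != set(self.structures):
            raise ValueError(
                "binding must provide a ratio for every structure: "
                f"structures={sorted(self.structures)}, binding={sorted(self.binding)}"
            )
        if self.big_putamen_factor <= 1:
            raise ValueError("big_putamen_factor must exceed 1 (strict superset)")


def _grid_mm(shape: tuple[int, int, int], voxel_size: float) -> tuple[np.ndarray, ...]:
    """Voxel-center coordinates in mm, origin at the grid center."""
    axes = [voxel_size * (np.arange(n) - (n - 1) / 2.0) for n in shape]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid_mask(
    ell: Ellipsoid, grid: tuple[np.ndarray, ...]
) -> np.ndarray:
    q = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grid, ell.center, ell.semi_axes)
    )
    return q <= 1.0


def default_phantom_spec(**overrides) -> PhantomSpec:
    """Default phantom; keyword overrides replace any PhantomSpec field.

    Per-structure binding ratios may be overridden with
    ``binding={"putamen_L": 0.5, ...}`` (missing structures keep the
    default ratio).
    """
    binding = {n: 4.0 for n in _DEFAULT_STRUCTURES}
    binding.update(overrides.pop("binding", {}))
    return PhantomSpec(binding=binding, **overrides)


def render_phantom(spec: PhantomSpec) -> tuple[VolumeImage, dict[str, ROIMask]]:
    """Render one phantom volume plus its matched ROI masks.

    The noiseless volume (blur applied, ``noise_scale == 0``) is
    deterministic regardless of the seed; the Poisson stage uses
    ``spec.seed``.  Structure ellipsoids must be pairwise disjoint on the
    grid, otherwise the ground truth would be ambiguous and the spec is
    rejected.
    """
    grid = _grid_mm(spec.shape, spec.voxel_size)
    brain = _ellipsoid_mask(spec.brain, grid)
    struct_masks = {
        name: _ellipsoid_mask(ell, grid) & brain
        for name, ell in spec.structures.items()
    }
    for name, m in struct_masks.items():
        if not m.any():
            raise ValueError(f"structure {name!r} lies outside the brain/grid")
    names = list(struct_masks)
    occupancy = np.zeros(spec.shape, dtype=np.int8)
    for m in struct_masks.values():
        occupancy += m
    if occupancy.max() > 1:
        raise ValueError(
            "structure ellipsoids overlap on the grid "
            f"({int((occupancy > 1).sum())} shared voxels); ground truth "
            "would be ambiguous"
        )

    vol = np.zeros(spec.shape, dtype=float)
    vol[brain] = spec.background
    for name in names:
        vol[struct_masks[name]] = spec.background * (1.0 + spec.binding[name])

    if spec.psf_fwhm > 0:
        sigma_vox = spec.psf_fwhm * _FWHM_TO_SIGMA / spec.voxel_size
        vol = gaussian_filter(vol, sigma_vox, mode="reflect")

    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        lam = vol * (spec.noise_scale / spec.background)
        vol = rng.poisson(lam).astype(float) * (spec.background / spec.noise_scale)

    masks: dict[str, ROIMask] = {}
    for name in names:
        masks[name] = ROIMask(struct_masks[name], spec.voxel_size, name)
    exclusion = np.zeros(spec.shape, dtype=bool)
    for side in ("L", "R"):
        pt = spec.structures[f"putamen_{side}"]
        big = _ellipsoid_mask(pt.scaled(spec.big_putamen_factor), grid) & brain
        if not (big & struct_masks[f"putamen_{side}"]).sum() == masks[
            f"putamen_{side}"
        ].n_voxels or not big.sum() > masks[f"putamen_{side}"].n_voxels:
            raise ValueError(f"big_putamen_{side} is not a strict superset")
        masks[f"big_putamen_{side}"] = ROIMask(big, spec.voxel_size, f"big_putamen_{side}")
        exclusion |= big
        cd = spec.structures[f"caudate_{side}"]
        exclusion |= _ellipsoid_mask(cd.scaled(spec.big_putamen_factor), grid)
    exclusion |= _ellipsoid_mask(spec.central_exclusion, grid)
    masks["reference"] = ROIMask(brain & ~exclusion, spec.voxel_size, "reference")

    return VolumeImage(vol, spec.voxel_size), masks
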