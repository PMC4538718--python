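"""Digital sandwich-style phantom: ground-truth uptake maps and PET simulation.

The physical technique this emulates builds a 3-D radioactive object by
stacking 2-mm-spaced printed slices of a modelled FDG uptake map.  Here the
"printout template" is a fine-grid relative-activity volume
(:class:`UptakeTemplate`) carrying its own lesion mask, i.e. the ground
truth comes for free.  A simplified scanner model
(:func:`simulate_pet`) turns a template into a PET-like image by
volume-conserving resampling onto the coarse PET grid, isotropic Gaussian
blurring (stand-in for scanner resolution plus reconstruction post-filter)
and Poisson noise.

Lesions are spheres, spheroids or procedurally generated irregular shapes,
filled with one of five uptake patterns: homogeneous, two-level, Gaussian,
necrotic, necrotic-Gaussian.  All relative levels are expressed against a
local background of 1.0 and a tumour-to-background ratio (TBR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import sph_harm_y

from .grids import GridSpec, cover_grid, resample_mean

__all__ = [
    "SPHERE_DIAMETERS_MM",
    "DEFAULT_TEMPLATE_SPACING",
    "DEFAULT_PET_SPACING",
    "DEFAULT_PSF_FWHM_MM",
    "BinaryMask",
    "PETImage",
    "LesionSpec",
    "ScannerConfig",
    "UptakeTemplate",
    "BackgroundStructure",
    "PageImage",
    "MarkerOffsets",
    "make_background",
    "make_lesion_template",
    "make_irregular_shape",
    "simulate_pet",
    "extract_ground_truth",
    "export_printout_pages",
    "locate_markers",
    "scale_mask",
]

#: Sphere battery S1-S6 diameters (mm).
SPHERE_DIAMETERS_MM = {"S1": 10.0, "S2": 13.0, "S3": 17.0, "S4": 22.0, "S5": 28.0, "S6": 38.0}

#: Template grid: in-plane 1 mm, axial 2 mm (the stacked-sheet pitch).
DEFAULT_TEMPLATE_SPACING = (1.0, 1.0, 2.0)

#: Clinical-protocol PET reconstruction grid spacing (mm).
DEFAULT_PET_SPACING = (2.73, 2.73, 3.27)

#: Isotropic Gaussian PSF standing in for resolution + post-filter (mm FWHM).
DEFAULT_PSF_FWHM_MM = 6.4

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

SHAPE_KINDS = ("sphere", "spheroid", "irregular")
PATTERNS = ("homogeneous", "two_level", "gaussian", "necrotic", "necrotic_gaussian")


# ---------------------------------------------------------------------------
# containers


@dataclass
class BinaryMask:
    """Boolean volume on an explicit grid."""

    grid: GridSpec
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * self.grid.voxel_volume

    @property
    def volume_ml(self) -> float:
        return self.volume_mm3 / 1000.0

    def same_as(self, other: "BinaryMask") -> bool:
        return self.grid.same_geometry(other.grid) and bool(
            np.array_equal(self.voxels, other.voxels)
        )


@dataclass
class PETImage:
    """Non-negative intensity volume, simulated or loaded from file."""

    grid: GridSpec
    values: np.ndarray
    provenance: str = "simulated"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("image shape does not match grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("image values must be finite")
        if np.any(self.values < 0):
            raise ValueError("image values must be non-negative")


@dataclass(frozen=True)
class LesionSpec:
    """Declarative lesion description.

    ``size`` is a diameter in mm for spheres and a target volume in mL for
    spheroids and irregular shapes.  ``centre`` defaults to the grid centre.
    """

    shape_kind: str
    size: float
    pattern: str = "homogeneous"
    tbr: float = 4.0
    centre: tuple[float, float, float] | None = None
    shape_seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in SHAPE_KINDS:
            raise ValueError(f"shape_kind must be one of {SHAPE_KINDS}")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.size <= 0:
            raise ValueError("size must be > 0")
        if self.tbr <= 1:
            raise ValueError("tbr must be > 1")

    @property
    def is_necrotic(self) -> bool:
        return self.pattern in ("necrotic", "necrotic_gaussian")


@dataclass(frozen=True)
class ScannerConfig:
    """Simplified scanner model parameters.

    ``noise_scale`` is the expected number of counts per unit (background
    normalised) intensity per voxel, controlling the Poisson regime; the
    recorded image is counts / noise_scale so intensities stay on the
    template's relative scale.
    """

    pet_grid: GridSpec | None = None
    psf_fwhm: float = DEFAULT_PSF_FWHM_MM
    noise_scale: float = 500.0
    noise_seed: int = 0
    noiseless: bool = False

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if not self.noiseless and self.noise_scale <= 0:
            raise ValueError("noise_scale must be > 0 unless noiseless")


@dataclass
class UptakeTemplate:
    """Fine-grid relative-activity map with its ground-truth lesion mask.

    ``lesion_mask`` is always the full outer lesion shape.  For necrotic
    patterns the delivered ground truth (:attr:`ground_truth`) excludes the
    inactive core, which is retained separately in ``core_mask``.
    """

    grid: GridSpec
    values: np.ndarray
    lesion_mask: BinaryMask | None = None
    core_mask: BinaryMask | None = None
    lesion_spec: LesionSpec | None = None
    background_level: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if np.any(self.values < 0):
            raise ValueError("uptake values must be non-negative")

    @property
    def ground_truth(self) -> BinaryMask:
        """Delivered ground-truth mask (outer shape minus necrotic core)."""
        if self.lesion_mask is None:
            raise ValueError("template has no lesion")
        if self.lesion_spec is not None and self.lesion_spec.is_necrotic and self.core_mask is not None:
            return BinaryMask(self.grid, self.lesion_mask.voxels & ~self.core_mask.voxels)
        return self.lesion_mask

    @property
    def total_activity(self) -> float:
        """Integral of relative activity over the volume (value x mm^3)."""
        return float(self.values.sum() * self.grid.voxel_volume)


@dataclass(frozen=True)
class BackgroundStructure:
    """Anatomical background structure with a constant relative uptake level.

    ``kind`` is ``"ellipsoid"`` (semiaxes in mm) or ``"cuboid"`` (half sizes
    in mm), centred at ``centre``.
    """

    centre: tuple[float, float, float]
    semiaxes: tuple[float, float, float]
    level: float
    kind: str = "ellipsoid"

    def __post_init__(self) -> None:
        if self.kind not in ("ellipsoid", "cuboid"):
            raise ValueError("kind must be 'ellipsoid' or 'cuboid'")
        if self.level <= 0:
            raise ValueError("uptake level must be > 0")
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError("semiaxes must be > 0")

    def inside(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        dx = (x - self.centre[0]) / self.semiaxes[0]
        dy = (y - self.centre[1]) / self.semiaxes[1]
        dz = (z - self.centre[2]) / self.semiaxes[2]
        if self.kind == "cuboid":
            return (np.abs(dx) <= 1) & (np.abs(dy) <= 1) & (np.abs(dz) <= 1)
        return dx * dx + dy * dy + dz * dz <= 1.0


# ---------------------------------------------------------------------------
# rasterisation helpers


def coverage_fraction(
    grid: GridSpec, inside_fn, supersample: tuple[int, int, int] = (4, 4, 6)
) -> np.ndarray:
    """Fraction of each voxel covered by an analytic region, by sub-sampling."""
    frac = np.zeros(grid.shape)
    nsub = int(np.prod(supersample))
    offsets = [(np.arange(s) + 0.5) / s - 0.5 for s in supersample]
    for ox in offsets[0]:
        x = (grid.axis_centres(0) + ox * grid.spacing[0])[:, None, None]
        for oy in offsets[1]:
            y = (grid.axis_centres(1) + oy * grid.spacing[1])[None, :, None]
            for oz in offsets[2]:
                z = (grid.axis_centres(2) + oz * grid.spacing[2])[None, None, :]
                frac += inside_fn(x, y, z)
    return frac / nsub


def rasterise(grid: GridSpec, inside_fn, supersample: tuple[int, int, int] = (4, 4, 6)) -> np.ndarray:
    """Volume-matched binarisation of an analytic region.

    Voxels are ranked by covered fraction and the top ``round(sum of
    fractions)`` are kept, so the binary volume matches the integrated
    analytic volume to within half a voxel regardless of how the shape
    aligns with the (anisotropic) grid - a plain majority rule can be
    several percent off for small shapes on 2-mm slices.  Fully covered
    voxels are always included, voxels the region does not touch never are.
    """
    frac = coverage_fraction(grid, inside_fn, supersample)
    target = int(round(frac.sum()))
    if target <= 0:
        return np.zeros(grid.shape, dtype=bool)
    order = np.argsort(-frac.ravel(), kind="stable")
    out = np.zeros(frac.size, dtype=bool)
    out[order[:target]] = True
    out &= frac.ravel() > 0
    return out.reshape(grid.shape)


def scale_mask(mask: BinaryMask, factor: float, centre: tuple[float, float, float] | None = None) -> BinaryMask:
    """Scaled copy of a mask about its centroid (linear factor, any shape).

    A voxel belongs to the scaled mask iff its centre, pulled back towards
    the centroid by ``1/factor``, lies inside the original mask.
    """
    if not 0 < factor:
        raise ValueError("factor must be > 0")
    if mask.count == 0:
        raise ValueError("cannot scale an empty mask")
    if centre is None:
        com = ndimage.center_of_mass(mask.voxels)
        centre = tuple(mask.grid.index_to_world(np.asarray(com)))
    x, y, z = mask.grid.meshgrid()
    coords = [
        (c + (w - c) / factor - mask.grid.origin[a]) / mask.grid.spacing[a]
        for a, (w, c) in enumerate(zip((x, y, z), centre))
    ]
    bx, by, bz = np.broadcast_arrays(*coords)
    vals = ndimage.map_coordinates(
        mask.voxels.astype(float), np.stack([bx, by, bz]), order=1, mode="constant", cval=0.0
    )
    return BinaryMask(mask.grid, vals >= 0.5)


# ---------------------------------------------------------------------------
# template construction


def make_background(grid: GridSpec, structures: list[BackgroundStructure] | None = None) -> UptakeTemplate:
    """Uniform background (relative level 1.0) with optional structures.

    Overlapping structures are painted in list order, so a later structure
    wins; the overlap is reported as a warning.
    """
    values = np.ones(grid.shape)
    occupied = np.zeros(grid.shape, dtype=bool)
    for s in structures or []:
        inside = rasterise(grid, s.inside, supersample=(2, 2, 2))
        if np.any(inside & occupied):
            warnings.warn(
                "overlapping background structures; the later specification wins",
                stacklevel=2,
            )
        values[inside] = s.level
        occupied |= inside
    empty = BinaryMask(grid, np.zeros(grid.shape, dtype=bool))
    return UptakeTemplate(grid, values, lesion_mask=empty)


def _equivalent_diameter_mm(volume_mm3: float) -> float:
    return (6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0)


def _outer_mask(grid: GridSpec, spec: LesionSpec, centre: tuple[float, float, float],
                spheroid_axis_ratios: tuple[float, float, float]) -> BinaryMask:
    if spec.shape_kind == "sphere":
        r = spec.size / 2.0

        def inside(x, y, z):
            return (x - centre[0]) ** 2 + (y - centre[1]) ** 2 + (z - centre[2]) ** 2 <= r * r

        return BinaryMask(grid, rasterise(grid, inside))
    if spec.shape_kind == "spheroid":
        target_mm3 = spec.size * 1000.0
        r1, r2, r3 = spheroid_axis_ratios
        s = (3.0 * target_mm3 / (4.0 * np.pi * r1 * r2 * r3)) ** (1.0 / 3.0)
        axes = (r1 * s, r2 * s, r3 * s)

        def inside(x, y, z):
            return (
                ((x - centre[0]) / axes[0]) ** 2
                + ((y - centre[1]) / axes[1]) ** 2
                + ((z - centre[2]) / axes[2]) ** 2
                <= 1.0
            )

        return BinaryMask(grid, rasterise(grid, inside))
    return make_irregular_shape(grid, spec.size, spec.shape_seed, centre=centre)


def _edge_clearance_mm(mask: BinaryMask) -> float:
    idx = np.argwhere(mask.voxels)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    clear = []
    for a in range(3):
        clear.append(lo[a] * mask.grid.spacing[a])
        clear.append((mask.grid.shape[a] - 1 - hi[a]) * mask.grid.spacing[a])
    return float(min(clear))


def make_lesion_template(
    background: UptakeTemplate,
    spec: LesionSpec,
    *,
    inner_fraction: float = 0.5,
    core_volume_fraction: float = 0.4,
    gaussian_fwhm_mm: float | None = None,
    spheroid_axis_ratios: tuple[float, float, float] = (1.0, 0.8, 1.25),
    min_edge_clearance_mm: float = 10.0,
) -> UptakeTemplate:
    """Insert a lesion with the requested uptake pattern into a background map.

    Pattern conventions against the local background level ``B`` (mean
    background value under the lesion footprint):

    * ``homogeneous``: ``tbr * B`` everywhere in the lesion.
    * ``two_level``: low rim ``L = tbr * B`` and a concentric central high
      region ``H = 2 L - B`` so the two contrast steps are equal
      (``H - L = L - B``).  The high region is a scaled copy of the outer
      shape with linear factor ``inner_fraction``.
    * ``gaussian``: background plus the homogeneous excess smoothed with a
      Gaussian kernel (default FWHM = half the equivalent diameter),
      modelling centrally peaked uptake.
    * ``necrotic``: homogeneous with a concentric core (a scaled copy
      holding ``core_volume_fraction`` of the lesion volume) reset to ``B``
      (zero excess).
    * ``necrotic_gaussian``: the necrotic excess, Gaussian smoothed.
    """
    if not 0 < inner_fraction < 1:
        raise ValueError("inner_fraction must be in (0, 1)")
    if not 0 < core_volume_fraction < 1:
        raise ValueError("core larger than lesion: core_volume_fraction must be in (0, 1)")
    grid = background.grid
    centre = spec.centre if spec.centre is not None else grid.centre
    outer = _outer_mask(grid, spec, centre, spheroid_axis_ratios)
    if outer.count == 0:
        raise ValueError("lesion rasterised to an empty mask")
    if _edge_clearance_mm(outer) < min_edge_clearance_mm:
        raise ValueError(
            f"lesion does not fit with >= {min_edge_clearance_mm} mm clearance to the grid edges"
        )

    b_level = float(background.values[outer.voxels].mean())
    values = background.values.copy()
    excess = (spec.tbr - 1.0) * b_level
    core = None

    if gaussian_fwhm_mm is None:
        # centrally peaked pattern: kernel of half the equivalent diameter;
        # necrotic smoothing only softens the rim/core edges - a broad kernel
        # would fill the cold core in and erase the annular pattern
        factor = 4.0 if spec.pattern == "necrotic_gaussian" else 2.0
        gaussian_fwhm_mm = _equivalent_diameter_mm(outer.volume_mm3) / factor
    sigma_vox = tuple(gaussian_fwhm_mm * _FWHM_TO_SIGMA / s for s in grid.spacing)

    if spec.pattern == "homogeneous":
        values[outer.voxels] = spec.tbr * b_level
    elif spec.pattern == "two_level":
        low = spec.tbr * b_level
        high = 2.0 * low - b_level
        inner = scale_mask(outer, inner_fraction, centre=centre)
        values[outer.voxels] = low
        values[inner.voxels] = high
    elif spec.pattern == "gaussian":
        bump = np.where(outer.voxels, excess, 0.0)
        values = values + ndimage.gaussian_filter(bump, sigma_vox, mode="constant")
    elif spec.pattern == "necrotic":
        core = scale_mask(outer, core_volume_fraction ** (1.0 / 3.0), centre=centre)
        values[outer.voxels] = spec.tbr * b_level
        values[core.voxels] = b_level
    elif spec.pattern == "necrotic_gaussian":
        core = scale_mask(outer, core_volume_fraction ** (1.0 / 3.0), centre=centre)
        bump = np.where(outer.voxels & ~core.voxels, excess, 0.0)
        values = values + ndimage.gaussian_filter(bump, sigma_vox, mode="constant")

    return UptakeTemplate(
        grid, values, lesion_mask=outer, core_mask=core, lesion_spec=spec,
        background_level=b_level,
    )


# ---------------------------------------------------------------------------
# irregular shape generator


def make_irregular_shape(
    grid: GridSpec,
    target_volume_ml: float,
    shape_seed: int,
    *,
    centre: tuple[float, float, float] | None = None,
    amplitude: float = 0.3,
    degree: int = 4,
    tolerance: float = 0.05,
) -> BinaryMask:
    """Connected non-convex lesion shape hitting a target volume.

    The shape is star-shaped about its centre: a sphere whose radius is
    modulated by a random real spherical-harmonic series of degree
    ``<= degree`` (seeded, hence deterministic), then rescaled so the
    rasterised volume is within ``tolerance`` of ``target_volume_ml``.
    This is a procedural stand-in for a manually delineated clinical
    tumour outline.
    """
    if target_volume_ml <= 0:
        raise ValueError("target volume must be > 0")
    rng = np.random.default_rng(shape_seed)
    if centre is None:
        centre = grid.centre

    # random real spherical-harmonic modulation, tabulated on (theta, phi)
    ntheta, nphi = 128, 256
    theta = np.linspace(0.0, np.pi, ntheta)
    phi = np.linspace(0.0, 2.0 * np.pi, nphi, endpoint=False)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    f = np.zeros_like(tt)
    for ell in range(1, degree + 1):
        for m in range(0, ell + 1):
            c = rng.normal(0.0, 1.0 / (1.0 + ell))
            y = sph_harm_y(ell, m, tt, pp)
            if m == 0:
                f += c * y.real
            else:
                c2 = rng.normal(0.0, 1.0 / (1.0 + ell))
                f += np.sqrt(2.0) * (c * y.real + c2 * y.imag)
    f *= amplitude / max(f.std(), 1e-12)
    radius_mod = np.clip(1.0 + f, 0.25, None)

    # analytic first guess for the base radius: V = (r0^3 / 3) * Int R^3 dOmega
    dtheta = theta[1] - theta[0]
    dphi = phi[1] - phi[0]
    integral = float(np.sum(radius_mod**3 * np.sin(tt)) * dtheta * dphi)
    target_mm3 = target_volume_ml * 1000.0
    r0 = (3.0 * target_mm3 / integral) ** (1.0 / 3.0)

    def inside(x, y, z):
        dx, dy, dz = x - centre[0], y - centre[1], z - centre[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        with np.errstate(invalid="ignore"):
            th = np.arccos(np.clip(np.divide(dz, np.maximum(r, 1e-12)), -1.0, 1.0))
        ph = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
        it = np.clip(np.round(th / np.pi * (ntheta - 1)).astype(int), 0, ntheta - 1)
        ip = np.round(ph / (2.0 * np.pi) * nphi).astype(int) % nphi
        return r <= r0 * radius_mod[it, ip]

    for _ in range(10):
        mask = rasterise(grid, inside)
        vol = mask.sum() * grid.voxel_volume
        if vol <= 0:
            raise ValueError("target volume unreachable on this grid")
        if abs(vol - target_mm3) / target_mm3 <= tolerance:
            return BinaryMask(grid, mask)
        r0 *= (target_mm3 / vol) ** (1.0 / 3.0)
    raise ValueError("volume rescaling did not converge to the target volume")


# ---------------------------------------------------------------------------
# scanner model


def simulate_pet(template: UptakeTemplate, cfg: ScannerConfig) -> PETImage:
    """Simulate a PET-like image from a template.

    Pipeline: (1) exact partial-volume resample of the fine template onto
    the PET grid (each PET voxel reads the mean template activity over its
    box, so the integrated activity over the covered region is conserved),
    (2) isotropic 3-D Gaussian blur of ``cfg.psf_fwhm`` FWHM with
    edge-replicating padding, (3) unless ``noiseless``, per-voxel Poisson
    counts with mean ``noise_scale x blurred value``, divided back by
    ``noise_scale``.  Deterministic for a fixed ``noise_seed``.
    """
    if np.any(template.values < 0):
        raise ValueError("template has negative values")
    pet_grid = cfg.pet_grid if cfg.pet_grid is not None else cover_grid(
        template.grid, DEFAULT_PET_SPACING
    )
    values, covered = resample_mean(template.values, template.grid, pet_grid)
    if template.values.max() > 0 and not np.any(covered):
        raise ValueError("template and PET grids do not overlap")
    if cfg.psf_fwhm > 0:
        sigma = tuple(cfg.psf_fwhm * _FWHM_TO_SIGMA / s for s in pet_grid.spacing)
        values = ndimage.gaussian_filter(values, sigma, mode="nearest")
    if not cfg.noiseless:
        rng = np.random.default_rng(cfg.noise_seed)
        values = rng.poisson(cfg.noise_scale * values).astype(float) / cfg.noise_scale
    return PETImage(pet_grid, values, provenance="simulated")


def extract_ground_truth(
    template: UptakeTemplate,
    pet_grid: GridSpec,
    *,
    which: str = "ground_truth",
) -> BinaryMask:
    """Resample the template's ground truth onto a PET grid.

    A PET voxel is true iff its fractional coverage by the fine-grid mask is
    at least one half.  ``which`` selects the delivered ground truth
    (core-excluding for necrotic lesions, the default), the full ``outer``
    shape, or the necrotic ``core``.
    """
    if which == "ground_truth":
        mask = template.ground_truth
    elif which == "outer":
        if template.lesion_mask is None:
            raise ValueError("template has no lesion")
        mask = template.lesion_mask
    elif which == "core":
        if template.core_mask is None:
            raise ValueError("template has no necrotic core")
        mask = template.core_mask
    else:
        raise ValueError("which must be 'ground_truth', 'outer' or 'core'")
    if mask.count == 0:
        raise ValueError("cannot extract ground truth from an empty lesion mask")
    coverage, _ = resample_mean(mask.voxels.astype(float), template.grid, pet_grid)
    return BinaryMask(pet_grid, coverage >= 0.5)


# ---------------------------------------------------------------------------
# printout pages and alignment markers


@dataclass
class PageImage:
    """One printable page: grey levels in [0, 1] plus T/L/R marker positions.

    ``marker_positions`` are (x, y) page coordinates in mm, x rightwards and
    y downwards from the page's top-left corner.
    """

    page_index: int
    pixels: np.ndarray
    marker_positions: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]


def export_printout_pages(
    template: UptakeTemplate,
    page_width_mm: float = 168.0,
    page_height_mm: float = 197.0,
    marker_offset_mm: float = 20.0,
    marker_arm_mm: float = 5.0,
) -> list[PageImage]:
    """One grey-level page per 2-mm axial slice, with T/L/R cross markers.

    Values are linearly mapped to [0, 1] grey by the template's global
    maximum (printer-calibration correction is applied separately by the
    calibration module).  The pattern is centred on the page and the three
    alignment crosses sit ``marker_offset_mm`` outside its bounding box.
    """
    if abs(template.grid.spacing[2] - 2.0) > 1e-6:
        raise ValueError("printout export requires 2-mm axial template spacing")
    pitch = template.grid.spacing[0]
    if abs(template.grid.spacing[1] - pitch) > 1e-9:
        raise ValueError("printout export requires isotropic in-plane spacing")
    npx = int(round(page_width_mm / pitch))
    npy = int(round(page_height_mm / pitch))
    nx, ny, nz = template.grid.shape
    ext_x, ext_y = nx * pitch, ny * pitch
    need_x = ext_x + 2.0 * (marker_offset_mm + marker_arm_mm)
    need_y = ext_y + 2.0 * (marker_offset_mm + marker_arm_mm)
    if need_x > page_width_mm or need_y > page_height_mm:
        raise ValueError("pattern plus markers exceeds the printable area")

    off_x = (npx - nx) // 2
    off_y = (npy - ny) // 2
    vmax = template.values.max()
    # bounding box of the pattern region on the page, mm
    x0, x1 = off_x * pitch, (off_x + nx) * pitch
    y0, y1 = off_y * pitch, (off_y + ny) * pitch
    t_pos = ((x0 + x1) / 2.0, y0 - marker_offset_mm)
    l_pos = (x0 - marker_offset_mm, (y0 + y1) / 2.0)
    r_pos = (x1 + marker_offset_mm, (y0 + y1) / 2.0)
    arm_px = max(1, int(round(marker_arm_mm / pitch)))

    def draw_cross(page: np.ndarray, pos: tuple[float, float]) -> None:
        i = int(round(pos[0] / pitch))
        j = int(round(pos[1] / pitch))
        page[max(0, i - arm_px):i + arm_px + 1, j] = 1.0
        page[i, max(0, j - arm_px):j + arm_px + 1] = 1.0

    pages = []
    for k in range(nz):
        page = np.zeros((npx, npy))
        if vmax > 0:
            page[off_x:off_x + nx, off_y:off_y + ny] = template.values[:, :, k] / vmax
        for pos in (t_pos, l_pos, r_pos):
            draw_cross(page, pos)
        pages.append(PageImage(page_index=k, pixels=page, marker_positions=(t_pos, l_pos, r_pos)))
    return pages


@dataclass
class MarkerOffsets:
    """Per-slice alignment-marker localisation result.

    ``offsets_mm[label]`` holds, per slice, the located in-plane position
    minus that marker's mean position over slices (the reported alignment
    error); ``deviation_from_expected_mm`` is relative to the expected
    position instead.  Flat search windows are flagged low-confidence.
    """

    labels: tuple[str, ...]
    positions_mm: dict[str, np.ndarray]
    offsets_mm: dict[str, np.ndarray]
    deviation_from_expected_mm: dict[str, np.ndarray]
    low_confidence: dict[str, np.ndarray]


def locate_markers(
    image: PETImage,
    expected_positions: list[tuple[float, float]],
    window: int = 5,
    labels: tuple[str, ...] = ("T", "L", "R"),
) -> MarkerOffsets:
    """Locate alignment markers slice by slice.

    Each marker is the highest-intensity voxel in a ``window x window``
    square around its expected in-plane position (ties broken by lowest
    linear index); a window clipped at the image boundary raises a warning.
    """
    if len(expected_positions) != len(labels):
        labels = tuple(f"M{i}" for i in range(len(expected_positions)))
    half = window // 2
    nz = image.grid.shape[2]
    positions: dict[str, np.ndarray] = {}
    lowconf: dict[str, np.ndarray] = {}
    for lab, (ex, ey) in zip(labels, expected_positions):
        ci, cj = image.grid.world_to_voxel([ex, ey, image.grid.origin[2]])[:2]
        if not (0 <= ci < image.grid.shape[0] and 0 <= cj < image.grid.shape[1]):
            raise ValueError(f"expected position of marker {lab} outside image")
        i0, i1 = ci - half, ci + half + 1
        j0, j1 = cj - half, cj + half + 1
        if i0 < 0 or j0 < 0 or i1 > image.grid.shape[0] or j1 > image.grid.shape[1]:
            warnings.warn(f"marker {lab}: search window clipped at image boundary", stacklevel=2)
            i0, j0 = max(0, i0), max(0, j0)
            i1 = min(image.grid.shape[0], i1)
            j1 = min(image.grid.shape[1], j1)
        pos = np.zeros((nz, 2))
        flat = np.zeros(nz, dtype=bool)
        for k in range(nz):
            win = image.values[i0:i1, j0:j1, k]
            flat[k] = bool(np.ptp(win) == 0)
            ii, jj = np.unravel_index(int(np.argmax(win)), win.shape)
            world = image.grid.index_to_world([i0 + ii, j0 + jj, k])
            pos[k] = world[:2]
        positions[lab] = pos
        lowconf[lab] = flat
    offsets = {lab: positions[lab] - positions[lab].mean(axis=0) for lab in positions}
    deviation = {
        lab: positions[lab] - np.asarray(exp)
        for lab, exp in zip(labels, expected_positions)
    }
    return MarkerOffsets(
        labels=tuple(labels),
        positions_mm=positions,
        offsets_mm=offsets,
        deviation_from_expected_mm=deviation,
        low_confidence=lowconf,
    )
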