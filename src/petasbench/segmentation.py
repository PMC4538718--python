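"""Ten classical PET auto-segmentation (PET-AS) methods behind one interface.

Methods, all operating on an ROI image cropped with a 10-mm margin around
the true contour's bounding box:

* ``AT`` - 3-D iterative background-subtracted adaptive thresholding.
* ``RG`` - 3-D iterative region growing with an automatic seed finder.
* ``GCM2`` .. ``GCM8`` - 3-D fuzzy C-means clustering of voxel intensities
  with Gaussian class models (means and variances re-estimated each sweep),
  for 2 to 8 clusters; the lowest-intensity cluster is taken as background
  and the union of the remaining clusters as tumour.
* ``WT`` - slice-by-slice marker-based watershed on the gradient magnitude
  (2-D by design; the other methods are 3-D).

Post-processing follows the behaviour the methods are known for on annular
(necrotic) lesions: RG and GCM masks are hole-filled (they enclose the
core), AT and WT masks are not (they exclude it).  Connectivity is
26-neighbour in 3-D and 8-neighbour in 2-D throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import sobel
from skimage.segmentation import watershed

from .phantom import BinaryMask, PETImage

__all__ = [
    "METHOD_NAMES",
    "ATParams",
    "RGParams",
    "GCMParams",
    "WTParams",
    "SegmentationRequest",
    "SegmentationResult",
    "find_seed",
    "estimate_background",
    "segment",
    "segment_AT",
    "segment_RG",
    "segment_GCM",
    "segment_WT",
]

METHOD_NAMES = ("AT", "RG", "GCM2", "GCM3", "GCM4", "GCM5", "GCM6", "GCM7", "GCM8", "WT")

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
_STRUCT_2D = np.ones((3, 3), dtype=bool)  # 8-connectivity


# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class ATParams:
    """Adaptive thresholding: T = bg + beta * (mean-in-mask - bg)."""

    beta: float = 0.5
    tol_factor: float = 1e-4  # threshold tolerance as a fraction of the image max
    max_iter: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.max_iter < 1 or self.tol_factor <= 0:
            raise ValueError("max_iter >= 1 and tol_factor > 0 required")


@dataclass(frozen=True)
class RGParams:
    """Region growing: decreasing relative-threshold schedule, plateau stop."""

    alpha_start: float = 0.95
    alpha_stop: float = 0.2
    alpha_step: float = 0.025
    plateau_tol: float = 0.02  # relative growth per step regarded as stable
    max_inner_iter: int = 50
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha_stop < self.alpha_start <= 1:
            raise ValueError("need 0 < alpha_stop < alpha_start <= 1")
        if self.alpha_step <= 0 or self.max_inner_iter < 1 or self.plateau_tol < 0:
            raise ValueError("alpha_step > 0, max_inner_iter >= 1, plateau_tol >= 0 required")

    @property
    def schedule(self) -> np.ndarray:
        return np.arange(self.alpha_start, self.alpha_stop - 1e-9, -self.alpha_step)


@dataclass(frozen=True)
class GCMParams:
    """Fuzzy C-means with Gaussian class models on voxel intensities."""

    n_clusters: int = 2
    fuzziness: float = 2.0
    tol: float = 1e-6
    max_iter: int = 200
    init: str = "quantile"  # "quantile" (deterministic) or "random"

    def __post_init__(self) -> None:
        if not 2 <= self.n_clusters <= 8:
            raise ValueError("n_clusters must be in 2..8")
        if self.fuzziness <= 1:
            raise ValueError("fuzziness must be > 1")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")
        if self.init not in ("quantile", "random"):
            raise ValueError("init must be 'quantile' or 'random'")


@dataclass(frozen=True)
class WTParams:
    """Slice-wise watershed marker rules.

    Internal marker: connected high-intensity region (above
    ``bg + internal_frac * (max - bg)``) containing the in-slice maximum;
    slices whose maximum stays below that level carry no internal marker
    and are omitted.  External markers: slice border plus pixels below
    ``bg + external_frac * (max - bg)``.  ``smoothing_sigma`` (voxels) is 0
    by default because simulated PET images are already post-filtered.
    """

    smoothing_sigma: float = 0.0
    internal_frac: float = 0.5
    external_frac: float = 0.25
    min_area: int = 2
    fill_holes: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.external_frac < self.internal_frac < 1:
            raise ValueError("need 0 < external_frac < internal_frac < 1")
        if self.smoothing_sigma < 0 or self.min_area < 1:
            raise ValueError("smoothing_sigma >= 0 and min_area >= 1 required")


def default_params(method: str):
    if method == "AT":
        return ATParams()
    if method == "RG":
        return RGParams()
    if method == "WT":
        return WTParams()
    if method.startswith("GCM"):
        return GCMParams(n_clusters=int(method[3:]))
    raise ValueError(f"unknown method {method!r}")


@dataclass
class SegmentationRequest:
    """One segmentation task: ROI image, method name, parameters, seed."""

    roi_image: PETImage
    method: str
    params: object | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHOD_NAMES:
            raise ValueError(f"method must be one of {METHOD_NAMES}")
        if self.params is None:
            self.params = default_params(self.method)


@dataclass
class SegmentationResult:
    mask: BinaryMask
    method: str
    n_iterations: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# shared helpers


def find_seed(roi_image: PETImage) -> tuple[int, int, int]:
    """Automatic seed: maximum of the 3x3x3-mean-smoothed image.

    The light smoothing keeps the seed off isolated noise spikes; ties are
    broken by lowest linear index.  A constant image has no meaningful seed
    and raises.
    """
    v = roi_image.values
    if np.ptp(v) == 0:
        raise ValueError("cannot find a seed in a constant image")
    smoothed = ndimage.uniform_filter(v, size=3, mode="nearest")
    # among voxels sharing the smoothed maximum, prefer the brightest raw
    # voxel; remaining ties break to the lowest linear index
    cand = smoothed == smoothed.max()
    raw = np.where(cand, v, -np.inf)
    return tuple(int(i) for i in np.unravel_index(int(np.argmax(raw)), v.shape))


def estimate_background(roi_image: PETImage) -> float:
    """Background level: mean of the one-voxel-thick outer shell of the ROI box.

    Valid because the ROI is the truth bounding box plus a 10-mm margin, so
    the shell stays clear of the lesion.
    """
    v = roi_image.values
    if any(n < 3 for n in v.shape):
        raise ValueError("ROI too small for a one-voxel background shell")
    shell = np.ones(v.shape, dtype=bool)
    shell[1:-1, 1:-1, 1:-1] = False
    return float(v[shell].mean())


def _largest_component(mask: np.ndarray, structure=_STRUCT_3D) -> np.ndarray:
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def _component_containing(mask: np.ndarray, seed: tuple[int, ...], structure=_STRUCT_3D) -> np.ndarray:
    labels, _ = ndimage.label(mask, structure=structure)
    lab = labels[seed]
    if lab == 0:
        return np.zeros_like(mask)
    return labels == lab


# ---------------------------------------------------------------------------
# AT: adaptive iterative background-subtracted thresholding


def segment_AT(req: SegmentationRequest) -> SegmentationResult:
    """Iterative background-subtracted thresholding.

    Starting from the half-max mask ``{v >= bg + 0.5 (max - bg)}``, the
    threshold is updated as ``T = bg + beta (mean-in-mask - bg)`` until the
    mask stops changing, the threshold moves by less than the tolerance, or
    the iteration cap is hit.  Returns the largest connected component of
    the final super-threshold set (no hole fill: annular lesions stay
    annular).
    """
    p: ATParams = req.params
    v = req.roi_image.values
    bg = estimate_background(req.roi_image)
    vmax = float(v.max())
    if vmax - bg <= 0 or np.ptp(v) == 0:
        empty = BinaryMask(req.roi_image.grid, np.zeros(v.shape, dtype=bool))
        return SegmentationResult(empty, "AT", 0, False, {"final_threshold": None, "background": bg})
    tol = p.tol_factor * vmax
    thr = bg + 0.5 * (vmax - bg)
    mask = v >= thr
    converged = False
    seen: set[bytes] = set()
    n_it = 0
    for n_it in range(1, p.max_iter + 1):
        inside_mean = float(v[mask].mean()) if mask.any() else bg
        new_thr = bg + p.beta * (inside_mean - bg)
        new_mask = v >= new_thr
        if np.array_equal(new_mask, mask) or abs(new_thr - thr) < tol:
            mask, thr = new_mask, new_thr
            converged = True
            break
        key = new_mask.tobytes()
        if key in seen:  # oscillation: keep the last mask
            mask, thr = new_mask, new_thr
            break
        seen.add(key)
        mask, thr = new_mask, new_thr
    final = _largest_component(mask) if mask.any() else mask
    return SegmentationResult(
        BinaryMask(req.roi_image.grid, final), "AT", n_it, converged,
        {"final_threshold": float(thr), "background": bg},
    )


# ---------------------------------------------------------------------------
# RG: iterative region growing


def _grow_region(v: np.ndarray, seed: tuple[int, int, int], alpha: float, max_iter: int) -> np.ndarray:
    """Region at relative threshold alpha: fixed point of
    region -> 26-connected component of {v >= alpha * mean(region)} containing the seed."""
    region = np.zeros(v.shape, dtype=bool)
    region[seed] = True
    for _ in range(max_iter):
        thr = alpha * float(v[region].mean())
        new = _component_containing(v >= thr, seed)
        if not new.any():
            new = region
        if np.array_equal(new, region):
            break
        region = new
    return region


def segment_RG(req: SegmentationRequest) -> SegmentationResult:
    """Iterative region growing with automatic seed finding.

    The acceptance threshold ``alpha x region mean`` is swept over a
    decreasing schedule.  Regions that reach the ROI border have flooded
    into the background and are discarded; among the remaining regions the
    sweep keeps the largest one whose growth is still on the slowest
    plateau (relative growth within ``plateau_tol`` of the minimum), i.e.
    growth has stalled at the lesion boundary but the background flood has
    not started.  The late-tie bias makes a two-level lesion resolve to the
    whole lesion rather than to its bright core.  The final mask is
    hole-filled, so annular lesions are delivered filled.
    """
    p: RGParams = req.params
    v = req.roi_image.values
    seed = find_seed(req.roi_image)
    schedule = p.schedule
    regions = []
    volumes = []
    touches_border = []
    border = np.ones(v.shape, dtype=bool)
    border[1:-1, 1:-1, 1:-1] = False
    for alpha in schedule:
        region = _grow_region(v, seed, float(alpha), p.max_inner_iter)
        regions.append(region)
        volumes.append(int(region.sum()))
        touches_border.append(bool((region & border).any()))
    volumes_arr = np.array(volumes, dtype=float)
    growth = np.diff(volumes_arr) / np.maximum(volumes_arr[:-1], 1.0)
    # regions touching the ROI border have flooded into the background
    flood = next((i for i, t in enumerate(touches_border) if t), len(regions))
    converged = flood > 0
    if flood <= 1:  # flooded immediately (or at every alpha): best effort
        idx = 0
    else:
        # growth[j-1] is the relative volume step into region j; keep the
        # largest region still within plateau_tol of the slowest growth
        scores = growth[: flood - 1]
        stable = np.where(scores <= scores.min() + p.plateau_tol)[0]
        idx = int(stable[-1]) + 1
    mask = regions[idx]
    if p.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return SegmentationResult(
        BinaryMask(req.roi_image.grid, mask), "RG", len(schedule), converged,
        {"seed": seed, "alpha": float(schedule[idx]), "volumes": volumes},
    )


# ---------------------------------------------------------------------------
# GCM: fuzzy C-means with Gaussian class models


def _memberships(x: np.ndarray, means: np.ndarray, expo: float) -> np.ndarray:
    d = np.maximum((x[:, None] - means[None, :]) ** 2, 1e-300)
    inv = d ** (-expo)
    return inv / inv.sum(axis=1, keepdims=True)


def _gcm_cluster(x: np.ndarray, k: int, p: GCMParams, rng: np.random.Generator):
    """1-D fuzzy C-means on intensities with Gaussian class statistics.

    Memberships use the classical inverse-squared-distance FCM rule on raw
    intensities; a Gaussian model (mean, variance) is re-estimated for each
    class from the fuzzy memberships every sweep and reported alongside.
    Intensity distance (rather than a variance-normalised form) keeps the
    background class anchored: PET ROIs are dominated by a narrow
    background mode, and scale-free distances let a broad tumour class
    swallow it.  Returns (means, variances, memberships, n_iter, converged).
    """
    xmin, xmax = float(x.min()), float(x.max())
    span = xmax - xmin
    var_floor = max(1e-12 * span * span, 1e-30)

    def quantile_init():
        q = np.quantile(x, (np.arange(k) + 0.5) / k)
        if np.unique(q).size < k:  # heavy ties: fall back to even spacing
            q = xmin + (np.arange(k) + 0.5) / k * span
        return q.astype(float)

    if p.init == "random":
        means = np.sort(rng.uniform(xmin, xmax, size=k))
    else:
        means = quantile_init()
    expo = 1.0 / (p.fuzziness - 1.0)
    variances = np.full(k, max(np.var(x) / k, var_floor))
    reinitialised = False
    n_it = 0
    converged = False
    for n_it in range(1, p.max_iter + 1):
        u = _memberships(x, means, expo)
        w = u**p.fuzziness
        wsum = w.sum(axis=0)
        if np.any(wsum < 1e-12 * x.size):
            if reinitialised:
                raise ValueError("empty cluster persisted after re-initialisation")
            reinitialised = True
            means = quantile_init() * (1.0 + 1e-3 * rng.standard_normal(k))
            continue
        new_means = (w * x[:, None]).sum(axis=0) / wsum
        variances = np.maximum(
            (w * (x[:, None] - new_means[None, :]) ** 2).sum(axis=0) / wsum, var_floor
        )
        if np.max(np.abs(new_means - means)) < p.tol * max(span, 1.0):
            means = new_means
            converged = True
            break
        means = new_means
    u = _memberships(x, means, expo)
    return means, variances, u, n_it, converged


def segment_GCM(req: SegmentationRequest) -> SegmentationResult:
    """Fuzzy C-means / Gaussian-class clustering of ROI intensities.

    Voxels are defuzzified to their maximum-membership cluster; the
    lowest-mean cluster is the background and the union of all other
    clusters the tumour.  The delivered mask is the largest connected
    component of that union, hole-filled.
    """
    p: GCMParams = req.params
    v = req.roi_image.values
    if np.ptp(v) == 0:
        raise ValueError("GCM requires a non-constant ROI image")
    rng = np.random.default_rng(req.seed)
    x = v.ravel()
    means, variances, u, n_it, converged = _gcm_cluster(x, p.n_clusters, p, rng)
    labels = np.argmax(u, axis=1).reshape(v.shape)
    bg_cluster = int(np.argmin(means))
    tumour = labels != bg_cluster
    if tumour.any():
        tumour = ndimage.binary_fill_holes(_largest_component(tumour))
    return SegmentationResult(
        BinaryMask(req.roi_image.grid, tumour), f"GCM{p.n_clusters}", n_it, converged,
        {
            "cluster_means": sorted(float(m) for m in means),
            "cluster_variances": [float(s) for s in variances],
            "background_cluster_mean": float(means[bg_cluster]),
            "labels": labels,
        },
    )


# ---------------------------------------------------------------------------
# WT: slice-by-slice marker-based watershed


def segment_WT(req: SegmentationRequest) -> SegmentationResult:
    """Slice-wise watershed segmentation with automatic markers.

    Per axial slice: optional Gaussian smoothing, gradient magnitude,
    marker-based watershed flooding from an internal high-intensity marker
    (containing the in-slice maximum) and external markers (slice border
    plus low-intensity pixels), keeping the internal basin.  Slices without
    an internal marker above background, or whose basin is smaller than
    ``min_area`` pixels, are omitted; the 3-D result is the union of the
    kept slices (largest 3-D component, no hole fill).
    """
    p: WTParams = req.params
    v = req.roi_image.values
    bg = estimate_background(req.roi_image)
    gmax = float(v.max())
    out = np.zeros(v.shape, dtype=bool)
    n_slices = 0
    if gmax - bg <= 0:
        return SegmentationResult(
            BinaryMask(req.roi_image.grid, out), "WT", 0, False, {"background": bg}
        )
    t_int = bg + p.internal_frac * (gmax - bg)
    t_ext = bg + p.external_frac * (gmax - bg)
    for k in range(v.shape[2]):
        sl = v[:, :, k]
        if p.smoothing_sigma > 0:
            sl = ndimage.gaussian_filter(sl, p.smoothing_sigma, mode="nearest")
        if sl.max() < t_int:
            continue  # no internal marker above background: slice omitted
        peak = np.unravel_index(int(np.argmax(sl)), sl.shape)
        internal = _component_containing(sl >= t_int, peak, structure=_STRUCT_2D)
        external = np.ones(sl.shape, dtype=bool)
        external[1:-1, 1:-1] = False
        external |= sl <= t_ext
        external &= ~internal
        markers = np.zeros(sl.shape, dtype=np.int32)
        markers[external] = 1
        markers[internal] = 2
        grad = sobel(sl)
        labels = watershed(grad, markers, connectivity=2)
        basin = labels == 2
        if basin.sum() < p.min_area:
            continue
        out[:, :, k] = basin
        n_slices += 1
    if out.any():
        out = _largest_component(out)
        if p.fill_holes:
            out = ndimage.binary_fill_holes(out)
    return SegmentationResult(
        BinaryMask(req.roi_image.grid, out), "WT", n_slices, n_slices > 0,
        {"background": bg, "internal_threshold": t_int, "external_threshold": t_ext},
    )


# ---------------------------------------------------------------------------
# dispatcher


def segment(req: SegmentationRequest) -> SegmentationResult:
    """Run the requested PET-AS method on an ROI image."""
    if req.method == "AT":
        return segment_AT(req)
    if req.method == "RG":
        return segment_RG(req)
    if req.method == "WT":
        return segment_WT(req)
    return segment_GCM(req)
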