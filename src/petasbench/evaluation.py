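"""Segmentation accuracy metrics and study-level bookkeeping.

Masks are compared voxel-wise on the PET grid.  With ``A`` the reference
(ground-truth) mask and ``B`` the evaluated mask:

* Dice similarity coefficient  ``DSC = 2|A n B| / (|A| + |B|)``
* Sensitivity                  ``S = TP / (TP + FN) = |A n B| / |A|``
* Positive predictive value    ``PPV = TP / (TP + FP) = |A n B| / |B|``

DSC above 0.7 is used as the indicator of good overlap, and the
experimental error bar on a DSC value is modelled as +/- 4% of (1 - DSC):
accurate methods are the least sensitive to setup variations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .phantom import BinaryMask, PETImage

__all__ = [
    "MetricsRecord",
    "CroppedRoi",
    "crop_roi",
    "dice",
    "sensitivity",
    "ppv",
    "dsc_error_bar",
    "good_overlap",
    "evaluate_pair",
    "evaluate_grid",
    "optimal_clusters",
]


@dataclass
class MetricsRecord:
    """One (method x lesion) evaluation row."""

    method: str
    lesion_id: str
    pattern: str
    dsc: float
    sensitivity: float
    ppv: float
    dsc_error: float
    tp: int
    fp: int
    fn: int
    converged: bool = True
    failed: bool = False


@dataclass
class CroppedRoi:
    """ROI crop of an image and its ground truth, with the crop slices."""

    image: PETImage
    truth: BinaryMask
    slices: tuple[slice, slice, slice]
    clipped: bool


def crop_roi(image: PETImage, truth: BinaryMask, margin_mm: float = 10.0) -> CroppedRoi:
    """Crop to the truth bounding box dilated by a margin (default 10 mm).

    The margin is converted to ``ceil(margin / spacing)`` voxels per axis
    and the crop is clipped at the image bounds (``clipped`` records
    whether clipping occurred); the truth is cropped identically.
    """
    if not image.grid.same_geometry(truth.grid):
        raise ValueError("truth must live on the image grid")
    if truth.count == 0:
        raise ValueError("cannot crop around an empty truth mask")
    idx = np.argwhere(truth.voxels)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    clipped = False
    slices = []
    for a in range(3):
        dil = math.ceil(margin_mm / image.grid.spacing[a])
        a0, a1 = int(lo[a]) - dil, int(hi[a]) + dil + 1
        if a0 < 0 or a1 > image.grid.shape[a]:
            clipped = True
        slices.append(slice(max(0, a0), min(image.grid.shape[a], a1)))
    slices = tuple(slices)
    sub_shape = tuple(s.stop - s.start for s in slices)
    origin = tuple(
        image.grid.origin[a] + slices[a].start * image.grid.spacing[a] for a in range(3)
    )
    from .grids import GridSpec

    sub_grid = GridSpec(sub_shape, image.grid.spacing, origin)
    return CroppedRoi(
        image=PETImage(sub_grid, image.values[slices], provenance=image.provenance),
        truth=BinaryMask(sub_grid, truth.voxels[slices]),
        slices=slices,
        clipped=clipped,
    )


def _check_pair(a: BinaryMask, b: BinaryMask) -> None:
    if not a.grid.same_geometry(b.grid):
        raise ValueError("masks must share a grid")


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient, undefined (error) when both masks are empty."""
    _check_pair(a, b)
    na, nb = a.count, b.count
    if na + nb == 0:
        raise ValueError("DSC undefined for two empty masks")
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)


def sensitivity(a: BinaryMask, b: BinaryMask) -> float:
    """Fraction of reference voxels recovered, |A n B| / |A|."""
    _check_pair(a, b)
    if a.count == 0:
        raise ValueError("sensitivity undefined for an empty reference mask")
    return int((a.voxels & b.voxels).sum()) / a.count


def ppv(a: BinaryMask, b: BinaryMask) -> float:
    """Fraction of evaluated voxels that are truly tumour, |A n B| / |B|."""
    _check_pair(a, b)
    if b.count == 0:
        raise ValueError("PPV undefined for an empty evaluated mask")
    return int((a.voxels & b.voxels).sum()) / b.count


def dsc_error_bar(dsc: float) -> float:
    """Experimental-setup error bar on DSC: 0.04 x (1 - DSC)."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError("dsc must be in [0, 1]")
    return 0.04 * (1.0 - dsc)


def good_overlap(dsc: float) -> bool:
    """True for DSC strictly above 0.7."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError("dsc must be in [0, 1]")
    return dsc > 0.7


def evaluate_pair(
    truth: BinaryMask,
    result_mask: BinaryMask,
    method: str,
    lesion_id: str,
    pattern: str = "",
    converged: bool = True,
) -> MetricsRecord:
    """Metrics for one segmentation against its ground truth.

    An empty segmentation is recorded as a failure with zero metrics rather
    than raising, so study tables stay rectangular.
    """
    _check_pair(truth, result_mask)
    tp = int((truth.voxels & result_mask.voxels).sum())
    fp = result_mask.count - tp
    fn = truth.count - tp
    if result_mask.count == 0:
        return MetricsRecord(
            method, lesion_id, pattern, 0.0, 0.0, 0.0, dsc_error_bar(0.0),
            tp, fp, fn, converged=converged, failed=True,
        )
    d = dice(truth, result_mask)
    return MetricsRecord(
        method, lesion_id, pattern, d, sensitivity(truth, result_mask),
        ppv(truth, result_mask), dsc_error_bar(d), tp, fp, fn,
        converged=converged, failed=False,
    )


def evaluate_grid(results, truths: dict, patterns: dict | None = None) -> list[MetricsRecord]:
    """Evaluate a batch of segmentation results.

    ``results`` is an iterable of ``(lesion_id, SegmentationResult)`` and
    ``truths`` maps lesion id to its ground-truth mask; a missing truth is
    an error naming the lesion.
    """
    records = []
    for lesion_id, res in results:
        if lesion_id not in truths:
            raise KeyError(f"no ground truth provided for lesion {lesion_id!r}")
        pattern = (patterns or {}).get(lesion_id, "")
        records.append(
            evaluate_pair(
                truths[lesion_id], res.mask, res.method, lesion_id, pattern,
                converged=res.converged,
            )
        )
    return records


def optimal_clusters(records: list[MetricsRecord]) -> dict[str, int]:
    """Per lesion, the cluster count k whose GCMk reached the highest DSC."""
    best: dict[str, tuple[float, int]] = {}
    for r in records:
        if not r.method.startswith("GCM"):
            continue
        k = int(r.method[3:])
        if r.lesion_id not in best or r.dsc > best[r.lesion_id][0]:
            best[r.lesion_id] = (r.dsc, k)
    return {lesion: k for lesion, (_, k) in best.items()}
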