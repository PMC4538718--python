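"""File formats: NIfTI volumes, grey-level page images, YAML configs.

NIfTI affines are built from :class:`~petasbench.grids.GridSpec` (axis
aligned, voxel centres); only axis-aligned affines are accepted on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

from .grids import GridSpec
from .phantom import BinaryMask, PageImage, PETImage, UptakeTemplate

__all__ = [
    "save_nifti",
    "load_pet_image",
    "load_mask",
    "save_page_png",
    "load_yaml",
    "dump_yaml",
    "dump_json",
]


def save_nifti(obj, path) -> Path:
    """Write an UptakeTemplate, PETImage or BinaryMask as NIfTI."""
    if isinstance(obj, UptakeTemplate):
        data, grid = obj.values.astype(np.float32), obj.grid
    elif isinstance(obj, PETImage):
        data, grid = obj.values.astype(np.float32), obj.grid
    elif isinstance(obj, BinaryMask):
        data, grid = obj.voxels.astype(np.uint8), obj.grid
    else:
        raise TypeError(f"cannot save object of type {type(obj).__name__}")
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def _load_grid(img: nib.Nifti1Image) -> GridSpec:
    return GridSpec.from_affine(tuple(img.shape[:3]), img.affine)


def load_pet_image(path, provenance: str = "file") -> PETImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return PETImage(_load_grid(img), data, provenance=provenance)


def load_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    return BinaryMask(_load_grid(img), data > 0.5)


def save_page_png(page: PageImage, path) -> Path:
    """Write a page as 16-bit grey PNG (grey 0..1 mapped to 0..65535).

    The array's first axis is x (rightwards) and second is y (downwards),
    so the image is transposed into row-major display order.
    """
    px = np.clip(page.pixels, 0.0, 1.0)
    arr = np.round(px.T * 65535).astype(np.uint16)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr, mode="I;16").save(str(path))
    return path


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(data: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


def dump_json(data, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
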