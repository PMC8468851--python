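"""Reading and writing images plus run provenance.

Grayscale single- and multi-page TIFF (8/16-bit) via tifffile and PNG via
imageio.  Images are converted to float in [0, 1] on read; writes scale the
declared intensity range onto the full integer range of the chosen bit
depth.  Every CLI run can drop a provenance JSON (input hash, configuration,
package versions) next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import Image


def _to_unit(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):  # RGB(A) → luminance
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        return arr.astype(np.float64) / info.max
    arr = arr.astype(np.float64)
    return arr


def read_image(path: str | Path, pixel_size_um: float = 1.0) -> Image:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
        raise ValueError(f"{path} is a stack; use read_stack")
    return Image(_to_unit(arr), pixel_size_um=pixel_size_um)


def read_stack(path: str | Path, pixel_size_um: float = 1.0) -> list[Image]:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return [Image(_to_unit(frame), pixel_size_um=pixel_size_um) for frame in arr]


def write_image(path: str | Path, img: Image, bits: int = 16) -> None:
    path = Path(path)
    lo, hi = img.intensity_range
    unit = np.clip((img.values - lo) / (hi - lo), 0.0, 1.0)
    if bits == 16:
        data = (unit * 65535).round().astype(np.uint16)
    elif bits == 8:
        data = (unit * 255).round().astype(np.uint8)
    else:
        raise ValueError("bits must be 8 or 16")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_mask_png(path: str | Path, mask_values: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask_values, bool) * 255).astype(np.uint8))


def write_provenance(
    path: str | Path, inputs: list[str | Path], config: dict
) -> None:
    import myxovision

    digests = {}
    for p in inputs:
        p = Path(p)
        if p.is_file():
            digests[str(p)] = hashlib.sha256(p.read_bytes()).hexdigest()
    record = {
        "inputs_sha256": digests,
        "config": config,
        "versions": {
            "python": sys.version.split()[0],
            "myxovision": myxovision.__version__,
            "numpy": np.__version__,
        },
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
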