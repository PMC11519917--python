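"""TIFF stack and sidecar-metadata I/O.

Images travel as single- or multi-page TIFF (8/16-bit unsigned integer or
32-bit float); every stack has a JSON sidecar (``<stem>.json`` next to the
TIFF) carrying acquisition timing, sensor law, seed and bit depth, so any
artifact can be re-run from its own metadata.  12-bit camera data lives in
a 16-bit container with the true bit depth recorded in the sidecar.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import InputError

__all__ = ["read_image_stack", "write_image_stack", "sidecar_path"]

_SUPPORTED = {np.dtype(np.uint8), np.dtype(np.uint16), np.dtype(np.float32)}


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_image_stack(stack: np.ndarray, path, metadata: dict | None = None) -> Path:
    """Write an image stack as TIFF plus a JSON sidecar.

    float64 input is stored as float32 (the O2/P_N dynamic range does not
    need more); integer dtypes round-trip bit-identically.
    """
    stack = np.asarray(stack)
    if stack.dtype == np.float64:
        stack = stack.astype(np.float32)
    if stack.dtype == np.bool_:
        stack = stack.astype(np.uint8)
    if stack.dtype not in _SUPPORTED:
        raise InputError(
            f"unsupported dtype {stack.dtype}; use uint8, uint16 or float32"
        )
    path = Path(path)
    tifffile.imwrite(path, stack, photometric="minisblack")
    meta = dict(metadata or {})
    meta.setdefault("dtype", str(stack.dtype))
    meta.setdefault("shape", list(stack.shape))
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_image_stack(path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its sidecar metadata.

    A missing sidecar yields a warning and an empty metadata dict;
    unsupported dtypes raise naming the dtype.
    """
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.dtype not in _SUPPORTED:
        raise InputError(
            f"unsupported TIFF dtype {stack.dtype} in {path.name}; "
            "expected uint8, uint16 or float32"
        )
    sc = sidecar_path(path)
    if sc.exists():
        metadata = json.loads(sc.read_text())
    else:
        warnings.warn(
            f"no sidecar metadata for {path.name}; applying defaults",
            stacklevel=2,
        )
        metadata = {}
    return stack, metadata
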