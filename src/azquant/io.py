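"""Grayscale TIFF readers/writers and table IO.

Images are 16-bit grayscale TIFF, single page (punctum images) or
multi-page (movies, one page per frame, order preserved). 8-bit input is
promoted to 16-bit with a flag recorded; RGB and other bit depths are
rejected. Tables travel as CSV, fits and reports as JSON.
"""

from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import tifffile


class _CaptureErrors(logging.Handler):
    """tifffile reports corrupt page chains through its logger, not exceptions."""

    def __init__(self):
        super().__init__(level=logging.ERROR)
        self.records: list[str] = []

    def emit(self, record):
        self.records.append(record.getMessage())

__all__ = ["read_image", "write_image", "write_json", "read_json"]

_SUPPORTED = {np.dtype(np.uint8), np.dtype(np.uint16)}


def write_image(path, data: np.ndarray) -> None:
    """Write a 2-D image or 3-D stack as 16-bit grayscale TIFF.

    uint16 round-trips losslessly; uint8 is widened; float data is clipped
    to [0, 65535] and rounded (documented lossy convenience for rendered
    synthetic images).
    """
    arr = np.asarray(data)
    if arr.ndim not in (2, 3):
        raise ValueError("expected a 2-D image or 3-D stack")
    if arr.dtype == np.uint16:
        out = arr
    elif arr.dtype == np.uint8:
        out = arr.astype(np.uint16)
    elif np.issubdtype(arr.dtype, np.floating) or np.issubdtype(arr.dtype, np.integer):
        out = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype: {arr.dtype}")
    tifffile.imwrite(str(path), out, photometric="minisblack")


def read_image(path) -> tuple[np.ndarray, dict]:
    """Read a grayscale TIFF; returns ``(array, meta)``.

    Single-page files give a 2-D array, multi-page files a 3-D stack with
    page order preserved. ``meta['promoted']`` is True when 8-bit input was
    widened to 16-bit. Unsupported bit depths and RGB raise; a truncated
    file raises an error naming the failing page.
    """
    pages = []
    size = os.path.getsize(path)
    capture = _CaptureErrors()
    tlog = logging.getLogger("tifffile")
    tlog.addHandler(capture)
    try:
        with tifffile.TiffFile(str(path)) as tif:
            for i, page in enumerate(tif.pages):
                if page.samplesperpixel and page.samplesperpixel > 1:
                    raise ValueError(f"RGB/multisample TIFF not supported (page {i})")
                if page.dataoffsets and page.databytecounts:
                    end = max(o + b for o, b in zip(page.dataoffsets, page.databytecounts))
                    if end > size:
                        raise IOError(f"truncated TIFF: page {i} data extends past end of file")
                try:
                    arr = page.asarray()
                except Exception as exc:
                    raise IOError(f"failed to read page {i} of {path}: {exc}") from exc
                if arr.dtype not in _SUPPORTED:
                    raise ValueError(f"unsupported bit depth {arr.dtype} (page {i})")
                pages.append(arr)
    finally:
        tlog.removeHandler(capture)
    if capture.records:
        raise IOError(
            f"corrupt TIFF {path}: page chain broken after page {len(pages) - 1} "
            f"({capture.records[0]})"
        )
    if not pages:
        raise IOError(f"no pages in {path}")
    promoted = pages[0].dtype == np.uint8
    stack = np.stack([p.astype(np.uint16) for p in pages])
    data = stack[0] if len(pages) == 1 else stack
    return data, {"promoted": promoted, "n_pages": len(pages)}


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
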