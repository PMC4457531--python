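"""Reading and writing the file formats the pipeline touches.

Wide-field recordings arrive as 16-bit grayscale multi-page TIFF stacks, one
page per frame in temporal order.  Internally a recording is an
:class:`ImageSequence`: a float64 array indexed ``(t, y, x)`` (row-major
pages, the numpy convention) plus acquisition metadata.  Scalar results go to
plain CSV, evaluation reports to JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ImageSequence",
    "read_tiff_sequence",
    "write_tiff_sequence",
    "write_results_table",
    "read_results_table",
    "write_json_report",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "recording_id",
    "method",
    "magnitude",
    "peak_value",
    "peak_frame",
    "latency",
    "duration",
]

MAX_UINT16 = 65535


@dataclass
class ImageSequence:
    """An ordered stack of equally sized intensity frames I(t).

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, h, w)``; converted to float64.  Values
        must be finite.  Data read from 16-bit TIFFs is nonnegative by
        construction; synthetic working arrays may dip below zero (additive
        noise) and are only clipped on TIFF export.
    frame_rate
        Acquisition rate in Hz.
    exposure_ms
        Per-frame exposure in milliseconds.
    source_id
        Opaque recording label carried through to result tables.
    """

    frames: np.ndarray
    frame_rate: float = 4.0
    exposure_ms: float = 200.0
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(
                f"frames must be a 3-D (t, y, x) array, got ndim={arr.ndim}"
            )
        if arr.shape[0] < 1:
            raise ValueError("an image sequence needs at least one frame")
        if arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError("frames must have nonzero spatial extent")
        if not np.isfinite(arr).all():
            raise ValueError("frame values must be finite")
        self.frames = arr

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def h(self) -> int:
        """Height in pixels (number of rows)."""
        return self.frames.shape[1]

    @property
    def w(self) -> int:
        """Width in pixels (number of columns)."""
        return self.frames.shape[2]

    def pixel_trace(self, x: int, y: int) -> np.ndarray:
        """Time series of the pixel at column ``x``, row ``y``."""
        return self.frames[:, y, x]

    def copy_with(self, frames: np.ndarray) -> "ImageSequence":
        return ImageSequence(
            frames=frames,
            frame_rate=self.frame_rate,
            exposure_ms=self.exposure_ms,
            source_id=self.source_id,
        )

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, ImageSequence):
            return NotImplemented
        return (
            self.frames.shape == other.frames.shape
            and np.array_equal(self.frames, other.frames)
            and self.frame_rate == other.frame_rate
        )


def read_tiff_sequence(path: str | Path, **metadata) -> ImageSequence:
    """Read a multi-page grayscale TIFF stack in page (= temporal) order.

    Accepts 8/16-bit unsigned and 16-bit signed integer pages, either byte
    order, uncompressed or deflate.  Rejects multi-sample (RGB) data and
    floating-point sample formats: the instrument produces single-channel
    integer counts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        pages = tf.pages
        if len(pages) == 0:
            raise ValueError(f"{path}: TIFF contains zero pages")
        shapes = {p.shape for p in pages}
        if len(shapes) != 1:
            raise ValueError(f"{path}: inconsistent frame dimensions {shapes}")
        for p in pages:
            if p.samplesperpixel != 1:
                raise ValueError(
                    f"{path}: multi-sample (e.g. RGB) TIFF is not supported"
                )
            if p.dtype is None or p.dtype.kind not in "ui":
                raise ValueError(
                    f"{path}: unsupported sample format {p.dtype}; "
                    "expected integer grayscale"
                )
        arr = np.stack([p.asarray() for p in pages])
    metadata.setdefault("source_id", path.stem)
    return ImageSequence(frames=arr, **metadata)


def write_tiff_sequence(
    seq: ImageSequence, path: str | Path, *, clip: bool = False
) -> Path:
    """Write a sequence as a 16-bit grayscale multi-page TIFF.

    Values are rounded to the nearest integer.  With ``clip=False`` (default)
    values outside [0, 65535] raise; with ``clip=True`` they are clipped —
    clipping happens only here, never in the working array.
    """
    path = Path(path)
    arr = np.rint(seq.frames)
    if clip:
        arr = np.clip(arr, 0, MAX_UINT16)
    else:
        lo, hi = arr.min(), arr.max()
        if lo < 0 or hi > MAX_UINT16:
            raise ValueError(
                f"values [{lo}, {hi}] not representable in 16 bits; "
                "pass clip=True to clip at export"
            )
    tifffile.imwrite(path, arr.astype(np.uint16), photometric="minisblack")
    return path


def write_results_table(records: Sequence[dict], path: str | Path) -> Path:
    """Write per-recording response parameters as a CSV table.

    ``records`` is a list of dicts with at least the :data:`RESULT_COLUMNS`
    keys; an empty list produces a header-only file.
    """
    path = Path(path)
    df = pd.DataFrame(list(records), columns=RESULT_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_report(report: dict, path: str | Path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(report, indent=2, default=_default, allow_nan=True))
    return path
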