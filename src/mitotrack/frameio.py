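"""Reading and writing frames, masks and tables.

Sequences are accepted as a multi-page TIFF or a directory of numbered
single-page TIFF/PNG files (lexicographic frame order); 8- and 16-bit
unsigned integer pixels are rescaled to [0, 1] on load.  Masks are written
as 8-bit images (0 background, 255 cell); level-set fields can be dumped
as 32-bit float TIFF for debugging.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .core import FrameSequence

__all__ = [
    "load_sequence",
    "save_sequence",
    "save_mask",
    "load_mask",
    "save_levelset",
    "write_table",
]

_FRAME_EXT = (".tif", ".tiff", ".png")


def _to_unit(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError("colour images are not supported")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return arr.astype(float)


def load_sequence(path, frame_interval_min: float = 5.0) -> FrameSequence:
    """Load a time-lapse from a multi-page TIFF or a directory of frames."""
    p = Path(path)
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _FRAME_EXT)
        if len(files) < 2:
            raise ValueError(f"need at least 2 frame files in {p}")
        frames = [_to_unit(iio.imread(f)) for f in files]
    else:
        stack = tifffile.imread(p)
        if stack.ndim == 2:
            raise ValueError("a single-page TIFF is not a sequence")
        frames = [_to_unit(stack[i]) for i in range(stack.shape[0])]
    return FrameSequence(frames=frames, frame_interval_min=frame_interval_min)


def save_sequence(path, seq: FrameSequence) -> None:
    """Write a sequence as a 16-bit multi-page TIFF (intensities clipped to [0, 1])."""
    stack = np.stack([np.clip(seq[i], 0, 1) for i in range(len(seq))])
    tifffile.imwrite(Path(path), (stack * 65535).astype(np.uint16))


def save_mask(path, mask) -> None:
    m = (np.asarray(mask).astype(bool) * np.uint8(255))
    iio.imwrite(Path(path), m)


def load_mask(path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > (arr.max() / 2 if arr.max() > 1 else 0)


def save_levelset(path, phi) -> None:
    tifffile.imwrite(Path(path), np.asarray(phi, dtype=np.float32))


def write_table(path, frame, header_lines: list[str]) -> None:
    """Atomically write a DataFrame as CSV with '#' comment header lines."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")
    os.replace(tmp, path)
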