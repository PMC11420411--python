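"""Image file I/O.

Float HU arrays saved as ``.npy`` are the source of truth.  Lossless
16-bit PNG export stores ``round(hu - offset)`` with the offset recorded in
a text chunk, so integer-valued HU images round-trip exactly.  Windowed
8-bit PNGs are for visual inspection only.  DICOM reading (rescale slope
and intercept applied) is available when pydicom is installed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
from PIL import Image
from PIL.PngImagePlugin import PngInfo

__all__ = [
    "save_hu",
    "load_hu",
    "save_png16",
    "load_png16",
    "save_windowed_png",
    "load_dicom_hu",
]

DEFAULT_PNG16_OFFSET = -1024.0
DEFAULT_WINDOW = (-160.0, 240.0)  # display window in HU


def save_hu(path: str | Path, hu: np.ndarray) -> None:
    np.save(str(path), np.asarray(hu, dtype=float))


def load_hu(path: str | Path) -> np.ndarray:
    return np.load(str(path))


def save_png16(path: str | Path, hu: np.ndarray, offset: float = DEFAULT_PNG16_OFFSET) -> None:
    """16-bit grayscale PNG with the HU offset stored in a ``hu_offset`` text chunk."""
    data = np.rint(np.asarray(hu, dtype=float) - offset)
    if data.min() < 0 or data.max() > 65535:
        raise ValueError(
            f"HU range [{hu.min():.0f}, {hu.max():.0f}] does not fit 16 bits at offset {offset}"
        )
    img = Image.fromarray(data.astype(np.uint16))
    info = PngInfo()
    info.add_text("hu_offset", repr(float(offset)))
    img.save(str(path), pnginfo=info)


def load_png16(path: str | Path) -> np.ndarray:
    img = Image.open(str(path))
    offset = float(img.text.get("hu_offset", repr(DEFAULT_PNG16_OFFSET)))
    return np.asarray(img, dtype=float) + offset


def save_windowed_png(
    path: str | Path, hu: np.ndarray, window: Tuple[float, float] = DEFAULT_WINDOW
) -> None:
    """8-bit display export; clips to ``window`` (HU low/high)."""
    lo, hi = window
    if hi <= lo:
        raise ValueError(f"invalid window {window}")
    x = np.clip((np.asarray(hu, dtype=float) - lo) / (hi - lo), 0.0, 1.0)
    Image.fromarray((x * 255).astype(np.uint8)).save(str(path))


def load_dicom_hu(path: str | Path) -> np.ndarray:
    """Read one DICOM slice as HU (rescale slope/intercept applied)."""
    try:
        import pydicom
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "DICOM support requires the optional 'pydicom' package"
        ) from err
    ds = pydicom.dcmread(str(path))
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return ds.pixel_array.astype(float) * slope + intercept
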