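"""Point-prompted crystal segmentation with pluggable backends.

A backend takes a grayscale image and a point of interest and returns a raw
binary foreground mask; the module then applies uniform post-processing
(hole filling, extraction of the 4-connected component containing the
point).  The default ``"otsu"`` backend uses a global inter-class-variance
threshold and works well on high-contrast reflective-light microscopy of a
single bright crystal.  A promptable foundation-model backend (``"sam"``) is
registered lazily and used only when the optional dependency is installed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "SegmentationError",
    "segment",
    "mask_centroid",
    "load_image",
    "register_backend",
]


class SegmentationError(RuntimeError):
    """Raised when no usable foreground component can be produced."""


BackendFn = Callable[[np.ndarray, tuple[float, float]], np.ndarray]

_BACKENDS: dict[str, BackendFn] = {}


def register_backend(name: str, fn: BackendFn) -> None:
    _BACKENDS[name] = fn


def _otsu_backend(image: np.ndarray, point: tuple[float, float]) -> np.ndarray:
    if image.max() == image.min():
        raise SegmentationError("uniform image: no foreground component")
    thresh = threshold_otsu(image)
    mask = image > thresh
    x, y = int(round(point[0])), int(round(point[1]))
    # orient so the prompted side of the threshold is foreground
    if not mask[y, x]:
        alt = image < thresh
        if alt[y, x] and alt.mean() < 0.5:
            mask = alt
    return mask


def _sam_backend(image: np.ndarray, point: tuple[float, float]) -> np.ndarray:
    try:
        import segment_anything  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the 'sam' backend needs the optional segment-anything package "
            "and a model checkpoint; install crystalsizer[sam] and register "
            "a configured predictor via register_backend()"
        ) from exc
    raise NotImplementedError(  # pragma: no cover
        "register a configured SAM predictor via register_backend('sam', fn)"
    )


register_backend("otsu", _otsu_backend)
register_backend("sam", _sam_backend)


def segment(
    image: np.ndarray, point: tuple[float, float], backend: str = "otsu"
) -> np.ndarray:
    """Binary mask of the crystal containing ``point`` (x, y).

    The raw backend mask is hole-filled and reduced to the single
    4-connected component containing the point; values are {0, 1} uint8 of
    the same shape as the image.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("segment expects a single-channel 2D image")
    h, w = image.shape
    x, y = point
    if not (0 <= x <= w - 1 and 0 <= y <= h - 1):
        raise SegmentationError(f"point {point} outside image bounds {(w, h)}")
    raw = np.asarray(_BACKENDS[backend](image, point), dtype=bool)
    if raw.shape != image.shape:
        raise SegmentationError("backend returned mask of wrong shape")
    filled = ndimage.binary_fill_holes(raw)
    labels, _ = ndimage.label(filled, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]
    ))
    lab = labels[int(round(y)), int(round(x))]
    if lab == 0:
        raise SegmentationError(
            f"no foreground component containing point {point}"
        )
    return (labels == lab).astype(np.uint8)


def mask_centroid(mask: np.ndarray) -> np.ndarray:
    """Mean (x, y) of foreground pixels."""
    mask = np.asarray(mask)
    ys, xs = np.nonzero(mask)
    if xs.size == 0:
        raise ValueError("empty mask has no centroid")
    return np.array([xs.mean(), ys.mean()])


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF frame as a float grayscale array in [0, 1].

    RGB input is converted by luminance; 8- and 16-bit integer images are
    rescaled by their dtype range.
    """
    import imageio.v3 as iio

    raw = iio.imread(Path(path))
    arr = np.asarray(raw, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if np.issubdtype(raw.dtype, np.integer):
        arr = arr / np.iinfo(raw.dtype).max
    return arr
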