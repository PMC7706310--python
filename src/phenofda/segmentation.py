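"""Plant/background segmentation by double-criteria thresholding and morphology.

The double-criteria threshold (DCT) marks a pixel as plant when it is both
bright enough (sum of the RGB intensities above ``threshold1``) and green
enough (a weighted channel contrast above ``threshold2``).  Requiring both
criteria makes the rule far less sensitive to either threshold than a single
cut-off: the brightness criterion deletes black pixels (bars, shadows) while
the chromatic criterion separates vegetation from the achromatic background.

When an empty-pot reference image is available the same rule can be applied
to the signed contrast ``reference - image``, and the two masks intersected,
which removes background structure shared by both frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DCTParams",
    "ROIConfig",
    "Rect",
    "box",
    "dct_binarize",
    "contrast_image",
    "mask_intersect",
    "dilate",
    "erode",
    "closing",
    "opening",
    "refine_mask",
    "largest_component",
    "detect_roi",
    "crop",
    "RoiDetectionError",
    "DEFAULT_REFINEMENT",
]


class RoiDetectionError(RuntimeError):
    """Raised when no region of interest can be located automatically."""


@dataclass(frozen=True)
class DCTParams:
    """Double-criteria threshold parameters.

    Defaults are the values that segment greenhouse RGB images well:
    ``threshold1 = 30/255`` on the summed intensity removes near-black
    pixels, and ``threshold2 = 0.02`` on the green contrast
    ``-R + 2G - B`` keeps most of the plant body.  Both comparisons are
    strict (``>``), so ties fall to background.
    """

    weight: tuple = (-1.0, 2.0, -1.0)
    threshold1: float = 30.0 / 255.0
    threshold2: float = 0.02

    def __post_init__(self):
        w = np.asarray(self.weight, dtype=np.float64)
        if w.shape != (3,) or not np.all(np.isfinite(w)):
            raise ValueError("weight must be 3 finite numbers")
        if not (np.isfinite(self.threshold1) and np.isfinite(self.threshold2)):
            raise ValueError("thresholds must be finite")


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle [r0, r1) x [c0, c1)."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self):
        if not (0 <= self.r0 < self.r1 and 0 <= self.c0 < self.c1):
            raise ValueError(f"invalid rectangle {self}")


@dataclass
class ROIConfig:
    """Region-of-interest detection settings.

    A column is a calibration bar when more than ``bar_min_frac`` of its
    pixels have summed intensity below ``dark_threshold``; the ROI is bounded
    by the innermost bars on each side of the frame.  The top of the pot is
    the first row (scanning down, between the bars) whose fraction of pixels
    with summed intensity below ``pot_threshold`` exceeds ``pot_min_frac``.
    Supplying ``manual`` skips detection and returns it verbatim.
    """

    manual: Rect | None = None
    dark_threshold: float = 0.3
    bar_min_frac: float = 0.5
    min_run: int = 2
    pot_threshold: float = 1.5
    pot_min_frac: float = 0.5


def box(n: int) -> np.ndarray:
    """All-true square structuring element of odd side ``n``."""
    se = np.ones((n, n), dtype=bool)
    _check_se(se)
    return se


def _check_se(se) -> np.ndarray:
    se = np.asarray(se, dtype=bool)
    if se.ndim != 2 or se.shape[0] % 2 == 0 or se.shape[1] % 2 == 0:
        raise ValueError(f"structuring element must be odd-dimensioned 2-D, got {se.shape}")
    if not se.any():
        raise ValueError("structuring element must have at least one true entry")
    return se


def _as_mask(m) -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 2:
        raise ValueError(f"mask must be 2-D, got shape {m.shape}")
    return m.astype(bool)


def dct_binarize(img: np.ndarray, params: DCTParams = DCTParams()) -> np.ndarray:
    """Double-criteria threshold of an RGB image (or signed contrast image).

    Foreground iff ``R + G + B > threshold1`` and
    ``weight . (R, G, B) > threshold2``.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) array, got shape {img.shape}")
    total = img.sum(axis=2)
    contrast = img @ np.asarray(params.weight, dtype=np.float64)
    return (total > params.threshold1) & (contrast > params.threshold2)


def contrast_image(img: np.ndarray, reference: np.ndarray, mode: str = "signed") -> np.ndarray:
    """Per-channel contrast between a plant image and its empty-pot reference.

    ``"signed"`` (default) returns ``reference - img``, so pixels where the
    plant replaced a brighter background show a positive summed contrast;
    ``"abs"`` returns the absolute difference.
    """
    img = np.asarray(img, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if img.shape != reference.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {reference.shape}")
    diff = reference - img
    if mode == "abs":
        return np.abs(diff)
    if mode != "signed":
        raise ValueError(f"unknown contrast mode {mode!r}")
    return diff


def mask_intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a & b


def dilate(m: np.ndarray, se) -> np.ndarray:
    """Binary dilation (Minkowski sum) with zero padding outside the image."""
    return ndimage.binary_dilation(_as_mask(m), structure=_check_se(se), border_value=0)


def erode(m: np.ndarray, se) -> np.ndarray:
    """Binary erosion with zero padding: border pixels erode away."""
    return ndimage.binary_erosion(_as_mask(m), structure=_check_se(se), border_value=0)


def closing(m: np.ndarray, se) -> np.ndarray:
    """Dilation followed by erosion; fills holes and gaps smaller than ``se``."""
    return erode(dilate(m, se), se)


def opening(m: np.ndarray, se) -> np.ndarray:
    """Erosion followed by dilation; removes specks smaller than ``se``."""
    return dilate(erode(m, se), se)


#: Default refinement: 5x5 closing then 3x3 opening, written out as the
#: elementary dilation/erosion sequence applied to the thresholded mask.
DEFAULT_REFINEMENT = (("dilate", 5), ("erode", 5), ("erode", 3), ("dilate", 3))


def refine_mask(m: np.ndarray, sequence=DEFAULT_REFINEMENT) -> np.ndarray:
    """Apply a dilation/erosion sequence given as (op, box size) pairs."""
    out = _as_mask(m)
    for op, size in sequence:
        if op == "dilate":
            out = dilate(out, box(size))
        elif op == "erode":
            out = erode(out, box(size))
        else:
            raise ValueError(f"unknown morphology op {op!r}")
    return out


def largest_component(m: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected foreground component.

    Ties go to the component whose first pixel comes first in row-major
    order.  An empty mask is returned unchanged with a warning.
    """
    m = _as_mask(m)
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    if not m.any():
        warnings.warn("largest_component: empty mask", stacklevel=2)
        return m.copy()
    labels, n = ndimage.label(m, structure=structure)
    counts = np.bincount(labels.ravel())[1:]
    # ndimage labels components in raster order of first pixel, and argmax
    # returns the first maximum, which implements the stated tie-break.
    best = int(np.argmax(counts)) + 1
    return labels == best


def _runs(flags: np.ndarray, min_run: int):
    """Maximal runs of consecutive true entries of length >= min_run."""
    runs = []
    start = None
    for i, f in enumerate(list(flags) + [False]):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    return runs


def detect_roi(img: np.ndarray, cfg: ROIConfig = ROIConfig()) -> Rect:
    """Locate the region of interest between the inner calibration bars and
    above the pot.

    Raises :class:`RoiDetectionError` when no bar pair is found and no manual
    rectangle was supplied; callers may then fall back to the full frame.
    """
    if cfg.manual is not None:
        return cfg.manual
    img = np.asarray(img, dtype=np.float64)
    H, W = img.shape[:2]
    total = img.sum(axis=2)

    dark_frac = (total < cfg.dark_threshold).mean(axis=0)
    bar_runs = _runs(dark_frac > cfg.bar_min_frac, cfg.min_run)
    mid = W / 2.0
    left = [run for run in bar_runs if run[1] <= mid]
    right = [run for run in bar_runs if run[0] >= mid]
    if not left or not right:
        raise RoiDetectionError("no bar pair found; supply a manual rectangle")
    c0 = left[-1][1]   # right edge of the innermost left bar
    c1 = right[0][0]   # left edge of the innermost right bar

    pot_frac = (total[:, c0:c1] < cfg.pot_threshold).mean(axis=1)
    pot_rows = np.nonzero(pot_frac > cfg.pot_min_frac)[0]
    r1 = int(pot_rows[0]) if pot_rows.size else H
    if r1 == 0:
        raise RoiDetectionError("pot band reaches the top of the frame")
    return Rect(0, r1, int(c0), int(c1))


def crop(x: np.ndarray, rect: Rect) -> np.ndarray:
    """Crop an image or mask to a rectangle (half-open bounds)."""
    x = np.asarray(x)
    H, W = x.shape[:2]
    if rect.r1 > H or rect.c1 > W:
        raise ValueError(f"rectangle {rect} out of bounds for shape {x.shape}")
    return x[rect.r0 : rect.r1, rect.c0 : rect.c1].copy()
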