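"""Image reading/writing, channel algebra, and synthetic greenhouse scenes.

Images are held as ``float64`` arrays of shape ``(H, W, 3)`` with channel
intensities in ``[0, 1]`` (an 8-bit value ``v`` maps to ``v / 255``).  All
coordinates are 0-based ``(row, col)``, row-major, and every rectangle in the
package is half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "channel_combine",
    "relative_green",
    "SceneConfig",
    "synth_scene",
]


def read_image(path) -> np.ndarray:
    """Read a PNG/JPEG into an ``(H, W, 3)`` float array scaled to [0, 1].

    RGBA images are accepted (the alpha channel is dropped); grayscale input
    raises ``ValueError`` since the segmentation methods need all three
    channels.
    """
    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: grayscale image, expected 3 channels")
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    arr = arr[:, :, :3]
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        return arr.astype(np.float64) / scale
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def write_image(path, img: np.ndarray) -> None:
    """Write an ``(H, W, 3)`` [0, 1] array as an 8-bit image."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) array, got shape {img.shape}")
    data = np.rint(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, data)


def write_mask(path, mask: np.ndarray) -> None:
    """Write a boolean mask as a single-channel PNG (0 = background, 255 = foreground)."""
    mask = np.asarray(mask, dtype=bool)
    iio.imwrite(path, (mask.astype(np.uint8)) * 255)


def read_mask(path) -> np.ndarray:
    """Read a 0/255 single-channel PNG back into a boolean mask."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[:, :, 0]
    return arr > 127


def _as_image(img) -> np.ndarray:
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) array, got shape {img.shape}")
    return img


def channel_combine(img: np.ndarray, weight) -> np.ndarray:
    """Weighted combination of the R, G, B channels.

    Returns the scalar field ``w_R * R + w_G * G + w_B * B``.  With weight
    ``(1, 1, 1)`` this is the summed intensity; ``(-1, 2, -1)`` is the green
    contrast used by the double-criteria threshold.
    """
    img = _as_image(img)
    weight = np.asarray(weight, dtype=np.float64)
    if weight.shape != (3,):
        raise ValueError(f"weight must have 3 entries, got shape {weight.shape}")
    if not np.all(np.isfinite(weight)):
        raise ValueError("weight entries must be finite")
    return img @ weight


def relative_green(img: np.ndarray) -> np.ndarray:
    """Relative green intensity G / (R + G + B), in [0, 1].

    Pixels with zero total intensity (pure black) map to 0 so that they are
    never mistaken for vegetation.
    """
    img = _as_image(img)
    total = img.sum(axis=2)
    out = np.zeros_like(total)
    np.divide(img[:, :, 1], total, out=out, where=total > 0)
    return out


def _check_rect(name, rect, height, width):
    r0, r1, c0, c1 = rect
    if not (0 <= r0 < r1 <= height and 0 <= c0 < c1 <= width):
        raise ValueError(f"{name} {rect} does not fit a {height}x{width} image")


@dataclass
class SceneConfig:
    """Geometry and colors of a synthetic greenhouse scene.

    The scene emulates a side-view pot image: a bright uniform background, a
    gray pot band near the bottom, dark vertical calibration bars near the
    left and right edges, and a plant (vertical stem plus a leaf canopy)
    standing above the pot.  All rectangles are half-open (r0, r1, c0, c1).

    ``canopy`` selects the canopy shape: ``"rect"`` gives a horizontal leaf
    rectangle (the plant is then a union of axis-aligned rectangles, which is
    invariant under the default morphological refinement), ``"ellipse"`` a
    rasterized filled ellipse.
    """

    height: int = 120
    width: int = 160
    stem_rect: tuple = (45, 90, 76, 84)
    canopy: str = "rect"
    leaf_rect: tuple = (55, 63, 50, 110)
    ellipse: tuple = (58, 80, 12, 28)  # (center_row, center_col, semi_r, semi_c)
    plant_color: tuple = (0.15, 0.45, 0.15)
    plant_color_sd: float = 0.02
    background_color: tuple = (0.85, 0.85, 0.85)
    pot_color: tuple = (0.45, 0.35, 0.28)
    pot_rect: tuple = (90, 120, 40, 120)
    bar_color: tuple = (0.05, 0.05, 0.05)
    bar_cols: tuple = ((10, 14), (146, 150))
    noise_sd: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("degenerate image size")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.plant_color_sd < 0:
            raise ValueError("plant_color_sd must be >= 0")
        _check_rect("stem_rect", self.stem_rect, self.height, self.width)
        _check_rect("pot_rect", self.pot_rect, self.height, self.width)
        if self.canopy == "rect":
            _check_rect("leaf_rect", self.leaf_rect, self.height, self.width)
        elif self.canopy == "ellipse":
            cr, cc, a, b = self.ellipse
            if a < 1 or b < 1:
                raise ValueError("degenerate ellipse axes")
            if not (0 <= cr - a and cr + a < self.height and 0 <= cc - b and cc + b < self.width):
                raise ValueError("ellipse does not fit inside the image")
        else:
            raise ValueError(f"unknown canopy shape {self.canopy!r}")
        for c0, c1 in self.bar_cols:
            if not (0 <= c0 < c1 <= self.width):
                raise ValueError(f"bar columns ({c0}, {c1}) outside image")


def plant_mask(cfg: SceneConfig) -> np.ndarray:
    """Ground-truth plant mask of the configured geometry."""
    cfg.validate()
    truth = np.zeros((cfg.height, cfg.width), dtype=bool)
    r0, r1, c0, c1 = cfg.stem_rect
    truth[r0:r1, c0:c1] = True
    if cfg.canopy == "rect":
        r0, r1, c0, c1 = cfg.leaf_rect
        truth[r0:r1, c0:c1] = True
    else:
        cr, cc, a, b = cfg.ellipse
        rr, cc_grid = np.ogrid[: cfg.height, : cfg.width]
        truth |= ((rr - cr) / a) ** 2 + ((cc_grid - cc) / b) ** 2 <= 1.0
    return truth


def synth_scene(cfg: SceneConfig):
    """Generate a (plant image, empty-pot image, truth mask) triple.

    The two images share an identical background (pot, bars, backdrop) and
    differ only inside the truth mask, apart from independent iid Gaussian
    pixel noise of standard deviation ``cfg.noise_sd`` truncated to [0, 1].
    Deterministic given ``cfg.seed``.
    """
    truth = plant_mask(cfg)
    rng = np.random.default_rng(cfg.seed)

    base = np.empty((cfg.height, cfg.width, 3), dtype=np.float64)
    base[:] = cfg.background_color
    r0, r1, c0, c1 = cfg.pot_rect
    base[r0:r1, c0:c1] = cfg.pot_color
    for c0, c1 in cfg.bar_cols:
        base[:, c0:c1] = cfg.bar_color

    plant = base.copy()
    plant[truth] = cfg.plant_color
    if cfg.plant_color_sd > 0:
        jitter = rng.normal(0.0, cfg.plant_color_sd, size=(int(truth.sum()), 3))
        plant[truth] = np.clip(plant[truth] + jitter, 0.0, 1.0)

    empty = base.copy()
    if cfg.noise_sd > 0:
        plant = np.clip(plant + rng.normal(0.0, cfg.noise_sd, plant.shape), 0.0, 1.0)
        empty = np.clip(empty + rng.normal(0.0, cfg.noise_sd, empty.shape), 0.0, 1.0)
    return plant, empty, truth
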