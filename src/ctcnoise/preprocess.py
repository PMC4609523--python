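"""Cutout preprocessing: physical-area crop, Gaussian smoothing,
downsampling and hue/saturation vectorisation.

Cutouts come from images taken at three magnifications (1.0, 0.5 or
0.25 µm² per pixel).  To present the classifier with a fixed physical
field of view, each cutout is cropped to a 2500 µm² centred square
(100, 71 or 50 px on a side depending on resolution), denoised with a
σ = 1 px Gaussian, resampled to 50 × 50 px, converted from RGB to HSV,
and — since overall brightness is not decisive for the CTC call — the V
channel is dropped.  The result is a 5000-entry vector: 2500 hue values
followed by 2500 saturation values, row-major.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.transform import resize

#: Pixel areas (µm² per pixel) of the three source magnifications.
PIXEL_AREAS = (1.0, 0.5, 0.25)


@dataclass(frozen=True)
class Cutout:
    """Square RGB raster centred on a candidate object, with its
    physical pixel size."""

    pixels: np.ndarray  # H x W x 3, floats in [0, 1]
    pixel_area: float  # µm² per pixel
    cutout_id: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 raster")
        if p.shape[0] != p.shape[1]:
            raise ValueError("cutouts must be square")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")
        object.__setattr__(self, "pixels", p)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class PreprocessConfig:
    region_area: float = 2500.0  # µm²
    sigma: float = 1.0  # px, at the source resolution
    target_side: int = 50  # px

    def __post_init__(self) -> None:
        if self.region_area <= 0 or self.sigma < 0 or self.target_side <= 0:
            raise ValueError("preprocessing parameters must be positive (sigma >= 0)")

    @property
    def n_features(self) -> int:
        return 2 * self.target_side**2


def crop_side(region_area: float, pixel_area: float) -> int:
    """Side length in px of a square covering ``region_area`` µm²."""
    return round(math.sqrt(region_area / pixel_area))


def crop_to_region(c: Cutout, region_area: float = 2500.0) -> Cutout:
    """Centred square crop covering a fixed physical area.

    No padding: a region larger than the raster is an error.
    """
    side = crop_side(region_area, c.pixel_area)
    if side > c.side:
        raise ValueError(
            f"requested region ({side} px) exceeds the raster ({c.side} px)"
        )
    start = (c.side - side) // 2
    return Cutout(
        pixels=c.pixels[start : start + side, start : start + side],
        pixel_area=c.pixel_area,
        cutout_id=c.cutout_id,
    )


def gaussian_smooth(c: Cutout, sigma: float = 1.0) -> Cutout:
    """Isotropic Gaussian blur, each colour channel independently."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return c
    smoothed = np.stack(
        [ndimage.gaussian_filter(c.pixels[..., k], sigma=sigma) for k in range(3)],
        axis=-1,
    )
    return Cutout(np.clip(smoothed, 0.0, 1.0), c.pixel_area, c.cutout_id)


def downsample(c: Cutout, target_side: int = 50) -> Cutout:
    """Bilinear resampling to a fixed raster size (downsampling only)."""
    if target_side > c.side:
        raise ValueError("upsampling is not supported")
    if target_side == c.side:
        return c
    out = resize(
        c.pixels,
        (target_side, target_side, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    new_area = c.pixel_area * (c.side / target_side) ** 2
    return Cutout(np.clip(out, 0.0, 1.0), new_area, c.cutout_id)


def to_hue_saturation(c: Cutout, expected_side: int = 50) -> np.ndarray:
    """Vectorise as [all H row-major, all S row-major], H and S in [0, 1].

    V is discarded.  Hue is kept as a plain real in [0, 1) — the red-hue
    wraparound is a known representational artifact — and is 0 for
    achromatic pixels (S = 0), where hue is undefined.
    """
    if c.side != expected_side:
        raise ValueError(f"expected a {expected_side} px raster, got {c.side} px")
    hsv = rgb2hsv(c.pixels)
    return np.concatenate([hsv[..., 0].ravel(), hsv[..., 1].ravel()])


def preprocess(c: Cutout, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Full deterministic pipeline: crop -> smooth -> downsample -> H/S
    vector of length ``2 * target_side**2`` (5000 at defaults)."""
    cfg = cfg or PreprocessConfig()
    out = crop_to_region(c, cfg.region_area)
    out = gaussian_smooth(out, cfg.sigma)
    out = downsample(out, cfg.target_side)
    return to_hue_saturation(out, cfg.target_side)


def preprocess_all(
    cutouts, cfg: PreprocessConfig | None = None
) -> np.ndarray:
    """Feature matrix: one preprocessed row per cutout."""
    cfg = cfg or PreprocessConfig()
    return np.array([preprocess(c, cfg) for c in cutouts])


# ---------------------------------------------------------------------------
# Image + metadata I/O
# ---------------------------------------------------------------------------

def load_cutout(image_path, pixel_area: float, cutout_id: str = "") -> Cutout:
    """Read a PNG/TIFF cutout (8- or 16-bit), rescaling values to [0, 1]."""
    raw = iio.imread(image_path)
    if raw.ndim != 3 or raw.shape[2] < 3:
        raise ValueError(f"{image_path}: expected a 3-channel image")
    raw = raw[..., :3]
    if np.issubdtype(raw.dtype, np.integer):
        scale = float(np.iinfo(raw.dtype).max)
        pixels = raw.astype(float) / scale
    else:
        pixels = raw.astype(float)
    return Cutout(pixels, pixel_area, cutout_id or Path(image_path).stem)


def save_cutout(c: Cutout, image_path) -> None:
    iio.imwrite(image_path, (c.pixels * 255).round().astype(np.uint8))


def load_cutout_dir(directory) -> list[Cutout]:
    """Load a cutout directory written by the synth generator or a
    compatible exporter: PNGs plus a ``metadata.csv`` sidecar with
    columns cutout_id, pixel_area_um2 (and optionally source_image,
    magnification)."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.csv")
    return [
        load_cutout(directory / f"{row.cutout_id}.png", row.pixel_area_um2, str(row.cutout_id))
        for row in meta.itertuples()
    ]


def save_features(features: np.ndarray, path, cutout_ids=None, target_side: int = 50) -> None:
    """Write the feature matrix with H(0,0)..H(s-1,s-1), S(0,0)..S(s-1,s-1) headers."""
    s = target_side
    cols = [f"H({i},{j})" for i in range(s) for j in range(s)] + [
        f"S({i},{j})" for i in range(s) for j in range(s)
    ]
    df = pd.DataFrame(features, columns=cols)
    if cutout_ids is not None:
        df.insert(0, "cutout_id", list(cutout_ids))
    df.to_csv(path, index=False)
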