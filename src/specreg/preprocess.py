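"""Preprocessing of raw inputs into resolution-matched, background-masked images.

The two modalities arrive in very different forms: the vibrational
microscopy side is a hyperspectral cube (an infrared absorption or Raman
emission spectrum per pixel), the histology side is an RGB photograph of an
H&E-stained section.  Before either can be presegmented into an index-color
image they must be reduced to a common footing:

* the cube is collapsed to an integral-absorption intensity image from which
  a foreground mask is derived by automatic (Otsu) thresholding;
* the stained image is resampled to the spectral pixel size, its global
  stain/illumination color cast is removed by division in intensity space
  (equivalent to subtraction in optical density), and near-white pixels are
  snapped to pure white, which marks the histology background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from skimage.filters import threshold_otsu

from .errors import DegenerateInputError

__all__ = [
    "HyperspectralCube",
    "RGBImage",
    "ForegroundMask",
    "integral_intensity_image",
    "background_mask_from_intensity",
    "estimate_background_color",
    "correct_color_cast",
    "resize_to_resolution",
    "he_background_mask",
]


@dataclass
class HyperspectralCube:
    """A rows x cols x bands grid of non-negative spectral intensities.

    ``wavenumbers`` is the strictly increasing spectral axis in 1/cm;
    ``pixel_size`` is the lateral sampling in micrometres per pixel.
    """

    values: np.ndarray
    wavenumbers: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("cube values must be rows x cols x bands")
        if self.wavenumbers.ndim != 1 or self.wavenumbers.size != self.values.shape[2]:
            raise ValueError("wavenumber axis must match the number of bands")
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("cube must contain at least one pixel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class RGBImage:
    """An 8-bit rows x cols x 3 stained-tissue image with known pixel size."""

    values: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3 or values.shape[2] != 3:
            raise ValueError("RGB image must be rows x cols x 3")
        if values.dtype != np.uint8:
            if values.min() < 0 or values.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            values = np.round(values).astype(np.uint8)
        self.values = values
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[:2]


@dataclass
class ForegroundMask:
    """Boolean grid, True where a pixel is covered by sample (foreground)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_foreground(self) -> int:
        return int(self.mask.sum())


def integral_intensity_image(cube: HyperspectralCube) -> np.ndarray:
    """Collapse a cube to the per-pixel integral absorption over all bands.

    Uses the trapezoid rule on the wavenumber axis, so the result is an
    integral in absorbance * 1/cm rather than a plain band sum.
    """
    if cube.n_bands < 2:
        raise DegenerateInputError("cannot integrate single-band cube")
    return np.trapezoid(cube.values, x=cube.wavenumbers, axis=2)


def background_mask_from_intensity(
    intensity: np.ndarray,
    nbins: int = 256,
    max_background_ratio: float | None = None,
) -> ForegroundMask:
    """Split an intensity image into sample and substrate by Otsu's method.

    Pixels strictly above the automatically determined cutoff are foreground.
    Otsu's scan returns the *center* of the last histogram bin assigned to
    the background class; the effective cutoff is that bin's upper edge, so
    that every value binned into the background class stays background.

    Otsu always produces a split, even when the field of view contains no
    substrate at all — in which case the lowest-absorbing tissue class would
    be misread as background.  Substrate absorbs an order of magnitude less
    than tissue, so with ``max_background_ratio`` set, a split whose
    background-class mean intensity exceeds that fraction of the
    foreground-class mean is rejected and the whole image is declared
    foreground.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.ndim != 2:
        raise ValueError("intensity image must be 2-D")
    if np.unique(intensity).size < 2:
        raise DegenerateInputError("degenerate intensity histogram")
    center = threshold_otsu(intensity, nbins=nbins)
    half_bin = (intensity.max() - intensity.min()) / (2.0 * nbins)
    mask = intensity > center + half_bin
    if max_background_ratio is not None and mask.any() and not mask.all():
        if intensity[~mask].mean() > max_background_ratio * intensity[mask].mean():
            mask = np.ones_like(mask)
    return ForegroundMask(mask)


_LUMA = np.array([0.299, 0.587, 0.114])


def estimate_background_color(
    he: RGBImage,
    luminance_percentile: float = 90.0,
    min_background_luminance: float = 128.0,
) -> np.ndarray:
    """Estimate the (cast-affected) background color of a stained image.

    Background pixels are assumed bright.  An initial candidate set — all
    pixels whose luminance reaches the given percentile — pins down the
    background mode, but averaging only that upper tail would bias the
    estimate bright by roughly one noise standard deviation.  The selection
    is therefore widened to the whole mode: every pixel within three robust
    standard deviations (1.4826 x MAD) below the candidates' median
    luminance, and the estimate is the mean color of that set.  If the
    candidates are not actually bright (mean luminance below
    ``min_background_luminance``) the image has no usable glass/air
    background and the color must be supplied manually.
    """
    rgb = he.values.astype(np.float64)
    lum = rgb @ _LUMA
    thresh = np.percentile(lum, luminance_percentile)
    candidates = lum >= thresh
    if not candidates.any():
        raise DegenerateInputError("no background found; supply color manually")
    med = np.median(lum[candidates])
    sigma = 1.4826 * np.median(np.abs(lum[candidates] - med))
    selected = lum >= med - 3.0 * sigma
    color = rgb[selected].mean(axis=0)
    if color @ _LUMA < min_background_luminance:
        raise DegenerateInputError("no background found; supply color manually")
    return color


def correct_color_cast(
    he: RGBImage, bg: np.ndarray, white_snap_distance: float = 15.0
) -> RGBImage:
    """Remove a global color cast by dividing out the background color.

    Subtracting the background color vector in optical density space
    (OD = -log10(I / I_ref)) is exactly a per-channel division in intensity
    space, which avoids taking logarithms of zero:
    ``out_c = round(255 * min(1, in_c / bg_c))``.  Corrected colors within
    ``white_snap_distance`` (Euclidean RGB) of pure white are set exactly to
    (255, 255, 255), which marks the histology background.
    """
    bg = np.asarray(bg, dtype=np.float64)
    if bg.shape != (3,):
        raise ValueError("background color must be a 3-vector")
    if np.any(bg <= 0):
        raise DegenerateInputError("background color has a zero channel")
    scaled = 255.0 * np.minimum(1.0, he.values.astype(np.float64) / bg)
    out = np.floor(scaled + 0.5)
    near_white = np.sum((out - 255.0) ** 2, axis=2) < white_snap_distance**2
    out[near_white] = 255.0
    return RGBImage(out.astype(np.uint8), he.pixel_size)


def resize_to_resolution(he: RGBImage, target_pixel_size: float) -> RGBImage:
    """Resample a stained image to a coarser pixel size (area averaging).

    Output dimensions are ``round(dim * pixel_size / target_pixel_size)``.
    Downscaling uses anti-aliased area (box) interpolation; a requested
    upscale triggers a warning and falls back to bicubic interpolation.
    """
    if target_pixel_size <= 0:
        raise ValueError("target pixel size must be positive")
    factor = he.pixel_size / target_pixel_size
    rows, cols = he.shape
    new_rows = max(1, int(round(rows * factor)))
    new_cols = max(1, int(round(cols * factor)))
    if factor > 1:
        warnings.warn(
            "upscaling requested beyond factor 1; using bicubic interpolation",
            stacklevel=2,
        )
        resample = Image.Resampling.BICUBIC
    else:
        resample = Image.Resampling.BOX
    img = Image.fromarray(he.values, mode="RGB")
    out = np.asarray(img.resize((new_cols, new_rows), resample=resample))
    return RGBImage(out, target_pixel_size)


def he_background_mask(he_corrected: RGBImage) -> ForegroundMask:
    """Foreground mask of a cast-corrected image: background is pure white."""
    return ForegroundMask(~np.all(he_corrected.values == 255, axis=2))
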