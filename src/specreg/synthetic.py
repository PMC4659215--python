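"""Synthetic co-registered phantom pairs with known ground-truth transforms.

Real paired FTIR/H&E measurements are large and not redistributable, so
every stage of the pipeline is exercised on phantoms: a smoothed random
"tissue" label map with a connected substrate border is rendered twice —
once as an H&E-like RGB slide (per-class colors, global color cast,
Gaussian sensor noise) and once as a hyperspectral ROI cube (per-class
smooth spectra over the 900-1800 1/cm fingerprint region) cut out of the
slide under a known similarity transform.  The exact spectral shapes are
irrelevant to the registration logic; only class separability matters, and
the default noise levels are derived from the minimum class separation so
that the class signal-to-noise ratio is about 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegenerateInputError
from .geometry import SimilarityTransform, map_coordinates
from .preprocess import HyperspectralCube, RGBImage

__all__ = ["PhantomScene", "make_label_map", "make_scene", "render_pair", "roi_true_labels"]

#: H&E-like palette (hematoxylin purples through eosin pinks); pairwise
#: distances >= ~50 gray levels so classes stay separable under noise.
_PALETTE = np.array(
    [
        (72, 36, 118),  # dense nuclei, dark purple
        (126, 70, 168),  # violet
        (196, 96, 158),  # magenta-pink
        (232, 148, 176),  # eosin pink
        (172, 58, 88),  # red-pink
        (96, 96, 186),  # blue-purple
        (238, 190, 208),  # pale pink
        (152, 116, 204),  # lavender
    ],
    dtype=np.float64,
)
_SUBSTRATE_COLOR = np.array([255.0, 255.0, 255.0])

DEFAULT_WAVENUMBERS = np.linspace(900.0, 1800.0, 60)


def make_label_map(
    rows: int,
    cols: int,
    n_classes: int,
    seed: int,
    blob_scale: float = 25.0,
    foreground_fraction: float = 0.8,
) -> np.ndarray:
    """Tissue-like label map: smoothed random blobs inside a substrate border.

    Labels are 0 (substrate) and 1..n_classes; every class is guaranteed
    present.  The substrate forms a connected frame around the tissue.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 tissue classes")
    if rows * cols < 16 * n_classes:
        raise DegenerateInputError(f"image {rows}x{cols} too small for {n_classes} classes")
    border = max(2, min(rows, cols) // 20)
    for attempt in range(20):
        rng = np.random.default_rng([seed, attempt])
        shape_field = gaussian_filter(rng.standard_normal((rows, cols)), min(rows, cols) / 4.0)
        fg = shape_field > np.quantile(shape_field, 1.0 - foreground_fraction)
        fg[:border, :] = fg[-border:, :] = False
        fg[:, :border] = fg[:, -border:] = False
        fields = gaussian_filter(
            rng.standard_normal((n_classes, rows, cols)), (0, blob_scale, blob_scale)
        )
        labels = np.zeros((rows, cols), dtype=np.int32)
        labels[fg] = np.argmax(fields, axis=0)[fg] + 1
        if len(np.unique(labels[fg])) == n_classes and fg.any():
            return labels
    raise DegenerateInputError("could not place all classes; image too small for class count")


def _make_class_spectra(n_classes: int, wavenumbers: np.ndarray, rng) -> np.ndarray:
    """Smooth random mixtures of Gaussian bands, one spectrum per class.

    Row 0 is the low-intensity substrate spectrum; rows 1..C are tissue
    classes, redrawn until pairwise L2 separation is adequate.
    """
    n_bands = wavenumbers.size
    spectra = np.zeros((n_classes + 1, n_bands))
    spectra[0] = 0.02  # bare substrate: almost no absorption
    min_sep = 0.15 * math.sqrt(n_bands)
    for c in range(1, n_classes + 1):
        for _ in range(60):
            bands = np.zeros(n_bands)
            for _ in range(5):
                center = rng.uniform(950.0, 1750.0)
                width = rng.uniform(15.0, 60.0)
                amp = rng.uniform(0.3, 1.0)
                bands += amp * np.exp(-0.5 * ((wavenumbers - center) / width) ** 2)
            if all(np.linalg.norm(bands - spectra[j]) >= min_sep for j in range(c)):
                spectra[c] = bands
                break
        else:
            raise DegenerateInputError("failed to draw separable class spectra")
    return spectra


@dataclass
class PhantomScene:
    """Full description of one synthetic study: tissue map, rendering
    parameters, and the ground-truth template-to-slide transform."""

    label_map: np.ndarray
    wavenumbers: np.ndarray
    class_spectra: np.ndarray  # (C+1, bands); row 0 = substrate
    class_colors: np.ndarray  # (C+1, 3); row 0 = substrate
    cast_color: np.ndarray
    true_transform: SimilarityTransform
    roi_shape: tuple[int, int]
    noise_sigma_spectral: float
    noise_sigma_rgb: float
    slide_pixel_size: float = 5.0
    roi_pixel_size: float = 5.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return self.class_spectra.shape[0] - 1

    @property
    def working_shape(self) -> tuple[int, int]:
        return self.label_map.shape

    @property
    def upsample_factor(self) -> int:
        f = self.roi_pixel_size / self.slide_pixel_size
        if f < 1 or abs(f - round(f)) > 1e-9:
            raise ValueError("roi/slide pixel size ratio must be a positive integer")
        return int(round(f))


def make_scene(
    seed: int,
    slide_shape: tuple[int, int] = (400, 600),
    roi_shape: tuple[int, int] = (120, 160),
    n_classes: int = 6,
    transform: SimilarityTransform | None = None,
    theta_range: float = 30.0,
    translation_only: bool = False,
    noise_sigma_spectral: float | None = None,
    noise_sigma_rgb: float | None = None,
    cast_color: tuple[float, float, float] = (242.0, 232.0, 238.0),
    slide_pixel_size: float = 5.0,
    roi_pixel_size: float = 5.0,
    wavenumbers: np.ndarray | None = None,
    blob_scale: float = 25.0,
) -> PhantomScene:
    """Build a reproducible phantom scene from a seed.

    ``slide_shape`` is the slide extent on the working grid (the spectral
    resolution); the rendered RGB slide is this times the integer
    roi/slide pixel-size ratio.  If no transform is given, a random rigid
    one is drawn: rotation uniform in +-theta_range degrees, integer
    translation uniform over positions keeping the ROI fully on the slide.
    """
    rng = np.random.default_rng([seed, 100])
    if n_classes > len(_PALETTE):
        raise ValueError(f"at most {len(_PALETTE)} classes supported")
    rows, cols = slide_shape
    label_map = make_label_map(rows, cols, n_classes, seed, blob_scale=blob_scale)
    if wavenumbers is None:
        wavenumbers = DEFAULT_WAVENUMBERS.copy()
    spectra = _make_class_spectra(n_classes, wavenumbers, rng)
    colors = np.vstack([_SUBSTRATE_COLOR, _PALETTE[:n_classes] + rng.uniform(-4, 4, (n_classes, 3))])
    colors = np.clip(colors, 0, 255)

    if transform is None:
        theta = 0.0 if translation_only else float(rng.uniform(-theta_range, theta_range))
        hw, hh = (roi_shape[1] - 1) / 2.0, (roi_shape[0] - 1) / 2.0
        th = math.radians(theta)
        half_w = hw * abs(math.cos(th)) + hh * abs(math.sin(th))
        half_h = hw * abs(math.sin(th)) + hh * abs(math.cos(th))
        margin = 2.0
        max_tx = math.floor((cols - 1) / 2.0 - half_w - margin)
        max_ty = math.floor((rows - 1) / 2.0 - half_h - margin)
        if max_tx < 0 or max_ty < 0:
            raise DegenerateInputError("ROI does not fit inside the slide")
        transform = SimilarityTransform(
            tx=int(rng.integers(-max_tx, max_tx + 1)),
            ty=int(rng.integers(-max_ty, max_ty + 1)),
            theta=theta,
        )

    # class SNR ~ 10: noise sigma = min class separation / (10 * sqrt(dim))
    tissue = spectra[1:]
    min_spec_sep = min(
        np.linalg.norm(tissue[i] - tissue[j])
        for i in range(len(tissue))
        for j in range(i + 1, len(tissue))
    )
    if noise_sigma_spectral is None:
        noise_sigma_spectral = min_spec_sep / (10.0 * math.sqrt(wavenumbers.size))
    min_col_sep = min(
        np.linalg.norm(colors[i] - colors[j])
        for i in range(len(colors))
        for j in range(i + 1, len(colors))
    )
    if noise_sigma_rgb is None:
        noise_sigma_rgb = min_col_sep / (10.0 * math.sqrt(3.0))

    return PhantomScene(
        label_map=label_map,
        wavenumbers=np.asarray(wavenumbers, dtype=np.float64),
        class_spectra=spectra,
        class_colors=colors,
        cast_color=np.asarray(cast_color, dtype=np.float64),
        true_transform=transform,
        roi_shape=roi_shape,
        noise_sigma_spectral=float(noise_sigma_spectral),
        noise_sigma_rgb=float(noise_sigma_rgb),
        slide_pixel_size=slide_pixel_size,
        roi_pixel_size=roi_pixel_size,
        seed=seed,
    )


def roi_true_labels(scene: PhantomScene) -> np.ndarray:
    """Ground-truth label of every ROI pixel: the label map sampled through
    the true transform (nearest neighbour, same rounding as registration)."""
    rows, cols = scene.roi_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = map_coordinates(
        scene.true_transform, scene.roi_shape, scene.working_shape, np.stack([rr, cc], axis=-1)
    )
    ir = np.floor(coords[..., 0] + 0.5).astype(np.int64)
    ic = np.floor(coords[..., 1] + 0.5).astype(np.int64)
    wr, wc = scene.working_shape
    if ir.min() < 0 or ir.max() >= wr or ic.min() < 0 or ic.max() >= wc:
        raise DegenerateInputError("ROI not fully inside slide under the true transform")
    return scene.label_map[ir, ic]


def render_pair(scene: PhantomScene) -> tuple[HyperspectralCube, RGBImage]:
    """Render (hyperspectral ROI cube, RGB slide) for a scene.

    The slide is the colored label map under the global cast
    (channel-wise multiplication by cast/255) plus Gaussian noise; the ROI
    cube carries the class spectra of the label map sampled through the
    true transform, plus spectral noise.  Same seed, bit-identical output.
    """
    labels_roi = roi_true_labels(scene)
    rng_cube = np.random.default_rng([scene.seed, 201])
    cube_vals = scene.class_spectra[labels_roi]
    if scene.noise_sigma_spectral > 0:
        cube_vals = cube_vals + rng_cube.normal(0.0, scene.noise_sigma_spectral, cube_vals.shape)
    cube = HyperspectralCube(
        np.clip(cube_vals, 0.0, None), scene.wavenumbers, scene.roi_pixel_size
    )

    rng_slide = np.random.default_rng([scene.seed, 202])
    f = scene.upsample_factor
    lab = scene.label_map
    if f > 1:
        lab = np.repeat(np.repeat(lab, f, axis=0), f, axis=1)
    slide = scene.class_colors[lab]
    if scene.noise_sigma_rgb > 0:
        slide = slide + rng_slide.normal(0.0, scene.noise_sigma_rgb, slide.shape)
    slide = slide * (scene.cast_color / 255.0)
    slide = np.clip(np.floor(slide + 0.5), 0, 255).astype(np.uint8)
    return cube, RGBImage(slide, scene.slide_pixel_size)
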