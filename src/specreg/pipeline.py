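"""End-to-end orchestration: preprocess, segment, estimate r0, search.

The spectral ROI is the fixed image (template); the stained slide is the
moving image.  ``register`` accepts either raw inputs (a hyperspectral cube
and an RGB image) or precomputed index images for one or both sides, runs
the full chain, and returns the search result together with the
intermediate artifacts needed for QC.  With k_fixed = k_moving = 1 the
pipeline degenerates to registration on binary foreground/background
images (the binary-metric variant).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from PIL import Image, ImageDraw

from .errors import DegenerateInputError
from .geometry import (
    SimilarityTransform,
    TransformBounds,
    TransformScorer,
    map_coordinates,
)
from .metric import joint_histogram
from .optimizer import (
    RegistrationResult,
    SearchSchedule,
    estimate_initial_radius,
    sparse_search,
)
from .preprocess import (
    HyperspectralCube,
    RGBImage,
    background_mask_from_intensity,
    correct_color_cast,
    estimate_background_color,
    he_background_mask,
    integral_intensity_image,
    resize_to_resolution,
)
from .segmentation import IndexImage, segment_spectral, segment_stained

__all__ = ["RegistrationConfig", "register", "evaluate_registration", "render_overlay"]


@dataclass
class RegistrationConfig:
    """All pipeline parameters with their standard defaults.

    k_moving=10 for whole-slide images, k_fixed=8 for the smaller spectral
    ROIs; alpha=0.25; threshold schedule k0=0.6, delta_k=0.5; scale limits
    [0.8, 1.2] and rotation limits [-30, 30] degrees (template matching).
    """

    k_fixed: int = 8
    k_moving: int = 10
    alpha: float = 0.25
    k0: float = 0.6
    delta_k: float = 0.5
    transform_class: str = "rigid"  # translation | rigid | similarity
    rotation_bounds: tuple[float, float] = (-30.0, 30.0)
    scale_bounds: tuple[float, float] = (0.8, 1.2)
    translation_bounds: tuple[float, float, float, float] | None = None
    log_base: float = 2.0
    seed: int = 0
    white_snap_distance: float = 15.0
    luminance_percentile: float = 90.0
    background_color: tuple[float, float, float] | None = None
    #: reject an intensity-based background split whose background class
    #: absorbs more than this fraction of the foreground mean (templates
    #: fully covered by tissue contain no substrate to find)
    background_intensity_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.transform_class not in ("translation", "rigid", "similarity"):
            raise ValueError("transform_class must be translation, rigid or similarity")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if min(self.k_fixed, self.k_moving) < 1:
            raise ValueError("cluster counts must be >= 1")

    def bounds_for(
        self,
        moving_shape: tuple[int, int],
        template_shape: tuple[int, int] | None = None,
    ) -> TransformBounds:
        """Search bounds for the template center.

        In template matching the ROI is a subregion of the slide, so the
        default translation range keeps the template essentially contained
        in the moving image (a 10 px overhang is allowed); when the
        template is not smaller than the slide, or its shape is unknown,
        the range falls back to the full slide extent.
        """
        if self.translation_bounds is not None:
            tx = tuple(self.translation_bounds[:2])
            ty = tuple(self.translation_bounds[2:])
        else:
            rows, cols = moving_shape
            half_x = (cols - 1) / 2.0
            half_y = (rows - 1) / 2.0
            if template_shape is not None:
                slack = 10.0
                half_x = min(half_x, max(0.0, (cols - template_shape[1]) / 2.0 + slack))
                half_y = min(half_y, max(0.0, (rows - template_shape[0]) / 2.0 + slack))
            tx = (-half_x, half_x)
            ty = (-half_y, half_y)
        theta = tuple(self.rotation_bounds) if self.transform_class != "translation" else None
        scale = tuple(self.scale_bounds) if self.transform_class == "similarity" else None
        return TransformBounds(tx=tx, ty=ty, theta=theta, scale=scale)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RegistrationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("rotation_bounds", "scale_bounds", "translation_bounds", "background_color"):
            if data.get(key) is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _prepare_fixed(
    spectral: HyperspectralCube | IndexImage,
    cfg: RegistrationConfig,
    fixed_mask,
) -> IndexImage:
    if isinstance(spectral, IndexImage):
        return spectral
    if fixed_mask is None:
        fixed_mask = background_mask_from_intensity(
            integral_intensity_image(spectral),
            max_background_ratio=cfg.background_intensity_ratio,
        )
    return segment_spectral(spectral, fixed_mask, cfg.k_fixed, cfg.seed)


def _prepare_moving(
    stained: RGBImage | IndexImage,
    cfg: RegistrationConfig,
    moving_mask,
    target_pixel_size: float | None,
) -> tuple[IndexImage, dict[str, Any]]:
    if isinstance(stained, IndexImage):
        return stained, {}
    he = stained
    if target_pixel_size is not None and not math.isclose(he.pixel_size, target_pixel_size):
        he = resize_to_resolution(he, target_pixel_size)
    bg = (
        np.asarray(cfg.background_color, dtype=np.float64)
        if cfg.background_color is not None
        else estimate_background_color(he, cfg.luminance_percentile)
    )
    corrected = correct_color_cast(he, bg, cfg.white_snap_distance)
    mask = moving_mask or he_background_mask(corrected)
    moving = segment_stained(corrected, mask, cfg.k_moving, cfg.seed)
    return moving, {"background_color": bg, "corrected": corrected}


def register(
    spectral: HyperspectralCube | IndexImage,
    stained: RGBImage | IndexImage,
    cfg: RegistrationConfig | None = None,
    fixed_mask=None,
    moving_mask=None,
    keep_trace: bool = False,
) -> tuple[RegistrationResult, dict[str, Any]]:
    """Run the full registration chain and return (result, artifacts).

    Artifacts carry the index images, the estimated per-parameter initial
    radii, the estimated background color (when computed), and the score at
    the recovered transform.
    """
    cfg = cfg or RegistrationConfig()
    fixed = _prepare_fixed(spectral, cfg, fixed_mask)
    if not fixed.foreground().any():
        raise DegenerateInputError("template has no foreground; cannot register")
    target_ps = fixed.pixel_size if isinstance(spectral, HyperspectralCube) else None
    moving, artifacts = _prepare_moving(stained, cfg, moving_mask, target_ps)
    bounds = cfg.bounds_for(moving.shape, fixed.shape)
    r0 = estimate_initial_radius(
        fixed, bounds, alpha=cfg.alpha, k0=cfg.k0, log_base=cfg.log_base
    )
    scorer = TransformScorer(fixed, moving, alpha=cfg.alpha, log_base=cfg.log_base)
    schedule = SearchSchedule(r0, k0=cfg.k0, delta_k=cfg.delta_k)
    result = sparse_search(scorer, bounds, schedule, fixed.shape, keep_trace=keep_trace)
    artifacts.update(
        {
            "fixed_index": fixed,
            "moving_index": moving,
            "r0": r0,
            "config": cfg,
            "n_score_evaluations": result.n_evaluations,
        }
    )
    return result, artifacts


def evaluate_registration(
    recovered: SimilarityTransform,
    truth: SimilarityTransform,
    template_shape: tuple[int, int],
) -> dict[str, float]:
    """Mean and max displacement (px) of the four template corners between
    the recovered and the true transform."""
    rows, cols = template_shape
    corners = np.array([[0, 0], [0, cols - 1], [rows - 1, 0], [rows - 1, cols - 1]], dtype=float)
    # the moving-image center offset cancels in the difference
    ref_shape = template_shape
    a = map_coordinates(recovered, template_shape, ref_shape, corners)
    b = map_coordinates(truth, template_shape, ref_shape, corners)
    d = np.linalg.norm(a - b, axis=-1)
    return {"mean_corner_error_px": float(d.mean()), "max_corner_error_px": float(d.max())}


_INDEX_COLORS = np.array(
    [
        (0, 0, 0),
        (230, 25, 75), (60, 180, 75), (255, 225, 25), (0, 130, 200),
        (245, 130, 48), (145, 30, 180), (70, 240, 240), (240, 50, 230),
        (210, 245, 60), (250, 190, 212), (0, 128, 128), (220, 190, 255),
        (170, 110, 40), (255, 250, 200), (128, 0, 0), (170, 255, 195),
    ],
    dtype=np.uint8,
)


def colorize_index(index: IndexImage) -> np.ndarray:
    """Render an index image with a categorical palette (0 = black)."""
    return _INDEX_COLORS[index.labels % len(_INDEX_COLORS)]


def render_overlay(
    moving_rgb: np.ndarray,
    transform: SimilarityTransform,
    template_shape: tuple[int, int],
    color: tuple[int, int, int] = (0, 0, 0),
    width: int = 2,
) -> Image.Image:
    """Draw the registered template outline onto the moving image."""
    moving_shape = moving_rgb.shape[:2]
    rows, cols = template_shape
    corners = np.array([[0, 0], [0, cols - 1], [rows - 1, cols - 1], [rows - 1, 0]], dtype=float)
    mapped = map_coordinates(transform, template_shape, moving_shape, corners)
    img = Image.fromarray(np.ascontiguousarray(moving_rgb), mode="RGB")
    draw = ImageDraw.Draw(img)
    pts = [(float(x), float(y)) for y, x in mapped]
    draw.polygon(pts, outline=tuple(color), width=width)
    return img


def write_outputs(
    out_dir: str | Path,
    result: RegistrationResult,
    artifacts: dict[str, Any],
) -> Path:
    """Persist a registration run: transform JSON, overlay PNG, index
    images, score trace CSV (if kept), and the config echo."""
    from . import io as sio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixed: IndexImage = artifacts["fixed_index"]
    moving: IndexImage = artifacts["moving_index"]
    (out / "transform.json").write_text(result.transform.to_json(fixed.shape, moving.shape))
    summary = {
        "score_bits": result.score,
        "n_evaluations": result.n_evaluations,
        "r0": artifacts.get("r0"),
        "level_stats": result.level_stats,
    }
    (out / "result.json").write_text(json.dumps(summary, indent=2))
    cfg: RegistrationConfig = artifacts["config"]
    cfg.to_yaml(out / "config.yaml")
    sio.write_index_image(out / "fixed_index.png", fixed)
    sio.write_index_image(out / "moving_index.png", moving)
    base = artifacts.get("corrected")
    base_rgb = base.values if base is not None else colorize_index(moving)
    render_overlay(base_rgb, result.transform, fixed.shape).save(out / "overlay.png")
    if result.trace is not None:
        names = [*map(str, range(len(result.trace[0]) - 2)), "score", "level"]
        lines = ["idx_" + ",idx_".join(names[:-2]) + ",score,level"]
        lines += [",".join(str(v) for v in row) for row in result.trace]
        (out / "score_trace.csv").write_text("\n".join(lines) + "\n")
    return out
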