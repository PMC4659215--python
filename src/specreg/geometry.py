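"""Similarity transforms, label resampling, and the transform score function.

The template (spectral ROI) is the fixed image; the whole-slide index image
moves.  A transform is parameterized as (tx, ty, theta, s): rotation by
theta degrees and isotropic scaling by s about the *template center*,
followed by translation of the template center by (tx, ty) relative to the
moving-image center.  With this parameterization the four axes act
approximately independently, which the per-parameter grid search exploits.

A template pixel x maps to the moving image as

    x' = s R(theta) (x - c_t) + c_m + (tx, ty)

in 0-based pixel-center coordinates (x = column, y = row, rows grow
downwards).  Labels are categorical, so resampling is nearest-neighbour
with half-up rounding; coordinates falling outside the moving image take
label 0 — off-slide means "no sample", and keeping every template pixel in
the joint table makes scores comparable across transforms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from ._kernels import HAVE_NUMBA, counts_numba, counts_numpy
from .metric import restricted_mi_from_counts
from .segmentation import IndexImage

__all__ = [
    "SimilarityTransform",
    "TransformBounds",
    "map_coordinates",
    "sample_moving",
    "score",
    "TransformScorer",
    "rotation_unit",
    "scale_unit",
]


@dataclass(frozen=True)
class SimilarityTransform:
    """(tx, ty, theta, s): translation in moving-image pixels, rotation in
    degrees about the template center, isotropic scale factor."""

    tx: float = 0.0
    ty: float = 0.0
    theta: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("scale must be positive")

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.tx, self.ty, self.theta, self.s)

    def matrix(
        self, template_shape: tuple[int, int], moving_shape: tuple[int, int]
    ) -> np.ndarray:
        """3x3 homogeneous matrix mapping template (x, y, 1) to moving (x', y', 1)."""
        ct_x, ct_y = _center(template_shape)
        cm_x, cm_y = _center(moving_shape)
        t = math.radians(self.theta)
        a = self.s * math.cos(t)
        b = self.s * math.sin(t)
        # x' = a (x - ctx) - b (y - cty) + cmx + tx
        return np.array(
            [
                [a, -b, -a * ct_x + b * ct_y + cm_x + self.tx],
                [b, a, -b * ct_x - a * ct_y + cm_y + self.ty],
                [0.0, 0.0, 1.0],
            ]
        )

    def to_json(
        self, template_shape: tuple[int, int], moving_shape: tuple[int, int]
    ) -> str:
        return json.dumps(
            {
                "tx": self.tx,
                "ty": self.ty,
                "theta_deg": self.theta,
                "scale": self.s,
                "matrix": self.matrix(template_shape, moving_shape).tolist(),
            },
            indent=2,
        )


@dataclass(frozen=True)
class TransformBounds:
    """Closed per-parameter search intervals; None disables a parameter.

    Default scale limits are [0.8, 1.2] when scale is enabled; default
    rotation limits are [-30, 30] for template matching and [-180, 180] for
    full-image registration.
    """

    tx: tuple[float, float]
    ty: tuple[float, float]
    theta: tuple[float, float] | None = None
    scale: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for name in ("tx", "ty", "theta", "scale"):
            iv = getattr(self, name)
            if iv is not None and iv[0] > iv[1]:
                raise ValueError(f"{name} bounds must satisfy lower <= upper")
        if self.scale is not None and self.scale[0] <= 0:
            raise ValueError("scale bounds must be positive")

    @classmethod
    def translation(cls, tx: tuple[float, float], ty: tuple[float, float]) -> "TransformBounds":
        return cls(tx=tx, ty=ty)

    @classmethod
    def rigid(
        cls,
        tx: tuple[float, float],
        ty: tuple[float, float],
        theta: tuple[float, float] = (-30.0, 30.0),
    ) -> "TransformBounds":
        return cls(tx=tx, ty=ty, theta=theta)

    @classmethod
    def similarity(
        cls,
        tx: tuple[float, float],
        ty: tuple[float, float],
        theta: tuple[float, float] = (-30.0, 30.0),
        scale: tuple[float, float] = (0.8, 1.2),
    ) -> "TransformBounds":
        return cls(tx=tx, ty=ty, theta=theta, scale=scale)


def _center(shape: tuple[int, int]) -> tuple[float, float]:
    rows, cols = shape
    return (cols - 1) / 2.0, (rows - 1) / 2.0


def max_radius(template_shape: tuple[int, int]) -> float:
    """Distance from the template center to its farthest pixel center."""
    cx, cy = _center(template_shape)
    return math.hypot(cx, cy)


def rotation_unit(template_shape: tuple[int, int]) -> float:
    """Rotation grid unit: the angle (degrees) that displaces the farthest
    template pixel by one pixel."""
    return math.degrees(1.0 / max(max_radius(template_shape), 1.0))


def scale_unit(template_shape: tuple[int, int]) -> float:
    """Scale grid unit: the scale change displacing the farthest pixel by 1 px."""
    return 1.0 / max(max_radius(template_shape), 1.0)


def map_coordinates(
    t: SimilarityTransform,
    template_shape: tuple[int, int],
    moving_shape: tuple[int, int],
    pixels: np.ndarray,
) -> np.ndarray:
    """Map template pixel (row, col) coordinates into the moving image.

    ``pixels`` is (..., 2) in (row, col) order; the result has the same
    shape and is in float (row, col) moving-image coordinates.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    ct_x, ct_y = _center(template_shape)
    cm_x, cm_y = _center(moving_shape)
    rel_x = pixels[..., 1] - ct_x
    rel_y = pixels[..., 0] - ct_y
    th = math.radians(t.theta)
    cos_t, sin_t = math.cos(th), math.sin(th)
    xs = t.s * (cos_t * rel_x - sin_t * rel_y) + cm_x + t.tx
    ys = t.s * (sin_t * rel_x + cos_t * rel_y) + cm_y + t.ty
    return np.stack([ys, xs], axis=-1)


def sample_moving(
    moving: IndexImage, t: SimilarityTransform, template_shape: tuple[int, int]
) -> IndexImage:
    """Resample the moving index image onto the template grid (nearest label).

    Half-up rounding (ties toward +inf) fixes the nearest pixel bit-exactly;
    coordinates outside the moving image yield background label 0.
    """
    rows, cols = template_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = map_coordinates(t, template_shape, moving.shape, np.stack([rr, cc], axis=-1))
    ir = np.floor(coords[..., 0] + 0.5).astype(np.int64)
    ic = np.floor(coords[..., 1] + 0.5).astype(np.int64)
    valid = (ir >= 0) & (ir < moving.shape[0]) & (ic >= 0) & (ic < moving.shape[1])
    labels = np.zeros(template_shape, dtype=np.int32)
    labels[valid] = moving.labels[ir[valid], ic[valid]]
    return IndexImage(labels, k=moving.k, modality=moving.modality, pixel_size=moving.pixel_size)


class TransformScorer:
    """Callable mapping a SimilarityTransform to its RMI score (bits).

    Precomputes template-relative coordinates and flattened label arrays so
    that repeated evaluations (the optimizer makes tens of thousands) cost a
    single pass over the template.  With ``counts_cache`` set to a dict, the
    integer joint tables are memoized by transform parameters, which lets
    several alpha values share one set of expensive table computations.
    """

    def __init__(
        self,
        fixed: IndexImage,
        moving: IndexImage,
        alpha: float = 0.25,
        log_base: float = 2.0,
        use_numba: bool = True,
        counts_cache: dict | None = None,
    ) -> None:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        self.fixed = fixed
        self.moving = moving
        self.alpha = alpha
        self.log_base = log_base
        self.use_numba = use_numba
        self.counts_cache = counts_cache
        if moving.k > 255:
            raise ValueError("moving image may carry at most 255 labels")
        self.use_numba = use_numba and HAVE_NUMBA
        rows, cols = fixed.shape
        ct_x, ct_y = _center(fixed.shape)
        rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
        self._rel_x = np.ascontiguousarray((cc - ct_x).ravel(), dtype=np.float64)
        self._rel_y = np.ascontiguousarray((rr - ct_y).ravel(), dtype=np.float64)
        self._fixed_base = np.ascontiguousarray(
            fixed.labels.ravel().astype(np.int64) * (moving.k + 1), dtype=np.int32
        )
        self._moving_flat = np.ascontiguousarray(moving.labels.ravel(), dtype=np.uint8)
        padded = np.zeros((moving.shape[0] + 2, moving.shape[1] + 2), dtype=np.uint8)
        padded[1:-1, 1:-1] = moving.labels
        self._padded_flat = np.ascontiguousarray(padded.ravel())
        self._idxbuf = np.zeros(rows * cols, dtype=np.int32)
        self._center_moving = _center(moving.shape)
        self._n_cells = (fixed.k + 1) * (moving.k + 1)
        self.n_evaluations = 0

    def counts(self, t: SimilarityTransform) -> np.ndarray:
        key = (t.tx, t.ty, t.theta, t.s)
        if self.counts_cache is not None and key in self.counts_cache:
            return self.counts_cache[key]
        if self.use_numba:
            flat = counts_numba(
                self._fixed_base, self._rel_x, self._rel_y, self._padded_flat,
                self.moving.shape, self._center_moving, key, self._n_cells, self._idxbuf,
            )
        else:
            flat = counts_numpy(
                self._fixed_base, self._rel_x, self._rel_y, self._moving_flat,
                self.moving.shape, self._center_moving, key, self._n_cells,
            )
        table = flat.reshape(self.fixed.k + 1, self.moving.k + 1)
        if self.counts_cache is not None:
            self.counts_cache[key] = table
        return table

    def __call__(self, t: SimilarityTransform) -> float:
        self.n_evaluations += 1
        if self.use_numba:
            from ._kernels import rmi_from_counts_fast

            return rmi_from_counts_fast(self.counts(t), self.alpha, self.log_base)
        return restricted_mi_from_counts(self.counts(t), self.alpha, self.log_base)


def score(
    fixed: IndexImage,
    moving: IndexImage,
    t: SimilarityTransform,
    alpha: float = 0.25,
    log_base: float = 2.0,
) -> float:
    """RMI score of the moving image against the template under transform t.

    Reference composition (resample, then histogram, then RMI); bit-identical
    to :class:`TransformScorer`, which is the fast path used by the optimizer.
    """
    from .metric import joint_histogram, restricted_mi

    sampled = sample_moving(moving, t, fixed.shape)
    return restricted_mi(joint_histogram(fixed, sampled, log_base=log_base), alpha)
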