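"""k-means presegmentation of both modalities into index-color images.

Registration does not operate on raw intensities but on *index-color*
images: each foreground pixel carries a categorical cluster label in 1..k,
label 0 is reserved for background.  The spectral image is clustered on its
per-pixel spectrum vectors, the stained image on its 3-D RGB vectors, both
with k-means++ seeding.  With k=1 the index image degenerates to the binary
foreground/background image used by the binary-metric variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .errors import DegenerateInputError
from .preprocess import ForegroundMask, HyperspectralCube, RGBImage

__all__ = ["IndexImage", "segment_spectral", "segment_stained"]

#: k-means settings: 5 k-means++ restarts, best inertia kept.
N_RESTARTS = 5
MAX_ITER = 300
TOL = 1e-4


@dataclass
class IndexImage:
    """2-D grid of integer cluster labels; 0 is background.

    The label grids of the fixed and moving images are the discrete random
    variables whose joint distribution the registration metric scores.
    """

    labels: np.ndarray
    k: int
    modality: str = "spectral"
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int32)
        if self.labels.ndim != 2:
            raise ValueError("label grid must be 2-D")
        if self.labels.min() < 0 or self.labels.max() > self.k:
            raise ValueError("labels must lie in [0, k]")
        if self.modality not in ("spectral", "stained"):
            raise ValueError("modality must be 'spectral' or 'stained'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def foreground(self) -> np.ndarray:
        return self.labels > 0


def _cluster(
    features: np.ndarray,
    mask: ForegroundMask,
    k: int,
    seed: int,
    shape: tuple[int, int],
) -> np.ndarray:
    """Shared k-means core: cluster foreground feature vectors into 1..k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    fg = mask.mask
    n_fg = int(fg.sum())
    labels = np.zeros(shape, dtype=np.int32)
    if n_fg == 0:
        warnings.warn("image is entirely background; index image is all zero", stacklevel=3)
        return labels
    if n_fg < k:
        raise DegenerateInputError(f"only {n_fg} foreground pixels for k={k} clusters")
    if k == 1:
        labels[fg] = 1
        return labels
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=N_RESTARTS,
        max_iter=MAX_ITER,
        tol=TOL,
        random_state=seed,
    )
    assignments = km.fit_predict(features[fg.ravel()])
    labels[fg] = assignments.astype(np.int32) + 1
    return labels


def segment_spectral(
    cube: HyperspectralCube, mask: ForegroundMask, k: int, seed: int
) -> IndexImage:
    """Cluster foreground spectra into k classes (Euclidean, k-means++).

    Spectra enter the clustering as-is, without per-spectrum normalization.
    """
    if mask.shape != cube.shape:
        raise ValueError("mask shape does not match cube shape")
    rows, cols = cube.shape
    features = cube.values.reshape(rows * cols, cube.n_bands)
    labels = _cluster(features, mask, k, seed, cube.shape)
    return IndexImage(labels, k=k, modality="spectral", pixel_size=cube.pixel_size)


def segment_stained(he: RGBImage, mask: ForegroundMask, k: int, seed: int) -> IndexImage:
    """Cluster foreground RGB vectors of a (cast-corrected) stained image."""
    if mask.shape != he.shape:
        raise ValueError("mask shape does not match image shape")
    rows, cols = he.shape
    features = he.values.reshape(rows * cols, 3).astype(np.float64)
    labels = _cluster(features, mask, k, seed, he.shape)
    return IndexImage(labels, k=k, modality="stained", pixel_size=he.pixel_size)
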