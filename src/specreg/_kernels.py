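"""Numba-accelerated inner loops for transform scoring.

The only hot operation in the whole pipeline is: map every template pixel
into the moving image under a similarity transform, look up the nearest
moving label (0 outside), and accumulate the joint label histogram.  The
work is split into three loops so LLVM can vectorize the coordinate
arithmetic: (1) transform + half-up rounding + clamp into a zero-padded
copy of the moving image (out-of-bounds reads land on the padding and thus
on background), (2) label gather, (3) four-way unrolled histogram.  The
result is the exact same integer table as the vectorized numpy path, so
the two are interchangeable; numba is used when available and falls back
to numpy otherwise.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - trivial import guard
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=False)
def _counts_kernel(
    fixed_base,
    rel_x,
    rel_y,
    padded_flat,
    mov_rows,
    mov_cols,
    cmx,
    cmy,
    tx,
    ty,
    cos_t,
    sin_t,
    scale,
    idxbuf,
    out,
):  # pragma: no cover - exercised via wrapper
    pcols = mov_cols + 2
    n = rel_x.shape[0]
    for i in range(n):
        xs = scale * (cos_t * rel_x[i] - sin_t * rel_y[i]) + cmx + tx
        ys = scale * (sin_t * rel_x[i] + cos_t * rel_y[i]) + cmy + ty
        ic = int(math.floor(xs + 0.5))
        ir = int(math.floor(ys + 0.5))
        ic = min(max(ic, -1), mov_cols)
        ir = min(max(ir, -1), mov_rows)
        idxbuf[i] = (ir + 1) * pcols + (ic + 1)
    for i in range(n):
        idxbuf[i] = fixed_base[i] + int(padded_flat[idxbuf[i]])
    h = np.zeros((4, out.shape[0]), dtype=np.int64)
    n4 = (n // 4) * 4
    for i in range(0, n4, 4):
        h[0, idxbuf[i]] += 1
        h[1, idxbuf[i + 1]] += 1
        h[2, idxbuf[i + 2]] += 1
        h[3, idxbuf[i + 3]] += 1
    for i in range(n4, n):
        h[0, idxbuf[i]] += 1
    for j in range(out.shape[0]):
        out[j] = h[0, j] + h[1, j] + h[2, j] + h[3, j]


@njit(cache=False)
def _rmi_kernel(counts, n_x, n_y, alpha, log_base):  # pragma: no cover - via wrapper
    m = 0
    for v in counts:
        m += v
    px = np.zeros(n_x)
    py = np.zeros(n_y)
    for i in range(n_x):
        for j in range(n_y):
            c = counts[i * n_y + j]
            px[i] += c
            py[j] += c
    inv = 1.0 / math.log(log_base)
    hx = 0.0
    for i in range(n_x):
        if px[i] > 0:
            p = px[i] / m
            hx -= p * math.log(p) * inv
    hy = 0.0
    for j in range(n_y):
        if py[j] > 0:
            p = py[j] / m
            hy -= p * math.log(p) * inv
    px0 = px[0] / m
    py0 = py[0] / m
    p00 = counts[0] / m
    pa00 = (1.0 - alpha) * p00 + alpha * (px0 + py0 - p00)
    ha = 0.0
    for i in range(n_x):
        for j in range(n_y):
            c = counts[i * n_y + j]
            if c == 0:
                continue
            p = c / m
            if i == 0 and j == 0:
                q = pa00
            elif i == 0 or j == 0:
                q = (1.0 - alpha) * p
            else:
                q = p
            if q <= 0.0:
                return -np.inf
            ha -= p * math.log(q) * inv
    return hx + hy - ha


def rmi_from_counts_fast(
    counts: np.ndarray, alpha: float, log_base: float = 2.0, use_numba: bool = True
) -> float:
    """Restricted MI straight from an integer joint table (jitted fast path).

    Same arithmetic as the reference numpy implementation; only the
    summation order differs, so results agree to float rounding."""
    if use_numba and HAVE_NUMBA:
        n_x, n_y = counts.shape
        return float(
            _rmi_kernel(np.ascontiguousarray(counts.ravel()), n_x, n_y, alpha, log_base)
        )
    from .metric import restricted_mi_from_counts

    return restricted_mi_from_counts(counts, alpha, log_base)


def counts_numpy(
    fixed_base: np.ndarray,
    rel_x: np.ndarray,
    rel_y: np.ndarray,
    moving_flat: np.ndarray,
    mov_shape: tuple[int, int],
    center_moving: tuple[float, float],
    params: tuple[float, float, float, float],
    n_cells: int,
) -> np.ndarray:
    """Reference numpy path for the joint table under a transform."""
    tx, ty, theta_deg, scale = params
    t = math.radians(theta_deg)
    cos_t, sin_t = math.cos(t), math.sin(t)
    mov_rows, mov_cols = mov_shape
    cmx, cmy = center_moving
    xs = scale * (cos_t * rel_x - sin_t * rel_y) + cmx + tx
    ys = scale * (sin_t * rel_x + cos_t * rel_y) + cmy + ty
    ic = np.floor(xs + 0.5).astype(np.int64)
    ir = np.floor(ys + 0.5).astype(np.int64)
    valid = (ir >= 0) & (ir < mov_rows) & (ic >= 0) & (ic < mov_cols)
    labels = np.zeros(fixed_base.shape[0], dtype=np.int64)
    labels[valid] = moving_flat[ir[valid] * mov_cols + ic[valid]]
    pair = fixed_base.astype(np.int64) + labels
    return np.bincount(pair, minlength=n_cells)


def counts_numba(
    fixed_base: np.ndarray,
    rel_x: np.ndarray,
    rel_y: np.ndarray,
    padded_flat: np.ndarray,
    mov_shape: tuple[int, int],
    center_moving: tuple[float, float],
    params: tuple[float, float, float, float],
    n_cells: int,
    idxbuf: np.ndarray,
) -> np.ndarray:
    """Jitted path; ``padded_flat`` is the moving label image with a one-pixel
    zero border, ``idxbuf`` a reusable int32 scratch array of template size."""
    tx, ty, theta_deg, scale = params
    t = math.radians(theta_deg)
    out = np.zeros(n_cells, dtype=np.int64)
    _counts_kernel(
        fixed_base,
        rel_x,
        rel_y,
        padded_flat,
        mov_shape[0],
        mov_shape[1],
        center_moving[0],
        center_moving[1],
        tx,
        ty,
        math.cos(t),
        math.sin(t),
        scale,
        idxbuf,
        out,
    )
    return out
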