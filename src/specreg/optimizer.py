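"""Sparse coarse-to-fine search over transformation space.

Exhaustive evaluation of the score over all candidate transforms is
prohibitively slow for whole-slide template matching, so the search space
(not the image) is decomposed into a hierarchy of equidistant grids.  The
coarsest grid has per-parameter spacing r0; each level halves the spacing,
re-evaluates only grid points near high-scoring points of the previous
level, and lowers the retention threshold nu_thresh = k0 * delta_k**level
(a fraction of the running score range).  The procedure stops once every
enabled parameter has been refined at its finest spacing: one pixel for
translations and, for rotation/scale, the grid unit that displaces the
farthest template pixel by one pixel.

The initial radius r0 is not a user parameter: it is estimated per
parameter by *self-registration* — sweeping the template against itself
along that axis alone and measuring how far the score stays above k0 times
the peak (the score at the neutral transform).
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, SearchFailureError
from .geometry import (
    SimilarityTransform,
    TransformBounds,
    TransformScorer,
    rotation_unit,
    scale_unit,
)
from .segmentation import IndexImage

__all__ = [
    "ParameterGrid",
    "SearchSchedule",
    "RegistrationResult",
    "make_grid",
    "estimate_initial_radius",
    "sparse_search",
    "exhaustive_search",
]

PARAM_ORDER = ("tx", "ty", "theta", "scale")


@dataclass(frozen=True)
class ParameterGrid:
    """Integer-index view of the enabled transform parameters.

    Index j along a parameter corresponds to the value ``j * unit`` (for
    scale: ``1 + j * unit``), so index 0 is always the neutral transform.
    """

    params: tuple[str, ...]
    units: tuple[float, ...]
    lo: tuple[int, ...]
    hi: tuple[int, ...]

    def transform(self, idx: tuple[int, ...]) -> SimilarityTransform:
        values = {"tx": 0.0, "ty": 0.0, "theta": 0.0, "s": 1.0}
        for name, unit, j in zip(self.params, self.units, idx):
            if name == "scale":
                values["s"] = 1.0 + j * unit
            else:
                values[name] = j * unit
        return SimilarityTransform(**values)

    @property
    def n_points(self) -> int:
        n = 1
        for lo, hi in zip(self.lo, self.hi):
            n *= hi - lo + 1
        return n


def make_grid(
    bounds: TransformBounds, template_shape: tuple[int, int] | None = None
) -> ParameterGrid:
    """Discretize the enabled parameters of ``bounds`` into unit grids."""
    params: list[str] = []
    units: list[float] = []
    los: list[int] = []
    his: list[int] = []
    for name in PARAM_ORDER:
        interval = getattr(bounds, name)
        if interval is None:
            continue
        if name in ("theta", "scale"):
            if template_shape is None:
                raise ValueError(f"template_shape required to discretize '{name}'")
            unit = rotation_unit(template_shape) if name == "theta" else scale_unit(template_shape)
            offset = 1.0 if name == "scale" else 0.0
        else:
            unit, offset = 1.0, 0.0
        lo = math.ceil((interval[0] - offset) / unit - 1e-12)
        hi = math.floor((interval[1] - offset) / unit + 1e-12)
        if lo > hi:  # interval narrower than one grid unit
            lo = hi = round(((interval[0] + interval[1]) / 2 - offset) / unit)
        params.append(name)
        units.append(unit)
        los.append(lo)
        his.append(hi)
    return ParameterGrid(tuple(params), tuple(units), tuple(los), tuple(his))


@dataclass
class SearchSchedule:
    """Per-parameter initial grid radii and the threshold decay schedule.

    ``max_retained`` caps how many points may seed the next refinement
    level; when the fractional threshold alone would keep more, only the
    highest-scoring ones are kept (the running best always survives).  This
    bounds the work per level on landscapes with broad score skirts without
    affecting unimodal basins, which are far smaller than the cap.
    """

    r0: Mapping[str, int]
    k0: float = 0.6
    delta_k: float = 0.5
    max_retained: int = 512

    def __post_init__(self) -> None:
        if not 0.0 < self.k0 <= 1.0:
            raise ValueError("k0 must lie in (0, 1]")
        if not 0.0 < self.delta_k <= 1.0:
            raise ValueError("delta_k must lie in (0, 1]")
        if self.max_retained < 1:
            raise ValueError("max_retained must be >= 1")
        for name, r in self.r0.items():
            if r < 1:
                raise ValueError(f"r0[{name!r}] must be >= 1 grid unit")

    def nu_thresh(self, level: int) -> float:
        """Retention threshold at a level: k0 * delta_k**level."""
        return self.k0 * self.delta_k**level


@dataclass
class RegistrationResult:
    """Outcome of a transform search."""

    transform: SimilarityTransform
    score: float
    n_evaluations: int
    level_stats: list[dict] = field(default_factory=list)
    trace: list[tuple] | None = None


def radius_from_profile(
    profile: np.ndarray, s0: float, k0: float, structure_frac: float = 0.1
) -> int:
    """Peak half-width of a 1-D self-registration score profile.

    ``profile[d-1]`` is the score at displacement d = 1..D, ``s0`` the score
    at the neutral transform.  Two features of such profiles matter:

    * the exact-overlap score s0 carries a one-unit "spike" from pixel-level
      texture and noise matching itself, which the cross-modality landscape
      around the true optimum does not share — the structural peak height is
      therefore the first off-peak score s(1);
    * far from the peak the score settles on a nonzero pedestal (residual
      self-similarity of tissue texture plus estimation bias), so widths are
      measured above the profile minimum, not above zero.

    The half-width is the largest contiguous d with

        s(d) >= bg + k0 * (s(1) - bg),        bg = min(profile).

    If the off-peak profile carries no structure (s(1) - bg below
    ``structure_frac`` of s0 - bg, as for pure speckle, which decorrelates
    completely after one unit) the basin is a single grid unit.
    """
    if len(profile) == 0:
        return 1
    profile = np.asarray(profile, dtype=float)
    bg = float(profile.min())
    ref = float(profile[0])
    if s0 <= bg or (ref - bg) <= structure_frac * (s0 - bg):
        return 1
    cut = bg + k0 * (ref - bg)
    run = 0
    for d, s in enumerate(profile, start=1):
        if s >= cut:
            run = d
        else:
            break
    return max(1, run)


def estimate_initial_radius(
    template: IndexImage,
    bounds: TransformBounds,
    alpha: float = 0.25,
    k0: float = 0.6,
    log_base: float = 2.0,
    use_numba: bool = True,
    structure_frac: float = 0.1,
) -> dict[str, int]:
    """Estimate per-parameter initial grid radii by self-registration.

    The template is registered against itself along each enabled parameter
    in turn (all others neutral), sweeping the parameter over its bounds in
    both directions; the half-width of the resulting score peak (see
    :func:`radius_from_profile`) is the initial grid radius, taking the
    wider of the two directions and clamping to at least one grid unit.
    """
    grid = make_grid(bounds, template.shape)
    scorer = TransformScorer(template, template, alpha=alpha, log_base=log_base, use_numba=use_numba)
    s0 = scorer(SimilarityTransform())
    if not s0 > 0:
        raise DegenerateInputError("degenerate template: self-score at identity is not positive")
    r0: dict[str, int] = {}
    for i, name in enumerate(grid.params):
        width = 1
        for direction in (1, -1):
            limit = grid.hi[i] if direction > 0 else -grid.lo[i]
            profile = []
            for d in range(1, max(limit, 0) + 1):
                idx = [0] * len(grid.params)
                idx[i] = direction * d
                profile.append(scorer(grid.transform(tuple(idx))))
            width = max(width, radius_from_profile(profile, s0, k0, structure_frac))
        r0[name] = width
    return r0


def _axis_points(lo: int, hi: int, spacing: int) -> range:
    """Multiples of ``spacing`` (anchored at index 0) within [lo, hi]."""
    start = -(-lo // spacing)
    stop = hi // spacing
    return range(start * spacing, stop * spacing + 1, spacing)


def sparse_search(
    score_fn,
    bounds: TransformBounds,
    schedule: SearchSchedule,
    template_shape: tuple[int, int] | None = None,
    keep_trace: bool = False,
) -> RegistrationResult:
    """Coarse-to-fine sparse grid search for the score maximum.

    Level 0 evaluates the full grid at spacing r0.  Each later level halves
    the spacing (to no less than one unit), evaluates all grid points within
    one previous-level spacing (per dimension) of any retained point, and
    retains the candidates whose score clears the fractional threshold
    ``nu_thresh(level)``.  The threshold is applied to scores normalized
    against the running *median* of all evaluated scores (a robust estimate
    of the background score level, which for mutual-information landscapes
    sits well above the minimum): a candidate is retained when

        score - median >= nu_thresh * (running max - median).

    The running best point is always retained, so the retained set is never
    empty, and no point is ever evaluated twice.
    """
    grid = make_grid(bounds, template_shape)
    ndim = len(grid.params)
    r = np.array([max(1, int(schedule.r0.get(p, 1))) for p in grid.params], dtype=np.int64)
    cache: dict[tuple[int, ...], float] = {}
    trace: list[tuple] | None = [] if keep_trace else None
    level_stats: list[dict] = []
    best_idx: tuple[int, ...] | None = None
    best_score = -math.inf
    level = 0

    def evaluate(idx: tuple[int, ...]) -> float:
        nonlocal best_idx, best_score
        s = score_fn(grid.transform(idx))
        cache[idx] = s
        if trace is not None:
            trace.append((*idx, s, level))
        if s > best_score or (s == best_score and (best_idx is None or idx < best_idx)):
            best_score, best_idx = s, idx
        return s

    def retain(candidates: list[tuple[int, ...]], nu: float) -> set[tuple[int, ...]]:
        finite = np.array([s for s in cache.values() if math.isfinite(s)])
        smax = best_score
        if finite.size == 0 or not math.isfinite(smax):
            kept = set()
        else:
            background = float(np.median(finite))
            if smax > background:
                cut = background + nu * (smax - background)
                kept = {idx for idx in candidates if cache[idx] >= cut}
            else:
                kept = set()
        if len(kept) > schedule.max_retained:
            ranked = sorted(kept, key=lambda idx: (-cache[idx], idx))
            kept = set(ranked[: schedule.max_retained])
        kept.add(best_idx)
        return kept

    candidates = sorted(
        itertools.product(*(_axis_points(grid.lo[i], grid.hi[i], int(r[i])) for i in range(ndim)))
    )
    for idx in candidates:
        evaluate(idx)
    retained = retain(candidates, schedule.nu_thresh(level))
    level_stats.append(
        {
            "level": level,
            "spacing": r.tolist(),
            "nu_thresh": schedule.nu_thresh(level),
            "n_candidates": len(candidates),
            "n_new_evaluations": len(cache),
            "n_retained": len(retained),
            "best_score": best_score,
        }
    )

    while np.any(r > 1):
        prev_r = r.copy()
        r = np.maximum(1, r // 2)
        level += 1
        nu = schedule.nu_thresh(level)
        seen_before = len(cache)
        cand_set: set[tuple[int, ...]] = set()
        for q in retained:
            axes = []
            for i in range(ndim):
                lo = max(grid.lo[i], q[i] - int(prev_r[i]))
                hi = min(grid.hi[i], q[i] + int(prev_r[i]))
                axes.append(_axis_points(lo, hi, int(r[i])))
            cand_set.update(itertools.product(*axes))
        candidates = sorted(cand_set)
        for idx in candidates:
            if idx not in cache:
                evaluate(idx)
        retained = retain(candidates, nu)
        level_stats.append(
            {
                "level": level,
                "spacing": r.tolist(),
                "nu_thresh": nu,
                "n_candidates": len(candidates),
                "n_new_evaluations": len(cache) - seen_before,
                "n_retained": len(retained),
                "best_score": best_score,
            }
        )

    if best_idx is None:
        raise SearchFailureError("search evaluated no points")
    return RegistrationResult(
        transform=grid.transform(best_idx),
        score=best_score,
        n_evaluations=len(cache),
        level_stats=level_stats,
        trace=trace,
    )


def exhaustive_search(
    score_fn,
    bounds: TransformBounds,
    step: Mapping[str, int] | int = 1,
    template_shape: tuple[int, int] | None = None,
    max_points: int = 2_000_000,
    keep_trace: bool = False,
) -> RegistrationResult:
    """Evaluate every grid point; ties broken by lexicographic parameter order.

    Serves as the search oracle in tests and as a fallback for tiny search
    spaces; refuses grids larger than ``max_points``.
    """
    grid = make_grid(bounds, template_shape)
    if isinstance(step, int):
        step = {p: step for p in grid.params}
    axes = [
        _axis_points(grid.lo[i], grid.hi[i], max(1, int(step.get(p, 1))))
        for i, p in enumerate(grid.params)
    ]
    total = int(np.prod([len(a) for a in axes]))
    if total > max_points:
        raise SearchFailureError(f"grid of {total} points exceeds cap; use sparse search")
    best_idx = None
    best_score = -math.inf
    trace: list[tuple] | None = [] if keep_trace else None
    for idx in itertools.product(*axes):
        s = score_fn(grid.transform(idx))
        if trace is not None:
            trace.append((*idx, s, 0))
        if s > best_score:
            best_score, best_idx = s, idx
    if best_idx is None:
        raise SearchFailureError("empty search grid")
    return RegistrationResult(
        transform=grid.transform(best_idx),
        score=best_score,
        n_evaluations=total,
        level_stats=[{"level": 0, "n_new_evaluations": total}],
        trace=trace,
    )
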