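"""Constrained boundary growth and cubic-polynomial fitting.

From the seed point the boundary is grown downward: at each step the
``W_band`` candidate pixels ``K_step`` rows below the current point are
scored on the enhanced image and the maximum wins.  Most candidates sit at
or left of the current column because the muscle narrows from top to
bottom; a single rightward candidate allows slight drift.  Growth stops
when the boundary comes within ``stop_margin`` columns of the left image
edge.  The grown points are then least-squares fitted with a cubic
polynomial (column as a function of row) and sampled at every row to give
the final boundary, which is rasterized into a region mask using the
half-open convention "muscle = columns strictly left of the boundary".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import PectoralRegion

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GrowthParams:
    """Growth-mask geometry.

    ``K_step``: row interval between successive seed points (larger steps
    smooth over noise and glandular clutter).  ``W_band``: number of
    candidate columns per step.  ``left_bias``: how many of the candidates
    sit at or left of the current column.  ``stop_margin``: growth stops
    once the boundary reaches within this many columns of the left edge.
    """

    K_step: int = 2
    W_band: int = 6
    left_bias: int = 5
    stop_margin: int = 5

    def __post_init__(self) -> None:
        if self.K_step < 1:
            raise ValueError("K_step must be >= 1")
        if self.W_band < 1:
            raise ValueError("W_band must be >= 1")
        if not 1 <= self.left_bias <= self.W_band:
            raise ValueError("left_bias must be in [1, W_band]")
        if self.stop_margin < 0:
            raise ValueError("stop_margin must be >= 0")


@dataclass(frozen=True)
class BoundaryPolyline:
    """Final boundary: one (row, column) sample per row, rows strictly
    increasing."""

    points: tuple[tuple[int, int], ...]
    source_shape: tuple[int, int]

    def __post_init__(self) -> None:
        pts = tuple((int(r), int(c)) for r, c in self.points)
        rows = [r for r, _ in pts]
        if any(b <= a for a, b in zip(rows, rows[1:])):
            raise ValueError("polyline rows must be strictly increasing")
        n_cols = self.source_shape[1]
        if any(not 0 <= c < n_cols for _, c in pts):
            raise ValueError("polyline columns must lie inside the image")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float).reshape(-1, 2)

    def column_at(self) -> dict[int, int]:
        return {r: c for r, c in self.points}


def candidate_offsets(params: GrowthParams) -> list[tuple[int, int]]:
    """The ``W_band`` (row, column) offsets scored at each growth step.

    All candidates lie ``K_step`` rows down; their column offsets are the
    contiguous run from ``-(left_bias - 1)`` to ``+(W_band - left_bias)``
    (defaults: -4 .. +1).
    """
    lo = -(params.left_bias - 1)
    hi = params.W_band - params.left_bias
    return [(params.K_step, dc) for dc in range(lo, hi + 1)]


def grow_boundary(
    enhanced: np.ndarray,
    seed: tuple[int, int],
    params: GrowthParams = GrowthParams(),
) -> list[tuple[int, int]]:
    """Grow seed points down the enhanced image from the initial seed.

    Returns the ordered list of seed points (first element is the input
    seed).  At each step the in-bounds candidate with the maximum enhanced
    value wins; ties go to the leftmost candidate, consistent with the
    muscle narrowing leftward.  Growth stops when the current column is
    within ``stop_margin`` of the left edge or no candidate remains in
    bounds.
    """
    enhanced = np.asarray(enhanced)
    n_rows, n_cols = enhanced.shape
    r, c = int(seed[0]), int(seed[1])
    if not (0 <= r < n_rows and 0 <= c < n_cols):
        raise ValueError(f"seed {seed} outside image of shape {enhanced.shape}")
    offsets = candidate_offsets(params)
    points = [(r, c)]
    while c > params.stop_margin:
        candidates = [
            (r + dr, c + dc)
            for dr, dc in offsets
            if 0 <= r + dr < n_rows and 0 <= c + dc < n_cols
        ]
        if not candidates:
            break
        # arg-max with leftmost tie-break: candidates are already ordered
        # left-to-right, and ">" keeps the first maximum
        best = candidates[0]
        best_val = enhanced[best]
        for cand in candidates[1:]:
            val = enhanced[cand]
            if val > best_val:
                best, best_val = cand, val
        points.append(best)
        r, c = best
    return points


def fit_cubic(
    points: list[tuple[int, int]],
    shape: tuple[int, int],
) -> BoundaryPolyline:
    """Least-squares cubic fit of column against row over the grown points,
    sampled at every integer row.

    Sampling starts at the first grown row and stops at the row where the
    polynomial first reaches column 0 (or the image bottom).  Columns are
    rounded to the nearest integer and clamped to the image width.  With
    fewer than four points the degree is reduced to ``len(points) - 1``.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit a boundary")
    n_rows, n_cols = shape
    rows = np.array([p[0] for p in points], dtype=float)
    cols = np.array([p[1] for p in points], dtype=float)
    degree = min(3, len(points) - 1)
    degree = min(degree, len(np.unique(rows)) - 1)
    if degree < 3:
        logger.info("only %d points; fitting degree-%d polynomial", len(points), degree)
    poly = np.polynomial.Polynomial.fit(rows, cols, deg=degree)
    sampled: list[tuple[int, int]] = []
    for r in range(int(rows[0]), n_rows):
        col = float(poly(float(r)))
        col_px = int(np.clip(np.rint(col), 0, n_cols - 1))
        sampled.append((r, col_px))
        if col_px == 0:
            break
    return BoundaryPolyline(points=tuple(sampled), source_shape=(n_rows, n_cols))


def boundary_to_region(
    boundary: BoundaryPolyline | None,
    shape: tuple[int, int],
) -> PectoralRegion:
    """Rasterize a boundary polyline into a pectoral region mask.

    For every polyline row, pixels with column strictly less than the
    boundary column are muscle (the boundary pixel itself belongs to the
    breast side).  Rows above the first polyline row reuse the first row's
    column; rows below the last polyline row are all breast.
    """
    n_rows, n_cols = shape
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    if boundary is None or len(boundary) == 0:
        return PectoralRegion(mask)
    col_of = boundary.column_at()
    first_row = boundary.points[0][0]
    first_col = boundary.points[0][1]
    for r in range(0, first_row):
        mask[r, : np.clip(first_col, 0, n_cols)] = True
    for r, c in boundary.points:
        if 0 <= r < n_rows:
            mask[r, : np.clip(c, 0, n_cols)] = True
    return PectoralRegion(mask)
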