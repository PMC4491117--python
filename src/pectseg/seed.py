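"""Seed-point selection on the top sub-image of the enhanced mammogram.

The search runs in five steps: (1) restrict to the top ``P`` rows of the
enhanced image, where glandular tissue rarely intrudes; (2) per row, keep
the ``Q`` largest enhanced values; (3) extract edges from the binary result
with a morphological gradient and label 8-connected components; (4) select
the initial boundary component by a cascade of rules — slanted orientation,
largest pixel count, highest mean source intensity, and finally the
rightmost edge (multi-layer muscles expose several nested edges, of which
the outermost/rightmost is the anatomical boundary); (5) the top-right
pixel of the chosen component is the seed point for boundary growth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)


class NoBoundaryError(RuntimeError):
    """Raised when no edge component qualifies as an initial boundary."""


@dataclass(frozen=True)
class SeedParams:
    """Sub-image height ``P`` (rows) and per-row survivor count ``Q``."""

    P: int = 100
    Q: int = 12
    # selection-cascade tolerances (the rules need a notion of "almost the
    # same" pixel count and "similar" intensity; both are relative)
    min_angle_deg: float = 15.0
    max_angle_deg: float = 90.0
    count_tol: float = 0.10
    intensity_tol: float = 0.05
    min_component_px: int = 3

    def __post_init__(self) -> None:
        if self.P < 1 or self.Q < 1:
            raise ValueError("P and Q must be positive")


@dataclass(frozen=True)
class EdgeComponent:
    """One connected edge component of the thresholded sub-image."""

    pixels: tuple[tuple[int, int], ...]
    mean_source_intensity: float
    orientation_deg: float  # principal-axis angle from horizontal, [0, 180)
    row_col_cov: float  # covariance of (row, col); <= 0 means down-left slope

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)

    @property
    def mean_column(self) -> float:
        return float(np.mean([c for _, c in self.pixels]))


def extract_subimage(enhanced: np.ndarray, P: int) -> np.ndarray:
    """Top ``P`` rows of the enhanced image (clamped with a warning)."""
    enhanced = np.asarray(enhanced)
    if P > enhanced.shape[0]:
        logger.warning(
            "P=%d exceeds image height %d; clamping", P, enhanced.shape[0]
        )
        P = enhanced.shape[0]
    return enhanced[:P, :]


def threshold_top_q(sub: np.ndarray, Q: int) -> np.ndarray:
    """Binary grid keeping exactly the ``Q`` largest values per row.

    Ties at the cutoff are broken leftmost-first so exactly
    ``min(Q, n_cols)`` pixels survive in every row.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    sub = np.asarray(sub)
    n_rows, n_cols = sub.shape
    q = min(Q, n_cols)
    out = np.zeros_like(sub, dtype=bool)
    cols = np.arange(n_cols)
    for r in range(n_rows):
        # sort by descending value, ascending column for ties
        order = np.lexsort((cols, -sub[r]))
        out[r, order[:q]] = True
    return out


def detect_edges(
    binary: np.ndarray,
    source: np.ndarray | None = None,
    min_component_px: int = 3,
) -> list[EdgeComponent]:
    """Morphological-gradient edges of a binary grid, as 8-connected
    components.

    The gradient (binary minus its erosion, 3x3 structuring element) traces
    the one-pixel outline of each thresholded blob.  Components smaller
    than ``min_component_px`` pixels are discarded as speckle.  Mean
    intensities are measured on ``source`` (the original image, cropped to
    the sub-image) because the muscle's high gray level is a property of
    the source, not of the enhancement.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.size == 0 or not binary.any():
        return []
    struct3 = np.ones((3, 3), dtype=bool)
    eroded = ndimage.binary_erosion(binary, structure=struct3)
    edges = binary & ~eroded
    labels, n = ndimage.label(edges, structure=struct3)  # 8-connectivity
    if source is None:
        source = np.zeros_like(binary, dtype=float)
    source = np.asarray(source, dtype=float)[: binary.shape[0], : binary.shape[1]]
    components: list[EdgeComponent] = []
    for idx in range(1, n + 1):
        rows, cols = np.nonzero(labels == idx)
        if rows.size < min_component_px:
            continue
        components.append(_make_component(rows, cols, source))
    return components


def _make_component(rows: np.ndarray, cols: np.ndarray, source: np.ndarray) -> EdgeComponent:
    mean_intensity = float(source[rows, cols].mean())
    orientation, cov_rc = _principal_orientation(rows, cols)
    return EdgeComponent(
        pixels=tuple(zip(rows.tolist(), cols.tolist())),
        mean_source_intensity=mean_intensity,
        orientation_deg=orientation,
        row_col_cov=cov_rc,
    )


def _principal_orientation(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Principal-axis angle from the horizontal, in [0, 180).

    Measured in image coordinates (columns rightward, rows downward): 0 is
    horizontal, 90 vertical.  Also returns the (row, col) covariance, whose
    sign distinguishes down-right (positive) from down-left (negative)
    slopes.
    """
    r = rows.astype(float) - rows.mean()
    c = cols.astype(float) - cols.mean()
    mu_rr = float((r * r).mean())
    mu_cc = float((c * c).mean())
    mu_rc = float((r * c).mean())
    # principal axis of the scatter in (col, row) coordinates
    theta = 0.5 * math.atan2(2.0 * mu_rc, mu_cc - mu_rr)
    angle = math.degrees(theta) % 180.0
    return angle, mu_rc


def _folded_angle(orientation_deg: float) -> float:
    """Unsigned angle between the principal axis and the horizontal, [0, 90]."""
    return min(orientation_deg % 180.0, 180.0 - (orientation_deg % 180.0))


def select_initial_boundary(
    edges: list[EdgeComponent],
    source: np.ndarray | None = None,
    params: SeedParams = SeedParams(),
    with_rule: bool = False,
):
    """Pick the edge component that is the initial pectoral boundary.

    Cascade: (a) keep components slanted strictly between ``min_angle_deg``
    and ``max_angle_deg`` from horizontal whose column weakly decreases with
    row; (b) take the largest pixel count; (c) if runners-up are within
    ``count_tol`` of the largest, prefer the highest mean source intensity;
    (d) if those are within ``intensity_tol`` of each other the muscle is
    treated as multi-layer and the rightmost edge (largest mean column)
    wins.  The rule that decided the selection is logged; pass
    ``with_rule=True`` to also get it back as a string.
    """
    if not edges:
        raise NoBoundaryError("no edge components to select from")
    eps = 1e-9
    slanted = [
        e
        for e in edges
        if params.min_angle_deg < _folded_angle(e.orientation_deg) < params.max_angle_deg
        and e.row_col_cov <= eps
    ]
    if not slanted:
        raise NoBoundaryError(
            "no edge component slanted like a pectoral boundary was found"
        )
    if len(slanted) == 1:
        chosen, rule = slanted[0], "angle-filter"
    else:
        max_count = max(e.pixel_count for e in slanted)
        near = [e for e in slanted if e.pixel_count >= (1 - params.count_tol) * max_count]
        if len(near) == 1:
            chosen, rule = near[0], "pixel-count"
        else:
            max_int = max(e.mean_source_intensity for e in near)
            bright = [
                e
                for e in near
                if e.mean_source_intensity >= (1 - params.intensity_tol) * max_int
            ]
            if len(bright) == 1:
                chosen, rule = bright[0], "mean-intensity"
            else:
                chosen = max(bright, key=lambda e: e.mean_column)
                rule = "rightmost-multilayer"
    logger.info(
        "initial boundary selected by rule '%s' (%d candidates, %d px, "
        "mean intensity %.1f, angle %.1f deg)",
        rule,
        len(slanted),
        chosen.pixel_count,
        chosen.mean_source_intensity,
        chosen.orientation_deg,
    )
    return (chosen, rule) if with_rule else chosen


def find_seed_point(boundary: EdgeComponent) -> tuple[int, int]:
    """Top-right pixel of the initial boundary: minimum row, then maximum
    column within that row."""
    if boundary.pixel_count == 0:
        raise ValueError("empty boundary component")
    min_row = min(r for r, _ in boundary.pixels)
    max_col = max(c for r, c in boundary.pixels if r == min_row)
    return (min_row, max_col)
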