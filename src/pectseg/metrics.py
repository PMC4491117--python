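"""Region-overlap rates and Hausdorff distance for segmentation evaluation.

With D the detected pectoral region and R the ground truth (pixel sets of
equal-shaped masks):

    FP rate    = (|D u R| - |R|) / |R| * 100   (detected but not true)
    FN rate    = (|D u R| - |D|) / |R| * 100   (true but not detected)
    total rate = (2|D u R| - |D| - |R|) / |R| * 100  ( = FP + FN exactly)

The Hausdorff distance compares boundary *point sets* A, B:

    H(A, B) = max( max_a min_b ||a - b||,  max_b min_a ||a - b|| )

reported in pixels, or in millimetres when a pixel spacing is given.
Undefined metrics (empty ground truth or empty point sets) raise rather
than return sentinels, so broken ground truth surfaces in batch runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

from .image_io import PectoralRegion


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator or point set is empty."""


@dataclass(frozen=True)
class EvaluationReport:
    """Overlap rates (percent) and Hausdorff distance for one image."""

    fp_rate_pct: float
    fn_rate_pct: float
    total_mismatch_pct: float
    hausdorff: float
    hausdorff_unit: str  # "pixels" or "mm"
    n_detected: int
    n_truth: int


def _counts(detected: PectoralRegion, truth: PectoralRegion) -> tuple[int, int, int]:
    if detected.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: detected {detected.shape} vs truth {truth.shape}"
        )
    n_r = truth.pixel_count
    if n_r == 0:
        raise UndefinedMetricError("ground-truth region is empty")
    n_d = detected.pixel_count
    n_union = int((detected.mask | truth.mask).sum())
    return n_d, n_r, n_union


def fp_rate(detected: PectoralRegion, truth: PectoralRegion) -> float:
    """False-positive pixel rate in percent of the truth size."""
    n_d, n_r, n_union = _counts(detected, truth)
    return (n_union - n_r) / n_r * 100.0


def fn_rate(detected: PectoralRegion, truth: PectoralRegion) -> float:
    """False-negative pixel rate in percent of the truth size."""
    n_d, n_r, n_union = _counts(detected, truth)
    return (n_union - n_d) / n_r * 100.0


def total_mismatch(detected: PectoralRegion, truth: PectoralRegion) -> float:
    """Total mismatched pixel rate: FP rate + FN rate, in percent."""
    n_d, n_r, n_union = _counts(detected, truth)
    return (2 * n_union - (n_d + n_r)) / n_r * 100.0


def hausdorff(
    a_points,
    b_points,
    spacing_mm: float | None = None,
) -> float:
    """Symmetric Hausdorff distance between two (row, column) point sets.

    Returned in pixel units, or multiplied by ``spacing_mm`` when given.
    """
    a = np.asarray(a_points, dtype=float).reshape(-1, 2)
    b = np.asarray(b_points, dtype=float).reshape(-1, 2)
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise UndefinedMetricError("Hausdorff distance needs non-empty point sets")
    d = max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])
    if spacing_mm is not None:
        d *= spacing_mm
    return float(d)


def region_boundary_points(region: PectoralRegion) -> np.ndarray:
    """Boundary pixels of a region mask: mask minus its 3x3 erosion.

    Used to compare region masks with the Hausdorff distance, which is
    defined over boundary point sets.
    """
    mask = region.mask
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool))
    rows, cols = np.nonzero(mask & ~eroded)
    return np.stack([rows, cols], axis=1)


def evaluate_regions(
    detected: PectoralRegion,
    truth: PectoralRegion,
    spacing_mm: float | None = None,
    detected_boundary=None,
    truth_boundary=None,
) -> EvaluationReport:
    """Full evaluation of one detection: overlap rates plus Hausdorff.

    Boundary point sets may be supplied directly (e.g. the detected
    polyline and the phantom truth polyline); otherwise they are derived
    from the region masks.
    """
    fp = fp_rate(detected, truth)
    fn = fn_rate(detected, truth)
    total = total_mismatch(detected, truth)
    a = (
        np.asarray(detected_boundary, dtype=float).reshape(-1, 2)
        if detected_boundary is not None
        else region_boundary_points(detected)
    )
    b = (
        np.asarray(truth_boundary, dtype=float).reshape(-1, 2)
        if truth_boundary is not None
        else region_boundary_points(truth)
    )
    h = hausdorff(a, b, spacing_mm)
    return EvaluationReport(
        fp_rate_pct=fp,
        fn_rate_pct=fn,
        total_mismatch_pct=total,
        hausdorff=h,
        hausdorff_unit="mm" if spacing_mm is not None else "pixels",
        n_detected=detected.pixel_count,
        n_truth=truth.pixel_count,
    )
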