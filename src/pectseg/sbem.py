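"""Shape-based enhancement mask (SBEM) construction and application.

The enhancement filter computes, at every pixel,

    g(x, y) = sum_{s=0}^{M} sum_{t=1}^{N} w_{s,t} * (I(x+s, y-t) - I(x+s, y+t))
              + w_c * I(x, y)

an antisymmetric weighted difference of N horizontal pixel pairs over M+1
rows below the current pixel, plus a fractional contribution ``w_c`` of the
pixel itself.  With left-bright / right-dark transitions — the muscle edge
after orientation normalization — the pair differences add constructively
and the boundary lights up, while homogeneous regions collapse to
``w_c * I``.  The sum of the pair coefficients (excluding ``w_c``) is zero
by construction.

For the shape-based variant the lower mask rows are shifted left, matching
the muscle's narrowing from top to bottom so the filter integrates along a
down-left boundary rather than a vertical one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# Default weights: w_{s,1}=1, w_{s,2}=2, w_{s,3}=0 for both rows s=0,1;
# the weight increases with t to suppress tissue away from the edge, and the
# outermost pair is zeroed so the shifted mask keeps a zero coefficient sum.
DEFAULT_WEIGHTS = ((1.0, 2.0, 0.0), (1.0, 2.0, 0.0))
DEFAULT_CENTER_WEIGHT = 0.5


@dataclass(frozen=True)
class FilterParams:
    """Parameters of the enhancement filter.

    ``weights[s][t-1]`` is the coefficient of the pair at horizontal offset
    ``+-t`` in mask row ``s``; ``M = len(weights) - 1`` rows below the
    current pixel participate, each with ``N = len(weights[s])`` pairs.
    """

    weights: tuple[tuple[float, ...], ...] = DEFAULT_WEIGHTS
    center_weight: float = DEFAULT_CENTER_WEIGHT
    use_shift: bool = True
    shift_per_row: int = 1

    def __post_init__(self) -> None:
        w = tuple(tuple(float(v) for v in row) for row in self.weights)
        if len(w) < 1 or any(len(row) < 1 for row in w):
            raise ValueError("weights must be a non-empty grid of pair coefficients")
        if len({len(row) for row in w}) != 1:
            raise ValueError("all weight rows must list the same number of pairs")
        object.__setattr__(self, "weights", w)
        if not 0.0 <= self.center_weight <= 1.0:
            raise ValueError("center_weight must lie in [0, 1]")
        if self.shift_per_row < 0:
            raise ValueError("shift_per_row must be non-negative")

    @property
    def n_rows(self) -> int:  # M + 1
        return len(self.weights)

    @property
    def n_pairs(self) -> int:  # N
        return len(self.weights[0])


@dataclass(frozen=True)
class EnhancementMask:
    """A built enhancement mask.

    ``coefficients`` holds the pair coefficients only (center weight kept
    separate), one grid row per mask row ``s = 0..M``; column ``j``
    corresponds to horizontal offset ``j - center_col``.  Any row shift is
    already applied, with vacated cells zero-filled.
    """

    coefficients: np.ndarray
    center_weight: float
    center_col: int
    shift_per_row: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "coefficients", np.asarray(self.coefficients, dtype=float)
        )

    @property
    def n_rows(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_cols(self) -> int:
        return self.coefficients.shape[1]

    def full_kernel(self) -> np.ndarray:
        """Symmetric odd-sized kernel (center weight included) whose
        cross-correlation with the image evaluates the filter."""
        m = self.n_rows - 1
        half_c = max(self.center_col, self.n_cols - 1 - self.center_col)
        kernel = np.zeros((2 * m + 1, 2 * half_c + 1))
        r0, c0 = m, half_c  # kernel center = offset (0, 0)
        for s in range(self.n_rows):
            for j in range(self.n_cols):
                kernel[r0 + s, c0 + (j - self.center_col)] = self.coefficients[s, j]
        kernel[r0, c0] += self.center_weight
        return kernel

    def __str__(self) -> str:  # debugging aid: print as a text grid
        rows = [
            " ".join(f"{v:+.2f}" for v in row) for row in self.coefficients
        ]
        return "\n".join(rows) + f"\n(w_c = {self.center_weight}, center col = {self.center_col})"


def build_mask(params: FilterParams) -> EnhancementMask:
    """Build the (optionally shifted) enhancement mask from its parameters.

    Row ``s`` carries ``+w_{s,t}`` at offset ``-t`` and ``-w_{s,t}`` at
    offset ``+t`` (0 at offset 0); when ``use_shift`` is set, row ``s`` is
    displaced left by ``s * shift_per_row`` columns.  The grid is padded so
    no coefficient is dropped by the shift.
    """
    n = params.n_pairs
    m = params.n_rows - 1
    shift = params.shift_per_row if params.use_shift else 0
    pad = m * shift
    width = 2 * n + 1 + pad
    center_col = n + pad  # offset 0 before shift
    grid = np.zeros((m + 1, width))
    for s, row_w in enumerate(params.weights):
        disp = s * shift
        for t, w in enumerate(row_w, start=1):
            grid[s, center_col - t - disp] += w
            grid[s, center_col + t - disp] += -w
    return EnhancementMask(
        coefficients=grid,
        center_weight=params.center_weight,
        center_col=center_col,
        shift_per_row=shift,
    )


def coefficient_sum(mask: EnhancementMask) -> float:
    """Arithmetic sum of all pair coefficients, excluding the center weight.

    Zero for every mask built from antisymmetric pairs — homogeneous regions
    then respond with exactly ``w_c * I``.
    """
    return float(mask.coefficients.sum())


def apply_sbem(image, mask: EnhancementMask) -> np.ndarray:
    """Apply the enhancement mask to an image by cross-correlation.

    Accepts a :class:`~pectseg.image_io.Mammogram` or a 2-D array.  Borders
    use replicate padding so the image frame does not fabricate edges (zero
    padding would plant a spurious bright-to-zero step exactly where the
    muscle sits).  The output is real-valued and unclipped: downstream steps
    only rank values.
    """
    pixels = getattr(image, "pixels", image)
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("apply_sbem expects a 2-D image")
    kernel = mask.full_kernel()
    if kernel.shape[0] > pixels.shape[0] or kernel.shape[1] > pixels.shape[1]:
        raise ValueError(
            f"mask {kernel.shape} larger than image {pixels.shape}"
        )
    return ndimage.correlate(pixels, kernel, mode="nearest")
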