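"""Synthetic MLO-like mammogram phantoms with known pectoral ground truth.

A phantom emulates the features the detector relies on: a bright, roughly
triangular pectoral region in the top-left corner whose boundary
``column(r) = a + b r + c r^2 + d r^3`` narrows monotonically from top to
bottom; an intensity step at the boundary plus a gentle ramp inside the
muscle (brighter away from the boundary); breast-tissue background with
Gaussian noise and optional glandular blobs; optionally a second, nested
muscle edge (multi-layer muscles) and a bright horizontal tape-artifact
strip near the top.

The default canvas is 512 x 512 at 0.4 mm/pixel, mirroring the working
resolution of a 1024 x 1024, 0.2 mm/pixel mammogram downsampled by two.

What phantoms do *not* emulate: real parenchymal texture, lesions, skin
lines, or scanner artifacts beyond the tape strip — passing on phantoms
shows the geometry and selection logic work, not clinical performance.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .growth import BoundaryPolyline, boundary_to_region
from .image_io import Mammogram, PectoralRegion


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic mammogram.

    ``boundary_coeffs`` are (a, b, c, d) of the true boundary column as a
    cubic in row; the boundary must be monotone non-increasing over the
    rows where it is positive.  ``muscle_base`` must exceed
    ``breast_base``.  ``inner_contrast`` scales the multi-layer inner
    edge's step relative to the outer step: below 1 gives the usual dimmer
    inner layer, above 1 reproduces the brighter-inner-layer failure mode.
    """

    shape: tuple[int, int] = (512, 512)
    boundary_coeffs: tuple[float, float, float, float] = (230.0, -0.8, 0.0, 0.0)
    muscle_base: int = 190
    breast_base: int = 120
    gradient_strength: float = 30.0
    noise_sd: float = 0.0
    n_glandular_blobs: int = 0
    multilayer: bool = False
    inner_contrast: float = 0.5
    tape_artifact: bool = False
    edge_softness: float = 1.0  # Gaussian sigma of the boundary transition
    pixel_spacing_mm: float = 0.4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.muscle_base <= self.breast_base:
            raise ValueError("muscle_base must exceed breast_base")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def boundary_column(self, rows: np.ndarray) -> np.ndarray:
        a, b, c, d = self.boundary_coeffs
        r = np.asarray(rows, dtype=float)
        return a + b * r + c * r**2 + d * r**3


def _truth_polyline(spec: PhantomSpec) -> BoundaryPolyline:
    n_rows, n_cols = spec.shape
    rows = np.arange(n_rows)
    cols = spec.boundary_column(rows)
    pts = []
    for r, col in zip(rows, cols):
        col_px = int(np.clip(np.rint(col), 0, n_cols - 1))
        pts.append((int(r), col_px))
        if col <= 0:
            break
    return BoundaryPolyline(points=tuple(pts), source_shape=(n_rows, n_cols))


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[Mammogram, PectoralRegion, BoundaryPolyline]:
    """Generate one phantom with its ground-truth region and polyline.

    Deterministic given ``spec.rng_seed``.  The truth mask uses the same
    strict "muscle = column < boundary" convention as the detector's
    rasterizer, so truth mask and truth polyline are mutually consistent by
    construction.
    """
    n_rows, n_cols = spec.shape
    rows = np.arange(n_rows, dtype=float)
    bcol = spec.boundary_column(rows)
    pos = bcol > 0
    if pos.any():
        diffs = np.diff(bcol[pos])
        if (diffs > 1e-9).any():
            raise ValueError(
                "boundary must be monotone non-increasing over its rows"
            )
    rng = np.random.default_rng(spec.rng_seed)

    img = np.full((n_rows, n_cols), float(spec.breast_base))

    # glandular clutter: Gaussian bumps in the breast region, below the
    # muscle intensity so the intensity tie-break stays discriminative
    for _ in range(spec.n_glandular_blobs):
        r0 = rng.uniform(0.2 * n_rows, 0.95 * n_rows)
        c0 = rng.uniform(0.3 * n_cols, 0.95 * n_cols)
        sigma = rng.uniform(8, 25)
        amp = rng.uniform(
            0.3 * (spec.muscle_base - spec.breast_base),
            0.8 * (spec.muscle_base - spec.breast_base),
        )
        rr, cc = np.meshgrid(rows, np.arange(n_cols, dtype=float), indexing="ij")
        img += amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))

    # muscle: step at the boundary plus a ramp growing away from it
    cc = np.arange(n_cols, dtype=float)[None, :]
    bb = bcol[:, None]
    inside = cc < bb
    ref = max(float(bcol[0]), 1.0)
    ramp = np.clip((bb - cc) / ref, 0.0, 1.0) * spec.gradient_strength
    muscle_val = spec.muscle_base + ramp
    img = np.where(inside, muscle_val, img)

    if spec.multilayer:
        # nested inner edge left of (inside) the true boundary; its step is
        # inner_contrast times the outer step
        inner_b = 0.55 * bb
        inner = cc < inner_b
        step = spec.inner_contrast * (spec.muscle_base - spec.breast_base)
        img = np.where(inside & inner, img + step, img)

    if spec.tape_artifact:
        r_top = max(2, n_rows // 64)
        img[r_top : r_top + 4, :] = 250.0

    if spec.edge_softness > 0:
        img = ndimage.gaussian_filter(img, sigma=spec.edge_softness)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    mammogram = Mammogram(
        pixels, pixel_spacing_mm=spec.pixel_spacing_mm, laterality="left"
    )
    truth_polyline = _truth_polyline(spec)
    truth_region = boundary_to_region(truth_polyline, spec.shape)
    return mammogram, truth_region, truth_polyline


def generate_suite(
    n: int,
    base_spec: PhantomSpec = PhantomSpec(),
    seed: int = 0,
) -> list[tuple[Mammogram, PectoralRegion, BoundaryPolyline]]:
    """Generate ``n`` phantoms with randomized boundary geometry.

    Intercepts are drawn in [0.35, 0.55] of the width and slopes in
    [-1.2, -0.4] columns/row — within the reach of the default candidate
    fan — plus a small quadratic term.  Reproducible from ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    n_rows, n_cols = base_spec.shape
    for i in range(n):
        a = rng.uniform(0.35, 0.55) * n_cols
        b = rng.uniform(-1.2, -0.4)
        # mild curvature, kept monotone non-increasing: c same sign as b's
        # trend and small enough that b + 2 c r never turns positive
        c = rng.uniform(-0.2, 0.2) * abs(b) / n_rows
        if b + 2 * c * n_rows > 0:
            c = 0.0
        spec = replace(
            base_spec,
            boundary_coeffs=(float(a), float(b), float(c), 0.0),
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_phantom(spec))
    return out
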