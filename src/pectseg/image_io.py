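"""Mammogram I/O, orientation normalization and downsampling.

Coordinate convention used by every module in this package: 0-based
``(row, column)`` indices, row 0 at the top of the image, column 0 at the
left.  After :func:`normalize_orientation` the pectoral muscle sits in the
top-left corner, so all downstream steps can assume a left-bright,
down-left-sloping boundary.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

logger = logging.getLogger(__name__)

LATERALITIES = ("left", "right", "unknown")


@dataclass(frozen=True)
class Mammogram:
    """A single 2-D 8-bit mammographic image plus acquisition metadata.

    Parameters
    ----------
    pixels
        2-D uint8 array of intensities in [0, 255].
    pixel_spacing_mm
        Isotropic per-pixel spacing in millimetres (mini-MIAS digitizes at
        0.2 mm/pixel).
    laterality
        Which side the pectoral muscle is expected on: ``"left"``,
        ``"right"`` or ``"unknown"`` (triggers auto-detection when the
        orientation is normalized).
    """

    pixels: np.ndarray
    pixel_spacing_mm: float = 0.2
    laterality: str = "unknown"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mammogram pixels must be 2-D, got ndim={px.ndim}")
        if px.size == 0:
            raise ValueError("mammogram must have at least one pixel")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("mammogram intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)
        if not self.pixel_spacing_mm > 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.laterality not in LATERALITIES:
            raise ValueError(f"laterality must be one of {LATERALITIES}")

    @property
    def n_rows(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_cols(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PectoralRegion:
    """Binary pixel mask of a (detected or ground-truth) pectoral muscle."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("region mask must be 2-D")
        object.__setattr__(self, "mask", m.astype(bool))

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def read_mammogram(
    path: str | Path,
    pixel_spacing_mm: float = 0.2,
    laterality: str = "unknown",
) -> Mammogram:
    """Read a PGM (P2/P5) or PNG mammogram as an 8-bit grayscale image.

    Accidental multi-channel inputs are collapsed to grayscale by an
    unweighted channel mean.  Raises ``IOError`` naming the path when the
    file cannot be decoded.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # truncated / undecodable file
        raise IOError(f"cannot read mammogram from {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected 2-D image data, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    return Mammogram(arr, pixel_spacing_mm=pixel_spacing_mm, laterality=laterality)


def write_mammogram(m: Mammogram, path: str | Path) -> None:
    """Write the image as binary PGM (P5) or PNG, chosen by file suffix."""
    path = Path(path)
    im = Image.fromarray(m.pixels)
    if path.suffix.lower() == ".pgm":
        im.save(path, format="PPM")
    else:
        im.save(path)


def _muscle_on_right(pixels: np.ndarray) -> bool:
    """Compare mean intensity of the left vs right quarter columns of the
    top quarter rows; the brighter side hosts the muscle.  Ties count as
    already-left."""
    top = pixels[: max(1, pixels.shape[0] // 4), :]
    q = max(1, pixels.shape[1] // 4)
    left_mean = float(top[:, :q].mean())
    right_mean = float(top[:, -q:].mean())
    return right_mean > left_mean


def normalize_orientation(m: Mammogram) -> Mammogram:
    """Place the pectoral muscle on the top-left side.

    Right-lateral images are flipped by pure column reversal.  When the
    laterality is unknown, the brighter top-quarter side is taken as the
    muscle side (the rule fired is logged).  The returned image always has
    ``laterality="left"``.
    """
    if m.laterality == "right":
        flip = True
        logger.info("orientation: flagged right, flipping columns")
    elif m.laterality == "left":
        flip = False
        logger.info("orientation: flagged left, unchanged")
    else:
        flip = _muscle_on_right(m.pixels)
        logger.info(
            "orientation: auto-detected muscle on the %s, %s",
            "right" if flip else "left",
            "flipping columns" if flip else "unchanged",
        )
    pixels = m.pixels[:, ::-1] if flip else m.pixels
    return Mammogram(pixels, pixel_spacing_mm=m.pixel_spacing_mm, laterality="left")


def downsample(m: Mammogram, factor: int) -> Mammogram:
    """Block-mean downsampling by an integer factor.

    Each output pixel is the mean of its ``factor x factor`` block (partial
    edge blocks are averaged over the pixels available), rounded to the
    nearest integer; the pixel spacing is multiplied by the factor.  Block
    averaging rather than decimation suppresses noise ahead of filtering.
    """
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        return m
    n_rows, n_cols = m.shape
    out_rows = -(-n_rows // factor)
    out_cols = -(-n_cols // factor)
    pad_r = out_rows * factor - n_rows
    pad_c = out_cols * factor - n_cols
    px = m.pixels.astype(np.float64)
    padded = np.pad(px, ((0, pad_r), (0, pad_c)), mode="constant", constant_values=np.nan)
    blocks = padded.reshape(out_rows, factor, out_cols, factor)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(blocks, axis=(1, 3))
    out = np.clip(np.rint(means), 0, 255).astype(np.uint8)
    return Mammogram(
        out,
        pixel_spacing_mm=m.pixel_spacing_mm * factor,
        laterality=m.laterality,
    )


# ---------------------------------------------------------------------------
# boundary / mask / overlay files


def write_boundary(points: Iterable[tuple[int, int]], path: str | Path) -> None:
    """Write boundary samples to CSV with header ``row,column``."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["row", "column"])
        for r, c in points:
            writer.writerow([int(r), int(c)])


def read_boundary_csv(path: str | Path) -> list[tuple[int, int]]:
    """Read a boundary CSV written by :func:`write_boundary`."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != ["row", "column"]:
            raise ValueError(f"{path}: expected header 'row,column'")
        return [(int(r), int(c)) for r, c in reader]


def write_region_mask(region: PectoralRegion, path: str | Path) -> None:
    """Write a binary region mask as an 8-bit PNG (0 / 255)."""
    im = Image.fromarray(np.where(region.mask, 255, 0).astype(np.uint8))
    im.save(Path(path))


def read_region_mask(path: str | Path) -> PectoralRegion:
    """Read a 0/255 mask image back into a :class:`PectoralRegion`."""
    with Image.open(Path(path)) as im:
        arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return PectoralRegion(arr > 127)


def write_overlay(
    m: Mammogram,
    points: Sequence[tuple[int, int]],
    path: str | Path,
    thickness: int = 1,
) -> None:
    """Write a PNG with the boundary drawn in red over the grayscale image."""
    rgb = np.stack([m.pixels] * 3, axis=-1).astype(np.uint8)
    n_rows, n_cols = m.shape
    for r, c in points:
        for dc in range(-thickness, thickness + 1):
            cc = c + dc
            if 0 <= r < n_rows and 0 <= cc < n_cols:
                rgb[r, cc] = (255, 0, 0)
    Image.fromarray(rgb).save(Path(path))
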