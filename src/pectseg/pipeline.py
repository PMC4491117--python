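"""End-to-end detection pipeline and its configuration.

The pipeline chains preprocess (orientation flip, block-mean downsample) →
shape-based enhancement → seed-point selection → constrained growth →
cubic fit → region rasterization.  :class:`PipelineConfig` gathers every
tunable parameter, serializes to/from YAML, and defaults to the standard
parameter set (unit pair weights with double outer weight, w_c = 0.5,
P = 100, Q = 12, K_step = 2, W_band = 6).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .growth import BoundaryPolyline, GrowthParams, boundary_to_region, fit_cubic, grow_boundary
from .image_io import Mammogram, PectoralRegion, downsample, normalize_orientation
from .sbem import FilterParams, apply_sbem, build_mask
from .seed import (
    NoBoundaryError,
    SeedParams,
    detect_edges,
    extract_subimage,
    find_seed_point,
    select_initial_boundary,
    threshold_top_q,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    filter: FilterParams = field(default_factory=FilterParams)
    seed: SeedParams = field(default_factory=SeedParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    downsample_factor: int = 1
    laterality: str = "unknown"

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "filter": asdict(self.filter),
            "seed": asdict(self.seed),
            "growth": asdict(self.growth),
            "preprocessing": {
                "downsample_factor": self.downsample_factor,
                "laterality": self.laterality,
            },
        }
        data["filter"]["weights"] = [list(row) for row in self.filter.weights]
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        fp = data.get("filter", {})
        if "weights" in fp:
            fp["weights"] = tuple(tuple(row) for row in fp["weights"])
        pre = data.get("preprocessing", {})
        return cls(
            filter=FilterParams(**fp),
            seed=SeedParams(**data.get("seed", {})),
            growth=GrowthParams(**data.get("growth", {})),
            downsample_factor=pre.get("downsample_factor", 1),
            laterality=pre.get("laterality", "unknown"),
        )


@dataclass(frozen=True)
class DetectionResult:
    """Everything one pipeline run produced."""

    status: str  # "ok" or "no-boundary"
    boundary: BoundaryPolyline | None
    region: PectoralRegion | None
    seed_point: tuple[int, int] | None
    seed_rule: str | None  # which selection-cascade rule decided the seed
    grown_points: tuple[tuple[int, int], ...]
    image: Mammogram  # the preprocessed image the detection ran on
    enhanced: np.ndarray | None = None  # kept only when debug=True


def detect_pectoral(
    m: Mammogram,
    config: PipelineConfig = PipelineConfig(),
    debug: bool = False,
) -> DetectionResult:
    """Run the full pectoral-boundary detection on one mammogram.

    A failed seed search (no slanted edge component) yields status
    ``"no-boundary"`` rather than an exception, so batch runs continue.
    """
    if config.laterality != "unknown":
        m = Mammogram(m.pixels, m.pixel_spacing_mm, config.laterality)
    m = normalize_orientation(m)
    if config.downsample_factor > 1:
        m = downsample(m, config.downsample_factor)

    mask = build_mask(config.filter)
    enhanced = apply_sbem(m, mask)

    try:
        sub = extract_subimage(enhanced, config.seed.P)
        binary = threshold_top_q(sub, config.seed.Q)
        edges = detect_edges(
            binary,
            source=m.pixels,
            min_component_px=config.seed.min_component_px,
        )
        component, rule = select_initial_boundary(
            edges, source=m.pixels, params=config.seed, with_rule=True
        )
        seed_pt = find_seed_point(component)
    except NoBoundaryError as exc:
        logger.warning("detection failed: %s", exc)
        return DetectionResult(
            status="no-boundary",
            boundary=None,
            region=None,
            seed_point=None,
            seed_rule=None,
            grown_points=(),
            image=m,
            enhanced=enhanced if debug else None,
        )

    grown = grow_boundary(enhanced, seed_pt, config.growth)
    boundary = fit_cubic(grown, m.shape)
    region = boundary_to_region(boundary, m.shape)
    return DetectionResult(
        status="ok",
        boundary=boundary,
        region=region,
        seed_point=seed_pt,
        seed_rule=rule,
        grown_points=tuple(grown),
        image=m,
        enhanced=enhanced if debug else None,
    )
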