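import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pectseg import (
    EdgeComponent,
    NoBoundaryError,
    SeedParams,
    detect_edges,
    extract_subimage,
    find_seed_point,
    select_initial_boundary,
    threshold_top_q,
)


def make_component(pixels, intensity=100.0, angle=45.0, cov=-1.0):
    """Hand-built edge component with prescribed selection attributes."""
    return EdgeComponent(
        pixels=tuple(pixels),
        mean_source_intensity=intensity,
        orientation_deg=angle,
        row_col_cov=cov,
    )


def diagonal(n, col0=100, row0=0):
    return [(row0 + i, col0 - i) for i in range(n)]


class TestExtractSubimage:
    def test_top_p_rows(self):
        img = np.arange(200 * 10).reshape(200, 10)
        sub = extract_subimage(img, 100)
        assert sub.shape == (100, 10)
        assert (sub == img[:100]).all()

    def test_p_equals_rows_gives_whole_image(self):
        img = np.zeros((50, 10))
        assert extract_subimage(img, 50).shape == (50, 10)

    def test_oversized_p_clamps_with_warning(self, caplog):
        img = np.zeros((20, 10))
        with caplog.at_level(logging.WARNING, logger="pectseg.seed"):
            sub = extract_subimage(img, 100)
        assert sub.shape == (20, 10)
        assert any("clamping" in r.message for r in caplog.records)


class TestThresholdTopQ:
    def test_top_two_of_row(self):
        out = threshold_top_q(np.array([[5.0, 1.0, 3.0, 2.0]]), 2)
        assert out.tolist() == [[True, False, True, False]]

    def test_constant_row_ties_leftmost(self):
        out = threshold_top_q(np.full((1, 5), 7.0), 2)
        assert out.tolist() == [[True, True, False, False, False]]

    def test_q_at_least_columns_marks_all(self):
        out = threshold_top_q(np.zeros((2, 3)), 10)
        assert out.all()

    def test_bad_q(self):
        with pytest.raises(ValueError):
            threshold_top_q(np.zeros((2, 3)), 0)

    @given(
        q=st.integers(1, 12),
        n_cols=st.integers(1, 15),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, deadline=None)
    def test_exactly_min_q_ncols_marked_per_row(self, q, n_cols, seed):
        rng = np.random.default_rng(seed)
        sub = rng.integers(0, 5, size=(6, n_cols)).astype(float)  # many ties
        out = threshold_top_q(sub, q)
        assert (out.sum(axis=1) == min(q, n_cols)).all()


class TestDetectEdges:
    def test_solid_block_yields_border_trace(self):
        grid = np.zeros((9, 9), dtype=bool)
        grid[2:7, 2:7] = True
        comps = detect_edges(grid)
        assert len(comps) == 1
        # 5x5 block: the one-pixel border ring has 16 pixels
        assert comps[0].pixel_count == 16
        assert set(comps[0].pixels) <= {
            (r, c) for r in range(2, 7) for c in range(2, 7)
        }

    def test_all_false_gives_empty_list(self):
        assert detect_edges(np.zeros((5, 5), dtype=bool)) == []

    def test_two_disjoint_blocks_two_components(self):
        grid = np.zeros((12, 12), dtype=bool)
        grid[1:4, 1:4] = True
        grid[7:10, 7:10] = True
        assert len(detect_edges(grid)) == 2

    def test_speckle_below_min_size_discarded(self):
        grid = np.zeros((8, 8), dtype=bool)
        grid[4, 4] = True  # single pixel
        assert detect_edges(grid) == []

    def test_edge_pixels_subset_of_input(self, rng):
        grid = rng.random((20, 20)) > 0.6
        for comp in detect_edges(grid):
            assert all(grid[r, c] for r, c in comp.pixels)

    def test_mean_intensity_measured_on_source(self):
        grid = np.zeros((6, 6), dtype=bool)
        grid[1:4, 1:4] = True
        source = np.full((6, 6), 42.0)
        comps = detect_edges(grid, source=source)
        assert comps[0].mean_source_intensity == pytest.approx(42.0)


class TestSelectInitialBoundary:
    def test_angle_filter_rejects_horizontal(self, caplog):
        diag = make_component(diagonal(30), angle=45.0, cov=-1.0)
        horiz = make_component([(5, c) for c in range(60)], angle=0.0, cov=0.0)
        with caplog.at_level(logging.INFO, logger="pectseg.seed"):
            chosen, rule = select_initial_boundary([diag, horiz], with_rule=True)
        assert chosen is diag
        assert rule == "angle-filter"
        assert any("angle-filter" in r.message for r in caplog.records)

    def test_up_right_slope_rejected(self):
        # slanted but sloping down-right: not a pectoral boundary
        wrong = make_component([(i, 10 + i) for i in range(30)], angle=135.0, cov=+1.0)
        with pytest.raises(NoBoundaryError):
            select_initial_boundary([wrong])

    def test_largest_pixel_count_wins(self):
        big = make_component(diagonal(100), intensity=100.0)
        small = make_component(diagonal(40, col0=200), intensity=250.0)
        chosen, rule = select_initial_boundary([big, small], with_rule=True)
        assert chosen is big
        assert rule == "pixel-count"

    def test_intensity_tiebreak_when_counts_similar(self):
        a = make_component(diagonal(100), intensity=200.0)
        b = make_component(diagonal(98, col0=200), intensity=120.0)
        chosen, rule = select_initial_boundary([a, b], with_rule=True)
        assert chosen is a
        assert rule == "mean-intensity"

    def test_rightmost_rule_for_multilayer(self, caplog):
        left = make_component(diagonal(100, col0=80), intensity=200.0)
        right = make_component(diagonal(98, col0=200), intensity=198.0)
        with caplog.at_level(logging.INFO, logger="pectseg.seed"):
            chosen, rule = select_initial_boundary([left, right], with_rule=True)
        assert chosen is right
        assert rule == "rightmost-multilayer"
        assert any("rightmost-multilayer" in r.message for r in caplog.records)

    def test_no_survivor_raises(self):
        horiz = make_component([(5, c) for c in range(30)], angle=0.0, cov=0.0)
        with pytest.raises(NoBoundaryError):
            select_initial_boundary([horiz])

    def test_empty_input_raises(self):
        with pytest.raises(NoBoundaryError):
            select_initial_boundary([])

    def test_deterministic(self):
        comps = [
            make_component(diagonal(100), intensity=150.0),
            make_component(diagonal(97, col0=220), intensity=150.0),
        ]
        first = select_initial_boundary(comps)
        for _ in range(5):
            assert select_initial_boundary(comps) is first


class TestFindSeedPoint:
    @pytest.mark.parametrize(
        "pixels, expected",
        [
            ([(2, 10), (3, 9), (4, 8)], (2, 10)),
            ([(2, 10), (2, 11), (3, 9)], (2, 11)),
            ([(5, 5)], (5, 5)),
        ],
    )
    def test_top_right_pixel(self, pixels, expected):
        comp = make_component(pixels)
        assert find_seed_point(comp) == expected


class TestSeedParams:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            SeedParams(P=0)
        with pytest.raises(ValueError):
            SeedParams(Q=0)
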