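import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafseg.core import (Contour, LeafScan, MultipleComponentsError,
                          NoObjectFoundError, connected_components,
                          extract_tile, fill_contour, mask_to_contour,
                          px_to_physical, rough_foreground)


class TestUnits:
    @pytest.mark.parametrize("px,dpi,mm", [
        (300, 300, 25.4),
        (0, 300, 0.0),
        (6, 300, 0.508),
    ])
    def test_known_conversions(self, px, dpi, mm):
        assert px_to_physical(px, dpi) == pytest.approx(mm)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            px_to_physical(-1, 300)
        with pytest.raises(ValueError):
            px_to_physical(10, 0)

    @given(a=st.floats(0, 1e5), b=st.floats(0, 1e5))
    def test_linearity(self, a, b):
        assert px_to_physical(a + b, 300) == pytest.approx(
            px_to_physical(a, 300) + px_to_physical(b, 300))


class TestRoughForeground:
    def test_all_white_image_has_no_object(self):
        scan = LeafScan(np.ones((32, 32, 3), dtype=np.float32))
        with pytest.raises(NoObjectFoundError):
            rough_foreground(scan)

    def test_dust_specks_excluded_by_largest_component(self):
        img = np.ones((60, 60, 3), dtype=np.float32)
        img[20:40, 20:40] = 0.2          # the object
        img[5:8, 5:8] = 0.1              # a speck
        mask = rough_foreground(LeafScan(img))
        assert mask[30, 30]
        assert not mask[6, 6]

    def test_dark_object_on_white(self):
        img = np.full((50, 50, 3), 0.97, dtype=np.float32)
        img[10:40, 15:35] = 0.3
        mask = rough_foreground(LeafScan(img))
        truth = np.zeros((50, 50), dtype=bool)
        truth[10:40, 15:35] = True
        inter = (mask & truth).sum()
        union = (mask | truth).sum()
        assert inter / union >= 0.9


class TestExtractTile:
    def test_interior_center_has_no_padding(self):
        img = np.random.default_rng(0).random((100, 100, 3)).astype(np.float32)
        tile = extract_tile(img, (50, 50), 32)
        assert not tile.pad_mask.any()
        assert tile.pixels.shape == (32, 32, 3)

    def test_corner_center_pads_top_left_quadrant(self):
        img = np.zeros((300, 300, 3), dtype=np.float32)
        tile = extract_tile(img, (0, 0), 256)
        # Center pixel sits at index (128, 128): rows/cols < 128 are padding.
        assert tile.pad_mask[:128, :].all()
        assert tile.pad_mask[:, :128].all()
        assert not tile.pad_mask[128:, 128:].any()

    def test_center_pixel_convention(self):
        img = np.zeros((64, 64), dtype=np.float32)
        img[20, 30] = 1.0
        tile = extract_tile(img, (20, 30), 16, pad_value=0.0)
        assert tile.pixels[8, 8, 0] == 1.0

    def test_constant_image_gives_constant_tile(self):
        img = np.full((64, 64, 3), 0.5, dtype=np.float32)
        tile = extract_tile(img, (32, 32), 16)
        assert np.all(tile.pixels == 0.5)

    def test_uint8_rescaled(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        tile = extract_tile(img, (32, 32), 16)
        assert np.all(tile.pixels == 1.0)

    def test_reembedding_recovers_values(self):
        rng = np.random.default_rng(1)
        img = rng.random((40, 40, 3)).astype(np.float32)
        tile = extract_tile(img, (5, 35), 16)
        half = 8
        for tr in range(16):
            for tc in range(16):
                r, c = 5 - half + tr, 35 - half + tc
                if 0 <= r < 40 and 0 <= c < 40:
                    assert np.all(tile.pixels[tr, tc] == img[r, c])
                    assert not tile.pad_mask[tr, tc]
                else:
                    assert tile.pad_mask[tr, tc]

    def test_center_out_of_bounds(self):
        img = np.zeros((10, 10, 3), dtype=np.float32)
        with pytest.raises(ValueError):
            extract_tile(img, (10, 3), 8)


def _flood_count(mask, connectivity):
    """Brute-force component count by iterative flood fill."""
    mask = mask.copy()
    if connectivity == 8:
        neigh = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1)
                 if (a, b) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                count += 1
                stack = [(r, c)]
                mask[r, c] = False
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in neigh:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < h and 0 <= nc < w and mask[nr, nc]:
                            mask[nr, nc] = False
                            stack.append((nr, nc))
    return count


class TestConnectedComponents:
    def test_empty_mask(self):
        count, _ = connected_components(np.zeros((5, 5), dtype=bool))
        assert count == 0

    def test_diagonal_pair(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1, 1] = m[2, 2] = True
        assert connected_components(m, connectivity=8)[0] == 1
        assert connected_components(m, connectivity=4)[0] == 2

    def test_plus_sign(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, :] = True
        m[:, 2] = True
        assert connected_components(m, 4)[0] == 1
        assert connected_components(m, 8)[0] == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = rng.random((24, 24)) < 0.35
            assert connected_components(m, connectivity)[0] == \
                _flood_count(m, connectivity)


class TestContours:
    def test_single_pixel(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 3] = True
        contour = mask_to_contour(m)
        assert len(contour) == 1
        assert tuple(contour.points[0]) == (2, 3)

    def test_filled_square_boundary(self):
        m = np.zeros((5, 5), dtype=bool)
        m[1:4, 1:4] = True
        contour = mask_to_contour(m)
        assert len(contour) == 8
        expected = {(1, 1), (1, 2), (1, 3), (2, 1), (2, 3),
                    (3, 1), (3, 2), (3, 3)}
        assert {tuple(p) for p in contour.points} == expected
        # Consecutive points are 8-adjacent.
        d = np.abs(np.diff(np.vstack([contour.points,
                                      contour.points[:1]]), axis=0))
        assert d.max() <= 1

    def test_multiple_components_rejected(self):
        m = np.zeros((6, 6), dtype=bool)
        m[0, 0] = m[5, 5] = True
        with pytest.raises(MultipleComponentsError):
            mask_to_contour(m)

    def test_trace_fill_roundtrip(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            m = np.zeros((40, 40), dtype=bool)
            r, c = rng.integers(12, 28, 2)
            rad = rng.integers(5, 10)
            yy, xx = np.mgrid[0:40, 0:40]
            m[(yy - r) ** 2 + (xx - c) ** 2 <= rad ** 2] = True
            contour = mask_to_contour(m)
            refilled = fill_contour(contour, m.shape)
            assert np.array_equal(refilled, m)


class TestFillContour:
    def test_square_boundary_fills_interior(self):
        pts = np.array([(1, 1), (1, 2), (1, 3), (2, 3), (3, 3),
                        (3, 2), (3, 1), (2, 1)])
        mask = fill_contour(Contour(points=pts, closed=True), (5, 5))
        assert mask.sum() == 9

    def test_degenerate_single_pixel(self):
        mask = fill_contour(Contour(points=np.array([(2, 2)]), closed=True),
                            (5, 5))
        assert mask.sum() == 1
        assert mask[2, 2]

    def test_orientation_invariance(self):
        pts = np.array([(1, 1), (1, 2), (1, 3), (2, 3), (3, 3),
                        (3, 2), (3, 1), (2, 1)])
        a = fill_contour(Contour(points=pts, closed=True), (5, 5))
        b = fill_contour(Contour(points=pts[::-1].copy(), closed=True),
                         (5, 5))
        assert np.array_equal(a, b)

    def test_open_contour_rejected(self):
        with pytest.raises(ValueError):
            fill_contour(Contour(points=np.array([(0, 0), (0, 1)]),
                                 closed=False), (3, 3))
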