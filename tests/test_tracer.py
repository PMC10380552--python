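import numpy as np
import pytest

from leafseg.core import Contour, LeafScan, mask_to_contour
from leafseg.synthetic import generate_leaf, small_leaf_params
from leafseg.tracer import (AugmentConfig, OracleTracer, TracerNet,
                            TracerConfig, build_tracer_dataset,
                            make_trace_target, small_tracer_config,
                            trace_leaf, trace_weights, weighted_mse)


class TestTraceWeights:
    def test_endpoints_round_to_two_and_one(self):
        w = trace_weights(128)
        assert round(w[0]) == 2
        assert round(w[-1]) == 1
        assert w[0] == pytest.approx(1.99962, abs=1e-4)
        assert w[-1] == pytest.approx(1.000335, abs=1e-5)

    def test_midpoint_is_exactly_three_halves(self):
        w = trace_weights(128)
        assert w[63] == pytest.approx(1.5)  # i = N/2, tanh(0) = 0

    def test_strictly_decreasing_within_open_interval(self):
        w = trace_weights(128)
        assert np.all(np.diff(w) < 0)
        assert w.max() < 2.0
        assert w.min() > 1.0

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            trace_weights(0)


class TestWeightedMse:
    def test_perfect_prediction(self):
        p = np.arange(8, dtype=float).reshape(2, 4)
        assert weighted_mse(p, p, np.ones(4)) == 0.0

    def test_uniform_unit_offset(self):
        t = np.zeros((2, 5))
        p = np.ones((2, 5))
        assert weighted_mse(p, t, np.ones(5)) == pytest.approx(2.0)

    def test_single_point_weighted(self):
        p = np.array([[3.0], [4.0]])
        t = np.zeros((2, 1))
        assert weighted_mse(p, t, np.array([2.0])) == pytest.approx(50.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            weighted_mse(np.zeros((2, 3)), np.zeros((2, 4)), np.ones(4))


def _straight_contour(n=200):
    """A long horizontal closed loop, 2 rows tall."""
    top = [(10, c) for c in range(5, 5 + n)]
    bottom = [(11, c) for c in range(5 + n - 1, 4, -1)]
    return Contour(points=np.array(top + bottom), closed=True)


class TestMakeTraceTarget:
    def test_straight_segment_has_evenly_spaced_col_displacements(self):
        img = np.full((40, 260, 3), 0.5, dtype=np.float32)
        contour = _straight_contour()
        tile, disp = make_trace_target(img, contour, start_index=60,
                                       direction=1, N=16, tile_size=32)
        assert np.all(disp[0] == 0)          # stays on the same row
        steps = np.diff(np.concatenate([[0], disp[1]]))
        assert np.all(steps > 0)
        assert np.ptp(steps) <= 1            # equal spacing up to rounding

    def test_reversed_direction_mirrors_displacements(self):
        img = np.full((40, 260, 3), 0.5, dtype=np.float32)
        contour = _straight_contour()
        _, fwd = make_trace_target(img, contour, 60, 1, 16, 32)
        _, back = make_trace_target(img, contour, 60, -1, 16, 32)
        assert np.all(back[1] < 0) and np.all(fwd[1] > 0)

    def test_displacements_land_on_contour_pixels(self):
        s = generate_leaf(small_leaf_params(seed=2))
        contour = mask_to_contour(s.leaf_mask)
        pix = {tuple(p) for p in contour.points}
        _, disp = make_trace_target(s.image, contour, 50, 1, 32, 64)
        center = contour.points[50]
        for k in range(disp.shape[1]):
            p = (int(center[0] + disp[0, k]), int(center[1] + disp[1, k]))
            # within one pixel of some contour pixel (rounding slack)
            assert any(abs(p[0] - q[0]) <= 1 and abs(p[1] - q[1]) <= 1
                       for q in pix)

    def test_overlay_channel_marks_recent_path_only(self):
        img = np.full((40, 260, 3), 0.5, dtype=np.float32)
        contour = _straight_contour()
        tile, _ = make_trace_target(img, contour, 100, 1, 16, 32,
                                    overlay_len=10)
        overlay = tile.pixels[..., 3]
        assert 0 < overlay.sum() <= 11
        # marked pixels sit behind (left of) the center column
        rows, cols = np.nonzero(overlay)
        assert cols.max() <= 16

    def test_contour_shorter_than_n_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.float32)
        tiny = Contour(points=np.array([(2, 2), (2, 3), (3, 3), (3, 2)]),
                       closed=True)
        with pytest.raises(ValueError):
            make_trace_target(img, tiny, 0, 1, 16, 8)


class TestTracerDataset:
    def test_target_count_is_contour_pixels_times_directions(self):
        s = generate_leaf(small_leaf_params(seed=1))
        contour = mask_to_contour(s.leaf_mask)
        ds = build_tracer_dataset([(s.image, s.leaf_mask)],
                                  small_tracer_config())
        assert len(ds) == 2 * len(contour)

    def test_batch_shapes_and_ranges(self):
        s = generate_leaf(small_leaf_params(seed=1))
        cfg = small_tracer_config()
        ds = build_tracer_dataset([(s.image, s.leaf_mask)], cfg,
                                  AugmentConfig(jitter_px=3))
        tiles, targets = ds.sample_batch(np.random.default_rng(0), 8)
        assert tiles.shape == (8, 64, 64, 4)
        assert targets.shape == (8, 2, 32)
        assert tiles.min() >= 0.0 and tiles.max() <= 1.0
        assert np.abs(targets).max() <= cfg.tile_size

    def test_zero_magnitude_augmentation_is_identity(self):
        s = generate_leaf(small_leaf_params(seed=1))
        cfg = small_tracer_config()
        plain = AugmentConfig(rot90=False, flips=False, jitter_px=0,
                              color=0.0, overlay_truncate_prob=0.0)
        ds = build_tracer_dataset([(s.image, s.leaf_mask)], cfg, plain)
        t1, d1 = ds.sample_batch(np.random.default_rng(5), 4)
        t2, d2 = ds.sample_batch(np.random.default_rng(5), 4, augment=False)
        assert np.allclose(t1, t2)
        assert np.allclose(d1, d2)

    def test_rot180_negates_displacements(self):
        from leafseg.tracer import _apply_rot_flip

        rng = np.random.default_rng(0)
        px = rng.random((16, 16, 4)).astype(np.float32)
        disp = np.array([[2.0, 4.0], [3.0, -5.0]])
        _, d2 = _apply_rot_flip(px, disp, k=2, flip=False)
        # Exact inverse for an even-sized tile includes the -1 center shift.
        assert np.allclose(d2[0], -disp[0] - 1)
        assert np.allclose(d2[1], -disp[1] - 1)


class TestTracerNet:
    def test_output_shape_and_finiteness(self):
        cfg = small_tracer_config()
        net = TracerNet(cfg, seed=0)
        x = np.random.default_rng(0).random((2, 64, 64, 4),
                                            dtype=np.float32)
        y = net.forward(x)
        assert y.shape == (2, 2, 32)
        assert np.isfinite(y).all()

    def test_spatial_reduction_contract(self):
        assert TracerConfig().head_spatial == 4          # 256 / 2^6
        assert small_tracer_config().head_spatial == 16  # 64 / 2^2

    def test_wrong_input_shape_rejected(self):
        net = TracerNet(small_tracer_config(), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 32, 32, 4), dtype=np.float32))

    def test_save_load_roundtrip(self, tmp_path):
        net = TracerNet(small_tracer_config(), seed=3)
        x = np.random.default_rng(1).random((1, 64, 64, 4),
                                            dtype=np.float32)
        y1 = net.forward(x)
        path = tmp_path / "tracer.npz"
        net.save(path)
        net2 = TracerNet.load(path)
        assert np.allclose(net2.forward(x), y1)


@pytest.fixture(scope="module")
def oracle_setup():
    s = generate_leaf(small_leaf_params(seed=21))
    cfg = small_tracer_config()
    contour = mask_to_contour(s.leaf_mask)
    return s, cfg, OracleTracer(contour, cfg)


class TestTraceLeafWithOracle:
    def test_reproduces_ground_truth_mask(self, oracle_setup):
        s, cfg, oracle = oracle_setup
        scan = LeafScan(s.image, sample_id="oracle")
        contour, mask = trace_leaf(oracle, scan, cfg)
        inter = (mask & s.leaf_mask).sum()
        union = (mask | s.leaf_mask).sum()
        assert inter / union >= 0.99

    def test_output_mask_single_component_no_holes(self, oracle_setup):
        from leafseg.core import connected_components
        from scipy import ndimage

        s, cfg, oracle = oracle_setup
        scan = LeafScan(s.image, sample_id="oracle")
        _, mask = trace_leaf(oracle, scan, cfg)
        assert connected_components(mask)[0] == 1
        assert np.array_equal(ndimage.binary_fill_holes(mask), mask)

    def test_rotation_equivariance(self, oracle_setup):
        s, cfg, _ = oracle_setup
        rot_img = np.rot90(s.image, 1, axes=(0, 1)).copy()
        rot_mask = np.rot90(s.leaf_mask, 1).copy()
        oracle = OracleTracer(mask_to_contour(rot_mask), cfg)
        scan = LeafScan(rot_img, sample_id="rot")
        _, mask = trace_leaf(oracle, scan, cfg)
        inter = (mask & rot_mask).sum()
        union = (mask | rot_mask).sum()
        assert inter / union >= 0.99
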