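import numpy as np
import pytest

from leafseg.core import LeafScan, connected_components
from leafseg.grower import (GrowLossConfig, GrowerNet, OracleGrower,
                            ProbabilityAccumulator, build_grower_dataset,
                            focal_loss, grow_veins, select_threshold,
                            small_grower_config)
from leafseg.synthetic import generate_leaf, small_leaf_params


class TestFocalLoss:
    def test_perfect_prediction_vanishes(self):
        assert focal_loss(1 - 1e-9, 1) == pytest.approx(0.0, abs=1e-6)
        assert focal_loss(1e-9, 0) == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_at_half(self):
        # -0.25 * 0.5^2 * log(0.5)
        assert focal_loss(0.5, 1) == pytest.approx(0.25 * 0.25 * np.log(2))

    def test_bce_reduction_identity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(1e-6, 1 - 1e-6, 10_000)
        y = rng.integers(0, 2, 10_000)
        f = focal_loss(p, y, GrowLossConfig(mode="bce"))
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert np.abs(f - bce).max() < 1e-12

    def test_gamma_zero_is_half_bce(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.01, 0.99, 1000)
        y = rng.integers(0, 2, 1000)
        f = focal_loss(p, y, GrowLossConfig(alpha=0.5, gamma=0.0))
        bce = -(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert np.allclose(f, 0.5 * bce, atol=1e-12)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            GrowLossConfig(alpha=0.0)
        with pytest.raises(ValueError):
            GrowLossConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            GrowLossConfig(mode="dice")


class TestGrowerDataset:
    @pytest.fixture(scope="class")
    def sample(self):
        return generate_leaf(small_leaf_params(seed=4))

    def test_tile_count_bounded_by_eleven_v(self, sample):
        v = int((sample.vein_mask & sample.leaf_mask).sum())
        ds = build_grower_dataset(
            [(sample.image, sample.vein_mask, sample.leaf_mask)],
            small_grower_config(), neg_ratio=10.0)
        assert len(ds) <= 11 * v

    def test_neg_ratio_cap(self, sample):
        with pytest.raises(ValueError):
            build_grower_dataset(
                [(sample.image, sample.vein_mask, sample.leaf_mask)],
                small_grower_config(), neg_ratio=20.0)

    def test_center_deep_inside_thick_vein_is_all_ones(self):
        img = np.full((64, 64, 3), 0.5, dtype=np.float32)
        vein = np.zeros((64, 64), dtype=bool)
        vein[20:40, 20:40] = True
        leaf = np.ones((64, 64), dtype=bool)
        ds = build_grower_dataset([(img, vein, leaf)],
                                  small_grower_config(), neg_ratio=1.0)
        assert np.all(ds._target_patch(0, 30, 30) == 1.0)

    def test_batch_shapes(self, sample):
        ds = build_grower_dataset(
            [(sample.image, sample.vein_mask, sample.leaf_mask)],
            small_grower_config(), neg_ratio=2.0)
        tiles, targets = ds.sample_batch(np.random.default_rng(0), 16)
        assert tiles.shape == (16, 32, 32, 3)
        assert targets.shape == (16, 3, 3)
        assert set(np.unique(targets)) <= {0.0, 1.0}


class TestGrowerNet:
    def test_softmax_pairs_sum_to_one(self):
        net = GrowerNet(small_grower_config(), seed=0)
        x = np.random.default_rng(0).random((3, 32, 32, 3),
                                            dtype=np.float32)
        probs = net.forward(x)
        assert probs.shape == (3, 3, 3, 2)
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_full_scale_spatial_contract(self):
        from leafseg.grower import GrowerConfig

        assert GrowerConfig().head_spatial == 4  # 128 / 2^5

    def test_wrong_shape_rejected(self):
        net = GrowerNet(small_grower_config(), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 64, 64, 3), dtype=np.float32))

    def test_save_load_roundtrip(self, tmp_path):
        net = GrowerNet(small_grower_config(), seed=7)
        x = np.random.default_rng(2).random((2, 32, 32, 3),
                                            dtype=np.float32)
        y1 = net.forward(x)
        net.save(tmp_path / "g.npz")
        net2 = GrowerNet.load(tmp_path / "g.npz")
        assert np.allclose(net2.forward(x), y1)


class _AllBackground:
    def predict_batch_at(self, centers):
        return np.zeros((len(centers), 3, 3), dtype=np.float32)


class _AllVein:
    def predict_batch_at(self, centers):
        return np.ones((len(centers), 3, 3), dtype=np.float32)


@pytest.fixture(scope="module")
def vein_sample():
    return generate_leaf(small_leaf_params(seed=11))


class TestGrowVeins:
    def test_all_background_model_halts_after_seed_pass(self, vein_sample):
        s = vein_sample
        cfg = small_grower_config(n_seeds=50)
        scan = LeafScan(s.image)
        acc = grow_veins(_AllBackground(), scan, s.leaf_mask, cfg, seed=0)
        # Only the 3x3 neighborhoods of the 50 seeds were visited.
        assert 50 <= (acc.visit_count > 0).sum() <= 50 * 9

    def test_all_vein_model_covers_leaf_interior(self, vein_sample):
        s = vein_sample
        cfg = small_grower_config(n_seeds=10)
        scan = LeafScan(s.image)
        acc = grow_veins(_AllVein(), scan, s.leaf_mask, cfg, seed=0)
        # Flood-fill equivalence: every leaf pixel was visited.
        assert (acc.visit_count[s.leaf_mask] > 0).all()
        # Centers stay inside the leaf: visits reach at most 1 px outside.
        from scipy import ndimage

        dilated = ndimage.binary_dilation(s.leaf_mask, np.ones((3, 3)))
        assert not (acc.visit_count > 0)[~dilated].any()

    def test_deterministic_for_fixed_seed(self, vein_sample):
        s = vein_sample
        cfg = small_grower_config(n_seeds=40)
        scan = LeafScan(s.image)
        oracle = OracleGrower(s.vein_mask & s.leaf_mask)
        a = grow_veins(oracle, scan, s.leaf_mask, cfg, seed=9)
        b = grow_veins(oracle, scan, s.leaf_mask, cfg, seed=9)
        assert np.array_equal(a.prob_sum, b.prob_sum)
        assert np.array_equal(a.visit_count, b.visit_count)

    def test_oracle_recovers_vein_mask(self, vein_sample):
        s = vein_sample
        truth = s.vein_mask & s.leaf_mask
        cfg = small_grower_config(n_seeds=300)
        scan = LeafScan(s.image)
        acc = grow_veins(OracleGrower(truth), scan, s.leaf_mask, cfg, seed=1)
        theta, mask = select_threshold(acc)
        inter = (mask & truth).sum()
        union = (mask | truth).sum()
        assert inter / union >= 0.99
        assert connected_components(mask)[0] <= \
            connected_components(truth)[0] + 1

    def test_empty_leaf_mask_rejected(self, vein_sample):
        cfg = small_grower_config()
        with pytest.raises(ValueError):
            grow_veins(_AllVein(), LeafScan(vein_sample.image),
                       np.zeros_like(vein_sample.leaf_mask), cfg, seed=0)


class TestSelectThreshold:
    def test_constant_accumulator_prefers_nonempty_mask(self):
        acc = ProbabilityAccumulator(
            prob_sum=np.full((10, 10), 0.6), visit_count=np.ones((10, 10),
                                                                 dtype=int))
        theta, mask = select_threshold(acc, grid=[0.5, 0.7])
        assert theta == 0.5           # 1 component beats the empty mask
        assert mask.all()

    def test_faint_bridges_lower_threshold_wins(self):
        # Two bright blobs joined by a faint bridge: low theta merges them.
        prob = np.zeros((10, 30))
        prob[4:7, 2:10] = 0.9
        prob[4:7, 20:28] = 0.9
        prob[5, 10:20] = 0.4
        acc = ProbabilityAccumulator(prob_sum=prob,
                                     visit_count=(prob > 0).astype(int))
        theta, mask = select_threshold(acc, grid=[0.3, 0.8])
        assert theta == 0.3
        assert connected_components(mask)[0] == 1

    def test_component_counts_match_brute_force_over_grid(self):
        rng = np.random.default_rng(3)
        prob = rng.random((20, 20))
        acc = ProbabilityAccumulator(prob_sum=prob,
                                     visit_count=np.ones((20, 20), int))
        grid = [0.2, 0.4, 0.6, 0.8]
        counts = {t: connected_components(prob >= t)[0] for t in grid}
        best = min(grid, key=lambda t: (counts[t] if (prob >= t).any()
                                        else np.inf, t))
        theta, _ = select_threshold(acc, grid=grid)
        assert theta == best

    def test_empty_accumulator_rejected(self):
        acc = ProbabilityAccumulator.zeros((5, 5))
        with pytest.raises(ValueError):
            select_threshold(acc)

    def test_invalid_grid_rejected(self):
        acc = ProbabilityAccumulator(prob_sum=np.ones((3, 3)),
                                     visit_count=np.ones((3, 3), int))
        with pytest.raises(ValueError):
            select_threshold(acc, grid=[])
        with pytest.raises(ValueError):
            select_threshold(acc, grid=[0.0, 0.5])
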