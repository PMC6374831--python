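"""Patch classifier: architecture arithmetic, gradients, training, prediction."""

import numpy as np
import pytest

import brainseg as bs
from brainseg import cnn as C
from brainseg.preprocess import Tissue


class TestDimensionArithmetic:
    @pytest.mark.parametrize("inp,k,expected", [(32, 5, 28), (14, 5, 10),
                                                (7, 1, 7), (5, 5, 1)])
    def test_conv_output_dim(self, inp, k, expected):
        assert C.conv_output_dim(inp, k) == expected

    @pytest.mark.parametrize("inp,s,expected", [(28, 2, 14), (10, 2, 5), (6, 2, 3)])
    def test_pool_output_dim(self, inp, s, expected):
        assert C.pool_output_dim(inp, s) == expected
        # pooling quarters the map area
        assert (inp // s) ** 2 * s * s == inp * inp

    def test_oversized_kernel_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            C.conv_output_dim(4, 5)

    def test_overlapping_pool_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            C.pool_output_dim(7, 2)

    def test_lenet_dimension_chain(self):
        # 32 -> 28 -> 14 -> 10 -> 5 -> 1 (C5 acts fully connected on 5x5)
        assert C.CnnSpec("LENET").feature_sides() == [28, 14, 10, 5, 1]

    def test_inconsistent_spec_names_failing_layer(self):
        with pytest.raises(ValueError, match="layer 1"):
            C.CnnSpec("LENET", input_side=31)  # 27 not divisible by 2


class TestBuildModel:
    def test_forward_returns_four_scores(self):
        m = C.build_model(C.CnnSpec("LENET"), seed=0)
        out = m.forward(np.zeros((2, 32, 32), dtype=np.uint8))
        assert out.shape == (2, 4)

    def test_small_variant_pools_to_six_units(self):
        m = C.build_model(C.CnnSpec("SMALL"), seed=0)
        _, acts = m.forward(np.zeros((1, 4, 4), dtype=np.uint8),
                            return_activations=True)
        assert acts[1].shape == (1, 6, 1, 1)  # "the output has six pixels"

    def test_pooling_preserves_map_count(self):
        m = C.build_model(C.CnnSpec("LENET"), seed=0)
        _, acts = m.forward(np.zeros((1, 32, 32), dtype=np.uint8),
                            return_activations=True)
        assert acts[0].shape[1] == acts[1].shape[1] == 6
        assert acts[2].shape[1] == acts[3].shape[1] == 16

    def test_same_seed_identical_parameters(self):
        a = C.build_model(C.CnnSpec("LENET"), seed=5)
        b = C.build_model(C.CnnSpec("LENET"), seed=5)
        assert all(np.array_equal(x, y) for x, y in zip(a.params, b.params))

    def test_c3_connection_table_masks_weights(self):
        m = C.build_model(C.CnnSpec("LENET"), seed=0)
        c3 = m.layers[2]
        # map 0 connects to S2 maps {0,1,2} only
        assert np.abs(c3.W[0, 3:]).sum() == 0
        assert np.abs(c3.W[0, :3]).sum() > 0


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        m = C.build_model(C.CnnSpec("SMALL"), seed=1)
        X = rng.integers(0, 256, size=(5, 4, 4)).astype(np.uint8)
        y = rng.integers(0, 4, size=5)
        _, grads = m.loss_and_grads(X, y)
        eps = 1e-6
        for pi, p in enumerate(m.params):
            flat, gflat = p.ravel(), grads[pi].ravel()
            for j in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[j]
                flat[j] = orig + eps
                lp, _ = m.loss_and_grads(X, y)
                flat[j] = orig - eps
                lm, _ = m.loss_and_grads(X, y)
                flat[j] = orig
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(gflat[j], rel=1e-4, abs=1e-8)


class TestExtractPatches:
    def test_single_full_patch(self):
        img = np.full((32, 32), 70, dtype=np.uint8)
        lm = np.full((32, 32), Tissue.GM, dtype=np.uint8)
        ps = C.extract_patches(img, lm, 32, stride=1)
        assert len(ps) == 1 and ps.labels[0] == Tissue.GM

    def test_count_matches_brute_force(self, zero_noise_pair):
        img, lm = zero_noise_pair.image, zero_noise_pair.truth
        ps = C.extract_patches(img, lm, 32, stride=8)
        tissue = {int(t) for t in bs.TISSUE_CLASSES}
        expected = sum(
            1
            for i in range(0, 256 - 32 + 1, 8)
            for j in range(0, 256 - 32 + 1, 8)
            if int(lm[i + 16, j + 16]) in tissue
        )
        assert len(ps) == expected

    def test_background_image_gives_empty_set(self, caplog):
        with caplog.at_level("WARNING"):
            ps = C.extract_patches(np.zeros((64, 64), dtype=np.uint8),
                                   np.zeros((64, 64), dtype=np.uint8), 32)
        assert len(ps) == 0


class TestTraining:
    def test_validation_accuracy_reaches_095_on_clean_phantoms(self, trained_lenet):
        result, _, cfg = trained_lenet
        assert cfg.epochs <= 50
        assert result.best_val_accuracy >= 0.95

    def test_loss_drops_after_first_epoch(self, trained_lenet):
        result, _, _ = trained_lenet
        assert result.history[1]["loss"] < result.history[0]["loss"]

    def test_accuracy_not_far_below_range_oracle(self, trained_lenet):
        # the intensity-range rule is exact on clean phantoms (accuracy 1.0);
        # the trained network must come within 5 points of it
        result, patches, _ = trained_lenet
        ranges = bs.TissueRanges()
        c = patches.patch_side // 2
        centre = patches.patches[:, c, c]
        oracle = np.array([int(ranges.classify_value(v)) for v in centre])
        oracle_acc = (oracle == patches.labels).mean()
        y = np.array([C.CLASS_OF_TISSUE[int(t)] for t in patches.labels])
        cnn_acc = (result.model.predict(patches.patches) == y).mean()
        assert cnn_acc >= oracle_acc - 0.05

    def test_single_class_set_rejected(self):
        img = np.full((40, 40), 70, dtype=np.uint8)
        lm = np.full((40, 40), Tissue.GM, dtype=np.uint8)
        ps = C.extract_patches(img, lm, 32, stride=4)
        m = C.build_model(C.CnnSpec("LENET"), seed=0)
        with pytest.raises(ValueError, match="missing tissue classes"):
            C.train(m, ps, C.TrainConfig(epochs=1, split=None, seed=0))

    def test_training_is_deterministic(self):
        pair = bs.generate_phantom(
            bs.PhantomSpec(noise_sigma=0, facial_structures=False, seed=9)
        )
        ps = C.extract_patches(pair.image, pair.truth, 4, stride=6)
        cfg = C.TrainConfig(epochs=2, subepochs_per_epoch=3, batch_size=1,
                            patches_per_image=40, split=None, seed=3)
        runs = []
        for _ in range(2):
            m = C.build_model(C.CnnSpec("SMALL"), seed=2)
            runs.append(C.train(m, ps, cfg).history)
        assert runs[0] == runs[1]

    def test_split_must_sum_to_image_count(self, trained_lenet):
        _, patches, _ = trained_lenet
        m = C.build_model(C.CnnSpec("LENET"), seed=0)
        with pytest.raises(ValueError, match="sum"):
            C.train(m, patches, C.TrainConfig(epochs=1, split=(600, 100, 100)))


class TestPredictLabelmap:
    def test_untrained_model_rejected(self):
        m = C.build_model(C.CnnSpec("LENET"), seed=0)
        with pytest.raises(ValueError, match="trained"):
            C.predict_labelmap(m, np.zeros((64, 64), dtype=np.uint8))

    def test_all_zero_image_maps_to_background(self, trained_lenet):
        result, _, _ = trained_lenet
        out = C.predict_labelmap(result.model, np.zeros((64, 64), dtype=np.uint8))
        assert (out == Tissue.BACKGROUND).all()

    def test_jaccard_at_least_09_on_held_out_clean_slice(self, trained_lenet):
        result, _, _ = trained_lenet
        pair = bs.generate_phantom(
            bs.PhantomSpec(noise_sigma=0, facial_structures=False, seed=321)
        )
        sup = bs.suppress_out_of_range(pair.image)
        lm = C.predict_labelmap(result.model, sup, stride=2)
        for t in bs.TISSUE_CLASSES:
            assert bs.jaccard(lm, pair.truth, t) >= 0.9, t.name

    def test_strided_output_equals_subsampled_dense_output(self, trained_lenet):
        result, _, _ = trained_lenet
        pair = bs.generate_phantom(
            bs.PhantomSpec(noise_sigma=0, facial_structures=False, seed=55, size=64)
        )
        sup = bs.suppress_out_of_range(pair.image)
        dense = C.predict_labelmap(result.model, sup, stride=1)
        strided = C.predict_labelmap(result.model, sup, stride=3)
        # brute-force nearest-centre fill of the dense grid
        c = 16
        n = 64 - 32 + 1
        centres = np.arange(0, n, 3)
        for y in range(n):
            for x in range(n):
                gy = centres[min(int(round(y / 3)), len(centres) - 1)]
                gx = centres[min(int(round(x / 3)), len(centres) - 1)]
                if sup[y + c, x + c] == 0:
                    assert strided[y + c, x + c] == Tissue.BACKGROUND
                else:
                    assert strided[y + c, x + c] == dense[gy + c, gx + c]


class TestCheckpoints:
    def test_round_trip_preserves_predictions(self, trained_lenet, tmp_path):
        result, patches, cfg = trained_lenet
        C.save_checkpoint(result.model, tmp_path / "model.npz", cfg)
        back = C.load_checkpoint(tmp_path / "model.npz")
        X = patches.patches[:32]
        assert np.array_equal(back.predict(X), result.model.predict(X))
        assert back.trained
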