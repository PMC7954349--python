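"""Layer registry, tinynet extraction, temporal averaging, and the
train-only standardize+PCA pipeline."""

import numpy as np
import pytest

from layerprobe.features import (
    FeatureMatrix,
    RegistryError,
    TinyNetExtractor,
    apply_feature_pipeline,
    fit_feature_pipeline,
    list_layers,
    load_features,
    load_pipeline,
    pixel_features,
    random_init_network,
    save_features,
    save_pipeline,
    temporal_average,
)
from layerprobe.stimuli import StimulusItem


class TestRegistry:
    def test_alexnet_has_thirteen_layers_in_order(self):
        names = [s.name for s in list_layers("alexnet")]
        assert names == ["conv1", "norm1", "pool1", "conv2", "norm2", "pool2",
                         "conv3", "conv4", "conv5", "pool5", "fc6", "fc7", "fc8"]

    def test_vgg11_c3d_pool3_sits_in_block_three(self):
        spec = {s.name: s for s in list_layers("vgg11-c3d")}
        assert spec["pool3"].block == 3
        assert spec["conv3a"].block == 3 and spec["conv3b"].block == 3
        assert spec["fc8"].block == 8

    def test_block_structure_is_eight_blocks_everywhere(self):
        for arch in ("alexnet", "vgg16", "vgg11-c3d"):
            blocks = [s.block for s in list_layers(arch)]
            assert blocks == sorted(blocks)
            assert max(blocks) == 8

    def test_unknown_architecture_raises(self):
        with pytest.raises(RegistryError, match="unknown"):
            list_layers("resnet50")

    def test_tinynet_layers_match_its_extractor(self, extractor):
        assert [s.name for s in extractor.layers] == [
            "conv1", "pool1", "conv2", "pool2", "conv3", "pool3",
            "conv4", "pool4", "fc5", "fc6"]


class TestTinyNet:
    def test_identical_inputs_give_identical_rows(self, extractor):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, size=(1, 64, 64, 3))
        batch = np.concatenate([x, x])
        for layer in ("conv1", "pool2", "fc6"):
            acts = extractor.extract(layer, batch)
            assert np.array_equal(acts[0], acts[1])

    def test_conv1_pre_relu_is_homogeneous(self, extractor):
        # zero bias and no normalization: doubling the input doubles the
        # first-layer pre-ReLU response
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 0.5, size=(1, 64, 64, 3))
        a1 = extractor.extract("conv1", x)
        a2 = extractor.extract("conv1", 2 * x)
        assert np.allclose(a2, 2 * a1, atol=1e-10)

    def test_zero_input_gives_zero_conv_rows(self, extractor):
        acts = extractor.extract("conv1", np.zeros((1, 64, 64, 3)))
        assert np.allclose(acts, 0.0)

    def test_conv_layers_keep_negative_values(self, extractor):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 1, size=(2, 64, 64, 3))
        assert (extractor.extract("conv2", x) < 0).any()

    def test_chunked_forward_matches_single_batch(self, extractor):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=(7, 64, 64, 3))
        whole = extractor.forward_all(x)
        chunked = extractor.forward_all(x, chunk=3)
        for layer in whole:
            # summation order inside the matmul may differ across chunk shapes
            assert np.allclose(whole[layer], chunked[layer], atol=1e-12)

    def test_unknown_layer_raises(self, extractor):
        with pytest.raises(RegistryError):
            extractor.extract("conv9", np.zeros((1, 64, 64, 3)))


class TestRandomInit:
    def test_same_seed_reproduces_weights(self):
        a = random_init_network("tinynet", seed=7)
        b = random_init_network("tinynet", seed=7)
        for k in a.weights:
            assert np.array_equal(a.weights[k], b.weights[k])

    def test_all_biases_exactly_zero(self):
        net = random_init_network("tinynet", seed=3)
        for b in net.biases.values():
            assert np.all(b == 0.0)

    def test_weights_within_glorot_uniform_support(self):
        net = random_init_network("tinynet", seed=5)
        k = 5  # conv1 kernel: fan_in = k*k*3, fan_out = k*k*8
        limit = np.sqrt(6.0 / (k * k * 3 + k * k * 8))
        assert np.abs(net.weights["conv1"]).max() <= limit
        flat, out = net.weights["fc5"].shape
        assert np.abs(net.weights["fc5"]).max() <= np.sqrt(6.0 / (flat + out))

    def test_unregistered_architecture_raises(self):
        with pytest.raises(RegistryError):
            random_init_network("densenet", seed=0)

    def test_pretrained_architectures_have_no_bundled_forward(self):
        with pytest.raises(NotImplementedError):
            random_init_network("alexnet", seed=0)


class TestTemporalAverage:
    def test_constant_frames_average_to_the_constant(self):
        frames = np.full((32, 5), 3.5)
        assert np.allclose(temporal_average(frames), 3.5)

    def test_alternating_frames_average_to_midpoint(self):
        frames = np.zeros((16, 4))
        frames[1::2] = 2.0
        assert np.allclose(temporal_average(frames), 1.0)

    def test_matches_brute_force_mean(self):
        rng = np.random.default_rng(0)
        frames = rng.standard_normal((48, 7))
        out = temporal_average(frames)
        expected = np.stack([frames[i * 16 : (i + 1) * 16].mean(axis=0) for i in range(3)])
        assert np.abs(out - expected).max() < 1e-12

    def test_ragged_bins_rejected(self):
        with pytest.raises(ValueError):
            temporal_average(np.zeros((17, 3)))


class TestFeaturePipeline:
    def _train(self, n=14, p=100, seed=0):
        return np.random.default_rng(seed).standard_normal((n, p))

    def test_component_count_bounded_by_rank(self):
        X = self._train(n=14, p=10_000 // 100)  # keep it quick; bound is n-1
        pipe = fit_feature_pipeline(X)
        assert pipe.n_components == min(14 - 1, X.shape[1])

    def test_training_projection_is_centered(self):
        X = self._train()
        pipe = fit_feature_pipeline(X)
        proj = apply_feature_pipeline(pipe, X)
        assert np.abs(proj.mean(axis=0)).max() < 1e-10

    def test_zero_variance_column_maps_to_zero(self):
        X = self._train()
        X[:, 3] = 2.0
        pipe = fit_feature_pipeline(X)
        assert pipe.sd[3] == 0.0
        Z = pipe.standardize(X + 0.0)
        assert np.all(Z[:, 3] == 0.0)

    def test_projection_preserves_standardized_distances(self):
        # full-rank orthonormal basis: pairwise Euclidean distances of the
        # standardized training rows survive the projection
        X = self._train(n=10, p=40)
        pipe = fit_feature_pipeline(X)
        Z = pipe.standardize(X)
        Z = Z - Z.mean(axis=0)
        proj = apply_feature_pipeline(pipe, X)
        from scipy.spatial.distance import pdist

        assert np.abs(pdist(Z) - pdist(proj)).max() < 1e-8

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_feature_pipeline(np.ones((1, 5)))

    def test_all_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_feature_pipeline(np.ones((5, 4)))

    def test_train_only_fitting_ignores_test_rows(self):
        X = self._train()
        pipe_a = fit_feature_pipeline(X)
        pipe_b = fit_feature_pipeline(X.copy())
        assert np.array_equal(pipe_a.mean, pipe_b.mean)
        assert np.array_equal(pipe_a.sd, pipe_b.sd)
        assert np.array_equal(pipe_a.basis, pipe_b.basis)
        # applying to arbitrary extra rows never mutates the pipeline
        extra = self._train(n=5, p=100, seed=9) * 100
        before = pipe_a.basis.copy()
        apply_feature_pipeline(pipe_a, extra)
        assert np.array_equal(pipe_a.basis, before)

    def test_identical_train_and_test_rows_project_identically(self):
        X = self._train()
        pipe = fit_feature_pipeline(X)
        assert np.array_equal(apply_feature_pipeline(pipe, X[:3]),
                              apply_feature_pipeline(pipe, X.copy()[:3]))

    def test_column_mismatch_raises(self):
        pipe = fit_feature_pipeline(self._train())
        with pytest.raises(ValueError, match="columns"):
            apply_feature_pipeline(pipe, np.ones((2, 7)))

    def test_hdf5_round_trip(self, tmp_path):
        pipe = fit_feature_pipeline(self._train())
        save_pipeline(pipe, tmp_path / "pipe.h5", architecture="tinynet", seed=0)
        back = load_pipeline(tmp_path / "pipe.h5")
        assert np.array_equal(pipe.basis, back.basis)
        fm = FeatureMatrix(np.eye(3), ["a", "b", "c"], "conv1")
        save_features(fm, tmp_path / "fm.h5")
        fm2 = load_features(tmp_path / "fm.h5")
        assert fm2.ids == ["a", "b", "c"] and np.array_equal(fm2.data, fm.data)


class TestPixelFeatures:
    def _items(self, n=4, h=8):
        rng = np.random.default_rng(0)
        return [StimulusItem(id=f"s{i}", pixels=rng.uniform(0, 1, (h, h, 3)),
                             labels={"object": "x"}) for i in range(n)]

    def test_two_train_images_give_one_component(self):
        items = self._items(2)
        items[1].pixels = items[0].pixels.copy()
        items[1].pixels[0, 0, 0] = min(1.0, items[1].pixels[0, 0, 0] + 0.3)
        fm = pixel_features(items, ["s0", "s1"])
        # centered 2-row matrix has rank 1
        assert fm.data.shape[1] == 1
        assert fm.data.std() > 0

    def test_identical_train_test_image_maps_identically(self):
        items = self._items(3)
        twin = StimulusItem(id="twin", pixels=items[0].pixels.copy(), labels={}, role="test")
        fm = pixel_features(items + [twin], ["s0", "s1", "s2"])
        assert np.allclose(fm.rows_for(["s0"]), fm.rows_for(["twin"]))

    def test_channel_replication_scales_distances_by_sqrt3(self):
        # grayscale planes replicated to 3 channels triple every squared
        # pixel difference, so raw pixel distances scale by sqrt(3)
        rng = np.random.default_rng(1)
        gray = [rng.uniform(0, 1, (6, 6, 1)) for _ in range(4)]
        flat1 = np.stack([g.ravel() for g in gray])
        flat3 = np.stack([np.repeat(g, 3, axis=2).ravel() for g in gray])
        from scipy.spatial.distance import pdist

        assert np.allclose(pdist(flat3), np.sqrt(3) * pdist(flat1))
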