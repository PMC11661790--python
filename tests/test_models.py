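"""Model registry, training contract and tiled slice-wise inference."""

import numpy as np
import pytest

from tomoseg.annotate import TrainingSet
from tomoseg.core import Volume3D
from tomoseg.models import (
    TrainConfig,
    available_architectures,
    build_model,
    count_parameters,
    load_model,
    load_plugins,
    save_model,
    segment_volume,
    train_model,
)
from tomoseg.nn import Conv2D, Sequential

ARCHS = ["eman2_like", "vgg_small", "unet"]


def _toy_training_set(n=24, box=32, seed=0):
    """Bright blobs on noise; labels mark the blob disk."""
    rng = np.random.default_rng(seed)
    images = rng.normal(0, 0.3, size=(n, box, box)).astype(np.float32)
    labels = np.zeros_like(images)
    yy, xx = np.mgrid[:box, :box]
    for i in range(n):
        cy, cx = rng.integers(box // 4, box - box // 4, size=2)
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= 16
        images[i][mask] += 2.0
        labels[i][mask] = 1.0
    images = (images - images.mean(axis=(1, 2), keepdims=True)) / images.std(
        axis=(1, 2), keepdims=True
    )
    return TrainingSet("blob", box, images, labels, pixel_size=10.0, counts=(n, 0))


class TestRegistry:
    @pytest.mark.parametrize("arch", ARCHS)
    def test_contract_output_shape_and_range(self, arch, rng):
        model = build_model(arch, 64, seed=0)
        x = rng.random((2, 64, 64, 1), dtype=np.float32)
        p = model.network.predict(x)
        assert p.shape == (2, 64, 64, 1)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_unknown_architecture_lists_available(self):
        with pytest.raises(KeyError, match="unet"):
            build_model("nonexistent", 64)

    def test_incompatible_box_size_explains_constraint(self):
        with pytest.raises(ValueError, match="multiple of 4"):
            build_model("unet", 50)

    def test_seeded_builds_identical(self, rng):
        x = rng.random((1, 64, 64, 1), dtype=np.float32)
        a = build_model("unet", 64, seed=7).network.predict(x)
        b = build_model("unet", 64, seed=7).network.predict(x)
        np.testing.assert_array_equal(a, b)
        c = build_model("unet", 64, seed=8).network.predict(x)
        assert not np.array_equal(a, c)

    def test_plugin_autoregistration(self, tmp_path, rng):
        (tmp_path / "myarch.py").write_text(
            "import numpy as np\n"
            "from tomoseg.nn import Conv2D, ReLU, Sequential\n"
            "ARCH_NAME = 'plugin_tiny'\n"
            "DOWNSAMPLE = 1\n"
            "def build(box_size, rng):\n"
            "    return Sequential([Conv2D(1, 2, 3, rng), ReLU(), Conv2D(2, 1, 3, rng)])\n"
        )
        names = load_plugins(tmp_path)
        assert names == ["plugin_tiny"]
        assert "plugin_tiny" in available_architectures()
        model = build_model("plugin_tiny", 16, seed=0)
        p = model.network.predict(rng.random((1, 16, 16, 1), dtype=np.float32))
        assert p.shape == (1, 16, 16, 1)

    def test_malformed_plugin_rejected(self, tmp_path):
        (tmp_path / "bad.py").write_text("ARCH_NAME = 'incomplete'\n")
        with pytest.raises(ValueError, match="DOWNSAMPLE"):
            load_plugins(tmp_path)


class TestCountParameters:
    def test_single_conv(self):
        model = build_model("eman2_like", 64, seed=0)
        net = Sequential([Conv2D(1, 8, 3, np.random.default_rng(0))])
        model.network = net
        assert count_parameters(model) == 3 * 3 * 1 * 8 + 8  # 80

    def test_stacked_convs(self):
        rng = np.random.default_rng(0)
        model = build_model("eman2_like", 64, seed=0)
        model.network = Sequential([Conv2D(1, 8, 3, rng), Conv2D(8, 8, 3, rng)])
        assert count_parameters(model) == 80 + (3 * 3 * 8 * 8 + 8)  # 80 + 584

    def test_unet_matches_layer_shape_sum(self):
        model = build_model("unet", 64, seed=0)
        expected = sum(w.size for w, _ in model.network.params())
        # independent per-layer summation over the known block structure
        def block(cin, cmid):
            return (3 * 3 * cin * cmid + cmid) + (3 * 3 * cmid * cmid + cmid)

        manual = (
            block(1, 8) + block(8, 16) + block(16, 32)
            + block(48, 16) + block(24, 8) + (1 * 1 * 8 * 1 + 1)
        )
        assert count_parameters(model) == expected == manual


class TestTraining:
    def test_loss_history_length_matches_epochs(self):
        ts = _toy_training_set(n=8, box=16)
        model = build_model("eman2_like", 16, seed=0)
        train_model(model, ts, TrainConfig(epochs=7, batch_size=4, seed=0))
        assert len(model.loss_history) == 7

    def test_all_zero_labels_drive_predictions_down(self):
        ts = _toy_training_set(n=8, box=16)
        ts.labels[:] = 0.0
        model = build_model("eman2_like", 16, seed=0)
        train_model(model, ts, TrainConfig(epochs=12, batch_size=4, seed=0))
        preds = model.network.predict(ts.images[..., None])
        assert preds.mean() < 0.1

    def test_learning_reduces_loss(self):
        ts = _toy_training_set(n=24, box=32)
        model = build_model("eman2_like", 32, seed=1)
        train_model(model, ts, TrainConfig(epochs=8, batch_size=8, seed=1))
        assert model.loss_history[-1] < model.loss_history[0]

    def test_reproducible_from_seeds(self):
        ts = _toy_training_set(n=8, box=16)
        runs = []
        for _ in range(2):
            model = build_model("vgg_small", 16, seed=3)
            train_model(model, ts, TrainConfig(epochs=2, batch_size=4, seed=5))
            runs.append(model.network.predict(ts.images[:2][..., None]))
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_validation_split_reports_validation_loss(self):
        ts = _toy_training_set(n=20, box=16)
        model = build_model("eman2_like", 16, seed=0)
        train_model(model, ts, TrainConfig(epochs=2, batch_size=8,
                                           validation_split=0.25, seed=0))
        assert len(model.loss_history) == 2

    def test_box_size_mismatch_rejected(self):
        ts = _toy_training_set(n=4, box=16)
        model = build_model("eman2_like", 32, seed=0)
        with pytest.raises(ValueError, match="box"):
            train_model(model, ts, TrainConfig(epochs=1))


class TestSegmentVolume:
    def _trained_blob_model(self, box=32):
        model = build_model("eman2_like", box, seed=2)
        train_model(model, _toy_training_set(n=24, box=box),
                    TrainConfig(epochs=30, batch_size=8, seed=2))
        return model

    def test_single_tile_identity(self):
        # slice exactly box-sized with stride = box: output == one patch prediction
        from tomoseg.annotate import normalize_patch

        model = build_model("eman2_like", 32, seed=0)
        vol = Volume3D(np.random.default_rng(0).random((2, 32, 32), dtype=np.float32))
        out = segment_volume(model, vol, stride=32)
        patch = normalize_patch(vol.data[0])[None, :, :, None]
        expected = model.network.predict(patch)[0, :, :, 0]
        np.testing.assert_allclose(out.data[0], expected, atol=1e-6)

    def test_constant_input_gives_constant_output(self):
        model = build_model("eman2_like", 32, seed=0)
        vol = Volume3D(np.full((1, 80, 80), 5.0, dtype=np.float32))
        out = segment_volume(model, vol, stride=16)
        assert out.data.max() - out.data.min() <= 1e-6

    def test_output_shape_range_and_small_slice_padding(self):
        model = build_model("eman2_like", 32, seed=0)
        vol = Volume3D(np.random.default_rng(1).random((2, 20, 25), dtype=np.float32))
        out = segment_volume(model, vol, stride=16)  # slice smaller than box
        assert out.data.shape == vol.data.shape
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_blob_recovery_iou(self):
        # phantom recovery: trained detector finds planted blobs
        model = self._trained_blob_model(box=32)
        rng = np.random.default_rng(9)
        vol = np.random.default_rng(10).normal(0, 0.3, size=(3, 64, 64)).astype(np.float32)
        truth = np.zeros_like(vol)
        yy, xx = np.mgrid[:64, :64]
        for z in range(3):
            cy, cx = rng.integers(10, 54, size=2)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= 16
            vol[z][mask] += 2.0
            truth[z][mask] = 1.0
        out = segment_volume(model, Volume3D(vol), stride=16)
        pred = out.data >= 0.5
        gt = truth > 0.5
        iou = (pred & gt).sum() / (pred | gt).sum()
        assert iou >= 0.8


def test_model_bundle_round_trip(tmp_path, rng):
    model = build_model("vgg_small", 32, seed=4, feature_name="membrane",
                        training_pixel_size=10.0)
    model.loss_history = [0.5, 0.25]
    model.default_threshold = 0.4
    save_model(model, tmp_path / "bundle")
    back = load_model(tmp_path / "bundle")
    assert back.feature_name == "membrane"
    assert back.training_pixel_size == 10.0
    assert back.default_threshold == 0.4
    assert back.loss_history == [0.5, 0.25]
    x = rng.random((1, 32, 32, 1), dtype=np.float32)
    np.testing.assert_array_equal(model.network.predict(x), back.network.predict(x))
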