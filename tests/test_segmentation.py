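"""U-Net geometry, schedule semantics, metrics, and small-scale training."""

import numpy as np
import pytest

from stromaprog import _nn
from stromaprog.segmentation import (
    GeometryError,
    PlateauSchedule,
    TrainConfig,
    UNet,
    UNetSpec,
    geometry_trace,
    output_size,
    segmentation_metrics,
)
from stromaprog.synthetic import SceneParams, generate_tile_scene
from stromaprog.tiling import IGNORE


class TestGeometry:
    def test_396_maps_to_212(self):
        assert output_size(396, UNetSpec()) == 212

    def test_classic_572_maps_to_388(self):
        assert output_size(572, UNetSpec()) == 388

    def test_depth_zero_two_convs_lose_four(self):
        assert output_size(572, UNetSpec(depth=0)) == 568

    def test_margin_is_92(self):
        assert (396 - output_size(396, UNetSpec())) // 2 == 92

    @pytest.mark.parametrize("bad_input", [50, 397, 100])
    def test_invalid_geometry_raises_with_stage_name(self, bad_input):
        with pytest.raises(GeometryError):
            output_size(bad_input, UNetSpec())

    def test_trace_consistent_with_built_model(self, small_spec):
        """Skip-connection crops must match the encoder sizes of the trace."""
        tr = geometry_trace(small_spec.input_px, small_spec)
        net = UNet(small_spec, seed=0)
        x = np.zeros((1, small_spec.input_px, small_spec.input_px, 3), np.float32)
        logits = net.forward(x)
        assert logits.shape[1] == tr["output_px"]
        assert [s.shape[1] for s in net._skips] == tr["encoder_sizes"]


class TestForward:
    def test_softmax_normalized(self, small_spec, rng):
        net = UNet(small_spec, seed=0)
        x = rng.integers(0, 255, (92, 92, 3)).astype(np.uint8)
        p = net.predict_proba(x)
        np.testing.assert_allclose(p.sum(axis=-1), 1.0, atol=1e-5)

    def test_eval_mode_deterministic_despite_dropout(self, small_spec, rng):
        net = UNet(small_spec, seed=0)  # dropout_rate 0.10 by default
        x = rng.integers(0, 255, (92, 92, 3)).astype(np.uint8)
        np.testing.assert_array_equal(net.predict_tile(x), net.predict_tile(x))

    def test_predictions_in_class_range(self, small_spec, rng):
        net = UNet(small_spec, seed=1)
        x = rng.integers(0, 255, (92, 92, 3)).astype(np.uint8)
        assert set(np.unique(net.predict_tile(x))) <= {0, 1, 2}

    def test_wrong_tile_size_rejected(self, small_spec):
        net = UNet(small_spec, seed=0)
        with pytest.raises(ValueError):
            net.predict_tile(np.zeros((100, 100, 3), np.uint8))

    def test_argmax_ties_break_to_lower_class(self):
        probs = np.array([[0.4, 0.4, 0.2], [0.3, 0.3, 0.3]])
        assert (probs.argmax(axis=-1) == 0).all()


class TestSchedule:
    def test_flat_losses_reduce_lr_exactly_once(self):
        s = PlateauSchedule(lr=1.0, factor=0.1, patience=3, stop_patience=5)
        for loss in [1.0, 1.0, 1.0, 1.0]:
            s.update(loss)
        assert s.n_reductions == 1
        assert s.lr == pytest.approx(0.1)

    def test_strictly_decreasing_loss_never_reduces_or_stops(self):
        s = PlateauSchedule(lr=1.0, factor=0.1, patience=3, stop_patience=5)
        stops = [s.update(loss) for loss in np.linspace(1.0, 0.1, 20)]
        assert s.n_reductions == 0
        assert not any(stops)

    def test_early_stop_after_patience_without_improvement(self):
        s = PlateauSchedule(lr=1.0, factor=0.1, patience=3, stop_patience=5)
        flags = [s.update(1.0) for _ in range(7)]
        assert flags[:5] == [False] * 5
        assert flags[5] is True  # 5th consecutive non-improving interval


class TestMetrics:
    def test_perfect_prediction(self, rng):
        t = rng.integers(0, 3, (32, 32)).astype(np.uint8)
        m = segmentation_metrics([t], [t])
        assert m.mean_iou == 1.0 and m.categorical_accuracy == 1.0

    def test_complement_two_class_gives_zero_iou(self):
        t = np.zeros((8, 8), np.uint8)
        t[:, 4:] = 1
        m = segmentation_metrics([1 - t], [t])
        assert np.nansum(m.per_class_iou) == 0.0

    def test_matches_brute_force_counts_on_random_masks(self, rng):
        preds = [rng.integers(0, 3, (8, 8)).astype(np.uint8) for _ in range(5)]
        truths = [rng.integers(0, 3, (8, 8)).astype(np.uint8) for _ in range(5)]
        m = segmentation_metrics(preds, truths)
        # exhaustive pixel loop oracle
        inter = np.zeros(3)
        union = np.zeros(3)
        correct = total = 0
        for p, t in zip(preds, truths):
            for i in range(8):
                for j in range(8):
                    correct += p[i, j] == t[i, j]
                    total += 1
                    for k in range(3):
                        a, b = p[i, j] == k, t[i, j] == k
                        inter[k] += a and b
                        union[k] += a or b
        np.testing.assert_allclose(m.per_class_iou, inter / union)
        assert m.categorical_accuracy == correct / total

    def test_ignored_pixels_excluded(self):
        t = np.zeros((4, 4), np.uint8)
        t[0] = IGNORE
        p = np.zeros((4, 4), np.uint8)
        p[0] = 2  # wrong only where ignored
        m = segmentation_metrics([p], [t])
        assert m.categorical_accuracy == 1.0


class TestTraining:
    def test_empty_dataset_rejected(self, small_spec):
        with pytest.raises(ValueError):
            UNet(small_spec, seed=0).fit([], TrainConfig())

    def test_learns_above_majority_baseline(self, small_spec):
        """A few epochs on small scenes beat the majority-class baseline."""
        tiles = []
        for s in range(10):
            rgb, mask = generate_tile_scene(
                SceneParams(image_size_px=(92, 92), tumor_gland_count=2,
                            lymphocyte_cluster_count=1, seed=s)
            )
            m = (92 - 52) // 2
            tiles.append((rgb, mask[m : m + 52, m : m + 52].copy()))
        labels = np.concatenate([t[1].ravel() for t in tiles])
        freq = np.bincount(labels, minlength=3)[:3]
        majority = freq.max() / labels.size
        weights = tuple(freq.sum() / (3.0 * freq))
        spec = UNetSpec(depth=2, base_channels=4, input_px=92)
        net = UNet(spec, seed=0)
        cfg = TrainConfig(batch_size=2, max_epochs=40, micro_batch=2, seed=0,
                          lr_init=3e-3, class_weights=weights)
        hist = net.fit(tiles, cfg)
        metrics = net.evaluate(tiles)
        assert metrics.categorical_accuracy > majority
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]

    def test_training_deterministic_given_seed(self, small_spec, rng):
        x = rng.integers(0, 255, (92, 92, 3)).astype(np.uint8)
        y = rng.integers(0, 3, (52, 52)).astype(np.uint8)
        spec = UNetSpec(depth=2, base_channels=2, input_px=92)
        outs = []
        for _ in range(2):
            net = UNet(spec, seed=3)
            net.fit([(x, y)], TrainConfig(batch_size=1, max_epochs=2,
                                          micro_batch=1, seed=7))
            outs.append(net.predict_proba(x))
        np.testing.assert_array_equal(outs[0], outs[1])
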