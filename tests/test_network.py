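import numpy as np
import pytest

from g4forge.dataset_builder import LabeledSequence
from g4forge.network import (
    G4Network,
    NetworkConfig,
    build_model,
    classify,
    encode_batch,
    load_model,
    one_hot_decode,
    one_hot_encode,
    save_model,
)

TINY = dict(input_length=32, conv_filters=(4, 3), kernel_size=4, pool_size=2,
            dense_units=8)


class TestOneHot:
    def test_acgt_is_identity(self):
        assert (one_hot_encode("ACGT", 4) == np.eye(4)).all()

    def test_n_rows_are_zero(self):
        assert (one_hot_encode("NN", 2) == 0).all()

    def test_decode_roundtrip(self):
        seq = "ACGTNNGTCA"
        assert one_hot_decode(one_hot_encode(seq, 10)) == seq

    def test_wrong_length(self):
        with pytest.raises(ValueError, match="length"):
            one_hot_encode("ACG", 4)

    def test_invalid_character(self):
        with pytest.raises(ValueError, match="invalid"):
            one_hot_encode("ACGU", 4)


class TestConfigAndArchitecture:
    def test_default_stack_matches_published_architecture(self):
        layers = build_model(NetworkConfig()).layer_summary()
        convs = [l for l in layers if l["kind"] == "conv1d"]
        assert [c["filters"] for c in convs] == [16, 8, 4, 3]
        assert all(c["kernel_size"] == 8 for c in convs)
        kinds = [l["kind"] for l in layers]
        assert kinds.count("batch_norm") == 4
        assert kinds.count("max_pool") == 4
        assert kinds.count("dropout") == 4
        assert layers[-1] == {"kind": "dense", "units": 1, "activation": "sigmoid"}

    def test_input_too_short_for_pooling_stages(self):
        with pytest.raises(ValueError, match="16"):
            NetworkConfig(input_length=8, conv_filters=(4, 3, 2, 2), pool_size=2)

    @pytest.mark.parametrize("bad", [{"dropout_rate": 1.0}, {"epochs": 0},
                                     {"conv_filters": ()}])
    def test_invalid_hyperparameters(self, bad):
        with pytest.raises(ValueError):
            NetworkConfig(**bad)


def _separable_set(n, length=32):
    half = n // 2
    pos = [LabeledSequence("G" * length, 1) for _ in range(half)]
    neg = [LabeledSequence("A" * length, 0) for _ in range(n - half)]
    return pos + neg


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        cfg = NetworkConfig(seed=0, epochs=3, **TINY)
        model = build_model(cfg).fit(_separable_set(500))
        assert model.history["loss"][-1] < model.history["loss"][0]
        assert len(model.history["loss"]) == cfg.epochs

    def test_memorizes_tiny_dataset(self, rng):
        # 64 random sequences with arbitrary labels, epochs raised to 200:
        # the full-size architecture must drive training accuracy to 1.0
        seqs = [
            LabeledSequence("".join("ACGT"[b] for b in rng.integers(0, 4, 200)), i % 2)
            for i in range(64)
        ]
        cfg = NetworkConfig(seed=1, epochs=200)
        model = build_model(cfg).fit(seqs)
        scores = model.predict([s.sequence for s in seqs])
        assert ((scores >= 0.5).astype(int) == [s.label for s in seqs]).all()

    def test_single_class_rejected(self):
        cfg = NetworkConfig(**TINY)
        with pytest.raises(ValueError, match="both classes"):
            build_model(cfg).fit([LabeledSequence("G" * 32, 1)] * 4)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_model(NetworkConfig(**TINY)).fit([])

    def test_validation_history_recorded(self):
        cfg = NetworkConfig(seed=0, epochs=2, **TINY)
        data = _separable_set(64)
        model = build_model(cfg).fit(data, data[:16])
        assert len(model.history["val_loss"]) == 2


class TestBackpropagation:
    def test_gradients_match_finite_differences(self, rng):
        cfg = NetworkConfig(seed=3, input_length=16, conv_filters=(3, 2),
                            kernel_size=3, pool_size=2, dense_units=4,
                            dropout_rate=0.0)
        model = build_model(cfg)
        # float64 weights so finite differences are not drowned by rounding
        for key in model.params:
            model.params[key] = model.params[key].astype(np.float64)
        x = rng.random((5, 16, 4)).astype(np.float32)
        y = np.array([1, 0, 1, 1, 0], dtype=np.float32)

        def loss():
            probs, caches = model.forward(x, training=True)
            logit = caches[-1]["logit"]
            return float(np.mean(np.maximum(logit, 0) - logit * y
                                 + np.log1p(np.exp(-np.abs(logit)))))

        probs, caches = model.forward(x, training=True)
        grads = model._backward(probs, y, caches)
        eps = 1e-4
        for key in ["conv0_W", "conv1_b", "bn0_gamma", "bn1_beta", "dense_W", "out_W"]:
            param = model.params[key]
            flat = param.reshape(-1)
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss()
                flat[idx] = orig - eps
                down = loss()
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                analytic = grads[key].reshape(-1)[idx]
                assert analytic == pytest.approx(fd, rel=5e-2, abs=2e-4), key


@pytest.fixture(scope="module")
def model():
    cfg = NetworkConfig(seed=2, epochs=2, **TINY)
    return build_model(cfg).fit(_separable_set(128))


class TestPrediction:
    def test_scores_in_unit_interval(self, model, rng):
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 32)) for _ in range(20)]
        scores = model.predict(seqs)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_inference_is_deterministic(self, model):
        seq = ["ACGT" * 8]
        assert model.predict(seq)[0] == model.predict(seq)[0]

    def test_batch_composition_invariance(self, model, rng):
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 32)) for _ in range(8)]
        alone = np.array([model.predict([s])[0] for s in seqs])
        together = model.predict(seqs)
        assert np.allclose(alone, together, atol=1e-6)

    def test_short_input_standardized_and_scored(self, model):
        scores = model.predict(["GGGAGGGAGGGAGGG"])  # 15 nt -> padded to 32
        assert 0.0 <= scores[0] <= 1.0

    def test_empty_input(self, model):
        assert model.predict([]).size == 0


class TestOcclusionForward:
    def test_strip_update_equals_full_forward(self, rng):
        eye = np.eye(4, dtype=np.float32)
        for cfg in [
            NetworkConfig(seed=5, input_length=50, conv_filters=(5, 3),
                          kernel_size=3, pool_size=2),
            NetworkConfig(seed=6, input_length=37, conv_filters=(4, 3, 2),
                          kernel_size=5, pool_size=3),
        ]:
            model = build_model(cfg)
            for key in model.bn_stats:  # non-trivial inference affine
                model.bn_stats[key] = (
                    np.abs(rng.normal(1, 0.3, model.bn_stats[key].shape)) + 0.1
                ).astype(np.float32)
            length = cfg.input_length
            base = eye[rng.integers(0, 4, length)]
            cache = model.occlusion_cache(base)
            w = 9
            for start in [0, 1, length - w, (length - w) // 2]:
                fills = eye[rng.integers(0, 4, (6, w))]
                fast = model.score_window_variants(cache, start, fills)
                full = np.repeat(base[None], 6, axis=0)
                full[:, start : start + w] = fills
                assert np.allclose(fast, model.predict_encoded(full), atol=1e-5)


class TestClassify:
    @pytest.mark.parametrize(
        "score,mode,expected",
        [
            (0.9, "precise", True),
            (0.6, "sensitive", True),
            (0.6, "precise", False),
            (0.85, "precise", True),
            (0.5, "sensitive", True),
            (0.4999, "sensitive", False),
        ],
    )
    def test_named_thresholds(self, score, mode, expected):
        assert classify(score, mode) is expected

    def test_custom_threshold(self):
        assert classify(0.3, "custom", 0.25) is True
        with pytest.raises(ValueError, match="custom_threshold"):
            classify(0.3, "custom")

    def test_score_out_of_range(self):
        with pytest.raises(ValueError):
            classify(1.5, "sensitive")


class TestPersistence:
    def test_roundtrip_identical_scores(self, tmp_path, rng):
        cfg = NetworkConfig(seed=4, epochs=2, **TINY)
        model = build_model(cfg).fit(_separable_set(64))
        path = tmp_path / "m.npz"
        save_model(model, path)
        loaded = load_model(path)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 32)) for _ in range(100)]
        assert (model.predict(seqs) == loaded.predict(seqs)).all()
        assert loaded.config == model.config
        assert loaded.history["loss"] == model.history["loss"]

    def test_truncated_file_rejected(self, tmp_path):
        cfg = NetworkConfig(seed=4, **TINY)
        path = tmp_path / "m.npz"
        save_model(build_model(cfg), path)
        path.write_bytes(path.read_bytes()[:100])
        with pytest.raises(ValueError, match="cannot load"):
            load_model(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "absent.npz")
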