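"""Multitask classifier: construction, transfer, training and inference."""

import numpy as np
import pytest

from deepbeat import cdae as cdae_mod
from deepbeat import model as mm
from deepbeat import nn
from deepbeat.types import ValidationError


@pytest.fixture(scope="module")
def toy_data():
    """Small separable two-class window set (amplitude-coded classes)."""
    rng = np.random.default_rng(0)
    t = np.arange(800) / 32.0
    X, y = [], []
    for i in range(96):
        f = rng.uniform(1.0, 1.3) if i % 2 else rng.uniform(1.8, 2.2)
        X.append(np.clip(np.sin(2 * np.pi * f * t), 0, None)
                 + 0.05 * rng.normal(size=800))
        y.append(i % 2)
    X = np.stack(X)
    y = np.array(y)
    qa = rng.integers(0, 3, size=len(y))
    return X[:64], y[:64], qa[:64], X[64:], y[64:], qa[64:]


class TestConstruction:
    def test_multitask_has_both_heads_single_task_one(self):
        mt = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        st = mm.build_deepbeat(mm.Variant.ST_RANDOM, seed=0)
        assert mt.qa_head is not None
        assert st.qa_head is None

    def test_six_shared_hidden_conv_layers(self):
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        convs = [l for l in net.trunk.layers if isinstance(l, nn.Conv1D)]
        assert len(convs) == 6

    def test_same_seed_identical_initialization(self):
        a = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=4)
        b = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=4)
        for pa, pb in zip(a.params, b.params):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_heads_share_no_parameters(self):
        """QA-arm gradients can only reach the event arm through the shared
        trunk: the two heads hold disjoint parameter objects."""
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        event_ids = {id(p) for p in net.event_head.params}
        qa_ids = {id(p) for p in net.qa_head.params}
        assert event_ids.isdisjoint(qa_ids)

    def test_incompatible_input_length_rejected(self):
        with pytest.raises(ValidationError):
            mm.build_deepbeat(mm.Variant.ST_RANDOM, input_length=801)

    def test_parameter_count_positive_and_reported(self):
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        assert net.parameter_count() > 10000


class TestTransfer:
    def _encoder(self, seed=0, filters=(32, 16, 8)):
        cfg = cdae_mod.CdaeConfig(seed=seed, enc_filters=filters,
                                  dec_filters=(16, 32))
        return cdae_mod.extract_encoder(cdae_mod.build_cdae(cfg))

    def test_trunk_layer3_activations_equal_cdae_encoder(self):
        cfg = cdae_mod.CdaeConfig(seed=8)
        source = cdae_mod.build_cdae(cfg)
        enc = cdae_mod.extract_encoder(source)
        net = mm.build_deepbeat(mm.Variant.MT_PRETRAINED, seed=1)
        net.transfer_encoder_weights(enc)
        x = np.random.default_rng(2).random((100, 800))
        a = source.encode(x)
        b = net.encoder_activations(x)
        assert np.max(np.abs(a - b)) < 1e-6

    def test_transfer_idempotent(self):
        enc = self._encoder()
        net = mm.build_deepbeat(mm.Variant.MT_PRETRAINED, seed=1)
        net.transfer_encoder_weights(enc)
        once = net.get_state()
        net.transfer_encoder_weights(enc)
        for k, v in net.get_state().items():
            np.testing.assert_array_equal(v, once[k])

    def test_random_variants_refuse_transfer(self):
        enc = self._encoder()
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=1)
        with pytest.raises(ValidationError, match="random initialization"):
            net.transfer_encoder_weights(enc)

    def test_shape_mismatch_lists_expected_and_actual(self):
        enc = self._encoder(filters=(16, 8, 4))
        net = mm.build_deepbeat(mm.Variant.MT_PRETRAINED, seed=1)
        with pytest.raises(ValidationError, match="shape mismatch"):
            net.transfer_encoder_weights(enc)

    def test_transferred_layers_remain_trainable(self, toy_data):
        Xtr, ytr, qtr, Xva, yva, qva = toy_data
        enc = self._encoder()
        net = mm.build_deepbeat(mm.Variant.MT_PRETRAINED, seed=1)
        net.transfer_encoder_weights(enc)
        before = [p.value.copy() for p in net._transferred_params]
        mm.train(net, Xtr, ytr, qtr, Xva, yva, qva,
                 mm.TrainConfig(epochs=1, seed=0, batch=16))
        after = [p.value for p in net._transferred_params]
        assert any(np.any(a != b) for a, b in zip(before, after))


class TestTraining:
    def test_single_task_loss_equals_multitask_with_zero_qa_weight(
            self, toy_data):
        """At epoch 1 with identical seeds, an MT graph trained with
        w_qa=0 follows the ST loss trajectory."""
        Xtr, ytr, qtr, Xva, yva, qva = toy_data
        mt = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=3)
        st = mm.build_deepbeat(mm.Variant.ST_RANDOM, seed=3)
        cfg = mm.TrainConfig(epochs=1, seed=5, batch=16, w_qa=0.0)
        h_mt = mm.train(mt, Xtr, ytr, qtr, Xva, yva, qva, cfg)
        h_st = mm.train(st, Xtr, ytr, None, Xva, yva, None, cfg)
        assert h_mt["af_loss"][0] == pytest.approx(h_st["af_loss"][0],
                                                   rel=1e-6)

    def test_single_class_training_labels_rejected(self, toy_data):
        Xtr, ytr, qtr, Xva, yva, qva = toy_data
        net = mm.build_deepbeat(mm.Variant.ST_RANDOM, seed=0)
        with pytest.raises(ValidationError):
            mm.train(net, Xtr, np.zeros_like(ytr), None, Xva, yva, None,
                     mm.TrainConfig(epochs=1))

    def test_history_tracks_validation_f1_checkpointing(self, toy_data):
        Xtr, ytr, qtr, Xva, yva, qva = toy_data
        net = mm.build_deepbeat(mm.Variant.ST_RANDOM, seed=0)
        h = mm.train(net, Xtr, ytr, None, Xva, yva, None,
                     mm.TrainConfig(epochs=3, seed=1, batch=16))
        assert len(h["val_f1"]) == 3
        # the restored checkpoint reproduces the best recorded validation F1
        from deepbeat.evaluate import evaluate_labels
        probs, _ = net.predict_proba(Xva)
        f1 = evaluate_labels(list(yva), list(probs.argmax(axis=1)),
                             [0, 1]).aggregate["f1"]
        assert f1 == pytest.approx(max(h["val_f1"]), abs=1e-9)

    def test_training_reproducible_from_seed(self, toy_data):
        Xtr, ytr, qtr, Xva, yva, qva = toy_data
        outs = []
        for _ in range(2):
            net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=2)
            mm.train(net, Xtr, ytr, qtr, Xva, yva, qva,
                     mm.TrainConfig(epochs=2, seed=9, batch=16))
            probs, _ = net.predict_proba(Xva)
            outs.append(probs)
        np.testing.assert_array_equal(outs[0], outs[1])


class TestInference:
    def test_probabilities_sum_to_one(self, toy_data):
        Xtr, *_ = toy_data
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        records = net.predict(Xtr[:8])
        for r in records:
            assert r.af_probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert r.qa_probs.sum() == pytest.approx(1.0, abs=1e-6)
            assert r.af_pred == int(np.argmax(r.af_probs))

    def test_repeated_inference_identical(self, toy_data):
        Xtr, *_ = toy_data
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        a, _ = net.predict_proba(Xtr[:8])
        b, _ = net.predict_proba(Xtr[:8])
        np.testing.assert_array_equal(a, b)

    def test_batch_size_invariance(self, toy_data):
        Xtr, *_ = toy_data
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        one, _ = net.predict_proba(Xtr, batch=1)
        big, _ = net.predict_proba(Xtr, batch=256)
        assert np.max(np.abs(one - big)) < 1e-5

    def test_wrong_window_length_rejected(self):
        net = mm.build_deepbeat(mm.Variant.ST_RANDOM, seed=0)
        with pytest.raises(ValidationError):
            net.predict_proba(np.zeros((2, 700)))

    def test_embedding_dimension_and_determinism(self, toy_data):
        Xtr, *_ = toy_data
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        emb = net.embed(Xtr[:6])
        assert emb.shape == (6, net.event_cfg.dense)
        assert np.all(np.isfinite(emb))
        # identical windows give identical embeddings up to float blocking
        np.testing.assert_allclose(net.embed(Xtr[:1])[0],
                                   net.embed(Xtr[:6])[0], atol=1e-5)

    def test_checkpoint_roundtrip(self, tmp_path, toy_data):
        Xtr, *_ = toy_data
        net = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=0)
        net.save(tmp_path / "model.npz")
        clone = mm.build_deepbeat(mm.Variant.MT_RANDOM, seed=1)
        clone.load(tmp_path / "model.npz")
        a, _ = net.predict_proba(Xtr[:4])
        b, _ = clone.predict_proba(Xtr[:4])
        np.testing.assert_array_equal(a, b)
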