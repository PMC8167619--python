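"""Attention Bi-LSTM: gradients, masking/batching invariances, splitting,
training contracts, baseline."""

import numpy as np
import pytest

from bilirad.classifier import (
    AttentionBiLSTM,
    ClassifierConfig,
    baseline_logistic,
    encode,
    encode_batch,
    predict_batch,
    stratified_split,
    train,
)
from bilirad.mapping import MappingModel
from bilirad.nn import cross_entropy
from bilirad.reports import LABELS, Label, Modality, Report
from bilirad.synth import SynthConfig, generate_corpus


def tiny_config(**kw):
    base = dict(embedding_dim=24, hidden_per_direction=8, attention_dim=8, max_len=16,
                dropout=0.0, seed=2)
    base.update(kw)
    return ClassifierConfig(**base)


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        cfg = ClassifierConfig(embedding_dim=5, hidden_per_direction=4, attention_dim=3,
                               max_len=6, dropout=0.0, seed=3)
        m = AttentionBiLSTM(cfg)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 6, 5))
        mask = np.ones((3, 6))
        mask[0, 4:] = 0
        mask[1, 3:] = 0
        y = np.array([0, 1, 2])
        probs, _ = m.forward_batch(x, mask)
        grads = m.backward_batch(probs, y)
        eps = 1e-6
        for key, param in m.parameters().items():
            for idx in [tuple(rng.integers(0, s) for s in param.shape) for _ in range(4)]:
                orig = param[idx]
                param[idx] = orig + eps
                lp = cross_entropy(m.forward_batch(x, mask)[0], y)
                param[idx] = orig - eps
                lm = cross_entropy(m.forward_batch(x, mask)[0], y)
                param[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-7), key


class TestForwardInvariants:
    def test_single_token_attention_is_one(self):
        cfg = tiny_config()
        m = AttentionBiLSTM(cfg)
        x = np.zeros((1, cfg.max_len, cfg.embedding_dim))
        x[0, 0] = 1.0
        mask = np.zeros((1, cfg.max_len))
        mask[0, 0] = 1
        probs, alpha = m.forward_batch(x, mask)
        assert alpha[0, 0] == pytest.approx(1.0)
        assert probs[0].sum() == pytest.approx(1.0, abs=1e-6)

    def test_padding_never_changes_probabilities(self):
        cfg = tiny_config(max_len=12)
        m = AttentionBiLSTM(cfg)
        rng = np.random.default_rng(1)
        x_short = np.zeros((1, 12, cfg.embedding_dim))
        x_short[0, :5] = rng.standard_normal((5, cfg.embedding_dim))
        mask_short = np.zeros((1, 12))
        mask_short[0, :5] = 1
        x_garbage = x_short.copy()
        x_garbage[0, 5:] = 99.0  # pads hold arbitrary values
        p1, _ = m.forward_batch(x_short, mask_short)
        p2, _ = m.forward_batch(x_garbage, mask_short)
        assert np.abs(p1 - p2).max() <= 1e-12

    def test_zeroed_output_layer_gives_uniform(self):
        cfg = tiny_config()
        m = AttentionBiLSTM(cfg)
        m.out.W[...] = 0
        m.out.b[...] = 0
        x = np.random.default_rng(0).standard_normal((2, cfg.max_len, cfg.embedding_dim))
        probs, _ = m.forward_batch(x, np.ones((2, cfg.max_len)))
        assert np.abs(probs - 1 / 3).max() <= 1e-12

    def test_fully_masked_errors(self):
        cfg = tiny_config()
        m = AttentionBiLSTM(cfg)
        with pytest.raises(ValueError):
            m.forward_batch(np.zeros((1, cfg.max_len, cfg.embedding_dim)),
                            np.zeros((1, cfg.max_len)))

    def test_attention_weights_nonnegative_and_sum_to_one(self):
        cfg = tiny_config()
        m = AttentionBiLSTM(cfg)
        rng = np.random.default_rng(4)
        x = rng.standard_normal((5, cfg.max_len, cfg.embedding_dim))
        mask = (rng.random((5, cfg.max_len)) < 0.7).astype(float)
        mask[:, 0] = 1
        preds = m.predict(x, mask)
        for p, msk in zip(preds, mask):
            assert (p.attention_weights >= 0).all()
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-6)
            # weights cover exactly the unmasked prefix recorded in token_count
            assert p.token_count == int(msk.sum())


class TestEncode:
    def test_mapping_touches_only_hangul(self, tiny_embedding):
        rng = np.random.default_rng(0)
        q, _ = np.linalg.qr(rng.standard_normal((24, 24)))
        mm = MappingModel(transform=q)
        text = "consolidation in rll lobe"
        x1, m1, _ = encode(text, tiny_embedding, mapping=mm, max_len=8)
        x2, m2, _ = encode(text, tiny_embedding, mapping=None, max_len=8)
        assert np.array_equal(x1, x2) and np.array_equal(m1, m2)

    def test_identity_mapping_matches_source_vector(self, tiny_embedding):
        mm = MappingModel(transform=np.eye(24))
        x1, _, _ = encode("의심", tiny_embedding, mapping=mm, max_len=4)
        x2, _, _ = encode("의심", tiny_embedding, mapping=None, max_len=4)
        assert np.allclose(x1, x2)

    def test_truncation_to_max_len(self, tiny_embedding):
        text = " ".join(["ggo"] * 30)
        x, mask, kept = encode(text, tiny_embedding, max_len=10)
        assert x.shape == (10, 24) and mask.sum() == 10 and len(kept) == 10

    def test_token_vectors_unit_norm(self, tiny_embedding):
        x, mask, _ = encode("consolidation 의심 ggo", tiny_embedding, max_len=8)
        norms = np.linalg.norm(x[mask > 0], axis=1)
        assert np.allclose(norms[norms > 0], 1.0)


class TestStratifiedSplit:
    @staticmethod
    def _reports(counts):
        out = []
        for lab, n in zip(LABELS, counts):
            out += [Report(f"{lab.name}{i}", Modality.CT, "GGO", lab) for i in range(n)]
        return out

    def test_per_class_arithmetic(self):
        tr, te = stratified_split(self._reports((60, 30, 10)), 0.2, seed=1)
        te_counts = [sum(r.label is lab for r in te) for lab in LABELS]
        assert te_counts == [12, 6, 2]
        assert len(tr) + len(te) == 100
        assert {r.id for r in tr}.isdisjoint({r.id for r in te})

    def test_published_class_mix_yields_published_test_counts(self):
        tr, te = stratified_split(self._reports((4005, 895, 550)), 0.2, seed=3)
        te_counts = [sum(r.label is lab for r in te) for lab in LABELS]
        assert te_counts == [801, 179, 110]

    def test_same_seed_identical(self):
        pool = self._reports((20, 10, 5))
        a = stratified_split(pool, 0.3, seed=9)
        b = stratified_split(pool, 0.3, seed=9)
        assert a == b

    def test_empty_class_warns(self):
        with pytest.warns(UserWarning, match="no members"):
            stratified_split(self._reports((10, 5, 0)), 0.2, seed=1)


@pytest.fixture(scope="module")
def trained_tiny(tiny_embedding, small_corpus):
    """One small end-to-end training used by several contract tests."""
    reports, _ = small_corpus
    tr, te = stratified_split(reports, 0.2, seed=4)
    cfg = ClassifierConfig(embedding_dim=24, hidden_per_direction=16, attention_dim=16,
                           max_len=64, dropout=0.1, learning_rate=3e-3, max_epochs=8,
                           patience=3, seed=4)
    model, history = train(cfg, tr, tiny_embedding)
    return model, history, tr, te


class TestTraining:
    def test_history_and_early_stopping_contract(self, trained_tiny):
        _, hist, _, _ = trained_tiny
        assert hist.epochs == list(range(1, len(hist.epochs) + 1))
        best = hist.val_loss[hist.best_epoch - 1]
        assert best <= hist.val_loss[0]
        assert best == min(hist.val_loss)

    def test_checkpoint_roundtrip_identical_predictions(self, trained_tiny, tiny_embedding,
                                                        tmp_path):
        model, _, _, te = trained_tiny
        p = tmp_path / "model.zip"
        model.save(p)
        again = AttentionBiLSTM.load(p)
        a = predict_batch(model, te[:20], tiny_embedding)
        b = predict_batch(again, te[:20], tiny_embedding)
        for x, y in zip(a, b):
            assert np.array_equal(x.probabilities, y.probabilities)

    def test_empty_training_set_errors(self, tiny_embedding):
        with pytest.raises(ValueError):
            train(tiny_config(), [], tiny_embedding)


class TestPredictBatch:
    def test_batch_size_invariance(self, trained_tiny, tiny_embedding):
        model, _, _, te = trained_tiny
        one = predict_batch(model, te[:17], tiny_embedding, batch_size=1)
        many = predict_batch(model, te[:17], tiny_embedding, batch_size=32)
        for a, b in zip(one, many):
            assert np.abs(a.probabilities - b.probabilities).max() <= 1e-6

    def test_order_preserved_under_shuffle(self, trained_tiny, tiny_embedding):
        model, _, _, te = trained_tiny
        sub = te[:10]
        fwd = predict_batch(model, sub, tiny_embedding)
        rev = predict_batch(model, sub[::-1], tiny_embedding)
        for a, b in zip(fwd, rev[::-1]):
            assert np.abs(a.probabilities - b.probabilities).max() <= 1e-9

    def test_empty_list(self, trained_tiny, tiny_embedding):
        model, _, _, _ = trained_tiny
        assert predict_batch(model, [], tiny_embedding) == []


class TestOrderRegime:
    def test_model_beats_bag_of_ngrams_on_order_dependent_obscure(self, tiny_embedding):
        """When negative vs obscure is decided by cue ORDER (same token
        bag), the recurrent model's obscure F1 exceeds the bag-of-substring
        baseline's, which is blind to order by construction."""
        from bilirad.metrics import evaluate as ev

        cfg = SynthConfig(n_reports=900, cue_noise=0.0, order_regime=True, seed=21,
                          class_priors=(0.45, 0.1, 0.45))
        reports, _ = generate_corpus(cfg)
        tr, te = stratified_split(reports, 0.25, seed=21)
        true = [r.label for r in te]

        base_preds, base_probs = baseline_logistic(tr, te, seed=0)
        base_f1 = ev((base_preds, base_probs), true).per_class["obscure"].f1

        ccfg = ClassifierConfig(embedding_dim=24, hidden_per_direction=24, attention_dim=24,
                                max_len=64, dropout=0.1, learning_rate=3e-3,
                                max_epochs=20, patience=5, seed=21)
        model, _ = train(ccfg, tr, tiny_embedding)
        preds = predict_batch(model, te, tiny_embedding)
        model_f1 = ev(preds, true).per_class["obscure"].f1
        assert model_f1 > base_f1
        assert model_f1 >= 0.7  # order rule actually learned, not a coin flip


class TestBaseline:
    def test_separable_corpus_high_accuracy(self, small_corpus):
        reports, _ = small_corpus
        tr, te = stratified_split(reports, 0.2, seed=6)
        preds, _ = baseline_logistic(tr, te, seed=0)
        acc = np.mean([p is r.label for p, r in zip(preds, te)])
        assert acc >= 0.9

    def test_single_class_train_set(self):
        tr = [Report(f"t{i}", Modality.CT, f"GGO filler{i}", Label.POSITIVE) for i in range(10)]
        te = [Report("e", Modality.CT, "something else", Label.NEGATIVE)]
        preds, probs = baseline_logistic(tr, te, seed=0)
        assert preds == [Label.POSITIVE]
        assert probs[0, Label.POSITIVE.value] == pytest.approx(1.0)

    def test_deterministic(self, small_corpus):
        reports, _ = small_corpus
        tr, te = stratified_split(reports, 0.2, seed=6)
        a = baseline_logistic(tr, te[:30], seed=1)[1]
        b = baseline_logistic(tr, te[:30], seed=1)[1]
        assert np.array_equal(a, b)
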