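"""Cross-lingual mapping: Procrustes oracles, CSLS, dictionary induction."""

import warnings

import numpy as np
import pytest

from bilirad.mapping import (
    MappingModel,
    csls_neighbors,
    induce_dictionary,
    procrustes,
    seed_dictionary,
    train_mapping,
    translate_embedding,
    load_transform,
    save_transform,
)
from bilirad.subword import EmbeddingConfig, SubwordEmbedding
from bilirad.synth import generate_planted_rotation


def _word_embedding(words, vectors):
    return SubwordEmbedding(
        words=list(words),
        word_vectors=np.asarray(vectors, dtype=float),
        ngrams={},
        ngram_vectors=np.zeros((0, np.asarray(vectors).shape[1])),
        config=EmbeddingConfig(dim=np.asarray(vectors).shape[1], ngram_min=2, ngram_max=2),
    )


class TestProcrustes:
    def test_identity_pairing(self):
        rng = np.random.default_rng(0)
        s = rng.standard_normal((30, 5))
        w = procrustes(s, s)
        assert np.abs(w - np.eye(5)).max() <= 1e-10

    def test_recovers_planted_rotation_exactly(self):
        fx = generate_planted_rotation(100, 10, 0.0, 3)
        w = procrustes(fx.source_matrix, fx.target_matrix)
        assert np.linalg.norm(w - fx.planted_transform) <= 1e-6

    def test_noise_robust_recovery_over_seeds(self):
        for seed in range(5):
            fx = generate_planted_rotation(100, 10, 0.01, seed)
            w = procrustes(fx.source_matrix, fx.target_matrix)
            assert np.linalg.norm(w - fx.planted_transform) <= 0.1

    def test_underdetermined_errors(self):
        with pytest.raises(ValueError):
            procrustes(np.ones((1, 2)), np.ones((1, 2)))

    def test_equals_bruteforce_rotation_search_2d(self):
        """Exhaustive angle grid (with/without reflection) as an
        independent minimizer for d=2."""
        rng = np.random.default_rng(5)
        angles = np.arange(0, 2 * np.pi, 1e-3)
        cos, sin = np.cos(angles), np.sin(angles)
        for _ in range(5):
            s = rng.standard_normal((12, 2))
            t = rng.standard_normal((12, 2))
            w = procrustes(s, t)
            best = np.inf
            for c, si in zip(cos, sin):
                for refl in (1.0, -1.0):
                    cand = np.array([[c, -si * refl], [si, c * refl]])
                    best = min(best, np.linalg.norm(s @ cand - t))
            assert np.linalg.norm(s @ w - t) <= best + 1e-4


class TestCsls:
    def test_exact_match_ranked_first(self):
        t = np.array([[1.0, 0.0], [0.0, 1.0]])
        ranked = csls_neighbors(np.array([1.0, 0.0]), t, k=1)
        assert ranked[0][0] == 0

    def test_hub_penalized_below_exact_match(self):
        """A hub similar to every query loses to a specific exact match.
        Hand-computed on a 3x3 cosine table with k=1 source neighbourhoods."""
        targets = np.array(
            [
                [1.0, 0.0, 0.0],  # exact match of the query
                [np.sqrt(1 / 3), np.sqrt(1 / 3), np.sqrt(1 / 3)],  # hub
                [0.0, 1.0, 0.0],
            ]
        )
        sources = np.array([[1.0, 0.0, 0.0], [0.0, 0.9, np.sqrt(1 - 0.81)], [0.0, 0.0, 1.0]])
        ranked = csls_neighbors(targets[0], targets, k=1, source_matrix=sources)
        # raw cosine of hub to query ~0.577 but its r_S is large; exact match wins
        assert ranked[0][0] == 0
        scores = dict(ranked)
        # verify the analytic CSLS value of the exact match: 2*1 - 1 - 1 = 0
        assert scores[0] == pytest.approx(0.0, abs=1e-12)

    def test_k_out_of_range_errors(self):
        t = np.eye(3)
        with pytest.raises(ValueError):
            csls_neighbors(t[0], t, k=4)


class TestInduceDictionary:
    def test_planted_mates_are_mutual_neighbours(self):
        fx = generate_planted_rotation(60, 8, 0.0, 2)
        pairs = induce_dictionary(fx.source_matrix, fx.target_matrix, fx.planted_transform, k=5)
        hits = sum(a == b for a, b, _ in pairs)
        assert hits / 60 >= 0.9
        assert len(pairs) == len({a for a, _, _ in pairs})

    def test_zero_transform_warns(self):
        fx = generate_planted_rotation(20, 4, 0.0, 1)
        with pytest.warns(UserWarning, match="zero transform"):
            induce_dictionary(fx.source_matrix, fx.target_matrix, np.zeros((4, 4)), k=3)

    def test_max_pairs_truncates(self):
        fx = generate_planted_rotation(30, 4, 0.0, 6)
        pairs = induce_dictionary(
            fx.source_matrix, fx.target_matrix, fx.planted_transform, k=3, max_pairs=5
        )
        assert len(pairs) <= 5

    def test_empty_vocabulary_errors(self):
        with pytest.raises(ValueError):
            induce_dictionary(np.zeros((0, 3)), np.eye(3), np.eye(3), k=1)


class TestSeedDictionary:
    def test_identical_strings_mode(self):
        src = _word_embedding(["ggo", "ct", "의심"], np.eye(3))
        tgt = _word_embedding(["ct", "scan", "ggo"], np.eye(3))
        pairs = seed_dictionary(src, tgt, "IDENTICAL_STRINGS")
        assert set(pairs) == {("ggo", "ggo"), ("ct", "ct")}

    def test_disjoint_vocabularies_error(self):
        src = _word_embedding(["하나", "둘"], np.eye(2))
        tgt = _word_embedding(["one", "two"], np.eye(2))
        with pytest.raises(ValueError, match="FREQUENCY_INIT"):
            seed_dictionary(src, tgt, "IDENTICAL_STRINGS")

    def test_frequency_init_pairs_by_rank(self):
        src = _word_embedding(["가", "나", "다"], np.eye(3))
        tgt = _word_embedding(["a", "b", "c"], np.eye(3))
        assert seed_dictionary(src, tgt, "FREQUENCY_INIT") == [("가", "a"), ("나", "b"), ("다", "c")]

    def test_frequency_init_precision_on_parallel_corpora(self):
        """The generator keeps frequency ranks matched across scripts, so
        rank-pairing the vocabularies recovers at least half of the gold
        dictionary (checked at a moderate vocabulary where ranks separate)."""
        from bilirad.subword import _build_vocab
        from bilirad.synth import SynthConfig, generate_corpus, generate_monolingual_corpora

        cfg = SynthConfig(n_reports=3000, filler_vocab_size=80, seed=2)
        _, gold = generate_corpus(SynthConfig(n_reports=10, filler_vocab_size=80, seed=2))
        hang, lat = generate_monolingual_corpora(cfg)
        words_h, _ = _build_vocab(hang, 3)
        words_l, _ = _build_vocab(lat, 3)
        src = _word_embedding(words_h, np.zeros((len(words_h), 2)))
        tgt = _word_embedding(words_l, np.zeros((len(words_l), 2)))
        pairs = seed_dictionary(src, tgt, "FREQUENCY_INIT")
        ref = gold.as_dict()
        scored = [(a, b) for a, b in pairs if a in ref]
        assert sum(ref[a] == b for a, b in scored) / len(scored) >= 0.5

    def test_supervised_tsv(self, tmp_path):
        p = tmp_path / "seed.tsv"
        p.write_text("의심\tsuspicious\n없음\tabsent\n", encoding="utf-8")
        src = _word_embedding(["의심"], np.eye(1))
        pairs = seed_dictionary(src, src, "SUPERVISED_TSV", tsv_path=p)
        assert pairs == [("의심", "suspicious"), ("없음", "absent")]


class TestTrainMapping:
    def test_planted_fixture_perfect_precision(self):
        fx = generate_planted_rotation(60, 8, 0.0, 4)
        words = [str(i) for i in range(60)]
        reference = {w: w for w in words}
        model = train_mapping(
            fx.source_matrix, fx.target_matrix, seed_pairs=[(w, w) for w in words[:20]],
            iterations=3, k=5, reference=reference,
        )
        assert model.precision_history[-1] == 1.0
        assert not np.diff(model.precision_history).min() < 0  # refinement never degrades

    def test_zero_iterations_is_pure_procrustes(self):
        fx = generate_planted_rotation(40, 6, 0.0, 5)
        words = [str(i) for i in range(40)]
        model = train_mapping(fx.source_matrix, fx.target_matrix,
                              [(w, w) for w in words], iterations=0, k=5)
        assert model.induced_dictionary == []
        assert model.iterations_run == 0

    def test_transform_orthogonal(self):
        fx = generate_planted_rotation(40, 6, 0.05, 7)
        words = [str(i) for i in range(40)]
        model = train_mapping(fx.source_matrix, fx.target_matrix,
                              [(w, w) for w in words[:15]], iterations=2, k=5)
        w = model.transform
        assert np.abs(w.T @ w - np.eye(6)).max() <= 1e-6

    def test_collapse_reports_iteration(self):
        fx = generate_planted_rotation(10, 8, 0.0, 1)
        with pytest.raises(ValueError, match="iteration 0"):
            train_mapping(fx.source_matrix, fx.target_matrix,
                          [("0", "0"), ("1", "1")], iterations=1, k=2)


class TestTranslateEmbedding:
    def test_identity_transform_unchanged(self):
        emb = _word_embedding(["가", "나"], [[1.0, 2.0], [3.0, 4.0]])
        model = MappingModel(transform=np.eye(2))
        out = translate_embedding(emb, model)
        assert np.array_equal(out.word_vectors, emb.word_vectors)

    def test_planted_fixture_maps_onto_target(self):
        fx = generate_planted_rotation(50, 6, 0.0, 9)
        emb = _word_embedding([str(i) for i in range(50)], fx.source_matrix)
        out = translate_embedding(emb, MappingModel(transform=fx.planted_transform))
        assert np.abs(out.word_vectors - fx.target_matrix).max() <= 1e-10

    def test_norm_preservation(self):
        rng = np.random.default_rng(3)
        fx = generate_planted_rotation(100, 7, 0.0, 2)
        vecs = rng.standard_normal((100, 7))
        emb = _word_embedding([str(i) for i in range(100)], vecs)
        out = translate_embedding(emb, MappingModel(transform=fx.planted_transform))
        before = np.linalg.norm(vecs, axis=1)
        after = np.linalg.norm(out.word_vectors, axis=1)
        assert np.abs(after / before - 1).max() <= 1e-6


def test_transform_roundtrip(tmp_path):
    fx = generate_planted_rotation(20, 5, 0.0, 3)
    model = MappingModel(transform=fx.planted_transform, csls_k=7, iterations_run=4)
    p = tmp_path / "w.tsv"
    save_transform(model, p)
    again = load_transform(p)
    assert np.abs(again.transform - model.transform).max() <= 1e-10
    assert again.csls_k == 7 and again.iterations_run == 4


def test_non_orthogonal_transform_rejected():
    with pytest.raises(ValueError, match="orthogonal"):
        MappingModel(transform=np.array([[1.0, 0.5], [0.0, 1.0]]))
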