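"""Character n-gram ("substring") skip-gram word embeddings.

Words are represented as the mean of the vectors of their boundary-marked
character n-grams plus a whole-word key, so any surface form — including
out-of-vocabulary words — composes to a vector. Training is skip-gram with
negative sampling over these composed vectors, with input-side gradients
scattered back to the constituent n-grams.

N-grams are stored in an exact hash table (no bucket collisions): at desk
scale exact tables are testable, and bucket hashing is an optimization,
not semantics. Composition uses the *mean*, not the sum, keeping OOV
vector norms comparable across word lengths (switchable via ``compose``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "SubwordEmbedding",
    "extract_ngrams",
    "train_embeddings",
    "save_embeddings",
    "load_embeddings",
]

_BOW, _EOW = "⟨", "⟩"  # ⟨ ⟩ word-boundary markers


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def extract_ngrams(word: str, nmin: int, nmax: int) -> list[str]:
    """All character n-grams of the boundary-marked word ``⟨word⟩`` for
    n in [nmin, nmax], left-to-right within increasing n, plus the
    whole-word key ``⟨word⟩`` itself (appended last, deduplicated)."""
    if not word:
        raise ValueError("word must be non-empty")
    if nmin > nmax:
        raise ValueError("ngram_min must be <= ngram_max")
    if nmin < 2:
        raise ValueError("ngram_min must be >= 2")
    marked = _BOW + word + _EOW
    grams: list[str] = []
    for n in range(nmin, nmax + 1):
        for i in range(len(marked) - n + 1):
            grams.append(marked[i : i + n])
    if marked not in grams:
        grams.append(marked)
    return grams


@dataclass(frozen=True)
class EmbeddingConfig:
    """Skip-gram hyperparameters (FastText-convention defaults)."""

    dim: int = 100
    ngram_min: int = 3
    ngram_max: int = 6
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    min_count: int = 1
    learning_rate: float = 0.05
    max_pairs_per_epoch: Optional[int] = None  # subsample cap for desk-scale runs
    compose: str = "mean"  # or "sum"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be positive")
        if not (2 <= self.ngram_min <= self.ngram_max):
            raise ValueError("need 2 <= ngram_min <= ngram_max")
        for name in ("window", "negatives", "epochs", "min_count"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.compose not in ("mean", "sum"):
            raise ValueError("compose must be 'mean' or 'sum'")


@dataclass
class SubwordEmbedding:
    """Vocabulary + n-gram vector tables; composes vectors for any word."""

    words: list[str]
    word_vectors: np.ndarray  # (V, d) composed vectors, cached at train time
    ngrams: dict[str, int]
    ngram_vectors: np.ndarray  # (G, d)
    config: EmbeddingConfig
    word_counts: Optional[dict[str, int]] = None
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.words)}

    @property
    def dim(self) -> int:
        return self.word_vectors.shape[1]

    def __contains__(self, word: str) -> bool:
        return word in self._index

    def _compose(self, grams: Sequence[str]) -> tuple[np.ndarray, bool]:
        idx = [self.ngrams[g] for g in grams if g in self.ngrams]
        if not idx:
            return np.zeros(self.dim), False
        v = self.ngram_vectors[idx].sum(axis=0)
        if self.config.compose == "mean":
            v = v / len(idx)
        return v, True

    def vector(self, word: str, normalized: bool = False) -> np.ndarray:
        """Composed vector for any surface word.

        In-vocabulary words use their cached composed vector; OOV words are
        the mean (or sum) of their *known* n-gram vectors. An OOV word with
        no known n-grams composes to the zero vector (see
        :meth:`vector_with_flag` for the explicit flag).
        """
        v, _ = self.vector_with_flag(word)
        if normalized:
            n = np.linalg.norm(v)
            if n > 0:
                v = v / n
        return v

    def vector_with_flag(self, word: str) -> tuple[np.ndarray, bool]:
        """(vector, known) — ``known`` is False only when nothing at all is
        known about the word and the zero vector is returned."""
        if not word:
            raise ValueError("word must be non-empty")
        i = self._index.get(word)
        if i is not None:
            return self.word_vectors[i].copy(), True
        if self.ngram_vectors.shape[0] == 0:
            return np.zeros(self.dim), False  # word-only embedding: OOV disabled
        grams = extract_ngrams(word, self.config.ngram_min, self.config.ngram_max)
        return self._compose(grams)

    def matrix(self, words: Optional[Sequence[str]] = None) -> np.ndarray:
        words = list(words) if words is not None else self.words
        return np.stack([self.vector(w) for w in words])


def _build_vocab(corpus: Sequence[Sequence[str]], min_count: int) -> tuple[list[str], dict[str, int]]:
    counts: dict[str, int] = {}
    for sent in corpus:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    kept = {w: c for w, c in counts.items() if c >= min_count}
    words = sorted(kept, key=lambda w: (-kept[w], w))  # frequency rank, stable
    return words, kept


def _ngram_index(words: Sequence[str], cfg: EmbeddingConfig) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Global n-gram ids plus a padded per-word id matrix (-1 = pad)."""
    ngrams: dict[str, int] = {}
    per_word: list[list[int]] = []
    for w in words:
        ids = []
        for g in extract_ngrams(w, cfg.ngram_min, cfg.ngram_max):
            if g not in ngrams:
                ngrams[g] = len(ngrams)
            ids.append(ngrams[g])
        per_word.append(ids)
    m = max(len(ids) for ids in per_word)
    mat = np.full((len(words), m), -1, dtype=np.int64)
    lens = np.empty(len(words), dtype=np.int64)
    for i, ids in enumerate(per_word):
        mat[i, : len(ids)] = ids
        lens[i] = len(ids)
    return ngrams, mat, lens


def _skipgram_pairs(
    corpus: Sequence[Sequence[str]], index: dict[str, int], window: int, rng: np.random.Generator
) -> np.ndarray:
    """(center, context) id pairs with word2vec-style dynamic windows,
    materialized once and reshuffled per epoch."""
    pairs: list[tuple[int, int]] = []
    for sent in corpus:
        ids = [index[w] for w in sent if w in index]
        for i, c in enumerate(ids):
            w = int(rng.integers(1, window + 1))
            for j in range(max(0, i - w), min(len(ids), i + w + 1)):
                if j != i:
                    pairs.append((c, ids[j]))
    return np.asarray(pairs, dtype=np.int64).reshape(-1, 2)


def train_embeddings(
    corpus: Sequence[Sequence[str]],
    config: EmbeddingConfig = EmbeddingConfig(),
    callback=None,
) -> SubwordEmbedding:
    """Skip-gram with negative sampling over composed subword vectors.

    ``callback(epoch, mean_loss)`` is invoked after each epoch (used by
    tests to check that training loss decreases). Fixed seed => identical
    tables.
    """
    words, counts = _build_vocab(corpus, config.min_count)
    if not words:
        raise ValueError("empty effective vocabulary after min_count pruning")
    index = {w: i for i, w in enumerate(words)}
    ngrams, gram_mat, gram_lens = _ngram_index(words, config)

    rng = np.random.default_rng([config.seed, 11])
    d = config.dim
    in_vecs = (rng.random((len(ngrams), d)) - 0.5) / d  # n-gram (input) table
    out_vecs = np.zeros((len(words), d))  # word (output/context) table

    freqs = np.array([counts[w] for w in words], dtype=float)
    noise = freqs**0.75
    noise /= noise.sum()

    pairs = _skipgram_pairs(corpus, index, config.window, rng)
    if pairs.shape[0] == 0:
        raise ValueError("no skip-gram pairs (corpus too small)")

    lr0, lr_min = config.learning_rate, 1e-4
    batch = 256  # batched updates accumulate per-word: keep batches modest
    k = config.negatives
    cap = config.max_pairs_per_epoch
    n_use = pairs.shape[0] if cap is None else min(cap, pairs.shape[0])
    total_steps = max(1, config.epochs * int(np.ceil(n_use / batch)))
    step = 0
    for epoch in range(config.epochs):
        order = rng.permutation(pairs.shape[0])[:n_use]
        ep = pairs[order]
        losses = []
        for s in range(0, ep.shape[0], batch):
            lr = max(lr_min, lr0 * (1 - step / total_steps))
            step += 1
            centers = ep[s : s + batch, 0]
            contexts = ep[s : s + batch, 1]
            b = centers.shape[0]
            negs = rng.choice(len(words), size=(b, k), p=noise)

            g_ids = gram_mat[centers]  # (b, m)
            g_mask = g_ids >= 0
            g_safe = np.where(g_mask, g_ids, 0)
            v = (in_vecs[g_safe] * g_mask[:, :, None]).sum(axis=1)
            lens = gram_lens[centers].astype(float)
            if config.compose == "mean":
                v = v / lens[:, None]

            u_pos = out_vecs[contexts]  # (b, d)
            u_neg = out_vecs[negs]  # (b, k, d)
            s_pos = _stable_sigmoid(np.einsum("bd,bd->b", v, u_pos))
            s_neg = _stable_sigmoid(-np.einsum("bd,bkd->bk", v, u_neg))  # sigma(-x)

            losses.append(float(-(np.log(s_pos + 1e-12).sum() + np.log(s_neg + 1e-12).sum()) / b))

            g_pos = s_pos - 1.0  # dL/d(v.u_pos)
            g_neg = 1.0 - s_neg  # dL/d(v.u_neg)
            # clip per-pair gradients: frequent words accumulate many
            # updates per batch against stale values, which diverges unclipped
            clip = 1.0
            dv = np.clip(g_pos[:, None] * u_pos + np.einsum("bk,bkd->bd", g_neg, u_neg), -clip, clip)
            du_pos = np.clip(g_pos[:, None] * v, -clip, clip)
            du_neg = np.clip(g_neg[:, :, None] * v[:, None, :], -clip, clip)

            np.add.at(out_vecs, contexts, -lr * du_pos)
            np.add.at(out_vecs, negs.ravel(), -lr * du_neg.reshape(-1, d))
            if config.compose == "mean":
                dv = dv / lens[:, None]
            contrib = np.repeat(-lr * dv, g_mask.sum(axis=1), axis=0)
            np.add.at(in_vecs, g_ids[g_mask], contrib)
        if callback is not None:
            callback(epoch, float(np.mean(losses)))

    emb = SubwordEmbedding(
        words=words,
        word_vectors=np.zeros((len(words), d)),
        ngrams=ngrams,
        ngram_vectors=in_vecs,
        config=config,
        word_counts=counts,
    )
    # cache composed in-vocabulary vectors
    mask = gram_mat >= 0
    vecs = (in_vecs[np.where(mask, gram_mat, 0)] * mask[:, :, None]).sum(axis=1)
    if config.compose == "mean":
        vecs = vecs / gram_lens[:, None].astype(float)
    emb.word_vectors = vecs
    return emb


# ---------------------------------------------------------------------------
# persistence: standard word2vec text format + n-gram TSV sidecar


def save_embeddings(emb: SubwordEmbedding, path: str | Path) -> None:
    """Word vectors in word2vec text format ('V d' header, word + floats per
    line); n-gram vectors in a ``<path>.ngrams.tsv`` sidecar."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(emb.words)} {emb.dim}\n")
        for w, v in zip(emb.words, emb.word_vectors):
            fh.write(w + " " + " ".join(f"{x:.8g}" for x in v) + "\n")
    if emb.ngrams:
        side = path.with_name(path.name + ".ngrams.tsv")
        inv = sorted(emb.ngrams, key=emb.ngrams.get)
        with side.open("w", encoding="utf-8") as fh:
            fh.write(f"# {emb.config.ngram_min} {emb.config.ngram_max} {emb.config.compose}\n")
            for g in inv:
                v = emb.ngram_vectors[emb.ngrams[g]]
                fh.write(g + "\t" + "\t".join(f"{x:.8g}" for x in v) + "\n")


def load_embeddings(path: str | Path, config: Optional[EmbeddingConfig] = None) -> SubwordEmbedding:
    """Load word2vec-text vectors; if the n-gram sidecar is absent (e.g. an
    externally pretrained file) the result is word-only: OOV composition is
    disabled and unknown words compose to flagged zero vectors."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("word2vec header must be 'n_words dim'")
        n, d = int(header[0]), int(header[1])
        words, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != d + 1:
                raise ValueError(
                    f"row for {parts[0]!r} has {len(parts) - 1} floats, header says dim {d}"
                )
            words.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if len(words) != n:
        raise ValueError(f"header says {n} words, file has {len(words)}")
    word_vectors = np.asarray(rows, dtype=float).reshape(len(words), d)

    side = path.with_name(path.name + ".ngrams.tsv")
    ngrams: dict[str, int] = {}
    gram_rows: list[list[float]] = []
    cfg = config
    if side.exists():
        with side.open("r", encoding="utf-8") as fh:
            meta = fh.readline().split()
            nmin, nmax, compose = int(meta[1]), int(meta[2]), meta[3]
            if cfg is None:
                cfg = EmbeddingConfig(dim=d, ngram_min=nmin, ngram_max=nmax, compose=compose)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != d + 1:
                    raise ValueError(f"ngram row {parts[0]!r} has wrong dimension")
                ngrams[parts[0]] = len(ngrams)
                gram_rows.append([float(x) for x in parts[1:]])
    if cfg is None:
        cfg = EmbeddingConfig(dim=d)
    gram_vectors = np.asarray(gram_rows, dtype=float).reshape(len(gram_rows), d)
    return SubwordEmbedding(
        words=words, word_vectors=word_vectors, ngrams=ngrams, ngram_vectors=gram_vectors, config=cfg
    )
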