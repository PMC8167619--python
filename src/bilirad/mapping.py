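"""Unsupervised cross-lingual embedding alignment (the Kor2Eng step).

Learns a d x d *orthogonal* transform carrying Hangul word vectors into
the Latin/English embedding space without any parallel data: a seed
dictionary is induced distributionally (identical surface strings or
matched frequency ranks), the transform is the closed-form orthogonal
Procrustes solution on the current pairs, and the dictionary is then
re-induced with CSLS (hubness-corrected nearest neighbours), alternating
for a few refinement iterations.

Embeddings are mean-centered and unit-normalized before mapping; the
orthogonality of the transform means mapped vectors keep their norms, and
the inverse mapping is simply the transpose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .subword import SubwordEmbedding

__all__ = [
    "MappingModel",
    "procrustes",
    "csls_neighbors",
    "induce_dictionary",
    "seed_dictionary",
    "train_mapping",
    "translate_embedding",
    "save_transform",
    "load_transform",
]


@dataclass
class MappingModel:
    """Orthogonal source->target transform plus the dictionary it induced."""

    transform: np.ndarray  # (d, d), W^T W = I within 1e-6
    induced_dictionary: list[tuple[str, str, float]] = field(default_factory=list)
    csls_k: int = 10
    iterations_run: int = 0
    precision_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        w = self.transform
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("transform must be square")
        err = np.abs(w.T @ w - np.eye(w.shape[0])).max()
        if err > 1e-6:
            raise ValueError(f"transform not orthogonal (max |W^T W - I| = {err:.2e})")

    @property
    def inverse(self) -> np.ndarray:
        return self.transform.T


def procrustes(source_vectors: np.ndarray, target_vectors: np.ndarray) -> np.ndarray:
    """Closed-form argmin over orthogonal W of ||S W - T||_F.

    W = U V^T from the SVD of S^T T; rows of the two matrices must be
    aligned pairwise and n >= d.
    """
    s = np.asarray(source_vectors, dtype=float)
    t = np.asarray(target_vectors, dtype=float)
    if s.shape != t.shape:
        raise ValueError("source and target must have the same shape")
    n, d = s.shape
    if n < d:
        raise ValueError(f"need at least d={d} aligned pairs, got n={n}")
    m = s.T @ t
    if np.linalg.matrix_rank(m) < d:
        warnings.warn("rank-deficient Procrustes input; solution not unique", stacklevel=2)
    u, _, vt = scipy.linalg.svd(m, full_matrices=False)
    return u @ vt


def _unit(m: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return m / norms


def _mean_topk_cos(sim: np.ndarray, k: int) -> np.ndarray:
    """Row-wise mean cosine to the k nearest columns (sim is a cosine matrix)."""
    part = np.partition(sim, -k, axis=1)[:, -k:]
    return part.mean(axis=1)


def csls_neighbors(
    query_vector: np.ndarray,
    target_matrix: np.ndarray,
    k: int,
    source_matrix: Optional[np.ndarray] = None,
) -> list[tuple[int, float]]:
    """Rank targets for one (mapped, unit-norm) query by CSLS score:

    ``score(x, y) = 2 cos(x, y) - r_T(x) - r_S(y)``

    where r_T(x) is the mean cosine of x to its k nearest targets and
    r_S(y) the mean cosine of target y to its k nearest *mapped source*
    vectors (``source_matrix``; the query alone if omitted). Descending
    score, ties broken by lower index.
    """
    t = np.asarray(target_matrix, dtype=float)
    if k < 1 or k > t.shape[0]:
        raise ValueError(f"k must be in [1, {t.shape[0]}]")
    q = np.asarray(query_vector, dtype=float)
    cos = t @ q
    r_t = float(np.sort(cos)[-k:].mean())
    if source_matrix is None:
        r_s = cos  # degenerate single-source neighbourhood
    else:
        s = np.asarray(source_matrix, dtype=float)
        kk = min(k, s.shape[0])
        r_s = _mean_topk_cos(t @ s.T, kk)
    scores = 2 * cos - r_t - r_s
    order = np.lexsort((np.arange(len(scores)), -scores))
    return [(int(i), float(scores[i])) for i in order]


def _csls_matrix(mapped: np.ndarray, target: np.ndarray, k: int) -> np.ndarray:
    """Full CSLS score matrix between unit-norm mapped sources and targets."""
    cos = mapped @ target.T  # (ns, nt)
    kk_t = min(k, target.shape[0])
    kk_s = min(k, mapped.shape[0])
    r_src = _mean_topk_cos(cos, kk_t)  # r_T(x) per source
    r_tgt = _mean_topk_cos(cos.T, kk_s)  # r_S(y) per target
    return 2 * cos - r_src[:, None] - r_tgt[None, :]


def induce_dictionary(
    source_emb: SubwordEmbedding | np.ndarray,
    target_emb: SubwordEmbedding | np.ndarray,
    transform: np.ndarray,
    k: int = 10,
    max_pairs: int = 10000,
    source_words: Optional[Sequence[str]] = None,
    target_words: Optional[Sequence[str]] = None,
) -> list[tuple[str, str, float]]:
    """Mutual-CSLS-nearest-neighbour pairs under ``transform``, sorted by
    score (descending) and truncated to ``max_pairs``."""
    s_mat, s_words = _as_matrix(source_emb, source_words)
    t_mat, t_words = _as_matrix(target_emb, target_words)
    if s_mat.shape[0] == 0 or t_mat.shape[0] == 0:
        raise ValueError("empty vocabulary")
    if np.abs(transform).max() == 0:
        warnings.warn("zero transform: induced dictionary is degenerate", stacklevel=2)
    mapped = _unit(_center_unit(s_mat) @ transform)
    target = _unit(_center_unit(t_mat))
    scores = _csls_matrix(mapped, target, k)
    best_t = scores.argmax(axis=1)
    best_s = scores.argmax(axis=0)
    pairs = [
        (s_words[i], t_words[int(best_t[i])], float(scores[i, best_t[i]]))
        for i in range(len(s_words))
        if int(best_s[int(best_t[i])]) == i
    ]
    pairs.sort(key=lambda p: -p[2])
    return pairs[:max_pairs]


def _as_matrix(emb, words):
    if isinstance(emb, np.ndarray):
        if words is None:
            words = [str(i) for i in range(emb.shape[0])]
        return np.asarray(emb, dtype=float), list(words)
    if words is None:
        words = emb.words
    return emb.matrix(words), list(words)


def _center_unit(m: np.ndarray) -> np.ndarray:
    m = _unit(m)
    m = m - m.mean(axis=0, keepdims=True)
    return _unit(m)


def seed_dictionary(
    source_emb: SubwordEmbedding,
    target_emb: SubwordEmbedding,
    mode: str = "IDENTICAL_STRINGS",
    tsv_path: Optional[str | Path] = None,
    max_pairs: int = 5000,
) -> list[tuple[str, str]]:
    """Initial pairs without parallel supervision.

    IDENTICAL_STRINGS pairs tokens whose normalized surfaces coincide
    across the corpora (digits, shared Latin loanword terms);
    FREQUENCY_INIT pairs the i-th most frequent words of each side;
    SUPERVISED_TSV reads a user dictionary.
    """
    mode = mode.upper()
    if mode == "IDENTICAL_STRINGS":
        shared = [w for w in source_emb.words if w in target_emb]
        if not shared:
            raise ValueError(
                "no identical strings across vocabularies; try FREQUENCY_INIT or SUPERVISED_TSV"
            )
        return [(w, w) for w in shared[:max_pairs]]
    if mode == "FREQUENCY_INIT":
        n = min(len(source_emb.words), len(target_emb.words), max_pairs)
        if n == 0:
            raise ValueError("empty vocabulary")
        return list(zip(source_emb.words[:n], target_emb.words[:n]))
    if mode == "SUPERVISED_TSV":
        if tsv_path is None:
            raise ValueError("SUPERVISED_TSV mode needs tsv_path")
        pairs = []
        with open(tsv_path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line:
                    a, b = line.split("\t")[:2]
                    pairs.append((a, b))
        if not pairs:
            raise ValueError("empty seed dictionary TSV")
        return pairs[:max_pairs]
    raise ValueError(f"unknown seed mode {mode!r}")


def train_mapping(
    source_emb: SubwordEmbedding | np.ndarray,
    target_emb: SubwordEmbedding | np.ndarray,
    seed_pairs: Sequence[tuple[str, str]],
    iterations: int = 5,
    k: int = 10,
    max_pairs: int = 10000,
    reference: Optional[dict[str, str]] = None,
    source_words: Optional[Sequence[str]] = None,
    target_words: Optional[Sequence[str]] = None,
    vocab_limit: Optional[int] = 10000,
) -> MappingModel:
    """Alternate Procrustes on the current pairs with CSLS dictionary
    re-induction. ``iterations=0`` reduces to pure Procrustes on the seed.

    Re-induction considers only the ``vocab_limit`` most frequent words of
    each side (word lists are frequency-sorted): rare words have unstable
    vectors and would otherwise flood the mutual-neighbour dictionary.

    ``reference`` (an evaluation-only gold dictionary) makes the model
    record precision@1 of the induced dictionary at each iteration.
    """
    s_mat, s_words = _as_matrix(source_emb, source_words)
    t_mat, t_words = _as_matrix(target_emb, target_words)
    if vocab_limit is not None:
        s_mat, s_words = s_mat[:vocab_limit], s_words[:vocab_limit]
        t_mat, t_words = t_mat[:vocab_limit], t_words[:vocab_limit]
    s_idx = {w: i for i, w in enumerate(s_words)}
    t_idx = {w: i for i, w in enumerate(t_words)}
    s_unit = _center_unit(s_mat)
    t_unit = _center_unit(t_mat)
    d = s_unit.shape[1]

    def solve(pairs: Sequence[tuple[str, str]], it: int) -> np.ndarray:
        rows = [(s_idx[a], t_idx[b]) for a, b in pairs if a in s_idx and b in t_idx]
        if len(rows) < d:
            raise ValueError(
                f"dictionary collapsed to {len(rows)} pairs (< d={d}) at iteration {it}"
            )
        si, ti = zip(*rows)
        return procrustes(s_unit[list(si)], t_unit[list(ti)])

    def precision(pairs) -> float:
        if reference is None or not pairs:
            return float("nan")
        scored = [(a, b) for a, b, *_ in pairs if a in reference]
        if not scored:
            return float("nan")
        return sum(reference[a] == b for a, b in scored) / len(scored)

    w = solve(list(seed_pairs), 0)
    history: list[float] = []
    current: list[tuple[str, str, float]] = [(a, b, 0.0) for a, b in seed_pairs]
    for it in range(1, iterations + 1):
        current = induce_dictionary(
            s_unit, t_unit, w, k=k, max_pairs=max_pairs,
            source_words=s_words, target_words=t_words,
        )
        history.append(precision(current))
        w = solve([(a, b) for a, b, _ in current], it)
    return MappingModel(
        transform=w,
        induced_dictionary=current if iterations > 0 else [],
        csls_k=k,
        iterations_run=iterations,
        precision_history=history,
    )


def translate_embedding(source_emb: SubwordEmbedding, model: MappingModel) -> SubwordEmbedding:
    """Map every source word (and n-gram) vector through the orthogonal
    transform; norms are preserved to within orthogonality tolerance."""
    w = model.transform
    if source_emb.dim != w.shape[0]:
        raise ValueError("dimension mismatch between embedding and transform")
    out = SubwordEmbedding(
        words=list(source_emb.words),
        word_vectors=source_emb.word_vectors @ w,
        ngrams=dict(source_emb.ngrams),
        ngram_vectors=source_emb.ngram_vectors @ w,
        config=source_emb.config,
        word_counts=source_emb.word_counts,
    )
    return out


def save_transform(model: MappingModel, path: str | Path) -> None:
    """TSV matrix with a one-line header: dim, csls_k, iterations_run."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"# dim={model.transform.shape[0]} csls_k={model.csls_k} iterations={model.iterations_run}\n")
        for row in model.transform:
            fh.write("\t".join(f"{x:.12g}" for x in row) + "\n")


def load_transform(path: str | Path) -> MappingModel:
    with Path(path).open("r", encoding="utf-8") as fh:
        header = fh.readline().lstrip("# ").split()
        meta = dict(kv.split("=") for kv in header)
        rows = [[float(x) for x in line.split("\t")] for line in fh if line.strip()]
    return MappingModel(
        transform=np.asarray(rows, dtype=float),
        csls_k=int(meta.get("csls_k", 10)),
        iterations_run=int(meta.get("iterations", 0)),
    )
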