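"""Attention Bi-LSTM report classifier plus a bag-of-substrings baseline.

Each report is encoded token-by-token: Hangul tokens are looked up in the
Hangul subword embedding and carried into the English space through the
learned orthogonal transform; Latin/digit tokens are looked up directly in
the English embedding; out-of-vocabulary forms compose from character
n-grams. The sequence feeds a bidirectional LSTM, a single-context
additive attention layer pools the per-position states into one context
vector, and a softmax head yields the three class probabilities. Attention
weights over the real (non-pad) tokens are returned with every prediction
and drive the explanation module.

The baseline is a multinomial logistic regression on hashed character
3-6-gram counts — the comparison floor the attention model must beat.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.feature_extraction.text import HashingVectorizer
from sklearn.linear_model import LogisticRegression

from .nn import Adam, AdditiveAttention, Dense, LSTMLayer, cross_entropy, softmax
from .mapping import MappingModel
from .preprocess import Script, classify_script, normalize, tokenize
from .reports import LABELS, Label, Report
from .subword import SubwordEmbedding

__all__ = [
    "ClassifierConfig",
    "AttentionPrediction",
    "AttentionBiLSTM",
    "encode",
    "encode_batch",
    "stratified_split",
    "train",
    "predict_batch",
    "baseline_logistic",
    "TrainingHistory",
]


@dataclass(frozen=True)
class ClassifierConfig:
    embedding_dim: int = 100
    hidden_per_direction: int = 64
    attention_dim: int = 64
    max_len: int = 64
    dropout: float = 0.2
    recurrent_dropout: float = 0.5  # variational; keeps attention localized
    learning_rate: float = 3e-3
    batch_size: int = 32
    max_epochs: int = 20
    patience: int = 3
    freeze_embeddings: bool = False  # fine-tune pretrained vectors by default
    validation_fraction: float = 0.1
    class_weighting: str = "balanced"  # or "none"; counters the negative-heavy prior
    seed: int = 0
    n_classes: int = 3

    def __post_init__(self) -> None:
        for name in ("embedding_dim", "hidden_per_direction", "attention_dim",
                     "max_len", "batch_size", "max_epochs", "patience"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")
        if not 0.0 <= self.recurrent_dropout < 1.0:
            raise ValueError("recurrent_dropout must be in [0,1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_classes != 3:
            raise ValueError("this classifier is fixed at 3 classes")


@dataclass(frozen=True)
class AttentionPrediction:
    """Class probabilities plus per-token attention for one report."""

    probabilities: np.ndarray  # (3,), sums to 1
    predicted_label: Label
    attention_weights: np.ndarray  # (token_count,), sums to 1 over real tokens
    token_count: int

    @staticmethod
    def from_arrays(probs: np.ndarray, alpha: np.ndarray, n_tokens: int) -> "AttentionPrediction":
        # argmax with ties broken by class order NEGATIVE < POSITIVE < OBSCURE
        pred = LABELS[int(np.argmax(probs))]
        return AttentionPrediction(
            probabilities=probs, predicted_label=pred,
            attention_weights=alpha[:n_tokens], token_count=n_tokens,
        )


def encode(
    tokens: Sequence[str] | Report | str,
    embedding: SubwordEmbedding,
    mapping: Optional[MappingModel] = None,
    max_len: int = 64,
    source_embedding: Optional[SubwordEmbedding] = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode one report into (max_len, d) vectors plus a pad mask.

    ``embedding`` is the Latin/English-space table; Hangul tokens are
    looked up in ``source_embedding`` (defaulting to ``embedding``) and,
    when a mapping is given, rotated into the English space. Token vectors
    are centered by their table's vocabulary mean and unit-normalized —
    skip-gram tables carry a large shared component that would otherwise
    drown the discriminative directions (and the mapping itself is learned
    on centered, normalized vectors). Sequences are truncated from the
    tail at ``max_len``. Returns (vectors, mask, kept_token_surfaces).
    """
    if isinstance(tokens, Report):
        tokens = [normalize(t) for t in tokenize(tokens.text)]
    elif isinstance(tokens, str):
        tokens = [normalize(t) for t in tokenize(tokens)]
    else:
        tokens = list(tokens)
    src = source_embedding if source_embedding is not None else embedding
    kept = tokens[:max_len]
    d = embedding.dim
    means = _vocab_means(embedding, src)
    x = np.zeros((max_len, d))
    mask = np.zeros(max_len)
    for i, tok in enumerate(kept):
        x[i] = _token_vector(tok, embedding, mapping, src, means)
        mask[i] = 1.0
    return x, mask, kept


def _vocab_means(embedding: SubwordEmbedding, src: SubwordEmbedding) -> tuple[np.ndarray, np.ndarray]:
    d = embedding.dim
    src_mean = src.word_vectors.mean(axis=0) if len(src.words) else np.zeros(d)
    tgt_mean = embedding.word_vectors.mean(axis=0) if len(embedding.words) else np.zeros(d)
    return src_mean, tgt_mean


def _token_vector(tok, embedding, mapping, src, means) -> np.ndarray:
    src_mean, tgt_mean = means
    if classify_script(tok) is Script.HANGUL:
        v, known = src.vector_with_flag(tok)
        if known:
            v = v - src_mean
        if mapping is not None:
            v = v @ mapping.transform
    else:
        v, known = embedding.vector_with_flag(tok)
        if known:
            v = v - tgt_mean
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def encode_batch(
    reports: Sequence[Report],
    embedding: SubwordEmbedding,
    mapping: Optional[MappingModel] = None,
    max_len: int = 64,
    source_embedding: Optional[SubwordEmbedding] = None,
) -> tuple[np.ndarray, np.ndarray, list[list[str]]]:
    xs, ms, toks = [], [], []
    for r in reports:
        x, m, t = encode(r, embedding, mapping, max_len, source_embedding)
        xs.append(x)
        ms.append(m)
        toks.append(t)
    return np.stack(xs), np.stack(ms), toks


class AttentionBiLSTM:
    """Bi-LSTM -> additive attention -> softmax over the 3 labels.

    When trained with ``freeze_embeddings=False`` the model carries its own
    fine-tuned token table (``token_vocab`` / ``token_table``), initialized
    from the pretrained subword vectors; tokens unseen in training fall
    back to the pretrained composition at inference.
    """

    def __init__(self, config: ClassifierConfig):
        self.config = config
        rng = np.random.default_rng([config.seed, 21])
        H = config.hidden_per_direction
        self.fwd = LSTMLayer(config.embedding_dim, H, rng, reverse=False)
        self.bwd = LSTMLayer(config.embedding_dim, H, rng, reverse=True)
        self.att = AdditiveAttention(2 * H, config.attention_dim, rng)
        self.out = Dense(2 * H, config.n_classes, rng)
        self._drop_rng = np.random.default_rng([config.seed, 22])
        self.token_vocab: Optional[dict[str, int]] = None
        self.token_table: Optional[np.ndarray] = None

    # -- parameter plumbing ------------------------------------------------
    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, layer in (("fwd", self.fwd), ("bwd", self.bwd), ("att", self.att), ("out", self.out)):
            for k, v in layer.params.items():
                out[f"{prefix}.{k}"] = v
        if self.token_table is not None:
            out["emb.table"] = self.token_table
        return out

    def load_parameters(self, params: dict[str, np.ndarray]) -> None:
        own = self.parameters()
        for k, v in params.items():
            own[k][...] = v

    # -- forward / backward ------------------------------------------------
    def forward_batch(
        self, x: np.ndarray, mask: np.ndarray, training: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """(B, T, D) + (B, T) -> probabilities (B, 3), attention (B, T)."""
        if (mask.sum(axis=1) == 0).any():
            raise ValueError("fully-masked input sequence")
        rdrop_f = rdrop_b = None
        p = self.config.recurrent_dropout
        if training and p > 0:
            H = self.config.hidden_per_direction
            keep = 1.0 - p
            rdrop_f = (self._drop_rng.random((x.shape[0], H)) < keep) / keep
            rdrop_b = (self._drop_rng.random((x.shape[0], H)) < keep) / keep
        hf = self.fwd.forward(x, mask, recurrent_drop=rdrop_f)
        hb = self.bwd.forward(x, mask, recurrent_drop=rdrop_b)
        h = np.concatenate([hf, hb], axis=2)
        ctx, alpha = self.att.forward(h, mask)
        if training and self.config.dropout > 0:
            keep = 1.0 - self.config.dropout
            dmask = (self._drop_rng.random(ctx.shape) < keep) / keep
            ctx = ctx * dmask
            self._dropout_mask = dmask
        else:
            self._dropout_mask = None
        logits = self.out.forward(ctx)
        return softmax(logits, axis=1), alpha

    def backward_batch(
        self,
        probs: np.ndarray,
        targets: np.ndarray,
        sample_weights: Optional[np.ndarray] = None,
        return_dx: bool = False,
    ):
        B = probs.shape[0]
        dlogits = probs.copy()
        dlogits[np.arange(B), targets] -= 1.0
        if sample_weights is not None:
            dlogits *= (sample_weights / sample_weights.sum())[:, None]
        else:
            dlogits /= B
        dctx, g_out = self.out.backward(dlogits)
        if self._dropout_mask is not None:
            dctx = dctx * self._dropout_mask
        dh, g_att = self.att.backward(dctx)
        H = self.config.hidden_per_direction
        dx_f, g_fwd = self.fwd.backward(dh[:, :, :H])
        dx_b, g_bwd = self.bwd.backward(dh[:, :, H:])
        grads = {}
        for prefix, g in (("fwd", g_fwd), ("bwd", g_bwd), ("att", g_att), ("out", g_out)):
            for k, v in g.items():
                grads[f"{prefix}.{k}"] = v
        if return_dx:
            return grads, dx_f + dx_b
        return grads

    def predict(self, x: np.ndarray, mask: np.ndarray) -> list[AttentionPrediction]:
        probs, alpha = self.forward_batch(x, mask, training=False)
        return [
            AttentionPrediction.from_arrays(probs[i], alpha[i], int(mask[i].sum()))
            for i in range(x.shape[0])
        ]

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Self-describing zip archive: config JSON + one .npy per tensor,
        plus the fine-tuned token vocabulary when present."""
        import io

        path = Path(path)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", json.dumps({"format_version": 1, **asdict(self.config)}))
            if self.token_vocab is not None:
                ordered = sorted(self.token_vocab, key=self.token_vocab.get)
                zf.writestr("token_vocab.json", json.dumps(ordered, ensure_ascii=False))
            for k, v in self.parameters().items():
                buf = io.BytesIO()
                np.save(buf, v)
                zf.writestr(f"params/{k}.npy", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "AttentionBiLSTM":
        import io

        with zipfile.ZipFile(Path(path), "r") as zf:
            cfg = json.loads(zf.read("config.json"))
            cfg.pop("format_version", None)
            model = cls(ClassifierConfig(**cfg))
            params = {}
            for name in zf.namelist():
                if name.startswith("params/"):
                    key = name[len("params/") : -len(".npy")]
                    params[key] = np.load(io.BytesIO(zf.read(name)))
            if "token_vocab.json" in zf.namelist():
                ordered = json.loads(zf.read("token_vocab.json"))
                model.token_vocab = {t: i for i, t in enumerate(ordered)}
                model.token_table = params["emb.table"].copy()
            model.load_parameters(params)
        return model


def stratified_split(
    reports: Sequence[Report], test_fraction: float, seed: int
) -> tuple[list[Report], list[Report]]:
    """Per-class shuffled split; test takes round(fraction * class size) of
    each class. Disjoint and exhaustive."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0,1)")
    rng = np.random.default_rng([seed, 31])
    train_set: list[Report] = []
    test_set: list[Report] = []
    import warnings

    for lab in LABELS:
        members = [r for r in reports if r.label is lab]
        if not members:
            warnings.warn(f"class {lab.name} has no members", stacklevel=2)
            continue
        order = rng.permutation(len(members))
        n_test = int(round(test_fraction * len(members)))
        for rank, idx in enumerate(order):
            (test_set if rank < n_test else train_set).append(members[int(idx)])
    unlabeled = [r for r in reports if r.label is None]
    if unlabeled:
        raise ValueError(f"{len(unlabeled)} reports have no label")
    return train_set, test_set


@dataclass
class TrainingHistory:
    epochs: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    best_epoch: int = 0

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            fh.write("epoch,train_loss,train_accuracy,val_loss,val_accuracy\n")
            for row in zip(self.epochs, self.train_loss, self.train_accuracy,
                           self.val_loss, self.val_accuracy):
                fh.write(",".join(str(x) for x in row) + "\n")


def train(
    config: ClassifierConfig,
    train_reports: Sequence[Report],
    embedding: SubwordEmbedding,
    mapping: Optional[MappingModel] = None,
    source_embedding: Optional[SubwordEmbedding] = None,
    validation_reports: Optional[Sequence[Report]] = None,
) -> tuple[AttentionBiLSTM, TrainingHistory]:
    """Minimize cross-entropy with Adam; early stopping on validation loss
    with the configured patience, restoring the best parameters.

    If no validation set is passed, ``validation_fraction`` of the training
    split (stratified) is held out for early stopping.
    """
    if not train_reports:
        raise ValueError("empty training set")
    if validation_reports is None:
        train_reports, validation_reports = stratified_split(
            list(train_reports), config.validation_fraction, config.seed + 1
        )
    y_tr = np.array([r.label.value for r in train_reports])
    y_va = np.array([r.label.value for r in validation_reports])

    model = AttentionBiLSTM(config)
    src = source_embedding if source_embedding is not None else embedding
    if config.freeze_embeddings:
        x_tr, m_tr, _ = encode_batch(train_reports, embedding, mapping, config.max_len,
                                     source_embedding)
        x_va, m_va, _ = encode_batch(validation_reports, embedding, mapping, config.max_len,
                                     source_embedding)
        ids_tr = ids_va = None
    else:
        # fine-tuning: per-token trainable table initialized from the
        # pretrained (centered, mapped, normalized) vectors
        means = _vocab_means(embedding, src)
        vocab: dict[str, int] = {}

        def to_ids(reports):
            ids = np.zeros((len(reports), config.max_len), dtype=np.int64)
            mask = np.zeros((len(reports), config.max_len))
            for i, r in enumerate(reports):
                toks = [normalize(t) for t in tokenize(r.text)][: config.max_len]
                for j, tok in enumerate(toks):
                    if tok not in vocab:
                        vocab[tok] = len(vocab)
                    ids[i, j] = vocab[tok]
                    mask[i, j] = 1.0
            return ids, mask

        ids_tr, m_tr = to_ids(train_reports)
        ids_va, m_va = to_ids(validation_reports)
        ordered = sorted(vocab, key=vocab.get)
        model.token_vocab = vocab
        model.token_table = np.stack(
            [_token_vector(t, embedding, mapping, src, means) for t in ordered]
        )
        x_tr = x_va = None
    opt = Adam(model.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng([config.seed, 23])
    if config.class_weighting == "balanced":
        counts = np.bincount(y_tr, minlength=3).astype(float)
        counts[counts == 0] = 1.0
        class_w = len(y_tr) / (3.0 * counts)
    else:
        class_w = np.ones(3)
    w_tr = class_w[y_tr]
    history = TrainingHistory()
    best_loss = np.inf
    best_params = {k: v.copy() for k, v in model.parameters().items()}
    bad_epochs = 0

    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(y_tr))
        losses, hits = [], 0
        for s in range(0, len(order), config.batch_size):
            idx = order[s : s + config.batch_size]
            if ids_tr is None:
                xb = x_tr[idx]
            else:
                xb = model.token_table[ids_tr[idx]]
            probs, _ = model.forward_batch(xb, m_tr[idx], training=True)
            loss = cross_entropy(probs, y_tr[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (non-finite loss) at epoch {epoch}")
            losses.append(loss)
            hits += int((probs.argmax(axis=1) == y_tr[idx]).sum())
            if ids_tr is None:
                grads = model.backward_batch(probs, y_tr[idx], sample_weights=w_tr[idx])
            else:
                grads, dx = model.backward_batch(
                    probs, y_tr[idx], sample_weights=w_tr[idx], return_dx=True
                )
                d_table = np.zeros_like(model.token_table)
                sel = m_tr[idx] > 0
                np.add.at(d_table, ids_tr[idx][sel], dx[sel])
                grads["emb.table"] = d_table
            gnorm = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
            if gnorm > 5.0:  # recurrent nets: clip global gradient norm
                grads = {k: g * (5.0 / gnorm) for k, g in grads.items()}
            opt.step(grads)
        if ids_va is None:
            xv = x_va
        else:
            xv = model.token_table[ids_va]
        probs_va, _ = model.forward_batch(xv, m_va, training=False)
        # early-stop on the same class-weighted objective the optimizer sees
        w_va = class_w[y_va]
        p_va = probs_va[np.arange(len(y_va)), y_va]
        vloss = float(-(w_va * np.log(np.clip(p_va, 1e-12, None))).sum() / w_va.sum())
        vacc = float((probs_va.argmax(axis=1) == y_va).mean())
        history.epochs.append(epoch)
        history.train_loss.append(float(np.mean(losses)))
        history.train_accuracy.append(hits / len(y_tr))
        history.val_loss.append(vloss)
        history.val_accuracy.append(vacc)
        if vloss < best_loss - 1e-9:
            best_loss = vloss
            best_params = {k: v.copy() for k, v in model.parameters().items()}
            history.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                break
    model.load_parameters(best_params)
    return model, history


def encode_for_model(
    model: AttentionBiLSTM,
    report: Report | str | Sequence[str],
    embedding: SubwordEmbedding,
    mapping: Optional[MappingModel] = None,
    source_embedding: Optional[SubwordEmbedding] = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Encode honoring the model's fine-tuned token table when it has one;
    tokens unseen in training fall back to the pretrained composition."""
    x, mask, kept = encode(report, embedding, mapping, model.config.max_len, source_embedding)
    if model.token_vocab is not None:
        for i, tok in enumerate(kept):
            j = model.token_vocab.get(tok)
            if j is not None:
                x[i] = model.token_table[j]
    return x, mask, kept


def predict_batch(
    model: AttentionBiLSTM,
    reports: Sequence[Report],
    embedding: SubwordEmbedding,
    mapping: Optional[MappingModel] = None,
    source_embedding: Optional[SubwordEmbedding] = None,
    batch_size: int = 64,
) -> list[AttentionPrediction]:
    """Order-preserving batched inference; batch size never changes outputs
    beyond float tolerance."""
    out: list[AttentionPrediction] = []
    reports = list(reports)
    for s in range(0, len(reports), batch_size):
        chunk = reports[s : s + batch_size]
        enc = [encode_for_model(model, r, embedding, mapping, source_embedding) for r in chunk]
        x = np.stack([e[0] for e in enc])
        m = np.stack([e[1] for e in enc])
        out.extend(model.predict(x, m))
    return out


def baseline_logistic(
    train_reports: Sequence[Report],
    test_reports: Sequence[Report],
    seed: int = 0,
    ngram_range: tuple[int, int] = (3, 6),
):
    """Multinomial logistic regression on hashed character n-gram counts.

    Returns (predicted_labels, probability_matrix) aligned with
    ``test_reports``; evaluation is left to the metrics module.
    """
    vec = HashingVectorizer(analyzer="char_wb", ngram_range=ngram_range,
                            n_features=2**18, alternate_sign=False)
    x_tr = vec.transform([r.text for r in train_reports])
    y_tr = np.array([r.label.value for r in train_reports])
    probs = np.zeros((len(test_reports), 3))
    if len(set(y_tr)) == 1:
        probs[:, int(y_tr[0])] = 1.0  # degenerate single-class training set
    else:
        clf = LogisticRegression(max_iter=3000, C=100.0, class_weight="balanced",
                                 random_state=seed)
        clf.fit(x_tr, y_tr)
        raw = clf.predict_proba(vec.transform([r.text for r in test_reports]))
        # expand to all 3 classes even if the training set lacked some
        for j, cls in enumerate(clf.classes_):
            probs[:, int(cls)] = raw[:, j]
    preds = [LABELS[int(i)] for i in probs.argmax(axis=1)]
    return preds, probs
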