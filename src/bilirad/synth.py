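"""Synthetic bilingual pseudo-report generator.

The hospital corpus this method was developed for is not public, so the
package ships a generator that emulates its stated structure: free-text
chest CT / x-ray reports in which most function words (verbs, adjectives)
are Hangul while disease nouns are English, every included report contains
at least one pneumonia lexeme, and the three-class label (negative /
positive / obscure) is driven by negation / affirmation / uncertainty cue
phrases ("no evidence of", "없음", "suspicious", "의심", ...).

The generator also produces:

* two *monolingual* corpora (one per script) rendered from a shared
  concept-level corpus, so they are distributionally parallel — the
  cross-lingual mapping is learnable, yet the alignment itself never sees
  the pairing;
* the ground-truth bilingual dictionary (used only to *evaluate* mappings);
* planted-rotation fixtures, the exact oracle for Procrustes recovery;
* a simulated second annotator for exercising Cohen's kappa.

Default sizes mirror the study: 5450 reports with class mix 4005/895/550.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .reports import LABELS, Label, Modality, Report

__all__ = [
    "SynthConfig",
    "BilingualDictionary",
    "PlantedRotationFixture",
    "generate_corpus",
    "generate_monolingual_corpora",
    "generate_planted_rotation",
    "simulate_second_annotator",
    "CUE_PHRASES",
    "PNEUMONIA_NOUNS",
    "cue_token_set",
]


# ---------------------------------------------------------------------------
# fixed lexical material

#: Latin disease-noun surfaces, all passing the pneumonia-lexeme filter.
PNEUMONIA_NOUNS: tuple[str, ...] = (
    "pneumonia",
    "pneumonic",
    "bronchopneumonia",  # caught via "pneumoni"? no — kept for realism, never the sole lexeme
    "consolidation",
    "consolidative",
    "infiltration",
    "infiltrate",
    "bronchiole",
    "bronchioles",
    "haziness",
    "hazziness",
    "opacity",
    "opacities",
    "ggo",
)

#: Latin nouns that do NOT match the inclusion lexicon (shared across both
#: scripts in the monolingual corpora, like real-world loanword terms).
NEUTRAL_NOUNS: tuple[str, ...] = (
    "effusion",
    "atelectasis",
    "nodule",
    "edema",
    "fibrosis",
    "lung",
    "lobe",
    "pleura",
    "rll",
    "rul",
    "ct",
)

#: Cue phrases per class, per script. Each phrase is a token tuple; the
#: label of a generated report is decided by which class's cue it carries.
#: The two scripts' inventories are index-aligned with matching phrase
#: lengths, so that rendering the same phrase index in both monolingual
#: corpora keeps every cue token's corpus frequency matched across scripts
#: (frequency-rank seeding of the mapping depends on this).
CUE_PHRASES: dict[Label, dict[str, tuple[tuple[str, ...], ...]]] = {
    Label.NEGATIVE: {
        "latin": (("no", "evidence", "of"), ("resolved",), ("cleared",), ("absent",)),
        "hangul": (("흔적", "보이지", "않음"), ("없음",), ("호전됨",), ("소실됨",)),
    },
    Label.POSITIVE: {
        "latin": (("newly", "developed"), ("confirmed",), ("definite",), ("active",)),
        "hangul": (("새로", "발생함"), ("확인됨",), ("증가함",), ("악화됨",)),
    },
    Label.OBSCURE: {
        "latin": (("suspicious",), ("suspected",), ("possible",), ("equivocal",)),
        "hangul": (("의심",), ("가능성",), ("애매함",), ("불분명함",)),
    },
}


def cue_token_set(label: Optional[Label] = None) -> frozenset[str]:
    """All cue tokens (both scripts), optionally restricted to one class."""
    labels = [label] if label is not None else list(CUE_PHRASES)
    toks: set[str] = set()
    for lab in labels:
        for phrases in CUE_PHRASES[lab].values():
            for phrase in phrases:
                toks.update(phrase)
    return frozenset(toks)


_LATIN_SYLLABLES = (
    "ba", "ce", "di", "fo", "gu", "ha", "je", "ki", "lo", "mu",
    "na", "pe", "ri", "so", "tu", "va", "we", "xi", "yo", "zu",
)


def _latin_filler(i: int) -> str:
    """Deterministic pseudo-word for filler index i. Most-significant
    syllable first and the syllable list is alphabetical, so lexicographic
    order equals index order — equal-count words then sort identically in
    both scripts, which keeps frequency ranks comparable across corpora.
    The stride-21 code makes neighbouring indices differ in at least two
    syllables, limiting shared character n-grams between distinct words."""
    if i >= 380:
        raise ValueError("filler_vocab_size > 380 not supported")
    n = 21 * i
    return "".join(_LATIN_SYLLABLES[k] for k in (n // 400 % 20, n // 20 % 20, n % 20))


def _hangul_fillers(count: int) -> list[str]:
    """Deterministic distinct Hangul filler words (real syllable-block
    strings, so Unicode script detection is exercised genuinely).
    Lexicographic order equals index order, mirroring ``_latin_filler``;
    consecutive indices share no syllable, so subword vectors of distinct
    fillers stay distinguishable."""
    if count > 380:
        raise ValueError("filler_vocab_size > 380 not supported")
    return [chr(0xAC00 + i) + chr(0xAC00 + (i * 277) % 11172) for i in range(count)]


# ---------------------------------------------------------------------------
# configuration and fixture types


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic study population.

    Defaults mirror the study conditions: 5450 reports with class
    priors 4005/895/550, Hangul-dominant function words.
    """

    n_reports: int = 5450
    class_priors: tuple[float, float, float] = (4005 / 5450, 895 / 5450, 550 / 5450)
    korean_fraction: float = 0.7
    filler_vocab_size: int = 200
    cue_noise: float = 0.0
    seed: int = 0
    order_regime: bool = False  # negative vs obscure decided by cue ORDER

    def __post_init__(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        if self.filler_vocab_size < 1:
            raise ValueError("filler_vocab_size must be >= 1")
        p = np.asarray(self.class_priors, dtype=float)
        if p.shape != (3,) or (p < 0).any() or (p > 1).any():
            raise ValueError("class_priors must be 3 probabilities in [0,1]")
        if abs(float(p.sum()) - 1.0) > 1e-12:
            raise ValueError("class_priors must sum to 1 within 1e-12")
        for name in ("korean_fraction", "cue_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")


@dataclass(frozen=True)
class BilingualDictionary:
    """Meaning-aligned (hangul, latin) pairs. Ground truth for *evaluating*
    a learned mapping; never an input to mapping training."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        sources = [h for h, _ in self.pairs]
        if len(set(sources)) != len(sources):
            raise ValueError("duplicated source word in dictionary")
        if any(not h or not l for h, l in self.pairs):
            raise ValueError("dictionary entries must be non-empty")

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for h, l in self.pairs:
                fh.write(f"{h}\t{l}\n")

    @classmethod
    def load(cls, path) -> "BilingualDictionary":
        pairs = []
        with open(path, "r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line:
                    h, l = line.split("\t")
                    pairs.append((h, l))
        return cls(tuple(pairs))


@dataclass(frozen=True)
class PlantedRotationFixture:
    """target = source @ planted_transform + N(0, noise_sd^2) noise."""

    source_matrix: np.ndarray
    target_matrix: np.ndarray
    planted_transform: np.ndarray
    noise_sd: float


# ---------------------------------------------------------------------------
# concept model shared by report and monolingual-corpus generation


class _ConceptSpace:
    """Filler/cue/noun inventory with Zipf frequencies and latent topics,
    rendered per script.

    Fillers are partitioned into topics; a sentence drawn under a topic
    prefers that topic's fillers. This gives dictionary mates matching
    co-occurrence *profiles* (not just matching frequencies), which is the
    distributional signal the unsupervised alignment relies on.
    """

    def __init__(self, config: SynthConfig):
        v = config.filler_vocab_size
        self.latin_fillers = [_latin_filler(i) for i in range(v)]
        self.hangul_fillers = _hangul_fillers(v)
        # Zipf weights over filler ranks — same ranks in both scripts, which
        # is what makes FREQUENCY_INIT seeding work downstream.
        w = 1.0 / np.arange(1, v + 1) ** 1.2
        self.filler_probs = w / w.sum()
        self.n_topics = max(1, min(12, v // 8))
        self.topic_of = np.arange(v) % self.n_topics
        self.topic_probs = []
        for t in range(self.n_topics):
            p = np.where(self.topic_of == t, w, 0.0)
            self.topic_probs.append(p / p.sum())
        self.dictionary = self._build_dictionary()

    def _build_dictionary(self) -> BilingualDictionary:
        pairs = list(zip(self.hangul_fillers, self.latin_fillers))
        # single-token cue translations, meaning-aligned by class & rank
        for lab in LABELS:
            h_phr = [p for p in CUE_PHRASES[lab]["hangul"] if len(p) == 1]
            l_phr = [p for p in CUE_PHRASES[lab]["latin"] if len(p) == 1]
            for (h,), (l,) in zip(h_phr, l_phr):
                pairs.append((h, l))
        return BilingualDictionary(tuple(pairs))

    def sample_filler(self, rng: np.random.Generator, script: str) -> str:
        i = self.sample_filler_idx(rng)
        return self.latin_fillers[i] if script == "latin" else self.hangul_fillers[i]

    def sample_filler_idx(self, rng: np.random.Generator, topic: Optional[int] = None) -> int:
        # under a topic, 75% of filler draws come from the topic's subset
        if topic is not None and rng.random() < 0.85:
            return int(rng.choice(len(self.filler_probs), p=self.topic_probs[topic]))
        return int(rng.choice(len(self.filler_probs), p=self.filler_probs))


def _sample_cue(rng: np.random.Generator, label: Label, korean_fraction: float) -> tuple[str, ...]:
    script = "hangul" if rng.random() < korean_fraction else "latin"
    phrases = CUE_PHRASES[label][script]
    return phrases[int(rng.integers(len(phrases)))]


# ---------------------------------------------------------------------------
# public generators


def generate_corpus(config: SynthConfig) -> tuple[list[Report], BilingualDictionary]:
    """Generate labeled pseudo-reports plus the ground-truth dictionary.

    Every report contains >= 1 pneumonia lexeme (so it passes the inclusion
    filter) and exactly one cue phrase; with probability ``cue_noise`` the
    emitted cue belongs to a *different* class than the label, simulating
    annotation/wording mismatch. Identical config => identical output.

    With ``order_regime=True`` negative and obscure reports each carry one
    negation and one uncertainty cue, and the *later* cue decides the label
    — a regime where bag-of-n-gram models are blind but sequence models
    are not.
    """
    space = _ConceptSpace(config)
    rng = np.random.default_rng([config.seed, 1])
    reports: list[Report] = []
    priors = np.asarray(config.class_priors, dtype=float)
    for i in range(config.n_reports):
        label = LABELS[int(rng.choice(3, p=priors))]
        length = int(rng.integers(8, 61))
        n_lexemes = int(rng.integers(1, 4))
        lexemes = [PNEUMONIA_NOUNS[int(rng.integers(len(PNEUMONIA_NOUNS)))] for _ in range(n_lexemes)]
        if all(l == "bronchopneumonia" for l in lexemes):
            lexemes[0] = "pneumonia"  # guarantee a filter hit ("pneumoni-" is not a prefix here)

        if config.order_regime and label in (Label.NEGATIVE, Label.OBSCURE):
            neg = _sample_cue(rng, Label.NEGATIVE, config.korean_fraction)
            obs = _sample_cue(rng, Label.OBSCURE, config.korean_fraction)
            # later cue wins: obscure-last => OBSCURE, negation-last => NEGATIVE
            cue_chunks = [obs, neg] if label is Label.NEGATIVE else [neg, obs]
        else:
            cue_label = label
            if config.cue_noise > 0 and rng.random() < config.cue_noise:
                others = [l for l in LABELS if l is not label]
                cue_label = others[int(rng.integers(2))]
            cue_chunks = [_sample_cue(rng, cue_label, config.korean_fraction)]

        chunks: list[tuple[str, ...]] = [(lx,) for lx in lexemes]
        n_neutral = int(rng.integers(0, 3))
        chunks += [(NEUTRAL_NOUNS[int(rng.integers(len(NEUTRAL_NOUNS)))],) for _ in range(n_neutral)]
        n_filler = max(0, length - sum(len(c) for c in chunks) - sum(len(c) for c in cue_chunks))
        for _ in range(n_filler):
            script = "hangul" if rng.random() < config.korean_fraction else "latin"
            chunks.append((space.sample_filler(rng, script),))
        order = rng.permutation(len(chunks))
        chunks = [chunks[int(j)] for j in order]
        # cue chunks inserted in a fixed relative order (matters for order_regime)
        positions = sorted(int(p) for p in rng.integers(0, len(chunks) + 1, size=len(cue_chunks)))
        for off, (pos, cue) in enumerate(zip(positions, cue_chunks)):
            chunks.insert(pos + off, cue)
        tokens = [t for c in chunks for t in c]
        text = " ".join(tokens)
        if rng.random() < 0.5:
            text += "."
        modality = Modality.CT if rng.random() < 0.5 else Modality.XRAY
        reports.append(Report(id=f"R{i:06d}", modality=modality, text=text, label=label))
    return reports, space.dictionary


def generate_monolingual_corpora(
    config: SynthConfig,
) -> tuple[list[list[str]], list[list[str]]]:
    """Render one shared concept-level corpus into Hangul and Latin token
    sequences (``config.n_reports`` lines each).

    Latin medical nouns stay Latin in *both* corpora, as loanwords do in
    real bilingual reports — these shared surfaces are what the
    identical-strings seeding mode later exploits. A small independent
    per-side token dropout keeps the corpora from being literally parallel.
    """
    space = _ConceptSpace(config)
    rng = np.random.default_rng([config.seed, 2])
    drop = np.random.default_rng([config.seed, 3])
    shared = PNEUMONIA_NOUNS + NEUTRAL_NOUNS

    hangul_corpus: list[list[str]] = []
    latin_corpus: list[list[str]] = []
    for _ in range(config.n_reports):
        length = int(rng.integers(5, 16))
        topic = int(rng.integers(space.n_topics))
        h_line: list[str] = []
        l_line: list[str] = []
        for _ in range(length):
            u = rng.random()
            if u < 0.6:
                i = space.sample_filler_idx(rng, topic)
                h_tok, l_tok = space.hangul_fillers[i], space.latin_fillers[i]
            elif u < 0.85:
                tok = shared[int(rng.integers(len(shared)))]
                h_tok = l_tok = tok
            else:
                # a cue "concept": same class and phrase index on both sides,
                # so every cue token (multiword phrases included) gets a
                # trained vector and mates keep matched corpus frequencies
                lab = LABELS[int(rng.integers(3))]
                h_phr = CUE_PHRASES[lab]["hangul"]
                l_phr = CUE_PHRASES[lab]["latin"]
                j = int(rng.integers(len(l_phr)))
                h_tok = h_phr[j]
                l_tok = l_phr[j]
            h_toks = h_tok if isinstance(h_tok, tuple) else (h_tok,)
            l_toks = l_tok if isinstance(l_tok, tuple) else (l_tok,)
            if drop.random() >= 0.03:
                h_line.extend(h_toks)
            if drop.random() >= 0.03:
                l_line.extend(l_toks)
        hangul_corpus.append(h_line)
        latin_corpus.append(l_line)
    return hangul_corpus, latin_corpus


def generate_planted_rotation(
    n_words: int, dim: int, noise_sd: float, seed: int
) -> PlantedRotationFixture:
    """Random point cloud plus a planted orthogonal transform: the exact
    oracle for Procrustes recovery. Requires n_words >= dim >= 2."""
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if n_words < dim:
        raise ValueError("n_words must be >= dim (otherwise underdetermined)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng([seed, 4])
    source = rng.standard_normal((n_words, dim))
    q, r = np.linalg.qr(rng.standard_normal((dim, dim)))
    q = q * np.sign(np.diag(r))  # unique QR convention => seeded determinism
    target = source @ q
    if noise_sd > 0:
        target = target + noise_sd * rng.standard_normal(target.shape)
    return PlantedRotationFixture(source, target, q, float(noise_sd))


def simulate_second_annotator(
    reports: Sequence[Report],
    disagreement_rate_by_class: Sequence[float],
    seed: int,
) -> list[Label]:
    """Relabel each report, flipping to a uniformly random *other* class
    with the per-class disagreement probability. Exercises Cohen's kappa."""
    rates = np.asarray(disagreement_rate_by_class, dtype=float)
    if rates.shape != (3,) or (rates < 0).any() or (rates > 1).any():
        raise ValueError("disagreement rates must be 3 probabilities in [0,1]")
    rng = np.random.default_rng([seed, 5])
    out: list[Label] = []
    for r in reports:
        if r.label is None:
            raise ValueError(f"report {r.id} has no label")
        lab = r.label
        if rng.random() < rates[lab.value]:
            others = [l for l in LABELS if l is not lab]
            lab = others[int(rng.integers(2))]
        out.append(lab)
    return out
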