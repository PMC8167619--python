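import numpy as np
import pytest

from bilirad.preprocess import normalized_tokens
from bilirad.subword import EmbeddingConfig, train_embeddings
from bilirad.synth import SynthConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """600 cue-deterministic pseudo-reports plus the gold dictionary."""
    reports, dictionary = generate_corpus(SynthConfig(n_reports=600, cue_noise=0.0, seed=11))
    return reports, dictionary


@pytest.fixture(scope="session")
def tiny_embedding(small_corpus):
    """Subword embedding trained once on the small corpus token streams
    (both scripts in one table — adequate for classifier/explain tests)."""
    reports, _ = small_corpus
    corpus = [normalized_tokens(r.text) for r in reports]
    cfg = EmbeddingConfig(dim=24, ngram_min=3, ngram_max=4, epochs=3, min_count=2,
                          max_pairs_per_epoch=60_000, seed=7)
    return train_embeddings(corpus, cfg)
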