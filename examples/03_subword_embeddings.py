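"""Train character n-gram subword embeddings and compose OOV vectors.

Word vectors are the mean of boundary-marked character n-gram vectors, so
a misspelling or unseen inflection still lands near its neighbours.
"""

import numpy as np

from bilirad import EmbeddingConfig, SynthConfig, generate_monolingual_corpora, train_embeddings

_, latin_corpus = generate_monolingual_corpora(SynthConfig(n_reports=1500, seed=3))
config = EmbeddingConfig(dim=32, ngram_min=3, ngram_max=4, epochs=5, min_count=3, seed=3)
emb = train_embeddings(latin_corpus, config)
print(f"vocabulary: {len(emb.words)} words, {len(emb.ngrams)} n-grams, dim {emb.dim}")

mean = emb.word_vectors.mean(axis=0)  # skip-gram tables share a large common
                                      # component; compare centered vectors


def cos(a, b):
    va, vb = emb.vector(a) - mean, emb.vector(b) - mean
    return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))


print(f"cos(pneumonia, pneumonic)            = {cos('pneumonia', 'pneumonic'):.3f}")
print(f"cos(pneumonia, 'pneumonie' [OOV])    = {cos('pneumonia', 'pneumonie'):.3f}")
print(f"cos(pneumonia, effusion)             = {cos('pneumonia', 'effusion'):.3f}")
# Shared character n-grams pull the unseen spelling 'pneumonie' close to
# 'pneumonia'; an unrelated noun stays much farther away.
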