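# Methods

`bilirad` classifies free-text chest-imaging reports written in mixed
Hangul/Latin script into three pneumonia labels — *negative*, *positive*,
*obscure* — the phenotype-labeling setting of bilingual electronic health
records, where function words (verbs, adjectives) are mostly Korean while
disease nouns are English. This note documents the models, the synthetic
data they are validated on, and every numerically consequential choice.

## Report inclusion

Only reports containing at least one pneumonia lexeme enter the pipeline;
everything else is treated as pneumonia-negative by construction. The
default lexicon holds eight entries: the stems `pneumoni-`, `consolid-`,
`infiltra-`, `bronchiole-`, `hazi-`, `hazzi-`, `opacit-` match at the
*start of a normalized token* (a raw substring scan would wrongly match
e.g. "promethazine"), and `GGO` matches whole tokens only. `hazzi-` is
retained as its own entry for fidelity to the published stem list even
though it reads as a spelling variant of `hazi-`. The lexicon is a
2-column TSV and fully user-replaceable.

Tokenization yields maximal runs of a single script class (Hangul
syllable/jamo blocks, Latin letters, digits) with 0-based half-open
character offsets; punctuation, hyphens, slashes and apostrophes are
dropped, which also splits hyphenated compounds. Normalization is Unicode
NFC plus lowercasing of Latin. These conventions are this package's own
(the source system's exact preprocessing is not public) and are pinned by
tests.

## Subword embeddings

Word vectors are FastText-style: the mean of the vectors of all
boundary-marked character n-grams (default n = 3–6) plus a whole-word
key, trained with skip-gram negative sampling on per-script monolingual
corpora. Mean rather than sum composition keeps out-of-vocabulary vector
norms comparable across word lengths. N-grams live in an exact hash table
— bucket hashing is an optimization, not semantics, and exact tables are
testable. An OOV word composes from its known n-grams; a word with no
known n-grams gets a flagged zero vector.

Training details that matter numerically:

* skip-gram pairs are materialized once with word2vec-style dynamic
  windows (uniform 1..window) and reshuffled each epoch; an optional
  `max_pairs_per_epoch` cap subsamples pairs for desk-scale runs;
* updates are applied in vectorized batches of 256 via scatter-add, so a
  frequent word accumulates several updates against stale values within a
  batch; per-pair gradients are clipped to ±1, without which this
  accumulation diverges;
* learning rate decays linearly from 0.05 to 1e-4; negatives are drawn
  from the unigram distribution raised to 0.75; seeds make training
  bit-reproducible.

Desk-scale defaults used by the tests and the acceptance script are
dim 32, n-grams 3–4, 3 epochs, pair cap 120k — sized so a full run of the
pipeline is a matter of minutes on one CPU; the package defaults
(dim 100, n-grams 3–6, 5 epochs) follow the cited method's conventions.

## Unsupervised Korean-to-English transfer (Kor2Eng)

A single orthogonal matrix `W` carries Hangul word vectors into the
Latin embedding space. No parallel data is used anywhere in training:

1. vectors are unit-normalized, mean-centered, re-normalized;
2. a seed dictionary is induced distributionally: tokens with identical
   normalized surfaces across the corpora (digits, shared Latin loanword
   terms), topped up by frequency rank when fewer than `d` pairs exist; a
   supervised TSV mode exists for users who do have a dictionary;
3. `W` is the closed-form orthogonal Procrustes solution (`U Vᵀ` from the
   SVD of `SᵀT`) on the current pairs;
4. a new dictionary is induced as mutual nearest neighbours under CSLS
   (`2cos − r_T − r_S`, k = 10), restricted to the most frequent words
   (`vocab_limit`, default 10k) because rare-word vectors are unstable and
   flood mutual-neighbour retrieval;
5. steps 3–4 alternate (default 5 iterations).

Orthogonality is asserted to 1e-6 after every step; the inverse mapping
is `Wᵀ`. Adversarial initialization from the cited unsupervised-translation
literature is deliberately not implemented: it is fragile at desk scale
and the distributional seeds preserve the "no parallel supervision"
contract. Whether the original system used CSLS or plain nearest
neighbours, and how many refinement iterations, is not public; these are
reimplementation choices. A planted-rotation fixture (random point cloud,
known orthogonal `Q`, optional Gaussian noise) provides the exact oracle:
noise-free recovery is exact to 1e-6, and recovery error at noise 0.01
stays below 0.1 in Frobenius norm.

## Classifier

The classifier is a bidirectional LSTM (default 64 units per direction;
32 in the scaled-down test configuration) over the encoded token
sequence, followed by single-context additive attention
(`score_t = uᵀ tanh(W_a h_t + b_a)`, masked softmax, weighted sum) and a
softmax over the three labels. The original system's exact attention
equations are not published; the single-context additive form is this
package's choice. Ties at the argmax break by fixed class order
(negative < positive < obscure).

Encoding: Hangul tokens are looked up in the Hangul table and rotated by
`W`; Latin/digit tokens are looked up directly; every vector is centered
by its table's vocabulary mean and unit-normalized before use. The
centering matters: skip-gram tables carry one or two dominant shared
directions (≈99% of variance on the synthetic corpora) that otherwise
drown the discriminative signal. Sequences truncate at `max_len` = 64
tokens from the tail; padding is handled by carrying LSTM state through
masked positions and masking the attention softmax, which makes
predictions exactly invariant to appended padding.

Training is float64 numpy with hand-derived backprop (validated by a
finite-difference gradient check in the test suite) and Adam. Choices
that were found necessary rather than merely conventional:

* **learning rate 3e-3** — at 1e-3 the model sits on the majority-class
  plateau for tens of epochs;
* **balanced class weighting** of the cross-entropy — with the
  negative-heavy prior (≈73/16/10) unweighted training converges to the
  all-negative solution; early stopping monitors the *same* weighted
  validation loss, with patience 3 and best-parameter restore;
* **embedding fine-tuning by default** (`freeze_embeddings=False`): a
  per-token table initialized from the pretrained, mapped vectors is
  trained along with the network; with frozen desk-scale vectors the
  cue-token directions are too entangled and the model part-memorizes
  instead (held-out accuracy 0.7–0.9 versus ≈1.0 fine-tuned). Tokens
  unseen in training fall back to the pretrained subword composition at
  inference;
* **variational recurrent dropout 0.5** (one mask per sequence and
  direction, applied to the state fed back into the recurrence): without
  it, fine-tuned models broadcast the label signal along the sequence and
  attention settles on arbitrary positions; weakening state carry during
  training restores the property that attention concentrates on the
  decisive tokens, which the explanation module depends on;
* context-vector dropout 0.2; global gradient-norm clipping at 5;
  10% of the training split held out (stratified) for early stopping.

The comparison floor is a multinomial logistic regression on hashed
character 3–6-gram counts (`char_wb`, 2^18 features, C = 100, balanced
class weights) — a bag-of-substrings model that is order-blind by
construction.

## Attention explanations

Raw per-token softmax weights are kept alongside display weights obtained
by dividing by the per-report maximum (whether the original figure
normalizes per report is not stated; per-report max-normalization is
assumed because it preserves within-report contrast). `top_k` ranks by
raw weight with earlier-position tie-breaks. Renderings: standalone HTML
with background alpha proportional to display weight, or ANSI with 8
shading buckets; both deterministic, neither alters token order or
surfaces.

## Metrics

All per-class metrics are one-vs-rest: scoring a class treats only that
class's reports as positives. Precision = TP/predicted, recall =
TP/actual, F1 their harmonic mean, with 0/0 → 0. Accuracy is the
confusion-matrix trace over the total. AUROC is the midrank Mann–Whitney
concordance; AUPRC is step-wise average precision (no interpolation —
the conservative convention); both delegate to scikit-learn and are
checked in the tests against an O(n²) pair-counting oracle and hand
examples. Cohen's κ uses marginal-product chance agreement; two constant,
identical labelings define κ = 1. Display rounding follows the field's
table conventions (percentages to 0.1, F1 to integer percent, areas
to 0.01).

## Synthetic data

The clinical corpus this method targets is not publicly deposited, so the
generator is first-class, tested code that defines the study conditions:

* 5450 reports by default with class priors 4005/895/550
  (negative/positive/obscure), mirroring the published class mix; report
  length uniform 8–60 tokens; modality CT or x-ray;
* every report carries ≥1 pneumonia lexeme (so the inclusion filter is
  satisfiable by construction) plus Hangul/Latin filler function words
  (`korean_fraction` = 0.7 Hangul, reflecting Korean-dominant function
  words) and neutral disease nouns;
* the label is determined by exactly one injected cue phrase — negation
  ("no evidence of", "없음") → negative, affirmation ("confirmed",
  "확인됨") → positive, uncertainty ("suspicious", "의심") → obscure —
  flipped to another class's cue with probability `cue_noise` (default 0:
  the deterministic regime used for recovery tests);
* an `order_regime` variant makes negative vs obscure depend on the
  *order* of two cues with identical token bags, a regime where
  bag-of-n-gram models are blind but sequence models are not;
* monolingual corpora for embedding training are rendered from one shared
  concept-level corpus into each script with 3% independent per-side
  token dropout: distributionally parallel, never handed to the mapping
  as pairs. Fillers carry Zipf(1.2) frequencies partitioned into latent
  topics (85% of filler draws topic-bound) — without topical structure all
  words co-occur alike and there is no distributional signal to align.
  Filler surfaces sort lexicographically in frequency-rank order in both
  scripts so that exact count ties break consistently across corpora, and
  cue-phrase inventories are index-aligned across scripts with matching
  phrase lengths so every cue token's corpus frequency has a mate —
  frequency-rank seeding depends on both. Consecutive filler surfaces
  share no syllables, limiting character-n-gram smearing between unrelated
  words. Latin medical nouns stay Latin in both corpora, as loanwords do,
  anchoring identical-string seeds;
* the ground-truth bilingual dictionary (filler and single-token cue
  pairs) exists only to *evaluate* mappings; a planted-rotation fixture
  generator provides the exact Procrustes oracle; a simulated second
  annotator with per-class disagreement rates exercises κ.

What the generator does not emulate — radiology section structure,
negation scope, spelling noise, report-length/vocabulary statistics of
any real hospital, label noise correlated with content — bounds what
passing tests show: they validate the *machinery* (filtering, embedding,
alignment, classification, attention, metrics) under controlled
conditions, not clinical performance. The published headline accuracies
(91.01% test, 80.0% extra-validation) depend on 5450 private hospital
reports and are not reproducible here; what is reproduced exactly is the
metric arithmetic of the published per-class count pairs.

## Degenerate inputs and numerical conventions

Empty text tokenizes to an empty list; a fully-masked sequence is a
forward-pass error; an all-OOV (zero-vector) sequence is legal and
flagged. A zero mapping matrix warns and yields a degenerate dictionary.
Procrustes requires n ≥ d aligned pairs and warns on rank deficiency;
dictionary collapse below d pairs during refinement raises with the
iteration number. Stage manifests (config hash + input checksums + seed)
make pipeline re-runs no-ops on unchanged inputs; one global seed
determines every artifact byte-for-byte.

## Problem sizes

Tests and the acceptance script run the full pipeline at reduced sizes
chosen as this package's desk-scale defaults: corpora of 600–2000
reports, embedding dim 32 with n-grams 3–4 and 3 epochs, mapping over the
150 most frequent words, classifier hidden 32/direction with ≤20 epochs.
The classifier-recovery and mapping-refinement checks repeat over 5 seeds.
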