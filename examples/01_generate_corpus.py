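"""Generate a small synthetic bilingual report corpus and inspect it.

The generator emulates bilingual chest-imaging reports: Hangul function
words, English disease nouns (always at least one pneumonia lexeme), and a
negation / affirmation / uncertainty cue phrase that determines the
negative / positive / obscure label.
"""

from collections import Counter

from bilirad import SynthConfig, generate_corpus

config = SynthConfig(n_reports=200, seed=42)
reports, dictionary = generate_corpus(config)

print(f"generated {len(reports)} reports")
print("label counts:", dict(Counter(r.label.name for r in reports)))
print("\nfirst three reports:")
for r in reports[:3]:
    print(f"  [{r.id} {r.modality.value} {r.label.name}] {r.text}")
print(f"\nbilingual dictionary: {len(dictionary.pairs)} pairs, e.g. {dictionary.pairs[:3]}")
# The label counts track the configured class priors (negative-heavy, as in
# real perioperative imaging); each report text passes the pneumonia filter.
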