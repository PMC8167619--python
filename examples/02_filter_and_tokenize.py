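"""Tokenize mixed-script text and apply the pneumonia-lexeme filter.

Tokens are maximal single-script runs (Hangul / Latin / digits); the
inclusion filter keeps reports with at least one pneumonia lexeme, where
the seven stems match token prefixes and GGO matches whole tokens only.
"""

from bilirad import Modality, Report, keyword_filter, normalize, tokenize

text = "Peribronchial infiltration 의심, GGO3개 in RLL."
print(f"text: {text}")
for t in tokenize(text):
    print(f"  {normalize(t):>15s}  {t.script.name:<7s} [{t.start}:{t.end}]")

reports = [
    Report("r1", Modality.XRAY, "GGO noted in both lungs"),
    Report("r2", Modality.XRAY, "clear lungs, no acute lesion"),
    Report("r3", Modality.CT, "Pneumonic consolidation in RLL"),
    Report("r4", Modality.CT, "promethazine given"),  # 'hazi' inside a token: no match
]
kept = keyword_filter(reports)
print("\nfilter kept:", [r.id for r in kept])
# r1 (GGO whole token) and r3 (pneumoni-/consolid- prefixes) pass; r4 shows
# why matching is token-anchored rather than a raw substring scan.
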