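"""Mixed-script tokenization, normalization and the pneumonia-lexeme filter.

Reports in this domain interleave Hangul function words with Latin-script
disease nouns ("Peribronchial infiltration 의심"). Tokens are maximal runs
of a single script class — Hangul syllables/jamo, Latin letters, or digits —
with punctuation dropped; hyphens, slashes and apostrophes therefore split
or vanish. Normalization applies Unicode NFC and lowercases Latin.

The inclusion filter keeps reports containing at least one pneumonia
lexeme. Seven stems match as token *prefixes* ("pneumoni-", "consolid-",
"infiltra-", "bronchiole-", "hazi-", "hazzi-", "opacit-"); "GGO" matches
only as a whole token, so e.g. a token "ethazine" is never caught by a raw
substring scan of "hazi". The lexicon is user-replaceable via a 2-column
TSV (pattern, mode).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .reports import Report


class Script(Enum):
    HANGUL = "HANGUL"
    LATIN = "LATIN"
    DIGIT = "DIGIT"
    MIXED = "MIXED"
    OTHER = "OTHER"


# Hangul syllable block, compatibility jamo, and conjoining jamo ranges.
_HANGUL_RANGES = ((0xAC00, 0xD7A3), (0x1100, 0x11FF), (0x3130, 0x318F), (0xA960, 0xA97F))


def _char_script(ch: str) -> Script:
    cp = ord(ch)
    if any(lo <= cp <= hi for lo, hi in _HANGUL_RANGES):
        return Script.HANGUL
    if ("a" <= ch <= "z") or ("A" <= ch <= "Z"):
        return Script.LATIN
    if "0" <= ch <= "9":
        return Script.DIGIT
    return Script.OTHER


def classify_script(s: str) -> Script:
    """Script class of a whole string: MIXED if it spans classes."""
    seen = {_char_script(c) for c in s if _char_script(c) is not Script.OTHER}
    if not seen:
        return Script.OTHER
    if len(seen) == 1:
        return next(iter(seen))
    return Script.MIXED


@dataclass(frozen=True)
class Token:
    surface: str
    script: Script
    start: int  # 0-based character offset into the source text
    end: int  # exclusive

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("token offsets must satisfy 0 <= start < end")
        if not self.surface:
            raise ValueError("token surface must be non-empty")


def tokenize(text: str) -> list[Token]:
    """Split text into maximal single-script runs; punctuation is dropped.

    Offsets index the *original* string, so ``text[t.start:t.end]`` recovers
    the raw surface before normalization.
    """
    tokens: list[Token] = []
    run_start = None
    run_script = Script.OTHER
    for i, ch in enumerate(text):
        sc = _char_script(ch)
        if sc is Script.OTHER:
            if run_start is not None:
                tokens.append(Token(text[run_start:i], run_script, run_start, i))
                run_start = None
            continue
        if run_start is None:
            run_start, run_script = i, sc
        elif sc is not run_script:
            tokens.append(Token(text[run_start:i], run_script, run_start, i))
            run_start, run_script = i, sc
    if run_start is not None:
        tokens.append(Token(text[run_start:], run_script, run_start, len(text)))
    return tokens


def normalize(token: Token | str) -> str:
    """NFC-normalize; lowercase Latin. Hangul passes through unchanged."""
    s = token.surface if isinstance(token, Token) else token
    return unicodedata.normalize("NFC", s).lower()


def normalized_tokens(text: str) -> list[str]:
    return [normalize(t) for t in tokenize(text)]


class MatchMode(Enum):
    PREFIX_SUBSTRING = "PREFIX_SUBSTRING"
    EXACT = "EXACT"


@dataclass(frozen=True)
class LexiconEntry:
    pattern: str
    mode: MatchMode

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("lexicon pattern must be non-empty")

    def matches_token(self, token: str) -> bool:
        pat = self.pattern.lower()
        if self.mode is MatchMode.PREFIX_SUBSTRING:
            return token.startswith(pat)
        return token == pat


@dataclass(frozen=True)
class Lexicon:
    entries: tuple[LexiconEntry, ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("lexicon must have at least one entry")

    def matches(self, text: str) -> bool:
        toks = normalized_tokens(text)
        return any(e.matches_token(t) for t in toks for e in self.entries)

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(f"{e.pattern}\t{e.mode.value}\n")

    @classmethod
    def load(cls, path: str | Path) -> "Lexicon":
        entries = []
        with Path(path).open("r", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                pattern, mode = line.split("\t")
                entries.append(LexiconEntry(pattern, MatchMode[mode]))
        return cls(tuple(entries))


#: The 8 pneumonia lexemes used for report inclusion: hyphen-written stems
#: match at token start; the acronym GGO matches whole tokens only.
#: "hazzi-" is kept as a distinct entry alongside "hazi-" for fidelity to
#: the published stem list even though it reads like a spelling variant.
DEFAULT_LEXICON = Lexicon(
    tuple(
        [
            LexiconEntry(p, MatchMode.PREFIX_SUBSTRING)
            for p in ("pneumoni", "consolid", "infiltra", "bronchiole", "hazi", "hazzi", "opacit")
        ]
        + [LexiconEntry("GGO", MatchMode.EXACT)]
    )
)


def keyword_filter(reports: Sequence[Report], lexicon: Lexicon = DEFAULT_LEXICON) -> list[Report]:
    """Keep exactly the reports whose normalized token stream matches the
    lexicon; order preserved."""
    return [r for r in reports if lexicon.matches(r.text)]
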