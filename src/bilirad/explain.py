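"""Attention-weight explanations: ranked keywords and shaded renderings.

The classifier returns one softmax attention weight per real token; for
display those raw weights are divided by their per-report maximum (raw
weights are kept alongside), so the most influential token is always at
full intensity and relative contrast within the report is preserved.
Renderings are a standalone HTML page (background alpha proportional to
display weight) or an ANSI string with 8 shading levels.
"""

from __future__ import annotations

import html as _html
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .classifier import AttentionPrediction
from .preprocess import Script, classify_script
from .reports import Label, Report

__all__ = ["AnnotatedToken", "AnnotatedReport", "annotate", "top_k", "render", "render_gallery"]


@dataclass(frozen=True)
class AnnotatedToken:
    surface: str
    script: Script
    raw_weight: float
    display_weight: float  # raw / max(raw); 1.0 for the top token


@dataclass(frozen=True)
class AnnotatedReport:
    report_id: str
    tokens: tuple[AnnotatedToken, ...]
    predicted_label: Label
    probabilities: np.ndarray


def annotate(
    report: Report | str,
    prediction: AttentionPrediction,
    tokens: Sequence[str] | None = None,
) -> AnnotatedReport:
    """Pair each (non-pad) token with its attention weight.

    ``tokens`` must be the normalized token sequence the prediction was
    made from (pads excluded); if omitted it is recomputed from the report
    text, truncated to the prediction's token count.
    """
    if tokens is None:
        from .preprocess import normalized_tokens

        text = report.text if isinstance(report, Report) else report
        tokens = normalized_tokens(text)[: prediction.token_count]
    tokens = list(tokens)
    if len(tokens) != prediction.token_count:
        raise ValueError(
            f"token count {len(tokens)} does not match prediction ({prediction.token_count})"
        )
    raw = np.asarray(prediction.attention_weights, dtype=float)
    peak = raw.max() if raw.size and raw.max() > 0 else 1.0
    annotated = tuple(
        AnnotatedToken(
            surface=t, script=classify_script(t),
            raw_weight=float(w), display_weight=float(w / peak),
        )
        for t, w in zip(tokens, raw)
    )
    rid = report.id if isinstance(report, Report) else ""
    return AnnotatedReport(
        report_id=rid, tokens=annotated,
        predicted_label=prediction.predicted_label,
        probabilities=np.asarray(prediction.probabilities, dtype=float),
    )


def top_k(annotated: AnnotatedReport, k: int) -> list[tuple[str, float]]:
    """The k highest raw attention weights, ties broken by earlier
    position; k beyond the report length returns everything."""
    if k < 1:
        raise ValueError("k must be >= 1")
    raw = np.array([t.raw_weight for t in annotated.tokens])
    order = np.lexsort((np.arange(len(raw)), -raw))
    return [(annotated.tokens[int(i)].surface, float(raw[int(i)])) for i in order[:k]]


_ANSI_LEVELS = (255, 254, 252, 250, 247, 244, 241, 238)  # light -> dark greyscale


def render(annotated: AnnotatedReport, format: str = "HTML") -> str:
    """Deterministic shaded rendering; token order and surfaces untouched."""
    fmt = format.upper()
    if fmt == "HTML":
        spans = []
        for t in annotated.tokens:
            alpha = round(t.display_weight, 4)
            spans.append(
                f'<span class="tok" style="background: rgba(214,39,40,{alpha})" '
                f'title="weight {t.raw_weight:.4f}">{_html.escape(t.surface)}</span>'
            )
        probs = ", ".join(
            f"{lab}: {p:.3f}"
            for lab, p in zip(("negative", "positive", "obscure"), annotated.probabilities)
        )
        return (
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<style>.tok{padding:1px 2px;margin:1px;display:inline-block}</style></head><body>"
            f"<p><b>{_html.escape(annotated.report_id)}</b> &mdash; predicted "
            f"{annotated.predicted_label.name.lower()} ({probs})</p>"
            "<p>" + " ".join(spans) + "</p></body></html>"
        )
    if fmt == "ANSI":
        parts = []
        for t in annotated.tokens:
            level = min(7, int(t.display_weight * 8))  # 8 buckets; weight 1.0 -> darkest
            parts.append(f"\x1b[48;5;{_ANSI_LEVELS[level]}m{t.surface}\x1b[0m")
        return " ".join(parts)
    raise ValueError(f"unknown render format {format!r}")


def render_gallery(annotated_reports: Sequence[AnnotatedReport], path: str | Path) -> None:
    """One combined HTML page, plus a JSON sidecar of (token, weight) pairs."""
    bodies = []
    for ar in annotated_reports:
        page = render(ar, "HTML")
        start = page.index("<body>") + len("<body>")
        end = page.index("</body>")
        bodies.append(page[start:end])
    doc = (
        "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
        "<style>.tok{padding:1px 2px;margin:1px;display:inline-block}</style>"
        "</head><body>" + "<hr>".join(bodies) + "</body></html>"
    )
    path = Path(path)
    path.write_text(doc, encoding="utf-8")
    sidecar = [
        {
            "id": ar.report_id,
            "predicted": ar.predicted_label.name.lower(),
            "tokens": [[t.surface, t.raw_weight] for t in ar.tokens],
        }
        for ar in annotated_reports
    ]
    path.with_suffix(".json").write_text(
        json.dumps(sidecar, ensure_ascii=False, indent=1), encoding="utf-8"
    )
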