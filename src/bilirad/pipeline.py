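"""End-to-end orchestration of the three-step pipeline.

Stages: SYNTH (generate the bilingual pseudo-corpus) -> FILTER
(pneumonia-lexeme inclusion) -> EMBED (per-script subword embeddings) ->
ALIGN (unsupervised Hangul->Latin mapping) -> TRAIN (attention Bi-LSTM)
-> EVAL (metric suite) -> EXPLAIN (attention gallery).

Each stage writes its artifacts plus a manifest recording the config
hash, input checksums and seed; re-running a stage whose manifest still
matches is a no-op unless forced. The global seed determines every
stage's seed (fixed offsets), so one integer reproduces the whole run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import classifier as clf
from . import mapping as mp
from . import metrics as mx
from . import subword as sw
from . import synth
from .explain import annotate, render_gallery, top_k
from .preprocess import DEFAULT_LEXICON, Lexicon, keyword_filter
from .reports import read_reports, write_reports

log = logging.getLogger("bilirad.pipeline")

__all__ = ["Stage", "PipelineConfig", "PipelineError", "ConfigError", "MissingUpstreamError",
           "run_stage", "run_all"]


class PipelineError(RuntimeError):
    pass


class ConfigError(PipelineError):
    pass


class MissingUpstreamError(PipelineError):
    def __init__(self, stage: "Stage", missing: Path):
        self.stage = stage
        super().__init__(
            f"missing upstream artifact {missing} — run stage {stage.name} first"
        )


class Stage(Enum):
    SYNTH = "synth"
    FILTER = "filter"
    EMBED = "embed"
    ALIGN = "align"
    TRAIN = "train"
    EVAL = "eval"
    EXPLAIN = "explain"


_ORDER = [Stage.SYNTH, Stage.FILTER, Stage.EMBED, Stage.ALIGN, Stage.TRAIN, Stage.EVAL,
          Stage.EXPLAIN]


@dataclass
class MappingConfig:
    seed_mode: str = "IDENTICAL_STRINGS"
    iterations: int = 5
    csls_k: int = 10
    max_pairs: int = 10000


@dataclass
class PipelineConfig:
    out_dir: Path = Path("bilirad_run")
    seed: int = 0
    test_fraction: float = 0.2
    gallery_size: int = 10
    report_format: str = "jsonl"
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig)
    # desk-scale profile: a full default run finishes in minutes on one CPU
    embedding: sw.EmbeddingConfig = field(
        default_factory=lambda: sw.EmbeddingConfig(
            dim=32, ngram_min=3, ngram_max=4, epochs=8, min_count=5,
            max_pairs_per_epoch=150_000,
        )
    )
    mapping: MappingConfig = field(default_factory=MappingConfig)
    classifier: clf.ClassifierConfig = field(
        default_factory=lambda: clf.ClassifierConfig(
            embedding_dim=32, hidden_per_direction=32, attention_dim=32
        )
    )
    lexicon: Lexicon = field(default_factory=lambda: DEFAULT_LEXICON)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if not 0 < self.test_fraction < 1:
            raise ConfigError("test_fraction must be in (0,1)")

    @classmethod
    def from_dict(cls, d: dict, seed: Optional[int] = None) -> "PipelineConfig":
        """Build from nested plain dicts (e.g. parsed YAML). Stage seeds
        derive from the global seed unless explicitly overridden."""
        d = dict(d)
        if seed is not None:
            d["seed"] = seed
        g = int(d.get("seed", 0))
        try:
            synth_d = dict(d.pop("synth", {}))
            synth_d.setdefault("seed", g * 8 + 1)
            if "class_priors" in synth_d:
                synth_d["class_priors"] = tuple(synth_d["class_priors"])
            emb_d = dict(d.pop("embedding", {}))
            emb_d.setdefault("seed", g * 8 + 2)
            map_d = dict(d.pop("mapping", {}))
            clf_d = dict(d.pop("classifier", {}))
            clf_d.setdefault("seed", g * 8 + 3)
            return cls(
                synth=synth.SynthConfig(**synth_d),
                embedding=sw.EmbeddingConfig(**emb_d),
                mapping=MappingConfig(**map_d),
                classifier=clf.ClassifierConfig(**clf_d),
                **d,
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path: str | Path, seed: Optional[int] = None) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d, seed=seed)

    def config_hash(self, stage: Stage) -> str:
        sub = {
            Stage.SYNTH: dataclasses.asdict(self.synth),
            Stage.FILTER: [(e.pattern, e.mode.value) for e in self.lexicon.entries],
            Stage.EMBED: dataclasses.asdict(self.embedding),
            Stage.ALIGN: dataclasses.asdict(self.mapping),
            Stage.TRAIN: {**dataclasses.asdict(self.classifier),
                          "test_fraction": self.test_fraction, "seed": self.seed},
            Stage.EVAL: {},
            Stage.EXPLAIN: {"gallery_size": self.gallery_size},
        }[stage]
        return hashlib.sha256(json.dumps(sub, sort_keys=True, default=str).encode()).hexdigest()


# ---------------------------------------------------------------------------
# manifest plumbing


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest_path(cfg: PipelineConfig, stage: Stage) -> Path:
    return cfg.out_dir / f"manifest_{stage.value}.json"


def _inputs_fresh(cfg: PipelineConfig, stage: Stage, inputs: list[Path]) -> bool:
    mpath = _manifest_path(cfg, stage)
    if not mpath.exists():
        return False
    try:
        man = json.loads(mpath.read_text())
    except json.JSONDecodeError:
        return False
    if man.get("config_hash") != cfg.config_hash(stage):
        return False
    old = man.get("input_checksums", {})
    if set(old) != {str(p) for p in inputs}:
        return False
    for p in inputs:
        if not p.exists() or _checksum(p) != old[str(p)]:
            return False
    for out in man.get("outputs", []):
        if not Path(out).exists():
            return False
    return True


def _write_manifest(cfg: PipelineConfig, stage: Stage, inputs: list[Path],
                    outputs: list[Path], seconds: float) -> None:
    man = {
        "stage": stage.value,
        "config_hash": cfg.config_hash(stage),
        "seed": cfg.seed,
        "input_checksums": {str(p): _checksum(p) for p in inputs},
        "outputs": [str(p) for p in outputs],
        "seconds": round(seconds, 3),
    }
    _manifest_path(cfg, stage).write_text(json.dumps(man, indent=1))


def _require(cfg: PipelineConfig, stage_of_input: Stage, path: Path) -> Path:
    if not path.exists():
        raise MissingUpstreamError(stage_of_input, path)
    return path


# ---------------------------------------------------------------------------
# stage bodies


def _paths(cfg: PipelineConfig) -> dict[str, Path]:
    o = cfg.out_dir
    ext = cfg.report_format
    return {
        "reports": o / f"reports.{ext}",
        "mono_hangul": o / "mono_hangul.txt",
        "mono_latin": o / "mono_latin.txt",
        "dictionary": o / "dictionary.tsv",
        "filtered": o / f"filtered.{ext}",
        "emb_hangul": o / "emb_hangul.vec",
        "emb_latin": o / "emb_latin.vec",
        "transform": o / "transform.tsv",
        "induced": o / "induced_dictionary.tsv",
        "model": o / "model.zip",
        "history": o / "history.csv",
        "train_split": o / f"train.{ext}",
        "test_split": o / f"test.{ext}",
        "metrics_json": o / "metrics.json",
        "metrics_md": o / "metrics.md",
        "gallery": o / "gallery.html",
    }


def _stage_synth(cfg: PipelineConfig, p: dict[str, Path]) -> tuple[list[Path], list[Path]]:
    reports, dictionary = synth.generate_corpus(cfg.synth)
    write_reports(reports, p["reports"], cfg.report_format)
    hang, lat = synth.generate_monolingual_corpora(cfg.synth)
    p["mono_hangul"].write_text("\n".join(" ".join(s) for s in hang) + "\n", encoding="utf-8")
    p["mono_latin"].write_text("\n".join(" ".join(s) for s in lat) + "\n", encoding="utf-8")
    dictionary.save(p["dictionary"])
    return [], [p["reports"], p["mono_hangul"], p["mono_latin"], p["dictionary"]]


def _stage_filter(cfg: PipelineConfig, p: dict[str, Path]) -> tuple[list[Path], list[Path]]:
    inp = _require(cfg, Stage.SYNTH, p["reports"])
    reports = read_reports(inp, cfg.report_format)
    kept = keyword_filter(reports, cfg.lexicon)
    log.info("filter kept %d / %d reports", len(kept), len(reports))
    write_reports(kept, p["filtered"], cfg.report_format)
    return [inp], [p["filtered"]]


def _read_corpus(path: Path) -> list[list[str]]:
    return [line.split() for line in path.read_text(encoding="utf-8").splitlines() if line.strip()]


def _stage_embed(cfg: PipelineConfig, p: dict[str, Path]) -> tuple[list[Path], list[Path]]:
    inputs = [_require(cfg, Stage.SYNTH, p["mono_hangul"]),
              _require(cfg, Stage.SYNTH, p["mono_latin"])]
    for src, dst in ((p["mono_hangul"], p["emb_hangul"]), (p["mono_latin"], p["emb_latin"])):
        emb = sw.train_embeddings(_read_corpus(src), cfg.embedding)
        sw.save_embeddings(emb, dst)
    return inputs, [p["emb_hangul"], p["emb_latin"]]


def _stage_align(cfg: PipelineConfig, p: dict[str, Path]) -> tuple[list[Path], list[Path]]:
    inputs = [_require(cfg, Stage.EMBED, p["emb_hangul"]),
              _require(cfg, Stage.EMBED, p["emb_latin"])]
    src = sw.load_embeddings(p["emb_hangul"])
    tgt = sw.load_embeddings(p["emb_latin"])
    mcfg = cfg.mapping
    try:
        seeds = mp.seed_dictionary(src, tgt, mcfg.seed_mode)
    except ValueError:
        log.warning("seed mode %s found no pairs; falling back to FREQUENCY_INIT", mcfg.seed_mode)
        seeds = mp.seed_dictionary(src, tgt, "FREQUENCY_INIT")
    if len(seeds) < src.dim:  # Procrustes needs >= d pairs; top up by frequency rank
        used_s = {a for a, _ in seeds}
        used_t = {b for _, b in seeds}
        extra = [(a, b) for a, b in mp.seed_dictionary(src, tgt, "FREQUENCY_INIT")
                 if a not in used_s and b not in used_t]
        seeds = seeds + extra[: max(0, 2 * src.dim - len(seeds))]
    reference = None
    if p["dictionary"].exists():
        reference = synth.BilingualDictionary.load(p["dictionary"]).as_dict()
    model = mp.train_mapping(src, tgt, seeds, iterations=mcfg.iterations, k=mcfg.csls_k,
                             max_pairs=mcfg.max_pairs, reference=reference)
    mp.save_transform(model, p["transform"])
    with p["induced"].open("w", encoding="utf-8") as fh:
        for a, b, s in model.induced_dictionary:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")
    if model.precision_history:
        log.info("mapping precision@1 by iteration: %s",
                 [f"{x:.3f}" for x in model.precision_history])
    return inputs, [p["transform"], p["induced"]]


def _load_mapping_and_embs(cfg, p):
    src = sw.load_embeddings(_require(cfg, Stage.EMBED, p["emb_hangul"]))
    tgt = sw.load_embeddings(_require(cfg, Stage.EMBED, p["emb_latin"]))
    model = mp.load_transform(_require(cfg, Stage.ALIGN, p["transform"]))
    return src, tgt, model


def _stage_train(cfg: PipelineConfig, p: dict[str, Path]) -> tuple[list[Path], list[Path]]:
    inputs = [_require(cfg, Stage.FILTER, p["filtered"]), p["emb_hangul"], p["emb_latin"],
              p["transform"]]
    src, tgt, mmodel = _load_mapping_and_embs(cfg, p)
    reports = read_reports(p["filtered"], cfg.report_format)
    train_set, test_set = clf.stratified_split(reports, cfg.test_fraction, cfg.seed)
    write_reports(train_set, p["train_split"], cfg.report_format)
    write_reports(test_set, p["test_split"], cfg.report_format)
    ccfg = dataclasses.replace(cfg.classifier, embedding_dim=tgt.dim)
    model, history = clf.train(ccfg, train_set, tgt, mmodel, source_embedding=src)
    model.save(p["model"])
    history.to_csv(p["history"])
    log.info("trained %d epochs (best %d, val acc %.3f)", len(history.epochs),
             history.best_epoch, max(history.val_accuracy, default=float("nan")))
    return inputs, [p["model"], p["history"], p["train_split"], p["test_split"]]


def _stage_eval(cfg: PipelineConfig, p: dict[str, Path]) -> tuple[list[Path], list[Path]]:
    inputs = [_require(cfg, Stage.TRAIN, p["model"]),
              _require(cfg, Stage.TRAIN, p["test_split"])]
    src, tgt, mmodel = _load_mapping_and_embs(cfg, p)
    model = clf.AttentionBiLSTM.load(p["model"])
    test_set = read_reports(p["test_split"], cfg.report_format)
    preds = clf.predict_batch(model, test_set, tgt, mmodel, source_embedding=src)
    report = mx.evaluate(preds, [r.label for r in test_set])
    report.to_json(p["metrics_json"])
    p["metrics_md"].write_text(report.to_markdown(), encoding="utf-8")
    log.info("accuracy %.4f on %d test reports", report.accuracy, len(test_set))
    return inputs, [p["metrics_json"], p["metrics_md"]]


def _stage_explain(cfg: PipelineConfig, p: dict[str, Path]) -> tuple[list[Path], list[Path]]:
    inputs = [_require(cfg, Stage.TRAIN, p["model"]),
              _require(cfg, Stage.TRAIN, p["test_split"])]
    src, tgt, mmodel = _load_mapping_and_embs(cfg, p)
    model = clf.AttentionBiLSTM.load(p["model"])
    test_set = read_reports(p["test_split"], cfg.report_format)[: cfg.gallery_size]
    annotated = []
    for r in test_set:
        x, m, toks = clf.encode_for_model(model, r, tgt, mmodel, source_embedding=src)
        pred = model.predict(x[None], m[None])[0]
        annotated.append(annotate(r, pred, tokens=toks))
    render_gallery(annotated, p["gallery"])
    return inputs, [p["gallery"]]


_BODIES = {
    Stage.SYNTH: _stage_synth,
    Stage.FILTER: _stage_filter,
    Stage.EMBED: _stage_embed,
    Stage.ALIGN: _stage_align,
    Stage.TRAIN: _stage_train,
    Stage.EVAL: _stage_eval,
    Stage.EXPLAIN: _stage_explain,
}


def run_stage(stage: Stage | str, cfg: PipelineConfig, force: bool = False) -> list[Path]:
    """Run one stage; no-op (returning the recorded outputs) when the
    manifest shows identical config and inputs, unless ``force``."""
    stage = Stage(stage) if not isinstance(stage, Stage) else stage
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    p = _paths(cfg)
    t0 = time.time()
    # probe inputs first so staleness is judged on the real input set
    body = _BODIES[stage]
    if not force:
        probe = {
            Stage.SYNTH: [],
            Stage.FILTER: [p["reports"]],
            Stage.EMBED: [p["mono_hangul"], p["mono_latin"]],
            Stage.ALIGN: [p["emb_hangul"], p["emb_latin"]],
            Stage.TRAIN: [p["filtered"], p["emb_hangul"], p["emb_latin"], p["transform"]],
            Stage.EVAL: [p["model"], p["test_split"]],
            Stage.EXPLAIN: [p["model"], p["test_split"]],
        }[stage]
        if all(x.exists() for x in probe) and _inputs_fresh(cfg, stage, probe):
            log.info("stage %s up to date — skipping", stage.value)
            man = json.loads(_manifest_path(cfg, stage).read_text())
            return [Path(x) for x in man["outputs"]]
    inputs, outputs = body(cfg, p)
    _write_manifest(cfg, stage, inputs, outputs, time.time() - t0)
    log.info("stage %s done in %.1fs -> %s", stage.value, time.time() - t0,
             ", ".join(str(o) for o in outputs))
    return outputs


def run_all(cfg: PipelineConfig, force: bool = False) -> mx.MetricsReport:
    """All stages in order; returns the final metrics report."""
    for stage in _ORDER:
        run_stage(stage, cfg, force=force)
    return mx.MetricsReport.from_json(_paths(cfg)["metrics_json"].read_text(encoding="utf-8"))
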