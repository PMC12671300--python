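"""End-to-end pipeline: QC -> clustering -> metrics (-> associations).

Mirrors the study flow: violations are marked, transcripts failing QC are
excluded from the metrics table (their cluster annotations are still
emitted, flagged, so exclusions can be audited), each requested
clustering method runs over the full retained sequences, and a manifest
records the configuration, seeds and model checksum for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import yaml

from .clusters import Clustering
from .lexicon import CategoryLexicon, load_lexicon
from .metrics import metrics_table, summarize_metrics
from .relatedness import (
    DEFAULT_THETA,
    EmbeddingModel,
    ThresholdConfig,
    identify_relatedness_clusters,
    load_word2vec_text,
    sequential_relatedness,
)
from .traditional import (
    ALL_RULES,
    PhonematicRuleConfig,
    identify_list_clusters,
    identify_rule_clusters,
)
from .transcripts import (
    Transcript,
    mark_violations,
    qc_transcript,
    read_transcripts,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ConfigError", "run_pipeline", "load_run_config"]


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    methods: tuple[str, ...] = ("list_based", "rule_based", "relatedness")
    model_path: str | None = None
    lexicon_path: str | None = None
    theta: dict = field(default_factory=lambda: dict(DEFAULT_THETA))
    rules: tuple[str, ...] = ALL_RULES
    first10_rule: bool = True
    flag_cue_mismatch: bool = True
    out_dir: str = "vft-out"
    seed: int = 1
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = set(self.methods) - {"list_based", "rule_based", "relatedness"}
        if unknown:
            raise ConfigError(f"unknown methods {sorted(unknown)}")
        if "relatedness" in self.methods and not self.model_path:
            raise ConfigError("relatedness clustering requires model_path")
        if "list_based" in self.methods and not self.lexicon_path:
            raise ConfigError("list-based clustering requires lexicon_path")
        for task, th in self.theta.items():
            if task not in ("semantic", "phonematic") or not 0 <= th <= 1:
                raise ConfigError(f"bad theta entry {task}={th}")


def load_run_config(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in data.items()})
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
    cfg.validate()
    return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _cluster_one(
    transcript: Transcript,
    method: str,
    cfg: RunConfig,
    model: EmbeddingModel | None,
    lex: CategoryLexicon | None,
) -> tuple[Clustering, list | None]:
    words = transcript.words
    if method == "list_based":
        return identify_list_clusters(transcript.tokens, lex), None
    if method == "rule_based":
        rc = PhonematicRuleConfig(rules=frozenset(cfg.rules))
        return identify_rule_clusters(transcript.tokens, rc), None
    theta = ThresholdConfig(cfg.theta[transcript.task])
    clustering = identify_relatedness_clusters(words, model, theta)
    scores = sequential_relatedness(words, model) if len(words) >= 2 else []
    return clustering, scores


def run_pipeline(cfg: RunConfig, transcripts: Sequence[Transcript] | str) -> dict:
    """Run QC, clustering and metrics; write the artifact bundle.

    Returns a summary dict with the output paths, QC counts and the
    metrics table.  All randomness (none at analysis time; training seeds
    live in the model) and configuration are recorded in a manifest.
    """
    cfg.validate()
    logging.basicConfig(level=cfg.log_level)
    if isinstance(transcripts, str):
        fmt = "csv" if transcripts.endswith(".csv") else "jsonl"
        transcripts = read_transcripts(transcripts, fmt)
    model = load_word2vec_text(cfg.model_path) if "relatedness" in cfg.methods else None
    lex = None
    if "list_based" in cfg.methods:
        fmt = "json" if str(cfg.lexicon_path).endswith(".json") else "csv"
        lex = load_lexicon(cfg.lexicon_path, fmt)

    os.makedirs(cfg.out_dir, exist_ok=True)
    qc_rows = []
    cluster_rows = []
    records = []
    n_excluded = 0
    for i, tr in enumerate(transcripts):
        tid = tr.transcript_id or f"t{i:04d}"
        marked = mark_violations(tr, flag_cue_mismatch=cfg.flag_cue_mismatch)
        qc = qc_transcript(marked, first10_rule=cfg.first10_rule)
        qc_rows.append(
            f"{tid},{marked.task},{qc.n_tokens},{qc.n_violations},"
            f"{qc.violation_fraction:.6f},{int(qc.excluded)},{';'.join(qc.reasons)}"
        )
        if qc.excluded:
            n_excluded += 1
        for method in cfg.methods:
            if method == "list_based" and marked.task != "semantic":
                continue
            if method == "rule_based" and marked.task != "phonematic":
                continue
            clustering, scores = _cluster_one(marked, method, cfg, model, lex)
            cluster_rows.append(json.dumps({
                "transcript_id": tid,
                "method": method,
                "excluded": qc.excluded,
                "clusters": [[c.start, c.end] for c in clustering.clusters],
                "links": [sorted(l) for l in clustering.links],
            }, ensure_ascii=False))
            if not qc.excluded:
                records.append((marked, clustering, scores))

    qc_path = os.path.join(cfg.out_dir, "qc_report.csv")
    with open(qc_path, "w", encoding="utf-8") as fh:
        fh.write("transcript_id,task,n_tokens,n_violations,violation_fraction,"
                 "excluded,reasons\n")
        fh.write("\n".join(qc_rows) + ("\n" if qc_rows else ""))

    clusters_path = os.path.join(cfg.out_dir, "clusters.jsonl")
    with open(clusters_path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(cluster_rows) + ("\n" if cluster_rows else ""))

    table = metrics_table(records)
    metrics_path = os.path.join(cfg.out_dir, "metrics.csv")
    table.to_csv(metrics_path, index=False, float_format="%.10g")
    summary_path = os.path.join(cfg.out_dir, "metrics_summary.csv")
    summarize_metrics(table).to_csv(summary_path, index=False, float_format="%.10g")

    manifest = {
        "config": {**asdict(cfg), "methods": list(cfg.methods),
                   "rules": list(cfg.rules)},
        "seed": cfg.seed,
        "n_transcripts": len(transcripts),
        "n_excluded": n_excluded,
        "model_sha256": _sha256(cfg.model_path) if cfg.model_path else None,
        "outputs": ["qc_report.csv", "clusters.jsonl", "metrics.csv",
                    "metrics_summary.csv"],
    }
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, ensure_ascii=False, sort_keys=True)

    logger.info("pipeline wrote %d metric rows (%d transcripts excluded) to %s",
                len(table), n_excluded, cfg.out_dir)
    return {
        "qc_report": qc_path, "clusters": clusters_path,
        "metrics": metrics_path, "summary": summary_path,
        "manifest": manifest_path, "table": table, "n_excluded": n_excluded,
    }
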