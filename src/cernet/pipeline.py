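"""End-to-end orchestration: filter -> DE -> candidate networks ->
binarize -> PMI score -> significance -> select -> assemble -> export."""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

from . import assembly, candidates, diffexpr, matrix, scoring

logger = logging.getLogger("cernet")


@dataclass
class PipelineConfig:
    expression_path: str
    metadata_path: str
    targets_path: str
    out_dir: str | None = None
    min_expressed_fraction: float = 0.5
    pseudocount: float = 1.0
    thresholds: diffexpr.DEThresholds = field(default_factory=diffexpr.DEThresholds)
    binarize_scope: str = "tumor"  # or "all"
    log_base: str = "e"
    grouping: str = "per_mirna"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.binarize_scope not in ("tumor", "all"):
            raise ValueError("binarize_scope must be 'tumor' or 'all'")
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        import yaml

        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = diffexpr.DEThresholds(
                fc_ratio_by_type=thr.get(
                    "fc_ratio_by_type", cfg.thresholds.fc_ratio_by_type
                ),
                p_max=thr.get("p_max", cfg.thresholds.p_max),
            )
        return cfg


@dataclass
class PipelineReport:
    """Stage-by-stage counts of an end-to-end run."""

    n_rnas_input: int = 0
    n_rnas_retained: int = 0
    n_samples: int = 0
    de_counts: dict[str, int] = field(default_factory=dict)
    n_candidate_networks: int = 0
    candidate_crosstalks_per_mirna: dict[str, int] = field(default_factory=dict)
    n_candidate_crosstalks: int = 0
    selected_per_mirna: dict[str, int] = field(default_factory=dict)
    n_selected_crosstalks: int = 0
    n_networks: int = 0

    def to_dict(self) -> dict:
        return {
            "n_rnas_input": self.n_rnas_input,
            "n_rnas_retained": self.n_rnas_retained,
            "n_samples": self.n_samples,
            "de_counts": dict(sorted(self.de_counts.items())),
            "n_candidate_networks": self.n_candidate_networks,
            "candidate_crosstalks_per_mirna": dict(
                sorted(self.candidate_crosstalks_per_mirna.items())
            ),
            "n_candidate_crosstalks": self.n_candidate_crosstalks,
            "selected_per_mirna": dict(sorted(self.selected_per_mirna.items())),
            "n_selected_crosstalks": self.n_selected_crosstalks,
            "n_networks": self.n_networks,
        }


@dataclass
class PipelineResult:
    report: PipelineReport
    de: object  # pd.DataFrame
    candidate_networks: list[candidates.CandidateNetwork]
    scored: list[scoring.ScoredCrosstalk]
    selected: list[scoring.ScoredCrosstalk]
    networks: list[assembly.CeRNANetwork]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline; writes intermediate tables and network
    exports when ``config.out_dir`` is set."""
    report = PipelineReport()

    x = _stage("read")(matrix.read_expression_table)(
        config.expression_path, config.metadata_path
    )
    tmap = _stage("read-targets")(candidates.read_target_map)(config.targets_path)
    report.n_rnas_input = x.n_rnas
    report.n_samples = x.n_samples

    x = _stage("filter")(matrix.filter_low_expression)(
        x, min_fraction=config.min_expressed_fraction
    )
    report.n_rnas_retained = x.n_rnas

    de = _stage("de")(diffexpr.differential_expression)(
        x, thresholds=config.thresholds, pseudocount=config.pseudocount
    )
    for rna_type in matrix.RNA_TYPES:
        sub = de[de["rna_type"] == rna_type]
        report.de_counts[rna_type] = int((sub["status"] != "unchanged").sum())

    nets = _stage("candidates")(candidates.build_candidate_networks)(tmap, de)
    report.n_candidate_networks = len(nets)
    for net in nets:
        report.candidate_crosstalks_per_mirna[net.mirna] = net.n * net.m
    report.n_candidate_crosstalks = sum(report.candidate_crosstalks_per_mirna.values())

    def _binarize():
        if config.binarize_scope == "tumor":
            return matrix.binarize_equal_frequency(matrix.subset_samples(x, "tumor"))
        binary = matrix.binarize_equal_frequency(x)
        tumor_cols = matrix.subset_samples(x, "tumor").sample_ids
        return matrix.BinaryExpressionMatrix(values=binary.values[tumor_cols])

    I = _stage("binarize")(_binarize)()

    def _score_all():
        scored: list[scoring.ScoredCrosstalk] = []
        for net in nets:
            scored.extend(
                scoring.score_network(net, I, log_base=config.log_base)
            )
        return scored

    scored = _stage("score")(_score_all)()
    scored = _stage("significance")(scoring.significance)(
        scored, grouping=config.grouping
    )
    selected = _stage("select")(scoring.select_significant)(scored, alpha=config.alpha)
    networks = _stage("assemble")(assembly.assemble_networks)(selected)

    for s in selected:
        report.selected_per_mirna[s.mirna] = report.selected_per_mirna.get(s.mirna, 0) + 1
    report.n_selected_crosstalks = len(selected)
    report.n_networks = len(networks)

    if config.out_dir is not None:
        os.makedirs(config.out_dir, exist_ok=True)
        out = config.out_dir
        matrix.write_expression_table(
            x,
            os.path.join(out, "filtered_expression.tsv"),
            os.path.join(out, "metadata.tsv"),
        )
        diffexpr.write_de_table(de, os.path.join(out, "de.tsv"))
        candidates.write_candidate_crosstalks(nets, os.path.join(out, "candidates.tsv"))
        scoring.write_scored_crosstalks(scored, os.path.join(out, "scored.tsv"))
        scoring.write_scored_crosstalks(selected, os.path.join(out, "selected.tsv"))
        assembly.export_networks(networks, os.path.join(out, "networks"))
        with open(os.path.join(out, "report.json"), "w", encoding="utf-8") as fh:
            json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    return PipelineResult(
        report=report,
        de=de,
        candidate_networks=nets,
        scored=scored,
        selected=selected,
        networks=networks,
    )
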