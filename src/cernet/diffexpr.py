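"""Tumor-vs-normal differential expression on a paired design.

Fold change is the log2 ratio of condition means with a pseudocount; the
test is a two-sided paired t-test on log2(x + 1) per-pair differences. RNAs
are classified up/down/unchanged under RNA-type-specific ratio thresholds
(defaults: lncRNA 3.0, miRNA/mRNA 2.0) and a p-value gate (default 0.05),
with inclusive boundary comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import CONDITIONS, RNA_TYPES, ExpressionMatrix

STATUSES = ("up", "down", "unchanged")


@dataclass
class DEThresholds:
    """Differential-expression cutoffs.

    ``fc_ratio_by_type`` holds ratio-scale fold-change cutoffs (an RNA passes
    when |log2 FC| >= log2(ratio)); ``p_max`` is the p-value gate.
    """

    fc_ratio_by_type: dict[str, float] = field(
        default_factory=lambda: {"lncRNA": 3.0, "miRNA": 2.0, "mRNA": 2.0}
    )
    p_max: float = 0.05

    def __post_init__(self) -> None:
        for rna_type, ratio in self.fc_ratio_by_type.items():
            if rna_type not in RNA_TYPES:
                raise ValueError(f"unknown RNA type {rna_type!r}")
            if ratio < 1:
                raise ValueError(f"fold-change ratio must be >= 1, got {ratio}")
        if not 0 < self.p_max < 1:
            raise ValueError(f"p_max must be in (0, 1), got {self.p_max}")

    def log2_cutoff(self, rna_type: str) -> float:
        try:
            return float(np.log2(self.fc_ratio_by_type[rna_type]))
        except KeyError:
            raise ValueError(f"no fold-change threshold for RNA type {rna_type!r}") from None


def _paired_frames(x: ExpressionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tumor and normal sub-frames with columns aligned by pair id."""
    for cond in CONDITIONS:
        if not (x.conditions == cond).any():
            raise ValueError(f"no samples with condition {cond!r}")
    x.validate_paired()
    by_pair: dict[str, dict[str, str]] = {}
    for sample in x.sample_ids:
        by_pair.setdefault(x.pair_ids[sample], {})[x.conditions[sample]] = sample
    pairs = sorted(by_pair)
    tumor = x.values[[by_pair[p]["tumor"] for p in pairs]]
    normal = x.values[[by_pair[p]["normal"] for p in pairs]]
    return tumor, normal


def log2_fold_changes(x: ExpressionMatrix, pseudocount: float = 1.0) -> pd.Series:
    """Per-RNA log2((mean_tumor + c) / (mean_normal + c)); > 0 means
    up-regulated in tumor."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    tumor, normal = _paired_frames(x)
    return np.log2((tumor.mean(axis=1) + pseudocount) / (normal.mean(axis=1) + pseudocount))


def log2_fold_change(x: ExpressionMatrix, rna: str, pseudocount: float = 1.0) -> float:
    if rna not in x.values.index:
        raise KeyError(f"unknown RNA id {rna!r}")
    return float(log2_fold_changes(x, pseudocount=pseudocount)[rna])


def paired_t_tests(x: ExpressionMatrix) -> pd.Series:
    """Two-sided paired t-test p-values on log2(value + 1) differences.

    Degenerate rows are resolved deterministically: all-zero differences give
    p = 1 (no evidence of change), constant nonzero differences give p = 0
    (the zero-variance limit of the t statistic).
    """
    tumor, normal = _paired_frames(x)
    if tumor.shape[1] < 2:
        raise ValueError("paired t-test needs at least 2 tumor/normal pairs")
    diffs = np.log2(tumor.to_numpy() + 1.0) - np.log2(normal.to_numpy() + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on zero-variance rows
        p = stats.ttest_rel(
            np.log2(tumor.to_numpy() + 1.0), np.log2(normal.to_numpy() + 1.0), axis=1
        ).pvalue
    sd = diffs.std(axis=1, ddof=1)
    mean = diffs.mean(axis=1)
    p = np.where(sd == 0, np.where(mean == 0, 1.0, 0.0), p)
    return pd.Series(p, index=x.values.index, name="p_value")


def paired_t_test(x: ExpressionMatrix, rna: str) -> float:
    if rna not in x.values.index:
        raise KeyError(f"unknown RNA id {rna!r}")
    return float(paired_t_tests(x)[rna])


def classify_differential(results: pd.DataFrame, thresholds: DEThresholds | None = None) -> pd.DataFrame:
    """Assign up/down/unchanged status from log2 fold changes and p-values.

    ``results`` must be indexed by RNA id with columns ``rna_type``,
    ``log2_fc`` and ``p_value``. up: log2_fc >= log2(ratio) and p <= p_max;
    down: log2_fc <= -log2(ratio) and p <= p_max; otherwise unchanged.
    """
    thresholds = thresholds or DEThresholds()
    out = results.copy()
    cutoffs = out["rna_type"].map(
        {t: thresholds.log2_cutoff(t) for t in set(out["rna_type"])}
    )
    passes_p = out["p_value"] <= thresholds.p_max
    status = np.where(
        passes_p & (out["log2_fc"] >= cutoffs), "up",
        np.where(passes_p & (out["log2_fc"] <= -cutoffs), "down", "unchanged"),
    )
    out["status"] = status
    return out


def differential_expression(
    x: ExpressionMatrix,
    thresholds: DEThresholds | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Full per-RNA DE table: rna_type, log2_fc, p_value, status."""
    results = pd.DataFrame(
        {
            "rna_type": x.rna_types,
            "log2_fc": log2_fold_changes(x, pseudocount=pseudocount),
            "p_value": paired_t_tests(x),
        }
    )
    results.index.name = "rna_id"
    return classify_differential(results, thresholds)


def write_de_table(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    de = pd.read_csv(path, sep="\t", index_col="rna_id")
    for col in ("rna_type", "log2_fc", "p_value", "status"):
        if col not in de.columns:
            raise ValueError(f"{path}: missing DE column {col!r}")
    return de
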