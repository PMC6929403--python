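"""Expression matrices: I/O, validation, noise filtering and binarization.

The central objects are :class:`ExpressionMatrix` — a non-negative RNA x
sample table carrying per-RNA type labels (lncRNA/miRNA/mRNA) and per-sample
condition (tumor/normal) and patient-pair metadata — and
:class:`BinaryExpressionMatrix`, its equal-frequency discretization: per RNA,
samples strictly above the row median are "relatively high" (1), the rest
"relatively low" (0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

RNA_TYPES = ("lncRNA", "miRNA", "mRNA")
CONDITIONS = ("tumor", "normal")


class ValidationError(ValueError):
    """Raised when a table violates the expression-matrix contract."""


@dataclass
class ExpressionMatrix:
    """Real-valued expression with RNA-type and sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by RNA id, columns are sample ids, entries are
        non-negative finite expression levels (normalized counts/FPKM-like).
    rna_types
        Series mapping RNA id -> one of ``lncRNA``, ``miRNA``, ``mRNA``.
    conditions
        Series mapping sample id -> ``tumor`` or ``normal``.
    pair_ids
        Series mapping sample id -> patient pair identifier.
    """

    values: pd.DataFrame
    rna_types: pd.Series
    conditions: pd.Series
    pair_ids: pd.Series

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate RNA ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float, copy=False)
        if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
            bad = v.index[np.where(~(np.isfinite(arr)) | (arr < 0))[0][0]]
            raise ValidationError(f"negative or non-finite expression value in row {bad!r}")
        self.rna_types = self.rna_types.reindex(v.index)
        if self.rna_types.isna().any():
            missing = self.rna_types.index[self.rna_types.isna()].tolist()
            raise ValidationError(f"RNA ids without a type label: {missing[:5]}")
        unknown = set(self.rna_types.unique()) - set(RNA_TYPES)
        if unknown:
            raise ValidationError(f"unknown RNA types {sorted(unknown)}; expected {RNA_TYPES}")
        self.conditions = self.conditions.reindex(v.columns)
        self.pair_ids = self.pair_ids.reindex(v.columns)
        if self.conditions.isna().any() or self.pair_ids.isna().any():
            missing = v.columns[self.conditions.isna() | self.pair_ids.isna()].tolist()
            raise ValidationError(
                f"samples missing from the metadata table: {missing[:5]}"
            )
        unknown = set(self.conditions.unique()) - set(CONDITIONS)
        if unknown:
            raise ValidationError(f"unknown conditions {sorted(unknown)}; expected {CONDITIONS}")

    # -- basic accessors -------------------------------------------------
    @property
    def rna_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_rnas(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def rnas_of_type(self, rna_type: str) -> list[str]:
        return self.rna_types.index[self.rna_types == rna_type].tolist()

    def validate_paired(self) -> None:
        """Check the paired design: each pair id has exactly one tumor and one
        normal sample."""
        df = pd.DataFrame({"condition": self.conditions, "pair": self.pair_ids})
        counts = df.groupby(["pair", "condition"]).size().unstack(fill_value=0)
        for cond in CONDITIONS:
            if cond not in counts.columns:
                counts[cond] = 0
        bad = counts[(counts["tumor"] != 1) | (counts["normal"] != 1)]
        if len(bad):
            raise ValidationError(
                "unpaired design: pair ids without exactly one tumor and one "
                f"normal sample: {bad.index.tolist()[:5]}"
            )


@dataclass
class BinaryExpressionMatrix:
    """0/1 high/low expression per (RNA, sample); accessor semantics I[r, s]."""

    values: pd.DataFrame  # int8, entries in {0, 1}

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("binary expression entries must be 0 or 1")

    def __getitem__(self, key: tuple[str, str]) -> int:
        rna, sample = key
        return int(self.values.at[rna, sample])

    @property
    def rna_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_expression_table(expression_path, metadata_path) -> ExpressionMatrix:
    """Read an expression TSV plus a sample-metadata TSV.

    The expression file has header ``rna_id<TAB>rna_type<TAB><sample ids...>``;
    the metadata file has columns ``sample_id``, ``condition``, ``pair_id``.
    Samples present in the expression header but absent from the metadata, or
    a broken paired design, raise :class:`ValidationError`.
    """
    with open(expression_path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 3 or header[0] != "rna_id" or header[1] != "rna_type":
        raise ValidationError(
            f"{expression_path}: expected header starting 'rna_id\\trna_type', got {header[:2]}"
        )
    sample_ids = header[2:]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValidationError(f"{expression_path}: duplicate sample ids in header")
    raw = pd.read_csv(
        expression_path, sep="\t", header=0, dtype={"rna_id": str, "rna_type": str}
    )
    try:
        values = raw.set_index("rna_id")[sample_ids].astype(float)
    except ValueError as exc:
        raise ValidationError(f"{expression_path}: non-numeric expression value ({exc})") from exc
    rna_types = raw.set_index("rna_id")["rna_type"]

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "condition", "pair_id"):
        if col not in meta.columns:
            raise ValidationError(f"{metadata_path}: missing column {col!r}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError(f"{metadata_path}: duplicate sample_id rows")
    meta = meta.set_index("sample_id")

    x = ExpressionMatrix(
        values=values,
        rna_types=rna_types,
        conditions=meta["condition"],
        pair_ids=meta["pair_id"],
    )
    x.validate_paired()
    return x


def write_expression_table(x: ExpressionMatrix, expression_path, metadata_path) -> None:
    """Write the TSV pair read back by :func:`read_expression_table`."""
    out = x.values.copy()
    out.insert(0, "rna_type", x.rna_types)
    out.index.name = "rna_id"
    out.to_csv(expression_path, sep="\t")
    meta = pd.DataFrame(
        {"sample_id": x.sample_ids,
         "condition": x.conditions.to_numpy(),
         "pair_id": x.pair_ids.to_numpy()}
    )
    meta.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filtering, binarization, subsetting
# ---------------------------------------------------------------------------

def filter_low_expression(x: ExpressionMatrix, min_fraction: float = 0.5) -> ExpressionMatrix:
    """Drop RNAs expressed (value > 0) in fewer than ``ceil(min_fraction * n)``
    samples.

    Low-frequency RNAs carry little signal and add noise downstream; the
    default keeps RNAs expressed in at least half of all samples.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    need = math.ceil(round(min_fraction * x.n_samples, 9))
    nonzero = (x.values > 0).sum(axis=1)
    keep = nonzero >= need
    if not keep.any():
        warnings.warn("filter_low_expression removed every RNA", stacklevel=2)
    return ExpressionMatrix(
        values=x.values.loc[keep],
        rna_types=x.rna_types.loc[keep],
        conditions=x.conditions,
        pair_ids=x.pair_ids,
    )


def binarize_equal_frequency(x: ExpressionMatrix) -> BinaryExpressionMatrix:
    """Equal-frequency (median) discretization.

    Per RNA row, entries strictly greater than the row median over the samples
    of ``x`` become 1 ("relatively high"), entries <= median become 0.
    Constant rows therefore binarize to all zeros.
    """
    if x.n_samples < 2:
        raise ValueError("binarization needs at least 2 samples")
    med = x.values.median(axis=1)
    binary = x.values.gt(med, axis=0).astype(np.int8)
    return BinaryExpressionMatrix(values=binary)


def subset_samples(x: ExpressionMatrix, condition: str) -> ExpressionMatrix:
    """Restrict to samples of one condition, preserving sample order."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    mask = (x.conditions == condition).to_numpy()
    if not mask.any():
        raise ValueError(f"no samples with condition {condition!r}")
    cols = x.values.columns[mask]
    return ExpressionMatrix(
        values=x.values[cols],
        rna_types=x.rna_types,
        conditions=x.conditions[cols],
        pair_ids=x.pair_ids[cols],
    )
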