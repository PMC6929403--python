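"""Competition-sample counting, PMI competition scores and erfc selection.

Within one miRNA's candidate network, a tumor sample supports the crosstalk
T = (lnc, mir, mr) when its binarized expression shows the competition
pattern — either (lnc=0, mir=1, mr=0) or (lnc=1, mir=0, mr=1). Support
counts over the n x m (lncRNA, mRNA) grid are normalized into a joint
distribution, and each crosstalk is scored by pointwise mutual information

    PMI(lnc_i, mr_j) = log P(lnc_i, mr_j) / (P(lnc_i) P(mr_j)),

where the marginals are row/column sums of the joint. Positive scores are
standardized within a group (per miRNA by default) to theta, converted to
p = erfc(theta / sqrt(2)), and crosstalks with p < alpha are selected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import erfc

from .candidates import CandidateNetwork
from .matrix import BinaryExpressionMatrix

_COMPETITION_PATTERNS = ((0, 1, 0), (1, 0, 1))


def is_competition_sample(
    I: BinaryExpressionMatrix, lnc: str, mirna: str, mr: str, sample: str
) -> bool:
    """True iff the sample shows (0,1,0) or (1,0,1) for (lnc, mir, mr)."""
    pattern = (I[lnc, sample], I[mirna, sample], I[mr, sample])
    return pattern in _COMPETITION_PATTERNS


def support_count(
    I: BinaryExpressionMatrix,
    lnc: str,
    mirna: str,
    mr: str,
    samples: list[str] | None = None,
) -> int:
    """Number of competition samples of T = (lnc, mir, mr) over ``samples``."""
    if samples is None:
        samples = I.sample_ids
    if len(samples) == 0:
        raise ValueError("empty sample set")
    a = I.values.loc[lnc, samples].to_numpy()
    b = I.values.loc[mirna, samples].to_numpy()
    c = I.values.loc[mr, samples].to_numpy()
    cond1 = (1 - a) * b * (1 - c)
    cond2 = a * (1 - b) * c
    return int(cond1.sum() + cond2.sum())


@dataclass
class SupportTable:
    """Support counts supp(lnc_i, mir, mr_j) over one miRNA's network grid."""

    mirna: str
    lnc_ids: tuple[str, ...]
    mr_ids: tuple[str, ...]
    supp: np.ndarray  # shape (n, m), non-negative ints
    n_samples: int

    def __post_init__(self) -> None:
        self.supp = np.asarray(self.supp, dtype=np.int64)
        if self.supp.shape != (len(self.lnc_ids), len(self.mr_ids)):
            raise ValueError("support matrix shape does not match id lists")
        if (self.supp < 0).any() or (self.supp > self.n_samples).any():
            raise ValueError("support counts must lie in [0, n_samples]")


def compute_support_table(
    net: CandidateNetwork,
    I: BinaryExpressionMatrix,
    samples: list[str] | None = None,
) -> SupportTable:
    """Vectorized support grid: supp(i, j) counts samples matching either
    competition pattern."""
    if samples is None:
        samples = I.sample_ids
    if len(samples) == 0:
        raise ValueError("empty sample set")
    A = I.values.loc[list(net.lnc_ids), samples].to_numpy(dtype=np.int64)
    b = I.values.loc[net.mirna, samples].to_numpy(dtype=np.int64)
    C = I.values.loc[list(net.mr_ids), samples].to_numpy(dtype=np.int64)
    supp = ((1 - A) * b) @ (1 - C).T + (A * (1 - b)) @ C.T
    return SupportTable(
        mirna=net.mirna,
        lnc_ids=net.lnc_ids,
        mr_ids=net.mr_ids,
        supp=supp,
        n_samples=len(samples),
    )


def network_probabilities(
    supports: SupportTable | np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint and marginal competition-sample probabilities of a network grid.

    Returns ``(p_joint, p_lnc, p_mr)`` where ``p_joint`` sums to 1 and the
    marginals are its row/column sums.
    """
    supp = supports.supp if isinstance(supports, SupportTable) else np.asarray(supports)
    total = supp.sum()
    if total == 0:
        raise ValueError("network has no competition samples")
    p_joint = supp / total
    return p_joint, p_joint.sum(axis=1), p_joint.sum(axis=0)


def pmi(p_joint: float, p_lnc: float, p_mr: float, log_base: str = "e") -> float:
    """Pointwise mutual information log(p_joint / (p_lnc * p_mr)).

    Returns NaN (flagged-undefined) when ``p_joint`` is 0; such crosstalks are
    discarded before significance. Negative values mean the pair co-occurs in
    competition samples less often than independence predicts.
    """
    if p_lnc <= 0 or p_mr <= 0:
        raise ValueError("marginal probabilities must be positive")
    if p_joint == 0:
        return float("nan")
    value = math.log(p_joint / (p_lnc * p_mr))
    if log_base == "2":
        value /= math.log(2.0)
    elif log_base != "e":
        raise ValueError(f"log_base must be 'e' or '2', got {log_base!r}")
    return value


@dataclass
class ScoredCrosstalk:
    """A crosstalk T = (lnc, mir, mr) with support, PMI score and, once
    significance has run, theta/p-value/selection."""

    lnc: str
    mirna: str
    mr: str
    supp: int
    p_joint: float
    p_lnc: float
    p_mr: float
    pmi: float  # NaN = flagged-undefined (supp == 0)
    theta: float = float("nan")
    p_value: float = float("nan")
    selected: bool = False

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pmi)


@dataclass
class ScoreSummary:
    """Positive-score statistics of one significance group."""

    group: str
    t: int  # number of positive scores
    mean_pmi: float
    sigma: float


def score_network(
    net: CandidateNetwork,
    I: BinaryExpressionMatrix,
    samples: list[str] | None = None,
    log_base: str = "e",
) -> list[ScoredCrosstalk]:
    """One ScoredCrosstalk per (lnc_i, mr_j) pair of the network, in
    lexicographic order; significance fields are left unset."""
    table = compute_support_table(net, I, samples)
    p_joint, p_lnc, p_mr = network_probabilities(table)
    out = []
    for i, lnc in enumerate(net.lnc_ids):
        for j, mr in enumerate(net.mr_ids):
            if p_joint[i, j] == 0:
                score = float("nan")  # flagged-undefined, incl. zero marginals
            else:
                score = pmi(p_joint[i, j], p_lnc[i], p_mr[j], log_base=log_base)
            out.append(
                ScoredCrosstalk(
                    lnc=lnc,
                    mirna=net.mirna,
                    mr=mr,
                    supp=int(table.supp[i, j]),
                    p_joint=float(p_joint[i, j]),
                    p_lnc=float(p_lnc[i]),
                    p_mr=float(p_mr[j]),
                    pmi=score,
                )
            )
    return out


def _groups(scored: list[ScoredCrosstalk], grouping: str) -> dict[str, list[int]]:
    if grouping == "per_mirna":
        groups: dict[str, list[int]] = {}
        for idx, s in enumerate(scored):
            groups.setdefault(s.mirna, []).append(idx)
        return groups
    if grouping == "global":
        return {"global": list(range(len(scored)))}
    raise ValueError(f"grouping must be 'per_mirna' or 'global', got {grouping!r}")


def significance(
    scored: list[ScoredCrosstalk], grouping: str = "per_mirna"
) -> list[ScoredCrosstalk]:
    """Standardize positive scores within each group and convert to p-values.

    Zero, negative and undefined scores are discarded first (their theta and
    p-value stay NaN). For a retained crosstalk a, theta_a = (PMI_a - mean) /
    sigma over the group's positive scores (population sigma) and
    p_a = erfc(theta_a / sqrt(2)), clamped to [0, 1]. A group whose sigma is 0
    gets p = 1 everywhere; a group with no positive score is dropped. Both
    cases emit a warning.
    """
    out = [replace(s, theta=float("nan"), p_value=float("nan"), selected=False) for s in scored]
    for group, indices in _groups(scored, grouping).items():
        positive = [i for i in indices if scored[i].defined and scored[i].pmi > 0]
        if not positive:
            warnings.warn(
                f"group {group!r}: no positive competition scores; group dropped",
                stacklevel=2,
            )
            continue
        values = np.array([scored[i].pmi for i in positive])
        mean = float(values.mean())
        sigma = float(values.std(ddof=0))
        # identical scores can leave sigma at rounding-noise scale (~1e-17)
        if sigma <= 1e-12 * max(1.0, abs(mean)):
            warnings.warn(
                f"group {group!r}: zero variance among positive scores; all p-values set to 1",
                stacklevel=2,
            )
            for i in positive:
                out[i].theta = 0.0
                out[i].p_value = 1.0
            continue
        for i in positive:
            theta = (scored[i].pmi - mean) / sigma
            out[i].theta = theta
            out[i].p_value = float(min(max(erfc(theta / math.sqrt(2.0)), 0.0), 1.0))
    return out


def group_summaries(
    scored: list[ScoredCrosstalk], grouping: str = "per_mirna"
) -> list[ScoreSummary]:
    """Positive-score count, mean and sigma per significance group."""
    summaries = []
    for group, indices in sorted(_groups(scored, grouping).items()):
        values = np.array(
            [scored[i].pmi for i in indices if scored[i].defined and scored[i].pmi > 0]
        )
        if len(values) == 0:
            continue
        summaries.append(
            ScoreSummary(
                group=group,
                t=len(values),
                mean_pmi=float(values.mean()),
                sigma=float(values.std(ddof=0)),
            )
        )
    return summaries


def select_significant(
    scored: list[ScoredCrosstalk], alpha: float = 0.05
) -> list[ScoredCrosstalk]:
    """Crosstalks with p-value strictly below ``alpha``, sorted by descending
    PMI (ties broken by ids for determinism); selection flags set."""
    if not 0 <= alpha <= 1:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    chosen = [
        replace(s, selected=True)
        for s in scored
        if not math.isnan(s.p_value) and s.p_value < alpha
    ]
    chosen.sort(key=lambda s: (-s.pmi, s.mirna, s.lnc, s.mr))
    return chosen


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = [
    "lnc_id", "mirna_id", "mr_id", "supp",
    "p_joint", "p_lnc", "p_mr", "pmi", "theta", "p_value", "selected",
]


def scored_to_frame(scored: list[ScoredCrosstalk]) -> pd.DataFrame:
    rows = [
        (s.lnc, s.mirna, s.mr, s.supp, s.p_joint, s.p_lnc, s.p_mr,
         s.pmi, s.theta, s.p_value, s.selected)
        for s in scored
    ]
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)


def frame_to_scored(df: pd.DataFrame) -> list[ScoredCrosstalk]:
    return [
        ScoredCrosstalk(
            lnc=row.lnc_id, mirna=row.mirna_id, mr=row.mr_id, supp=int(row.supp),
            p_joint=float(row.p_joint), p_lnc=float(row.p_lnc), p_mr=float(row.p_mr),
            pmi=float(row.pmi), theta=float(row.theta), p_value=float(row.p_value),
            selected=bool(row.selected),
        )
        for row in df.itertuples(index=False)
    ]


def write_scored_crosstalks(scored: list[ScoredCrosstalk], path) -> None:
    scored_to_frame(scored).to_csv(path, sep="\t", index=False)


def read_scored_crosstalks(path) -> list[ScoredCrosstalk]:
    df = pd.read_csv(path, sep="\t", dtype={"lnc_id": str, "mirna_id": str, "mr_id": str})
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return frame_to_scored(df)
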