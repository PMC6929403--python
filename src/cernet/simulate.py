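"""Synthetic paired tumor/normal RNA-seq data with planted ceRNA triples.

The generator emits everything the pipeline consumes — an expression matrix,
sample metadata, a miRNA target map — plus the ground truth needed to score
recovery. Each planted triple (lncRNA, miRNA, mRNA) follows the negative
competition-regulation pattern between conditions (lncRNA and mRNA
up-regulated in tumor, miRNA down-regulated) and, within tumor samples, an
anti-correlated high/low structure: a per-sample latent competition state
(a balanced random assignment — exactly half of the tumor samples high, so
each sample is marginally Bernoulli(1/2)) puts the lncRNA and mRNA in their
high regime and the miRNA in its low regime when active, and the reverse
otherwise. Each RNA's regime is flipped independently with probability
``flip_prob`` before negative-binomial counts are drawn, so ``flip_prob``
controls how cleanly the binarized tumor patterns satisfy the competition
conditions. Regime draws are kept on opposite sides of the tumor mean, so
with ``flip_prob = 0`` median binarization recovers the latent state at
every tumor sample.

Decoy RNAs are sampled independently of every latent state. Half of them
(``de_decoy_fraction``) are differentially expressed with the same fold
factors, so the differential-expression gate, the competition-regulation
sign filter and the PMI stage all have non-trivial work; the rest have equal
tumor and normal means. Decoy target-map edges wire differentially expressed
decoys into the planted (and decoy) miRNA networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import TargetMap
from .matrix import ExpressionMatrix


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate a modest paired cohort.

    Fold factors are tumor/normal mean ratios: 4.0 / 3.0 for planted lncRNAs
    and mRNAs (comfortably past the 3.0 / 2.0 differential-expression
    cutoffs) and 1/3 for planted miRNAs (down-regulation).
    """

    n_pairs: int = 50
    n_planted: int = 20
    n_decoy_lnc: int = 100
    n_decoy_mr: int = 100
    n_decoy_mirna: int = 10
    fold_lnc: float = 4.0
    fold_mr: float = 3.0
    fold_mirna: float = 1.0 / 3.0
    flip_prob: float = 0.1
    dispersion: float = 8.0
    baseline_mean: float = 100.0
    de_decoy_fraction: float = 0.5
    decoy_targets_per_mirna: int = 6
    regime_separation: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 2:
            raise ValueError("n_pairs must be >= 2")
        if self.n_planted < 0 or min(self.n_decoy_lnc, self.n_decoy_mr, self.n_decoy_mirna) < 0:
            raise ValueError("RNA counts must be non-negative")
        for name in ("fold_lnc", "fold_mr", "fold_mirna", "dispersion", "baseline_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5)")
        if not 0 <= self.de_decoy_fraction <= 1:
            raise ValueError("de_decoy_fraction must lie in [0, 1]")
        if not 0 < self.regime_separation < 1:
            raise ValueError("regime_separation must lie in (0, 1)")


@dataclass
class GroundTruth:
    """Planted triples and each planted RNA's true regulation direction."""

    triples: pd.DataFrame  # columns lnc_id, mirna_id, mr_id
    directions: pd.Series  # rna_id -> "up" / "down"

    def triple_set(self) -> set[tuple[str, str, str]]:
        return {
            (r.lnc_id, r.mirna_id, r.mr_id)
            for r in self.triples.itertuples(index=False)
        }


def _negative_binomial(rng: np.random.Generator, mean, dispersion: float, size) -> np.ndarray:
    """NB draws parameterized by mean and overdispersion r (variance
    mean + mean^2 / r)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size).astype(float)


def simulate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, TargetMap, GroundTruth]:
    """Generate (expression matrix, target map, ground truth); fully
    deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_t = cfg.n_pairs  # tumor samples == patient pairs

    pair_ids = [f"PT{i + 1:03d}" for i in range(cfg.n_pairs)]
    tumor_samples = [f"{p}-T" for p in pair_ids]
    normal_samples = [f"{p}-N" for p in pair_ids]

    planted = {
        "lncRNA": [f"LNC-P{k + 1:03d}" for k in range(cfg.n_planted)],
        "miRNA": [f"MIR-P{k + 1:03d}" for k in range(cfg.n_planted)],
        "mRNA": [f"MR-P{k + 1:03d}" for k in range(cfg.n_planted)],
    }
    decoys = {
        "lncRNA": [f"LNC-D{k + 1:03d}" for k in range(cfg.n_decoy_lnc)],
        "miRNA": [f"MIR-D{k + 1:03d}" for k in range(cfg.n_decoy_mirna)],
        "mRNA": [f"MR-D{k + 1:03d}" for k in range(cfg.n_decoy_mr)],
    }
    fold = {"lncRNA": cfg.fold_lnc, "miRNA": cfg.fold_mirna, "mRNA": cfg.fold_mr}

    rows: dict[str, np.ndarray] = {}
    rna_types: dict[str, str] = {}
    directions: dict[str, str] = {}
    sep = cfg.regime_separation

    def _regime_counts(state: np.ndarray, mean_t: float) -> np.ndarray:
        """Tumor counts: low-regime draws capped at the tumor mean, high-regime
        draws shifted above it, so the two regimes never overlap and the row
        median always separates them."""
        mid = math.floor(mean_t)
        lo = _negative_binomial(rng, mean_t * (1 - sep), cfg.dispersion, (n_t,))
        hi_mean = max(mean_t * (1 + sep) - mid - 1, 1.0)
        hi = mid + 1 + _negative_binomial(rng, hi_mean, cfg.dispersion, (n_t,))
        return np.where(state == 1, hi, np.minimum(lo, mid))

    # Planted triples: shared latent competition state per triple, balanced
    # so the equal-frequency median falls between the regimes.
    base_state = np.array([1] * (n_t // 2) + [0] * (n_t - n_t // 2))
    for k in range(cfg.n_planted):
        c = rng.permutation(base_state)
        for rna_type, anti in (("lncRNA", False), ("miRNA", True), ("mRNA", False)):
            rna = planted[rna_type][k]
            rna_types[rna] = rna_type
            directions[rna] = "down" if anti else "up"
            state = (1 - c) if anti else c
            flips = rng.random(n_t) < cfg.flip_prob
            state = np.where(flips, 1 - state, state)
            tumor = _regime_counts(state, fold[rna_type] * cfg.baseline_mean)
            normal = _negative_binomial(rng, cfg.baseline_mean, cfg.dispersion, (n_t,))
            rows[rna] = np.concatenate([tumor, normal])

    # Decoys: independent of every latent state; a fraction are DE.
    de_decoys: dict[str, list[str]] = {}
    for rna_type in ("lncRNA", "miRNA", "mRNA"):
        ids = decoys[rna_type]
        n_de = int(round(cfg.de_decoy_fraction * len(ids)))
        de_decoys[rna_type] = ids[:n_de]
        for idx, rna in enumerate(ids):
            rna_types[rna] = rna_type
            is_de = idx < n_de
            mean_t = fold[rna_type] * cfg.baseline_mean if is_de else cfg.baseline_mean
            tumor = _negative_binomial(rng, mean_t, cfg.dispersion, (n_t,))
            normal = _negative_binomial(rng, cfg.baseline_mean, cfg.dispersion, (n_t,))
            rows[rna] = np.concatenate([tumor, normal])

    rna_order = (
        planted["lncRNA"] + decoys["lncRNA"]
        + planted["miRNA"] + decoys["miRNA"]
        + planted["mRNA"] + decoys["mRNA"]
    )
    values = pd.DataFrame(
        np.vstack([rows[r] for r in rna_order]),
        index=pd.Index(rna_order, name="rna_id"),
        columns=tumor_samples + normal_samples,
    )
    sample_ids = tumor_samples + normal_samples
    x = ExpressionMatrix(
        values=values,
        rna_types=pd.Series(rna_types, name="rna_type"),
        conditions=pd.Series(
            ["tumor"] * n_t + ["normal"] * n_t, index=sample_ids, name="condition"
        ),
        pair_ids=pd.Series(pair_ids + pair_ids, index=sample_ids, name="pair_id"),
    )

    # Target map: planted pairs plus random decoy edges. Planted RNAs are
    # wired only to their own miRNA so the ground truth stays unambiguous.
    tmap = TargetMap()
    for k in range(cfg.n_planted):
        tmap.add(planted["miRNA"][k], planted["lncRNA"][k], "lncRNA")
        tmap.add(planted["miRNA"][k], planted["mRNA"][k], "mRNA")
    all_mirnas = planted["miRNA"] + decoys["miRNA"]
    for mirna in all_mirnas:
        for target_type in ("lncRNA", "mRNA"):
            pool = decoys[target_type]
            if not pool or cfg.decoy_targets_per_mirna == 0:
                continue
            k = min(cfg.decoy_targets_per_mirna, len(pool))
            for target in rng.choice(pool, size=k, replace=False):
                tmap.add(mirna, str(target), target_type)

    truth = GroundTruth(
        triples=pd.DataFrame(
            {
                "lnc_id": planted["lncRNA"],
                "mirna_id": planted["miRNA"],
                "mr_id": planted["mRNA"],
            }
        ),
        directions=pd.Series(directions, name="direction"),
    )
    return x, tmap, truth


def write_dataset(
    x: ExpressionMatrix, tmap: TargetMap, truth: GroundTruth, out_dir
) -> dict[str, str]:
    """Write expression/metadata/target/truth TSVs into ``out_dir``."""
    import os

    from .candidates import write_target_map
    from .matrix import write_expression_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "expression": os.path.join(out_dir, "expression.tsv"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "targets": os.path.join(out_dir, "targets.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
    }
    write_expression_table(x, paths["expression"], paths["metadata"])
    write_target_map(tmap, paths["targets"])
    truth.triples.to_csv(paths["truth"], sep="\t", index=False)
    return paths
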