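"""Candidate ceRNA networks from a miRNA target map plus DE statuses.

A candidate network N' = (lncR, mir, mR) keeps, among the miRNA's mapped and
differentially expressed targets, exactly those whose fold-change sign
opposes the miRNA's — the competition regulation mechanism:

* positive mechanism: miRNA up, lncRNAs and mRNAs down;
* negative mechanism: miRNA down, lncRNAs and mRNAs up.

Every (lnc, mr) pair of a candidate network forms a candidate crosstalk
T = (lnc, mir, mr).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

TARGET_TYPES = ("lncRNA", "mRNA")


@dataclass(frozen=True)
class CrosstalkCandidate:
    """A candidate triple T = (lnc, mir, mr)."""

    lnc: str
    mirna: str
    mr: str


class TargetMap:
    """miRNA -> target lncRNA/mRNA sets, miRWalk-export style."""

    def __init__(self) -> None:
        self._targets: dict[str, dict[str, set[str]]] = {}
        self._types: dict[str, str] = {}

    def add(self, mirna: str, target: str, target_type: str) -> None:
        if target_type not in TARGET_TYPES:
            raise ValueError(
                f"unknown target_type {target_type!r}; expected one of {TARGET_TYPES}"
            )
        if self._types.setdefault(target, target_type) != target_type:
            raise ValueError(
                f"inconsistent type for target {target!r}: "
                f"{self._types[target]} vs {target_type}"
            )
        if target in self._targets:
            raise ValueError(f"{target!r} appears both as an miRNA and as a target")
        entry = self._targets.setdefault(mirna, {"lncRNA": set(), "mRNA": set()})
        entry[target_type].add(target)

    def __contains__(self, mirna: str) -> bool:
        return mirna in self._targets

    @property
    def mirnas(self) -> list[str]:
        return sorted(self._targets)

    def lnc_targets(self, mirna: str) -> set[str]:
        return set(self._targets.get(mirna, {}).get("lncRNA", set()))

    def mr_targets(self, mirna: str) -> set[str]:
        return set(self._targets.get(mirna, {}).get("mRNA", set()))

    def n_edges(self) -> int:
        return sum(len(e["lncRNA"]) + len(e["mRNA"]) for e in self._targets.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (mirna, target, target_type)
            for mirna in self.mirnas
            for target_type in TARGET_TYPES
            for target in sorted(self._targets[mirna][target_type])
        ]
        return pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_type"])


def read_target_map(path) -> TargetMap:
    """Read a TSV with columns mirna_id, target_id, target_type; duplicate
    rows are collapsed."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mirna_id", "target_id", "target_type"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    tmap = TargetMap()
    for row in df.drop_duplicates().itertuples(index=False):
        tmap.add(row.mirna_id, row.target_id, row.target_type)
    return tmap


def write_target_map(tmap: TargetMap, path) -> None:
    tmap.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class InitialNetwork:
    """A miRNA with its mapped, differentially expressed target sets (before
    the competition-regulation filter)."""

    mirna: str
    lnc_ids: set[str] = field(default_factory=set)
    mr_ids: set[str] = field(default_factory=set)
    no_predicted_targets: bool = False


@dataclass
class CandidateNetwork:
    """N' = (lncR, mir, mR) after the competition-regulation filter."""

    mirna: str
    lnc_ids: tuple[str, ...]
    mr_ids: tuple[str, ...]
    mode: str  # "positive" or "negative"

    def __post_init__(self) -> None:
        if self.mode not in ("positive", "negative"):
            raise ValueError(f"mode must be positive/negative, got {self.mode!r}")
        self.lnc_ids = tuple(sorted(self.lnc_ids))
        self.mr_ids = tuple(sorted(self.mr_ids))
        if not self.lnc_ids or not self.mr_ids:
            raise ValueError("a candidate network needs >= 1 lncRNA and >= 1 mRNA")

    @property
    def n(self) -> int:
        return len(self.lnc_ids)

    @property
    def m(self) -> int:
        return len(self.mr_ids)


def _status(de: pd.DataFrame, rna: str) -> str:
    try:
        return de.at[rna, "status"]
    except KeyError:
        return "unchanged"


def build_initial_network(mirna: str, targets: TargetMap, de: pd.DataFrame) -> InitialNetwork:
    """Mapped targets of ``mirna`` that are themselves differentially
    expressed; a miRNA absent from the map yields an empty network flagged
    ``no_predicted_targets``."""
    if _status(de, mirna) == "unchanged":
        raise ValueError(f"miRNA {mirna!r} is not differentially expressed")
    if mirna not in targets:
        return InitialNetwork(mirna=mirna, no_predicted_targets=True)
    de_ids = set(de.index[de["status"] != "unchanged"])
    return InitialNetwork(
        mirna=mirna,
        lnc_ids=targets.lnc_targets(mirna) & de_ids,
        mr_ids=targets.mr_targets(mirna) & de_ids,
    )


def apply_competition_regulation(
    initial: InitialNetwork, de: pd.DataFrame
) -> CandidateNetwork | None:
    """Keep targets whose regulation direction opposes the miRNA's.

    Returns ``None`` when either retained set is empty (no crosstalk can
    form).
    """
    mir_status = _status(de, initial.mirna)
    if mir_status == "up":
        keep_status, mode = "down", "positive"
    elif mir_status == "down":
        keep_status, mode = "up", "negative"
    else:
        raise ValueError(f"miRNA {initial.mirna!r} is not differentially expressed")
    lnc = {r for r in initial.lnc_ids if _status(de, r) == keep_status}
    mr = {r for r in initial.mr_ids if _status(de, r) == keep_status}
    if not lnc or not mr:
        return None
    return CandidateNetwork(mirna=initial.mirna, lnc_ids=tuple(lnc), mr_ids=tuple(mr), mode=mode)


def enumerate_crosstalks(net: CandidateNetwork) -> list[CrosstalkCandidate]:
    """The full lncR x mR Cartesian product, lexicographic by (lnc, mr)."""
    return [
        CrosstalkCandidate(lnc=lnc, mirna=net.mirna, mr=mr)
        for lnc in net.lnc_ids
        for mr in net.mr_ids
    ]


def build_candidate_networks(targets: TargetMap, de: pd.DataFrame) -> list[CandidateNetwork]:
    """One candidate network per differentially expressed miRNA that retains
    at least one lncRNA and one mRNA under the competition filter."""
    mirnas = sorted(
        de.index[(de["rna_type"] == "miRNA") & (de["status"] != "unchanged")]
    )
    networks = []
    for mirna in mirnas:
        net = apply_competition_regulation(build_initial_network(mirna, targets, de), de)
        if net is not None:
            networks.append(net)
    return networks


def write_candidate_crosstalks(networks: list[CandidateNetwork], path) -> None:
    rows = [
        (c.lnc, c.mirna, c.mr, net.mode)
        for net in networks
        for c in enumerate_crosstalks(net)
    ]
    pd.DataFrame(rows, columns=["lnc_id", "mirna_id", "mr_id", "mode"]).to_csv(
        path, sep="\t", index=False
    )


def read_candidate_crosstalks(path) -> list[CandidateNetwork]:
    """Rebuild candidate networks from a crosstalk TSV (valid because each
    network's crosstalks are a full Cartesian product)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    networks = []
    for mirna, grp in df.groupby("mirna_id", sort=True):
        modes = grp["mode"].unique()
        if len(modes) != 1:
            raise ValueError(f"{path}: conflicting modes for miRNA {mirna!r}")
        networks.append(
            CandidateNetwork(
                mirna=str(mirna),
                lnc_ids=tuple(sorted(grp["lnc_id"].unique())),
                mr_ids=tuple(sorted(grp["mr_id"].unique())),
                mode=modes[0],
            )
        )
    return networks
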