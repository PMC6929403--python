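"""Grouping selected crosstalks into per-miRNA ceRNA networks and exporting
them as TSV edge lists, GraphML or JSON.

A ceRNA network N = (lnR, mir, mR) is the set of all selected crosstalks
mediated by one miRNA, viewed as a tripartite star: each crosstalk
contributes the two graph edges lnc--mir and mir--mr.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .scoring import ScoredCrosstalk

FORMATS = ("edge-tsv", "graphml", "json")
_EXTENSIONS = {"edge-tsv": "tsv", "graphml": "graphml", "json": "json"}


@dataclass
class CeRNANetwork:
    mirna: str
    edges: list[ScoredCrosstalk]

    def __post_init__(self) -> None:
        for e in self.edges:
            if e.mirna != self.mirna:
                raise ValueError(
                    f"crosstalk mediated by {e.mirna!r} in network of {self.mirna!r}"
                )
        self.edges = sorted(self.edges, key=lambda e: (e.lnc, e.mr))

    @property
    def lnc_ids(self) -> tuple[str, ...]:
        return tuple(sorted({e.lnc for e in self.edges}))

    @property
    def mr_ids(self) -> tuple[str, ...]:
        return tuple(sorted({e.mr for e in self.edges}))


def assemble_networks(selected: list[ScoredCrosstalk]) -> list[CeRNANetwork]:
    """One network per miRNA with at least one selected crosstalk, ordered by
    miRNA id."""
    by_mirna: dict[str, list[ScoredCrosstalk]] = {}
    for s in selected:
        by_mirna.setdefault(s.mirna, []).append(s)
    return [CeRNANetwork(mirna=m, edges=by_mirna[m]) for m in sorted(by_mirna)]


def _nan_to_none(x: float):
    return None if isinstance(x, float) and math.isnan(x) else x


def to_graph(net: CeRNANetwork) -> nx.MultiGraph:
    """Tripartite star graph: node attribute ``node_type``; each crosstalk
    yields a lnc--mir and a mir--mr edge tagged with a shared crosstalk
    index."""
    g = nx.MultiGraph()
    g.add_node(net.mirna, node_type="miRNA")
    for lnc in net.lnc_ids:
        g.add_node(lnc, node_type="lncRNA")
    for mr in net.mr_ids:
        g.add_node(mr, node_type="mRNA")
    for idx, e in enumerate(net.edges):
        attrs = {"crosstalk": idx, "pmi": e.pmi, "p_value": e.p_value}
        g.add_edge(e.lnc, net.mirna, kind="lnc-mir", **attrs)
        g.add_edge(net.mirna, e.mr, kind="mir-mr", **attrs)
    return g


def export_network(net: CeRNANetwork, path, fmt: str) -> None:
    if fmt == "edge-tsv":
        pd.DataFrame(
            [(e.lnc, e.mirna, e.mr, e.pmi, e.p_value) for e in net.edges],
            columns=["lnc_id", "mirna_id", "mr_id", "pmi", "p_value"],
        ).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        nx.write_graphml(to_graph(net), path)
    elif fmt == "json":
        doc = {
            "mirna": net.mirna,
            "lnc_ids": list(net.lnc_ids),
            "mr_ids": list(net.mr_ids),
            "crosstalks": [
                {
                    "lnc": e.lnc,
                    "mr": e.mr,
                    "supp": e.supp,
                    "p_joint": e.p_joint,
                    "p_lnc": e.p_lnc,
                    "p_mr": e.p_mr,
                    "pmi": _nan_to_none(e.pmi),
                    "theta": _nan_to_none(e.theta),
                    "p_value": _nan_to_none(e.p_value),
                    "selected": e.selected,
                }
                for e in net.edges
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def import_network(path, fmt: str) -> CeRNANetwork:
    """Inverse of :func:`export_network`. Fields absent from a format (e.g.
    supports in edge-tsv) come back as 0/NaN."""
    if fmt == "edge-tsv":
        df = pd.read_csv(path, sep="\t", dtype={"lnc_id": str, "mirna_id": str, "mr_id": str})
        if len(df) == 0:
            raise ValueError(f"{path}: empty edge list has no miRNA id")
        edges = [
            ScoredCrosstalk(
                lnc=r.lnc_id, mirna=r.mirna_id, mr=r.mr_id, supp=0,
                p_joint=float("nan"), p_lnc=float("nan"), p_mr=float("nan"),
                pmi=float(r.pmi), p_value=float(r.p_value), selected=True,
            )
            for r in df.itertuples(index=False)
        ]
        return CeRNANetwork(mirna=df["mirna_id"].iloc[0], edges=edges)
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
        mirnas = [n for n, d in g.nodes(data=True) if d.get("node_type") == "miRNA"]
        if len(mirnas) != 1:
            raise ValueError(f"{path}: expected exactly one miRNA node, found {len(mirnas)}")
        mirna = mirnas[0]
        halves: dict[int, dict[str, object]] = {}
        for u, v, d in g.edges(data=True):
            entry = halves.setdefault(int(d["crosstalk"]), dict(d))
            other = v if u == mirna else u
            entry["lnc" if d["kind"] == "lnc-mir" else "mr"] = other
        edges = [
            ScoredCrosstalk(
                lnc=str(h["lnc"]), mirna=mirna, mr=str(h["mr"]), supp=0,
                p_joint=float("nan"), p_lnc=float("nan"), p_mr=float("nan"),
                pmi=float(h["pmi"]), p_value=float(h["p_value"]), selected=True,
            )
            for h in halves.values()
        ]
        return CeRNANetwork(mirna=mirna, edges=edges)
    if fmt == "json":
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
        edges = [
            ScoredCrosstalk(
                lnc=c["lnc"], mirna=doc["mirna"], mr=c["mr"], supp=int(c["supp"]),
                p_joint=float(c["p_joint"]), p_lnc=float(c["p_lnc"]), p_mr=float(c["p_mr"]),
                pmi=float("nan") if c["pmi"] is None else float(c["pmi"]),
                theta=float("nan") if c["theta"] is None else float(c["theta"]),
                p_value=float("nan") if c["p_value"] is None else float(c["p_value"]),
                selected=bool(c["selected"]),
            )
            for c in doc["crosstalks"]
        ]
        return CeRNANetwork(mirna=doc["mirna"], edges=edges)
    raise ValueError(f"unknown format {fmt!r}; expected one of {FORMATS}")


def export_networks(networks: list[CeRNANetwork], out_dir, formats=FORMATS) -> list[str]:
    """Write ``<mirna>.<ext>`` for every network and format; returns paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for net in networks:
        for fmt in formats:
            path = os.path.join(out_dir, f"{net.mirna}.{_EXTENSIONS[fmt]}")
            export_network(net, path, fmt)
            paths.append(path)
    return paths
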