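"""Assembling selected crosstalks into per-miRNA networks and exporting them.

Builds a small set of significant crosstalks by hand, groups them into
ceRNA networks and writes each network as a TSV edge list, a tripartite
GraphML graph and a JSON document, then reads one back to show the round
trip.
"""

import tempfile
from pathlib import Path

from cernet import ScoredCrosstalk, assemble_networks, export_networks, import_network


def edge(lnc, mirna, mr, pmi, p):
    return ScoredCrosstalk(
        lnc=lnc, mirna=mirna, mr=mr, supp=12,
        p_joint=0.2, p_lnc=0.4, p_mr=0.4, pmi=pmi,
        theta=2.2, p_value=p, selected=True,
    )


selected = [
    edge("ENSG-lnc1", "hsa-miR-451a", "DLX6", 0.35, 0.012),
    edge("ENSG-lnc1", "hsa-miR-451a", "NTSR1", 0.29, 0.031),
    edge("ENSG-lnc2", "hsa-miR-375", "TFF1", 0.33, 0.018),
]

networks = assemble_networks(selected)
print(f"{len(networks)} ceRNA networks from {len(selected)} selected crosstalks")
for net in networks:
    print(f"  {net.mirna}: {len(net.edges)} crosstalks, "
          f"{len(net.lnc_ids)} lncRNAs, {len(net.mr_ids)} mRNAs")

with tempfile.TemporaryDirectory() as tmp:
    paths = export_networks(networks, tmp)
    print(f"wrote {len(paths)} files:", *(Path(p).name for p in paths))
    back = import_network(Path(tmp) / "hsa-miR-451a.graphml", "graphml")
    print(f"round trip via GraphML: {back.mirna} with "
          f"{len(back.edges)} crosstalks (2 graph edges each, star layout)")
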