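"""Bipartite tissue / group enrichment network.

Tissue nodes carry the count of tissue-enriched genes per tissue; group
nodes represent a distinct set of tissues sharing group-enriched genes
and link to each member tissue. Group nodes are kept in the display
network only when they span at most ``network_max_tissues`` tissues and
contain at least ``network_min_genes`` genes; larger or sparser sets are
dropped outright, never merged or truncated. Display size is the square
root of the gene count.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Literal, Sequence

import networkx as nx
import pandas as pd

from .config import ThresholdConfig
from .exceptions import ValidationError
from .specificity import Category, SpecificityCall

__all__ = ["build_network", "export_network", "group_node_id", "tissue_node_id"]


def tissue_node_id(tissue: str) -> str:
    return f"tissue:{tissue}"


def group_node_id(tissues: Iterable[str]) -> str:
    return "group:" + ";".join(sorted(tissues))


def build_network(
    calls: Sequence[SpecificityCall],
    config: ThresholdConfig | None = None,
    tissues: Sequence[str] | None = None,
) -> nx.Graph:
    """Build the enrichment network from classification calls.

    ``tissues`` fixes the tissue node set (e.g. all profile tissues);
    when omitted it is derived from the calls' elevated tissue sets.
    Node and edge sets depend only on the multiset of calls, so shuffled
    input order yields an identical graph.
    """
    cfg = config or ThresholdConfig()
    enriched_counts: Counter = Counter()
    group_counts: Counter = Counter()
    seen_tissues: set[str] = set(tissues or ())
    for call in calls:
        seen_tissues.update(call.elevated_tissues)
        if call.category is Category.TISSUE_ENRICHED:
            enriched_counts[call.elevated_tissues[0]] += 1
        elif call.category is Category.GROUP_ENRICHED:
            group_counts[tuple(sorted(call.elevated_tissues))] += 1

    graph = nx.Graph()
    for tissue in sorted(seen_tissues):
        graph.add_node(
            tissue_node_id(tissue),
            kind="tissue",
            tissue=tissue,
            gene_count=int(enriched_counts.get(tissue, 0)),
            display_size=math.sqrt(enriched_counts.get(tissue, 0)),
        )
    for members, count in sorted(group_counts.items()):
        if len(members) > cfg.network_max_tissues or count < cfg.network_min_genes:
            continue
        node = group_node_id(members)
        graph.add_node(
            node,
            kind="group",
            gene_count=int(count),
            display_size=math.sqrt(count),
        )
        for tissue in members:
            graph.add_edge(node, tissue_node_id(tissue))
    return graph


def export_network(
    net: nx.Graph,
    path,
    format: Literal["graphml", "edge_tsv"] = "graphml",
) -> None:
    """Write the network as schema-valid GraphML or a two-column edge TSV."""
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_tsv":
        rows = [
            {"group_id": u if u.startswith("group:") else v,
             "tissue": (v if u.startswith("group:") else u).removeprefix("tissue:")}
            for u, v in sorted(net.edges())
        ]
        pd.DataFrame(rows, columns=["group_id", "tissue"]).to_csv(path, sep="\t", index=False)
    else:
        raise ValidationError(f"unknown network export format {format!r}")
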