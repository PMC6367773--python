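"""Merged module network and its centrality profile.

Two molecules are connected in the merged network iff they share at
least one module AND their interaction exists in the corresponding
network (A for lncRNA-miRNA, B for miRNA-mRNA, C > 0 for mRNA-mRNA).
Nodes are layer-tagged ``(layer, identifier)`` tuples so the three
identifier namespaces cannot collide.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, Hashable, List, Mapping, Tuple

import networkx as nx
import pandas as pd

from .datatypes import InteractionData, ModuleSet, ValidationError

__all__ = [
    "build_module_network",
    "centralities",
    "top_k_by_layer",
    "modules_per_molecule",
    "network_to_table",
]

Node = Tuple[str, str]


def build_module_network(ms: ModuleSet, nets: InteractionData) -> nx.Graph:
    """Union over modules of within-module interacting pairs.

    Every module member appears as a node (isolated members keep
    ``has_edge=False``); each edge carries its ``interaction_class``.
    """
    lnc_idx = {m: i for i, m in enumerate(nets.lnc_ids)}
    mir_idx = {m: i for i, m in enumerate(nets.mir_ids)}
    mrna_idx = {m: i for i, m in enumerate(nets.mrna_ids)}

    G = nx.Graph()
    for mod in ms:
        for layer, members, idx in (
            ("lncRNA", mod.lnc_members, lnc_idx),
            ("miRNA", mod.mir_members, mir_idx),
            ("mRNA", mod.mrna_members, mrna_idx),
        ):
            for m in members:
                if m not in idx:
                    raise ValidationError(
                        f"module {mod.index}: {m!r} missing from the {layer} registry"
                    )
                G.add_node((layer, m), layer=layer)
        for l in mod.lnc_members:
            for m in mod.mir_members:
                if nets.A[mir_idx[m], lnc_idx[l]]:
                    G.add_edge(("miRNA", m), ("lncRNA", l),
                               interaction_class="lncRNA-miRNA")
        for m in mod.mir_members:
            for g in mod.mrna_members:
                if nets.B[mir_idx[m], mrna_idx[g]]:
                    G.add_edge(("miRNA", m), ("mRNA", g),
                               interaction_class="miRNA-mRNA")
        genes = sorted(mod.mrna_members)
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1:]:
                if nets.C[mrna_idx[g1], mrna_idx[g2]] > 0:
                    G.add_edge(("mRNA", g1), ("mRNA", g2),
                               interaction_class="mRNA-mRNA")
    for node in G.nodes:
        G.nodes[node]["has_edge"] = G.degree(node) > 0
    return G


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness (raw and normalized) and closeness per node.

    Betweenness counts each unordered pair once (unweighted shortest
    paths); closeness is computed within each connected component as
    (n_reachable - 1) / sum of distances, isolated nodes scoring 0.
    """
    deg = dict(net.degree())
    btw_raw = nx.betweenness_centrality(net, normalized=False)
    btw_norm = nx.betweenness_centrality(net, normalized=True)
    clo = nx.closeness_centrality(net, wf_improved=False)
    rows = []
    for node in sorted(net.nodes):
        layer, mol = node
        rows.append(
            {
                "layer": layer,
                "molecule_id": mol,
                "degree": deg[node],
                "betweenness": btw_raw[node],
                "betweenness_normalized": btw_norm[node],
                "closeness": clo[node],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "layer",
            "molecule_id",
            "degree",
            "betweenness",
            "betweenness_normalized",
            "closeness",
        ],
    )


def top_k_by_layer(values: Mapping[Node, float], k: int, layer: str) -> List[str]:
    """Identifiers of the k highest-valued nodes in one layer, descending,
    ties broken lexicographically.  Returns all nodes when fewer than k."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    items = [(mol, v) for (lay, mol), v in values.items() if lay == layer]
    items.sort(key=lambda t: (-t[1], t[0]))
    return [mol for mol, _ in items[:k]]


def modules_per_molecule(ms: ModuleSet) -> Dict[Node, int]:
    """How many modules each (layer, molecule) participates in."""
    counts: Counter = Counter()
    for mod in ms:
        for node in mod.all_members():
            counts[node] += 1
    return dict(counts)


def network_to_table(net: nx.Graph) -> pd.DataFrame:
    """3-column edge list (node, node, interaction_class) for external viewers."""
    rows = []
    for u, v, data in sorted(net.edges(data=True)):
        rows.append(
            {
                "node_a": f"{u[0]}:{u[1]}",
                "node_b": f"{v[0]}:{v[1]}",
                "interaction_class": data.get("interaction_class", ""),
            }
        )
    return pd.DataFrame(rows, columns=["node_a", "node_b", "interaction_class"])
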