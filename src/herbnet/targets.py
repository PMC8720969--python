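"""Component-target maps, DEG intersection and the bipartite drug-target network.

Gene/protein identifiers are plain HGNC-style symbols, uppercased and
whitespace-trimmed on ingest; no alias resolution is attempted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


def read_target_map(path: str | Path, sep: str = "\t") -> set[tuple[str, str]]:
    """Read a two-column (component, target) map; duplicates collapse."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("target map needs two columns: component, target")
    comp_col, tgt_col = df.columns[:2]
    return {
        (str(c).strip(), normalize_symbol(t))
        for c, t in zip(df[comp_col], df[tgt_col])
        if pd.notna(c) and pd.notna(t)
    }


def write_target_map(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    df = pd.DataFrame(sorted(edges), columns=["component", "target"])
    df.to_csv(path, sep="\t", index=False)


def common_targets(component_targets: set[str], degs: set[str]) -> list[str]:
    """Sorted intersection of component-target symbols with DEG symbols."""
    a = {normalize_symbol(s) for s in component_targets}
    b = {normalize_symbol(s) for s in degs}
    return sorted(a & b)


def build_bipartite(
    target_map: Iterable[tuple[str, str]],
    components: set[str],
    targets: set[str],
) -> nx.Graph:
    """Induced bipartite subgraph of the target map on the two given parts.

    Components carry ``bipartite='component'``, targets ``bipartite='target'``.
    A symbol present in both parts is a hard error — the two node namespaces
    must not collide.
    """
    targets = {normalize_symbol(t) for t in targets}
    overlap = set(components) & targets
    if overlap:
        raise ValueError(f"symbols in both parts: {sorted(overlap)}")
    g = nx.Graph()
    g.add_nodes_from(components, bipartite="component")
    g.add_nodes_from(targets, bipartite="target")
    for comp, tgt in target_map:
        tgt = normalize_symbol(tgt)
        if comp in components and tgt in targets:
            g.add_edge(comp, tgt)
    g.graph["n_components"] = len(components)
    g.graph["n_targets"] = len(targets)
    return g


def target_degree_ranking(net: nx.Graph, k: int | None = None) -> list[tuple[str, int]]:
    """Targets of the bipartite network by descending degree, ties alphabetical."""
    if k is not None and k < 0:
        raise ValueError("k must be >= 0")
    ranked = sorted(
        (
            (node, net.degree(node))
            for node, part in net.nodes(data="bipartite")
            if part == "target"
        ),
        key=lambda item: (-item[1], item[0]),
    )
    return ranked if k is None else ranked[:k]


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write a graph as SIF (node relation node per line, sorted)."""
    with open(path, "w") as fh:
        lines = sorted(
            f"{min(u, v)}\t{relation}\t{max(u, v)}" for u, v in graph.edges()
        )
        isolated = sorted(n for n in graph.nodes() if graph.degree(n) == 0)
        fh.write("\n".join(lines + isolated))
        if lines or isolated:
            fh.write("\n")
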