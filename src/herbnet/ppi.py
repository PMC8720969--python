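"""Two-stage topological screening of protein-protein interaction networks.

Stage 1 ("double-median-degree" screen) keeps nodes whose degree strictly
exceeds a threshold — by default twice the median degree of the whole
network, or an absolute cutoff when one is given — and induces the
subnetwork on them.  Stage 2 recomputes degree (DC) and betweenness (BC)
centrality *on that subnetwork* and keeps nodes with DC > dc_min and
BC > bc_min, yielding the core network.  The stage-wise recomputation
matters: centralities on an induced subgraph differ from the parent
network's values, and thresholds are calibrated to the graph they are
applied to.

Betweenness convention: unnormalized Brandes counts, each unordered node
pair counted once, endpoints excluded, equal-length shortest paths split
evenly — the convention under which a cutoff like "BC > 645" is meaningful
on a network of a few hundred nodes.  Closeness is computed within each
connected component and reported alongside, but does not participate in the
default screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable

import networkx as nx
import pandas as pd

from .targets import normalize_symbol

logger = logging.getLogger(__name__)

DEFAULT_DC_MIN = 60.0
DEFAULT_BC_MIN = 645.0


def load_network(source: str | Path | Iterable[tuple[str, str]]) -> nx.Graph:
    """Build a simple undirected symbol graph from an edge list.

    ``source`` is a SIF file (``A <tab> relation <tab> B``), a two-column
    TSV, or an iterable of symbol pairs.  Symbols are normalized; self-loops
    are dropped (count logged) and duplicate edges collapse.
    """
    if isinstance(source, (str, Path)):
        pairs = _read_edge_file(Path(source))
    else:
        pairs = [(a, b) for a, b in source]
    g = nx.Graph()
    self_loops = 0
    for a, b in pairs:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            self_loops += 1
            continue
        g.add_edge(a, b)
    if self_loops:
        logger.warning("dropped %d self-loop(s)", self_loops)
    return g


def _read_edge_file(path: Path) -> list[tuple[str, str]]:
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:  # SIF: a relation b
                pairs.append((fields[0], fields[2]))
            elif len(fields) == 2:
                pairs.append((fields[0], fields[1]))
            elif len(fields) == 1:
                continue  # isolated node in SIF; carries no edge
            else:
                raise ValueError(f"{path}:{lineno}: malformed edge record: {line!r}")
    return pairs


def centralities(net: nx.Graph) -> pd.DataFrame:
    """Per-node DC (degree), BC (betweenness) and CC (closeness) table.

    BC follows the unnormalized unordered-pair Brandes convention; CC is
    within-component closeness (no cross-component rescaling).  Values are
    also stored as node attributes on ``net``.
    """
    if net.number_of_nodes() == 0:
        return pd.DataFrame(columns=["DC", "BC", "CC"])
    dc = dict(net.degree())
    bc = nx.betweenness_centrality(net, normalized=False)
    cc = nx.closeness_centrality(net, wf_improved=False)
    nx.set_node_attributes(net, dc, "DC")
    nx.set_node_attributes(net, bc, "BC")
    nx.set_node_attributes(net, cc, "CC")
    table = pd.DataFrame({"DC": dc, "BC": bc, "CC": cc})
    return table.sort_index()


def dmd_screen(
    net: nx.Graph,
    multiplier: float = 2.0,
    absolute: float | None = None,
) -> tuple[nx.Graph, float]:
    """Median-degree screen: keep nodes with degree strictly above threshold.

    The threshold is ``multiplier * median(degree)`` unless an ``absolute``
    cutoff is supplied.  Returns the induced subgraph and the threshold used.
    """
    if net.number_of_nodes() == 0:
        return net.copy(), 0.0
    degrees = dict(net.degree())
    threshold = float(absolute) if absolute is not None else multiplier * median(degrees.values())
    keep = [n for n, d in degrees.items() if d > threshold]
    logger.info("dmd_screen: threshold %.3g keeps %d/%d nodes", threshold, len(keep), len(degrees))
    return net.subgraph(keep).copy(), threshold


def core_screen(
    subnet: nx.Graph,
    dc_min: float = DEFAULT_DC_MIN,
    bc_min: float = DEFAULT_BC_MIN,
) -> nx.Graph:
    """Centrality screen: DC > dc_min AND BC > bc_min, recomputed on subnet."""
    if subnet.number_of_nodes() == 0:
        return subnet.copy()
    table = centralities(subnet)
    keep = table.index[(table["DC"] > dc_min) & (table["BC"] > bc_min)]
    logger.info("core_screen: DC>%g & BC>%g keeps %d/%d nodes", dc_min, bc_min, len(keep), len(table))
    return subnet.subgraph(keep).copy()


@dataclass
class ScreenStage:
    name: str
    n_nodes: int
    n_edges: int
    threshold: str


@dataclass
class ScreenReport:
    """Per-stage node/edge counts of a screening cascade."""

    stages: list[ScreenStage] = field(default_factory=list)
    final_nodes: list[str] = field(default_factory=list)

    def to_records(self) -> list[dict]:
        return [vars(s) for s in self.stages]


def screen_report(stages: list[tuple[str, nx.Graph, str]]) -> ScreenReport:
    """Summarize a cascade as (name, graph, threshold-description) stages.

    Node/edge counts must be non-increasing along the cascade.
    """
    report = ScreenReport()
    prev: tuple[int, int] | None = None
    for name, graph, thr in stages:
        counts = (graph.number_of_nodes(), graph.number_of_edges())
        if prev is not None and (counts[0] > prev[0] or counts[1] > prev[1]):
            raise ValueError(f"stage {name!r} grew the network: {prev} -> {counts}")
        report.stages.append(ScreenStage(name, counts[0], counts[1], thr))
        prev = counts
    if stages:
        report.final_nodes = sorted(stages[-1][1].nodes())
    return report


def screen_cascade(
    net: nx.Graph,
    dmd_multiplier: float = 2.0,
    dmd_absolute: float | None = None,
    dc_min: float = DEFAULT_DC_MIN,
    bc_min: float = DEFAULT_BC_MIN,
) -> tuple[nx.Graph, ScreenReport]:
    """Full two-stage screen: median-degree filter then DC/BC core filter."""
    subnet, thr = dmd_screen(net, multiplier=dmd_multiplier, absolute=dmd_absolute)
    core = core_screen(subnet, dc_min=dc_min, bc_min=bc_min)
    label = f"DMD > {thr:g}" if dmd_absolute is None else f"degree > {thr:g} (absolute)"
    report = screen_report(
        [
            ("input", net, "none"),
            ("subnetwork", subnet, label),
            ("core", core, f"DC > {dc_min:g} and BC > {bc_min:g}"),
        ]
    )
    return core, report


def write_centrality_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="node")
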