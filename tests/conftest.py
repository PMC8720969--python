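import networkx as nx
import numpy as np
import pytest

from herbnet import components, docking, synthetic


@pytest.fixture(scope="session")
def pivotal_table():
    """The packaged nine-row pivotal-component reference table."""
    return components.load_pivotal_components()


@pytest.fixture(scope="session")
def reference_docking():
    """The packaged 16-row docking reference table."""
    return docking.load_reference_docking()


@pytest.fixture(scope="session")
def planted_expression():
    """Planted-DE expression at the standard 30-vs-9 design."""
    return synthetic.gen_expression(
        n_genes=2000, n_case=30, n_control=9, n_de=100, lfc=2.0, sigma=0.5, seed=7
    )


@pytest.fixture(scope="session")
def planted_ppi():
    """Scale-free background with a 30-node dense planted core."""
    return synthetic.gen_ppi(
        n_background=600, attach_m=2, core_size=30, core_p=0.8, seed=3
    )


def collect_run_blobs(root) -> dict:
    """All artifact bytes under a pipeline run root, made run-comparable:
    the root directory string is replaced by a placeholder and the report's
    wall-clock timings (the one legitimately varying field) are zeroed."""
    import json

    blobs = {}
    root_bytes = str(root).encode()
    for p in sorted(root.rglob("*")):
        if not p.is_file():
            continue
        rel = str(p.relative_to(root))
        if p.name == "run_report.json":
            payload = json.loads(p.read_text())
            for s in payload["stages"]:
                s["seconds"] = 0
            data = json.dumps(payload, sort_keys=True).encode()
        else:
            data = p.read_bytes()
        blobs[rel] = data.replace(root_bytes, b"<ROOT>")
    return blobs


def brute_force_betweenness(g: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration betweenness (unordered pairs,
    endpoints excluded, even split over equal-length paths).

    Independent of any library centrality routine: distances come from a
    hand-rolled BFS and the shortest paths are enumerated recursively.
    """
    from collections import deque

    def bfs_dist(src):
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v in g[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    q.append(v)
        return dist

    def all_shortest(src, dst, dist):
        # walk backwards from dst along strictly decreasing distance
        if dst == src:
            return [[src]]
        paths = []
        for u in g[dst]:
            if u in dist and dist[u] == dist[dst] - 1:
                paths.extend(p + [dst] for p in all_shortest(src, u, dist))
        return paths

    bc = {v: 0.0 for v in g}
    nodes = sorted(g)
    for i, s in enumerate(nodes):
        dist = bfs_dist(s)
        for t in nodes[i + 1 :]:
            if t not in dist:
                continue
            paths = all_shortest(s, t, dist)
            for path in paths:
                for interior in path[1:-1]:
                    bc[interior] += 1.0 / len(paths)
    return bc
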