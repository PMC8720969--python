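"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of input the pipeline normally takes from
curated databases, and returns both the artifact and a truth ledger so
downstream recovery can be scored without any download:

* component tables with a known ADME-passing subset,
* two-group normal log2 expression with planted mean-shift DE genes
  (default design 30 cases vs 9 controls, the classic small-control
  microarray cohort layout),
* a preferential-attachment PPI background with a planted dense core,
* gene-set collections with planted over-representation,
* bivariate-normal gene pairs at specified correlations,
* a docking table with a known passing subset (for end-to-end runs).

Reproducibility contract: one integer master seed; each generator mixes in
a fixed stream tag, so identical (seed, parameters) give byte-identical
artifacts after serialization, and adding a generator never perturbs the
streams of the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .components import COMPONENT_COLUMNS
from .deg import CASE, CONTROL, ExpressionMatrix
from .enrichment import GeneSet, GeneSetCollection, make_collection

#: the twelve constituent herbs of Shen Qi Sha Bai Decoction
HERBS = (
    "Hedyotis Diffusae Herba",
    "Scutellariae Barbatae Herba",
    "Lobeliae Chinensis Herba",
    "Codonopsis Radix",
    "Licorice",
    "Hedysarum Multijugum Maxim",
    "Scutellariae Radix",
    "Dioscoreae Bulbiferae",
    "Indigo Naturalis",
    "Glehniae Radix",
    "Asparagi Radix",
    "Agrimonia Eupatoria",
)

# fixed stream tags: a new generator appends a tag, never renumbers
_STREAMS = {
    "components": 1,
    "expression": 2,
    "ppi": 3,
    "genesets": 4,
    "coexpr": 5,
    "docking": 6,
    "targets": 7,
}

OB_THRESHOLD = 30.0
DL_THRESHOLD = 0.18


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


@dataclass
class SyntheticTruth:
    """Ground-truth ledger shared by all generators."""

    passing_component_ids: set[str] = field(default_factory=set)
    de_gene_ids_up: set[str] = field(default_factory=set)
    de_gene_ids_down: set[str] = field(default_factory=set)
    planted_core_nodes: set[str] = field(default_factory=set)
    enriched_set_ids: set[str] = field(default_factory=set)
    pair_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    passing_docking_pairs: set[tuple[str, str]] = field(default_factory=set)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            passing_component_ids=self.passing_component_ids | other.passing_component_ids,
            de_gene_ids_up=self.de_gene_ids_up | other.de_gene_ids_up,
            de_gene_ids_down=self.de_gene_ids_down | other.de_gene_ids_down,
            planted_core_nodes=self.planted_core_nodes | other.planted_core_nodes,
            enriched_set_ids=self.enriched_set_ids | other.enriched_set_ids,
            pair_correlations={**self.pair_correlations, **other.pair_correlations},
            passing_docking_pairs=self.passing_docking_pairs | other.passing_docking_pairs,
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "passing_component_ids": sorted(self.passing_component_ids),
            "de_gene_ids_up": sorted(self.de_gene_ids_up),
            "de_gene_ids_down": sorted(self.de_gene_ids_down),
            "planted_core_nodes": sorted(self.planted_core_nodes),
            "enriched_set_ids": sorted(self.enriched_set_ids),
            "pair_correlations": {f"{a}|{b}": r for (a, b), r in sorted(self.pair_correlations.items())},
            "passing_docking_pairs": sorted(f"{l}|{r}" for l, r in self.passing_docking_pairs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def gen_component_table(
    n_components: int,
    n_herbs: int = len(HERBS),
    frac_passing: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Component table with exactly round(frac_passing * n) ADME-passing rows.

    Passing rows sit strictly above both OB/DL thresholds (OB in (30, 70],
    DL in (0.18, 0.30], covering published pivotal-component ranges);
    failing rows fall strictly below at least one.  Each component belongs
    to 1-3 herbs drawn uniformly.
    """
    if n_components < 0 or n_herbs < 1:
        raise ValueError("counts must be non-negative (n_herbs >= 1)")
    if not 0 <= frac_passing <= 1:
        raise ValueError("frac_passing must be in [0, 1]")
    rng = _rng(seed, "components")
    n_pass = round(frac_passing * n_components)
    herbs = [HERBS[i % len(HERBS)] if n_herbs <= len(HERBS) else f"Herb{i+1:02d}" for i in range(n_herbs)]

    rows = []
    passing_ids: set[str] = set()
    for i in range(n_components):
        mol_id = f"MOL{i+1:06d}"
        is_pass = i < n_pass
        if is_pass:
            ob = rng.uniform(30.5, 70.0)
            dl = rng.uniform(0.19, 0.30)
            passing_ids.add(mol_id)
        else:
            # fail OB, DL, or both — strictly below the respective threshold
            mode = rng.integers(0, 3)
            ob = rng.uniform(5.0, 29.0) if mode in (0, 2) else rng.uniform(30.5, 70.0)
            dl = rng.uniform(0.02, 0.17) if mode in (1, 2) else rng.uniform(0.19, 0.30)
        n_memb = int(rng.integers(1, 4))
        memb = sorted(rng.choice(len(herbs), size=min(n_memb, len(herbs)), replace=False))
        rows.append(
            {
                "mol_id": mol_id,
                "name": f"compound-{i+1:04d}",
                "DL": round(float(dl), 4),
                "AlogP": round(float(rng.normal(2.5, 1.5)), 3),
                "OB": round(float(ob), 2),
                "HL": round(float(rng.uniform(2.0, 20.0)), 2),
                "herbs": ";".join(herbs[j] for j in memb),
            }
        )
    # shuffle so passing rows are not a prefix
    order = rng.permutation(n_components)
    table = pd.DataFrame(rows, columns=COMPONENT_COLUMNS)
    if n_components:
        table = table.iloc[order].reset_index(drop=True)
    return table, SyntheticTruth(passing_component_ids=passing_ids)


def gen_expression(
    n_genes: int,
    n_case: int = 30,
    n_control: int = 9,
    n_de: int = 0,
    lfc: float = 2.0,
    sigma: float = 0.5,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-group log2 expression with n_de planted mean-shift genes.

    Baseline per-gene means are uniform on [4, 12] log2 units; noise is
    i.i.d. normal(0, sigma).  Planted genes shift the case-group mean by
    +lfc (first half, rounding up) or -lfc (second half).
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if n_case < 2 or n_control < 2:
        raise ValueError("need >= 2 samples per group")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = _rng(seed, "expression")
    genes = [f"G{i+1:05d}" for i in range(n_genes)]
    samples = [f"case_{i+1:02d}" for i in range(n_case)] + [
        f"ctrl_{i+1:02d}" for i in range(n_control)
    ]
    base = rng.uniform(4.0, 12.0, size=n_genes)
    values = base[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_case + n_control))

    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    n_up = (n_de + 1) // 2  # odd n_de: extra up gene
    up_idx, down_idx = de_idx[:n_up], de_idx[n_up:]
    values[up_idx, :n_case] += lfc
    values[down_idx, :n_case] -= lfc

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        groups=pd.Series(
            [CASE] * n_case + [CONTROL] * n_control, index=samples, name="group"
        ),
    )
    truth = SyntheticTruth(
        de_gene_ids_up={genes[i] for i in up_idx},
        de_gene_ids_down={genes[i] for i in down_idx},
    )
    return matrix, truth


def gen_ppi(
    n_background: int,
    attach_m: int = 2,
    core_size: int = 0,
    core_p: float = 0.8,
    seed: int = 0,
    core_labels: list[str] | None = None,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free PPI background with a planted dense core.

    The background is a Barabási-Albert graph (preferential attachment,
    ``attach_m`` edges per new node).  Core nodes connect to each other with
    probability ``core_p`` and each also receives ``attach_m`` edges to
    random background nodes so the core is wired into the network.
    ``core_labels`` names the core nodes (e.g. with real gene symbols for
    end-to-end runs); default labels are CORE001, CORE002, ...
    """
    if core_size >= n_background:
        raise ValueError("core_size must be < n_background")
    if not 0 < core_p <= 1:
        raise ValueError("core_p must be in (0, 1]")
    if core_labels is not None and len(set(core_labels)) != core_size:
        raise ValueError("core_labels must provide core_size distinct names")
    rng = _rng(seed, "ppi")
    bg = nx.barabasi_albert_graph(n_background, attach_m, seed=int(rng.integers(2**31)))
    mapping = {i: f"BG{i+1:05d}" for i in bg.nodes()}
    g = nx.relabel_nodes(bg, mapping)
    core = list(core_labels) if core_labels is not None else [
        f"CORE{i+1:03d}" for i in range(core_size)
    ]
    g.add_nodes_from(core)
    for i in range(core_size):
        for j in range(i + 1, core_size):
            if rng.random() < core_p:
                g.add_edge(core[i], core[j])
        anchors = rng.choice(n_background, size=min(attach_m, n_background), replace=False)
        for a in anchors:
            g.add_edge(core[i], mapping[a])
    return g, SyntheticTruth(planted_core_nodes=set(core))


def gen_genesets(
    universe: list[str],
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 40),
    planted_list: list[str] | None = None,
    n_enriched: int = 0,
    seed: int = 0,
) -> tuple[GeneSetCollection, SyntheticTruth]:
    """Gene-set collection; n_enriched sets draw >= 60 % of members from
    planted_list, the rest uniformly from the universe."""
    planted_list = planted_list or []
    universe = list(dict.fromkeys(universe))
    if not set(planted_list) <= set(universe):
        raise ValueError("planted_list must be a subset of the universe")
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set sizes cannot exceed the universe size")
    if n_enriched > n_sets:
        raise ValueError("n_enriched cannot exceed n_sets")
    if n_enriched > 0 and not planted_list:
        raise ValueError("enriched sets need a non-empty planted_list")
    rng = _rng(seed, "genesets")
    uni = np.array(universe)
    non_planted = np.array(sorted(set(universe) - set(planted_list)))
    sets, enriched_ids = [], set()
    for i in range(n_sets):
        set_id = f"SET{i+1:04d}"
        size = int(rng.integers(lo, hi + 1))
        if i < n_enriched:
            n_from_planted = min(int(np.ceil(0.6 * size)), len(planted_list))
            picked = list(rng.choice(planted_list, size=n_from_planted, replace=False))
            rest_pool = non_planted if len(non_planted) else uni
            n_rest = min(size - n_from_planted, len(rest_pool))
            picked += list(rng.choice(rest_pool, size=n_rest, replace=False))
            enriched_ids.add(set_id)
        else:
            picked = list(rng.choice(uni, size=size, replace=False))
        sets.append(
            GeneSet(set_id=set_id, name=f"pathway {i+1}", category="custom",
                    members=frozenset(picked))
        )
    return make_collection(sets), SyntheticTruth(enriched_set_ids=enriched_ids)


def gen_coexpr_pairs(
    pairs: dict[tuple[str, str], float],
    n_samples: int,
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression matrix of bivariate-normal gene pairs at given correlations.

    Each pair is drawn independently from a bivariate normal with unit
    variance, mean 8 log2 units and the requested correlation; a gene may
    appear in only one pair.
    """
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    seen: set[str] = set()
    for (a, b), rho in pairs.items():
        if not abs(rho) < 1:
            raise ValueError(f"|rho| must be < 1 for pair ({a}, {b})")
        if a == b or a in seen or b in seen:
            raise ValueError(f"gene reused across pairs: ({a}, {b})")
        seen.update((a, b))
    rng = _rng(seed, "coexpr")
    samples = [f"S{i+1:04d}" for i in range(n_samples)]
    rows, genes = [], []
    for (a, b), rho in pairs.items():
        cov = [[1.0, rho], [rho, 1.0]]
        draw = rng.multivariate_normal([8.0, 8.0], cov, size=n_samples).T
        rows.extend([draw[0], draw[1]])
        genes.extend([a, b])
    values = pd.DataFrame(
        np.array(rows) if rows else np.empty((0, n_samples)),
        index=pd.Index(genes, name="gene"),
        columns=samples,
    )
    groups = pd.Series([CASE] * n_samples, index=samples, name="group")
    return ExpressionMatrix(values=values, groups=groups)


def gen_target_map(
    component_ids: list[str],
    gene_pool: list[str],
    targets_per_component: tuple[int, int] = (2, 8),
    seed: int = 0,
) -> set[tuple[str, str]]:
    """Random bipartite component→target map over a gene pool."""
    rng = _rng(seed, "targets")
    lo, hi = targets_per_component
    pool = np.array(list(dict.fromkeys(gene_pool)))
    edges = set()
    for comp in component_ids:
        k = int(rng.integers(lo, min(hi, len(pool)) + 1))
        for t in rng.choice(pool, size=k, replace=False):
            edges.add((comp, str(t)))
    return edges


def gen_docking_table(
    ligands: list[str],
    receptors: list[str],
    frac_passing: float = 0.75,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Docking table over the ligand x receptor grid with a known passing
    subset (energy <= -5.0 and >= 2 hydrogen bonds)."""
    rng = _rng(seed, "docking")
    grid = [(l, r) for l in ligands for r in receptors]
    n_pass = round(frac_passing * len(grid))
    rows, passing = [], set()
    for idx, (lig, rec) in enumerate(grid):
        if idx < n_pass:
            energy = rng.uniform(-9.5, -5.0)
            hbonds = int(rng.integers(2, 7))
            passing.add((lig, rec))
        else:
            if rng.random() < 0.5:
                energy, hbonds = rng.uniform(-4.9, -2.0), int(rng.integers(2, 7))
            else:
                energy, hbonds = rng.uniform(-9.5, -5.0), int(rng.integers(0, 2))
        rows.append(
            {"ligand": lig, "receptor": rec, "energy": round(float(energy), 2),
             "total_interactions": hbonds + int(rng.integers(0, 9)),
             "hydrogen_bonds": hbonds, "mode_index": 1}
        )
    return pd.DataFrame(rows), SyntheticTruth(passing_docking_pairs=passing)
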