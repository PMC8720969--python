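"""Gene-set enrichment: hypergeometric over-representation and preranked GSEA.

Over-representation analysis (ORA) tests a query gene list against each set
of a collection with the upper-tail hypergeometric probability
P(X >= k | N, K, n), where N is the universe size, K the set size within the
universe, n the query size and k the overlap.  Benjamini-Hochberg adjustment
runs *within each category* (BP/CC/MF/KEGG/custom), matching per-category
top-term reporting.  Unless given, the universe is the union of all set
members — the single biggest driver of ORA p-value differences between
tools, so callers comparing against other software should pass it
explicitly.

Preranked GSEA walks a score-ranked gene list accumulating a weighted
Kolmogorov-Smirnov-like running sum: a hit at rank i adds
|score_i|^weight / sum over hits of |score|^weight, a miss subtracts
1/(N - Nh).  The enrichment score ES is the maximum-magnitude deviation of
the running sum; significance comes from gene-label permutations with a
sign-matched null and the add-one p estimator (b+1)/(n_perm+1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .targets import normalize_symbol

CATEGORIES = ("BP", "CC", "MF", "KEGG", "custom")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.set_id} has no members")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


GeneSetCollection = dict[str, GeneSet]


def make_collection(sets: Iterable[GeneSet]) -> GeneSetCollection:
    coll: GeneSetCollection = {}
    for s in sets:
        if s.set_id in coll:
            raise ValueError(f"duplicate set_id {s.set_id}")
        coll[s.set_id] = s
    return coll


def read_gmt(path: str | Path, category: str = "custom") -> GeneSetCollection:
    """Read a GMT file: set_id <tab> description <tab> gene1 <tab> gene2 ...

    A description of the form ``category:NAME`` sets the category field.
    """
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            set_id, desc = fields[0], fields[1]
            cat, name = category, desc
            if ":" in desc:
                prefix, rest = desc.split(":", 1)
                if prefix in CATEGORIES:
                    cat, name = prefix, rest
            members = frozenset(normalize_symbol(g) for g in fields[2:] if g.strip())
            sets.append(GeneSet(set_id=set_id, name=name, category=cat, members=members))
    return make_collection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id in sorted(collection):
            s = collection[set_id]
            genes = "\t".join(sorted(s.members))
            fh.write(f"{s.set_id}\t{s.category}:{s.name}\t{genes}\n")


def collection_universe(collection: GeneSetCollection) -> set[str]:
    universe: set[str] = set()
    for s in collection.values():
        universe |= s.members
    return universe


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k | N, K, n)."""
    if k <= 0:
        return 1.0
    return float(min(hypergeom.sf(k - 1, N, K, n), 1.0))


def ora(
    query: set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    p_thresh: float = 0.05,
    keep_all: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Returns a DataFrame (one row per set) with columns set_id, name,
    category, k, K, n, N, p, adjusted_p, overlap, sorted ascending by
    adjusted p then set_id.  By default only sets with adjusted_p < p_thresh
    are retained; ``keep_all=True`` returns every set.
    """
    if universe is None:
        universe = collection_universe(collection)
    universe = {normalize_symbol(g) for g in universe}
    if not universe:
        raise ValueError("empty universe")
    query = {normalize_symbol(g) for g in query}
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe dropped",
            stacklevel=2,
        )
        query = query & universe

    N, n = len(universe), len(query)
    rows = []
    for set_id in sorted(collection):
        s = collection[set_id]
        members = s.members & universe
        K = len(members)
        overlap = sorted(members & query)
        k = len(overlap)
        p = hypergeom_tail(k, N, K, n) if K else 1.0
        rows.append(
            {
                "set_id": s.set_id,
                "name": s.name,
                "category": s.category,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": min(p, 1.0),
                "overlap": ";".join(overlap),
            }
        )
    result = pd.DataFrame(rows)
    if result.empty:
        result["adjusted_p"] = pd.Series(dtype=float)
        return result
    from .deg import bh_adjust  # local import to avoid cycle at module load

    result["adjusted_p"] = np.nan
    for cat, idx in result.groupby("category").groups.items():
        result.loc[idx, "adjusted_p"] = bh_adjust(result.loc[idx, "p"].to_numpy())
    result = result.sort_values(
        by=["adjusted_p", "set_id"], kind="mergesort"
    ).reset_index(drop=True)
    if not keep_all:
        result = result[result["adjusted_p"] < p_thresh].reset_index(drop=True)
    return result


def top_terms(results: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """First n results per category after the ORA sort."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if results.empty:
        return results
    return (
        results.groupby("category", group_keys=False, sort=False)
        .head(n)
        .reset_index(drop=True)
    )


def gene_term_edges(results: pd.DataFrame) -> list[tuple[str, str]]:
    """One (set_id, gene) edge per overlapping gene of each retained set."""
    edges: list[tuple[str, str]] = []
    for _, row in results.iterrows():
        for gene in str(row["overlap"]).split(";"):
            if gene:
                edges.append((row["set_id"], gene))
    return edges


def pathway_genes(results: pd.DataFrame, category: str | None = None) -> set[str]:
    """Union of overlap genes across retained sets (optionally one category)."""
    sub = results if category is None else results[results["category"] == category]
    return {g for _, g in gene_term_edges(sub)}


@dataclass
class GseaResult:
    """Preranked GSEA outcome for one gene set."""

    es: float
    nes: float
    p: float
    leading_edge: list[str] = field(default_factory=list)
    running_sum: np.ndarray | None = None


def _running_sum(
    scores: np.ndarray, hit_mask: np.ndarray, weight: float
) -> np.ndarray:
    """Running enrichment statistic along the ranking."""
    n = scores.size
    n_hit = int(hit_mask.sum())
    n_miss = n - n_hit
    increments = np.where(hit_mask, np.abs(scores) ** weight, 0.0)
    total = increments.sum()
    if total == 0:
        # all hit scores are zero (possible at weight > 0): fall back to equal steps
        increments = hit_mask.astype(float)
        total = increments.sum()
    steps = increments / total - (~hit_mask) / n_miss
    return np.cumsum(steps)


def _es_from_running(running: np.ndarray) -> float:
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def gsea_preranked(
    ranking: Sequence[tuple[str, float]],
    set_members: set[str],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> GseaResult:
    """Enrichment score of ``set_members`` on a descending score ranking.

    ``ranking`` must have unique symbols sorted by descending score; the set
    must hit at least one but not every ranked gene.  The permutation null
    redraws the hit positions uniformly (gene-label permutation), and the
    nominal p compares |ES| within the sign-matched half of the null.
    """
    symbols = [normalize_symbol(s) for s, _ in ranking]
    scores = np.array([float(v) for _, v in ranking])
    if len(set(symbols)) != len(symbols):
        raise ValueError("ranking symbols must be unique")
    if np.any(np.diff(scores) > 1e-12):
        raise ValueError("ranking must be sorted by descending score")
    members = {normalize_symbol(s) for s in set_members}
    hit_mask = np.array([s in members for s in symbols])
    n_hit = int(hit_mask.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranking")
    if n_hit == len(symbols):
        raise ValueError("gene set covers the whole ranking (no misses)")

    running = _running_sum(scores, hit_mask, weight)
    es = _es_from_running(running)

    peak = int(np.argmax(np.abs(running)))
    if es >= 0:
        leading = [s for s, hit in zip(symbols[: peak + 1], hit_mask[: peak + 1]) if hit]
    else:
        leading = [s for s, hit in zip(symbols[peak:], hit_mask[peak:]) if hit]

    rng = np.random.default_rng(seed)
    null_es = np.empty(n_perm)
    positions = np.arange(len(symbols))
    for b in range(n_perm):
        perm_mask = np.zeros(len(symbols), dtype=bool)
        perm_mask[rng.choice(positions, size=n_hit, replace=False)] = True
        null_es[b] = _es_from_running(_running_sum(scores, perm_mask, weight))

    same_sign = null_es[null_es >= 0] if es >= 0 else -null_es[null_es < 0]
    if same_sign.size:
        mean_abs = float(np.mean(np.abs(same_sign)))
        nes = es / mean_abs if mean_abs > 0 else np.nan
        b_exceed = int(np.sum(np.abs(same_sign) >= abs(es)))
        p = (b_exceed + 1) / (same_sign.size + 1)
    else:
        nes, p = np.nan, 1.0 / (n_perm + 1)

    return GseaResult(es=es, nes=float(nes), p=float(p), leading_edge=leading, running_sum=running)
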