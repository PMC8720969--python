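"""Two-group differential expression on log2-scale expression matrices.

The model is the standard microarray-era case/control comparison: per-gene
log2 fold change is the difference of group means on the log2 scale, the
per-gene p-value comes from a two-sided Welch t-test (unequal variances),
and false-discovery control uses Benjamini-Hochberg.  A gene is called
differentially expressed when |log2FC| > 1.0 and q < 0.05, both strict.

No moderated-t shrinkage is applied; the test backend is pluggable in
principle (``gene_test`` is the single point where the statistic enters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 intensities plus a case/control label per sample.

    ``values``: DataFrame indexed by gene symbol, columns are sample ids.
    ``groups``: Series indexed by sample id with values 'case'/'control'.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene symbols: {list(dups)[:5]}")
        if not set(self.values.columns) <= set(self.groups.index):
            raise ValueError("every sample column needs a group label")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if float(self.values.to_numpy().max(initial=0.0)) > 30:
            warnings.warn(
                "value range suggests raw intensities, not log2 scale",
                stacklevel=2,
            )

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def write(self, values_path: str | Path, groups_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.groups.rename("group").to_csv(groups_path, sep="\t", index_label="sample")

    @classmethod
    def read(cls, values_path: str | Path, groups_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        groups = pd.read_csv(groups_path, sep="\t", index_col=0)["group"]
        groups.index.name = None
        return cls(values=values, groups=groups)


def _split(matrix: ExpressionMatrix) -> tuple[np.ndarray, np.ndarray]:
    case = matrix.values[matrix.samples_in(CASE)].to_numpy(dtype=float)
    ctrl = matrix.values[matrix.samples_in(CONTROL)].to_numpy(dtype=float)
    if case.shape[1] == 0 or ctrl.shape[1] == 0:
        raise ValueError("both groups need at least one sample")
    return case, ctrl


def log2fc(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene log2 fold change: mean(case) - mean(control)."""
    case, ctrl = _split(matrix)
    return pd.Series(case.mean(axis=1) - ctrl.mean(axis=1), index=matrix.genes, name="log2FC")


def gene_test(matrix: ExpressionMatrix) -> pd.Series:
    """Two-sided Welch t-test p-value per gene.

    Degenerate rows (zero variance in both groups) get p = 1 when the group
    means coincide and p = 0 (with a warning) when they differ: a constant
    shift with no noise is unambiguous evidence.
    """
    case, ctrl = _split(matrix)
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("Welch test needs >= 2 samples per group")
    degenerate = (case.var(axis=1) == 0) & (ctrl.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    if degenerate.any():
        equal = np.isclose(case.mean(axis=1), ctrl.mean(axis=1))
        p[degenerate & equal] = 1.0
        shifted = degenerate & ~equal
        if shifted.any():
            warnings.warn(
                f"{int(shifted.sum())} zero-variance gene(s) with unequal means; p set to 0",
                stacklevel=2,
            )
            p[shifted] = 0.0
    return pd.Series(p, index=matrix.genes, name="p")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def deg_table(matrix: ExpressionMatrix, lfc_thresh: float = 1.0, q_thresh: float = 0.05) -> pd.DataFrame:
    """Full per-gene result: log2FC, raw p, BH q, and call direction.

    direction is 'up' when log2FC > lfc_thresh and q < q_thresh, 'down' when
    log2FC < -lfc_thresh and q < q_thresh, else 'none' (strict inequalities).
    """
    if lfc_thresh <= 0 or q_thresh <= 0:
        raise ValueError("thresholds must be > 0")
    lfc = log2fc(matrix)
    p = gene_test(matrix)
    q = pd.Series(bh_adjust(p.to_numpy()), index=matrix.genes, name="q")
    direction = pd.Series("none", index=matrix.genes, name="direction")
    direction[(lfc > lfc_thresh) & (q < q_thresh)] = "up"
    direction[(lfc < -lfc_thresh) & (q < q_thresh)] = "down"
    return pd.DataFrame({"log2FC": lfc, "p": p, "q": q, "direction": direction})


def call_degs(table: pd.DataFrame) -> tuple[set[str], set[str]]:
    """Up- and down-regulated gene sets from a deg_table result."""
    up = set(table.index[table["direction"] == "up"])
    down = set(table.index[table["direction"] == "down"])
    return up, down


def top_by_significance(table: pd.DataFrame, n: int = 100) -> list[str]:
    """The n most significant called DEGs.

    Sort: ascending q, then ascending raw p, then descending |log2FC|, then
    symbol — a total order so the list is reproducible.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    degs = table[table["direction"] != "none"].copy()
    degs["abs_lfc"] = degs["log2FC"].abs()
    degs["symbol"] = degs.index
    ordered = degs.sort_values(
        by=["q", "p", "abs_lfc", "symbol"],
        ascending=[True, True, False, True],
        kind="mergesort",
    )
    return list(ordered.index[:n])


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene")
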