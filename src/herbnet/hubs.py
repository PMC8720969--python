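"""Hub-target selection and coexpression flagging.

Hub targets sit at the intersection of three evidence layers: survival of
the PPI centrality cascade (core network membership), being targeted by the
formula's active components, and membership in disease-relevant enriched
pathways.  ``select_hubs`` performs the double intersection and records,
per symbol, which layers support it.

``coexpression`` correlates each hub with phenotype-indicator genes
(e.g. CCNB1 for G2/M cell cycle, CASP9 for apoptosis, CD11B/ITGAM for
myeloid differentiation) by Pearson r with the two-sided t-transform
p-value (n-2 df), flagging pairs with r > r_min and p < p_max.  The
positive-only rule mirrors the usual reporting convention; set
``absolute=True`` to flag strong negative correlations too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .deg import ExpressionMatrix
from .targets import normalize_symbol

DEFAULT_R_MIN = 0.3
DEFAULT_P_MAX = 0.05


@dataclass
class HubReport:
    """Result of the double intersection with per-symbol provenance."""

    core_active_targets: set[str]
    hub_targets: set[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)


def select_hubs(
    core_nodes: set[str],
    drug_targets: set[str],
    pathway_genes: set[str],
) -> HubReport:
    """core ∩ drug targets, then ∩ pathway genes, with provenance."""
    core = {normalize_symbol(s) for s in core_nodes}
    drugs = {normalize_symbol(s) for s in drug_targets}
    paths = {normalize_symbol(s) for s in pathway_genes}
    core_active = core & drugs
    hub = core_active & paths
    provenance = {}
    for sym in sorted(core_active):
        layers = ["core_network", "component_target"]
        if sym in paths:
            layers.append("pathway")
        provenance[sym] = layers
    return HubReport(core_active_targets=core_active, hub_targets=hub, provenance=provenance)


def coexpression(
    matrix: ExpressionMatrix,
    hubs: list[str],
    indicators: list[str],
    r_min: float = DEFAULT_R_MIN,
    p_max: float = DEFAULT_P_MAX,
    absolute: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every (hub, indicator) pair across samples.

    Returns a DataFrame with columns hub, indicator, r, p, flagged, reason.
    A zero-variance gene makes r undefined: the pair is reported unflagged
    with the reason recorded.
    """
    if matrix.values.shape[1] < 3:
        raise ValueError("coexpression needs >= 3 samples")
    hubs = [normalize_symbol(h) for h in hubs]
    indicators = [normalize_symbol(i) for i in indicators]
    missing = (set(hubs) | set(indicators)) - set(matrix.genes)
    if missing:
        raise KeyError(f"symbols absent from matrix: {sorted(missing)}")
    rows = []
    for hub in hubs:
        x = matrix.values.loc[hub].to_numpy(dtype=float)
        for ind in indicators:
            y = matrix.values.loc[ind].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append(
                    {"hub": hub, "indicator": ind, "r": np.nan, "p": np.nan,
                     "flagged": False, "reason": "zero variance"}
                )
                continue
            r, p = stats.pearsonr(x, y)
            strength = abs(r) if absolute else r
            flagged = bool(strength > r_min and p < p_max)
            rows.append(
                {"hub": hub, "indicator": ind, "r": float(r), "p": float(p),
                 "flagged": flagged, "reason": ""}
            )
    return pd.DataFrame(rows, columns=["hub", "indicator", "r", "p", "flagged", "reason"])
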