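"""Docking-result table ingestion, best-mode selection and ranking.

Docking computation itself (AutoDock/Vina, structure preparation) is out of
scope; this module consumes the tabular results: one row per ligand-receptor
binding mode with the estimated binding free energy in kcal/mol (more
negative = more favorable) and interaction counts.

Conventions: when a pair has multiple modes, mode 1 is the best mode if
present (docking engines emit modes ranked by affinity), otherwise the
minimum-energy record.  The customary "good binder" rule keeps records with
energy <= -5.0 kcal/mol and, when a hydrogen-bond column exists, >= 2
hydrogen bonds; "total interactions" stays an opaque count because published
tables mix hydrogen bonds with pi-stacking and alkyl contacts.
"""

from __future__ import annotations

import logging
import warnings
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_ENERGY_MAX = -5.0
DEFAULT_HBOND_MIN = 2

_HEADER_ALIASES = {
    "active ingredients": "ligand",
    "ligand": "ligand",
    "hub genes": "receptor",
    "receptor": "receptor",
    "target": "receptor",
    "kcal/mol": "energy",
    "energy": "energy",
    "binding energy": "energy",
    "total interactions": "total_interactions",
    "interactions": "total_interactions",
    "hydrogen bonds": "hydrogen_bonds",
    "hbonds": "hydrogen_bonds",
    "mode": "mode_index",
    "mode_index": "mode_index",
}


def read_docking(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a docking-results table.

    Required columns (case-insensitive, aliases accepted): ligand
    ("Active ingredients"), receptor ("Hub genes"), energy ("kcal/mol").
    Optional: total interactions, hydrogen bonds, mode index.  Unicode
    minus signs in energies are normalized.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    renames = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _HEADER_ALIASES:
            renames[col] = _HEADER_ALIASES[key]
    df = df.rename(columns=renames)
    missing = {"ligand", "receptor", "energy"} - set(df.columns)
    if missing:
        raise ValueError(f"docking table missing columns: {sorted(missing)}")
    df["energy"] = pd.to_numeric(
        df["energy"].str.replace("−", "-", regex=False), errors="raise"
    )
    for col in ("total_interactions", "hydrogen_bonds", "mode_index"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if not df["energy"].apply(lambda e: e == e and abs(e) < 1e6).all():
        raise ValueError("non-finite binding energy")
    return df.reset_index(drop=True)


def load_reference_docking() -> pd.DataFrame:
    """The published 16-pair docking table for the nine pivotal components
    of Shen Qi Sha Bai Decoction against the six AML hub targets; shipped
    with the package as a reference fixture."""
    with resources.as_file(
        resources.files("herbnet.data").joinpath("docking_results.tsv")
    ) as p:
        return read_docking(p)


def best_mode(records: pd.DataFrame) -> pd.Series:
    """Best binding mode among the records of one ligand-receptor pair.

    Mode 1 when a mode_index column lists it, else the minimum-energy record.
    """
    if records.empty:
        raise ValueError("no records for this pair")
    if "mode_index" in records.columns:
        first = records[records["mode_index"] == 1]
        if len(first):
            logger.debug("best_mode: mode 1 present, used")
            return first.iloc[0]
    logger.debug("best_mode: mode 1 absent, minimum energy used")
    return records.loc[records["energy"].idxmin()]


def best_modes(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a multi-mode table to one best-mode row per pair."""
    rows = [
        best_mode(grp) for _, grp in table.groupby(["ligand", "receptor"], sort=True)
    ]
    return pd.DataFrame(rows).reset_index(drop=True)


def apply_thresholds(
    records: pd.DataFrame,
    energy_max: float = DEFAULT_ENERGY_MAX,
    hbond_min: int = DEFAULT_HBOND_MIN,
) -> pd.DataFrame:
    """Keep good binders: energy <= energy_max (inclusive) and, when a
    hydrogen-bond column is present, hydrogen_bonds >= hbond_min."""
    if records.empty:
        return records.copy()
    mask = records["energy"] <= energy_max
    if "hydrogen_bonds" in records.columns:
        mask &= records["hydrogen_bonds"] >= hbond_min
    else:
        warnings.warn(
            "no hydrogen-bond column; H-bond threshold not applied",
            stacklevel=2,
        )
    return records.loc[mask].reset_index(drop=True)


def rank_pairs(records: pd.DataFrame, by: str = "energy") -> pd.DataFrame:
    """Rank by energy ascending (most negative first) or interactions
    descending; ties break on the other criterion then ligand/receptor."""
    if by not in ("energy", "interactions"):
        raise ValueError("by must be 'energy' or 'interactions'")
    df = records.copy()
    has_int = "total_interactions" in df.columns
    if by == "interactions" and not has_int:
        raise ValueError("no total_interactions column to rank by")
    if by == "energy":
        keys = ["energy"] + (["total_interactions"] if has_int else [])
        ascending = [True] + ([False] if has_int else [])
    else:
        keys = ["total_interactions", "energy"]
        ascending = [False, True]
    keys += ["ligand", "receptor"]
    ascending += [True, True]
    return df.sort_values(by=keys, ascending=ascending, kind="mergesort").reset_index(drop=True)
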