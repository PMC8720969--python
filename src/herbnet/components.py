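"""ADME-based screening of herbal-formula constituents.

A component table holds one row per distinct molecule (``mol_id``) with the
TCMSP-style absorption/distribution properties used for oral-drug screening:

``mol_id``  unique molecule identifier (e.g. ``MOL000098``)
``name``    molecule name
``DL``      drug-likeness score, unitless, >= 0
``AlogP``   octanol/water partition coefficient (optional)
``OB``      oral bioavailability, percent
``HL``      half-life, hours (optional)
``herbs``   semicolon-separated source herbs (optional, may be empty)

The canonical screen keeps components with OB >= 30 % and DL >= 0.18, the
standard TCMSP activity criterion; both thresholds are inclusive.
"""

from __future__ import annotations

import warnings
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

#: internal column order for a component table
COMPONENT_COLUMNS = ["mol_id", "name", "DL", "AlogP", "OB", "HL", "herbs"]

#: accepted header spellings in input files, mapped to internal names
_HEADER_ALIASES = {
    "mol id": "mol_id",
    "mol_id": "mol_id",
    "molecule name": "name",
    "name": "name",
    "dl": "DL",
    "alogp": "AlogP",
    "ob (%)": "OB",
    "ob": "OB",
    "hl": "HL",
    "herb": "herbs",
    "herbs": "herbs",
}

DEFAULT_OB_MIN = 30.0
DEFAULT_DL_MIN = 0.18


def read_components(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    """Read a component table from TSV/CSV.

    Required headers (case-insensitive): Mol ID, Molecule name, DL, OB (%).
    Optional: AlogP, HL, herb (semicolon-separated for multi-herb molecules).
    Duplicate mol_ids are collapsed to one record with the union of herbs.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str)
    raw.columns = [str(c).strip() for c in raw.columns]
    renames = {}
    for col in raw.columns:
        key = col.strip().lower()
        if key in _HEADER_ALIASES:
            renames[col] = _HEADER_ALIASES[key]
    df = raw.rename(columns=renames)
    missing = {"mol_id", "name", "DL", "OB"} - set(df.columns)
    if missing:
        raise ValueError(f"component table missing required columns: {sorted(missing)}")
    for col in ("DL", "AlogP", "OB", "HL"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            df[col] = float("nan")
    if "herbs" not in df.columns:
        df["herbs"] = ""
    df["herbs"] = df["herbs"].fillna("")
    df["mol_id"] = df["mol_id"].str.strip()
    if df["mol_id"].duplicated().any():
        df = _dedupe_by_mol_id(df)
    return df[COMPONENT_COLUMNS].reset_index(drop=True)


def _dedupe_by_mol_id(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse rows sharing a mol_id into one record with merged herb sets."""
    merged = []
    for _, grp in df.groupby("mol_id", sort=False):
        row = grp.iloc[0].copy()
        herbs: set[str] = set()
        for h in grp["herbs"]:
            herbs.update(x.strip() for x in str(h).split(";") if x.strip())
        row["herbs"] = ";".join(sorted(herbs))
        merged.append(row)
    return pd.DataFrame(merged)


def load_pivotal_components() -> pd.DataFrame:
    """The nine pivotal active components of Shen Qi Sha Bai Decoction
    (licochalcone A, quercetin, luteolin, kaempferol, wogonin, oroxylin A,
    formononetin, naringenin, baicalein) with their published TCMSP ADME
    properties; shipped with the package as a reference fixture."""
    with resources.as_file(
        resources.files("herbnet.data").joinpath("pivotal_components.tsv")
    ) as p:
        return read_components(p)


def filter_components(
    table: pd.DataFrame,
    ob_min: float = DEFAULT_OB_MIN,
    dl_min: float = DEFAULT_DL_MIN,
) -> pd.DataFrame:
    """Keep components with OB >= ob_min and DL >= dl_min (both inclusive).

    Row order is preserved and the input is not modified.  A row with a
    missing OB or DL value is a data error and is reported by mol_id.
    """
    for col in ("OB", "DL"):
        bad = table[table[col].isna()]
        if len(bad):
            ids = ", ".join(bad["mol_id"].astype(str))
            raise ValueError(f"component(s) missing {col}: {ids}")
    mask = (table["OB"] >= ob_min) & (table["DL"] >= dl_min)
    return table.loc[mask].copy()


def rank_by_dl(table: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Rank components by descending drug-likeness.

    Ties are broken by descending OB, then ascending mol_id, giving a total
    deterministic order.  Returns the first ``min(k, n)`` rows (all if ``k``
    is None).
    """
    if k is not None and k < 0:
        raise ValueError("k must be >= 0")
    ranked = table.sort_values(
        by=["DL", "OB", "mol_id"],
        ascending=[False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return ranked if k is None else ranked.head(k)


def herb_component_links(table: pd.DataFrame) -> list[tuple[str, str]]:
    """One (mol_id, herb) edge per herb membership, sorted (mol_id, herb).

    Components with an empty herb set contribute no edges and trigger a
    warning.
    """
    edges: list[tuple[str, str]] = []
    orphans: list[str] = []
    for _, row in table.iterrows():
        herbs = [h.strip() for h in str(row["herbs"]).split(";") if h.strip()]
        if not herbs:
            orphans.append(str(row["mol_id"]))
            continue
        edges.extend((str(row["mol_id"]), h) for h in herbs)
    if orphans:
        warnings.warn(
            f"{len(orphans)} component(s) with no source herb: {', '.join(orphans)}",
            stacklevel=2,
        )
    return sorted(edges)


def write_components(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
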