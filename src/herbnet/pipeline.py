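"""End-to-end orchestration of the network-pharmacology chain.

Stage order: component filter → differential expression → target/DEG
intersection (+ bipartite network) → over-representation enrichment → PPI
topological screening → hub selection → coexpression → docking ranking.
Each stage writes its artifact before the next starts, so a failure in
stage k leaves stages < k on disk together with a partial run report.

All stage thresholds live in :class:`RunConfig` with the conventional
defaults (OB ≥ 30, DL ≥ 0.18, |log2FC| > 1, q < 0.05, adjusted p < 0.05,
DMD = 2 × median degree, DC > 60, BC > 645, R > 0.3 & p < 0.05,
energy ≤ −5.0 kcal/mol, ≥ 2 H-bonds); nothing is hard-coded inside a stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import components as comp_mod
from . import deg as deg_mod
from . import docking as dock_mod
from . import enrichment as enr_mod
from . import hubs as hub_mod
from . import ppi as ppi_mod
from . import targets as tgt_mod

logger = logging.getLogger(__name__)

STAGES = (
    "filter_components",
    "deg",
    "intersect",
    "enrich",
    "screen",
    "hubs",
    "coexpr",
    "dock_rank",
)


@dataclass
class RunConfig:
    """Flat, fully-defaulted configuration for one pipeline run."""

    # inputs
    components_path: str = ""
    expression_path: str = ""
    groups_path: str = ""
    target_map_path: str = ""
    genesets_path: str = ""
    ppi_path: str = ""
    docking_path: str = ""
    indicators: list[str] = field(default_factory=lambda: ["CCNB1", "CASP9", "ITGAM"])
    # stage thresholds
    ob_min: float = 30.0
    dl_min: float = 0.18
    lfc_thresh: float = 1.0
    q_thresh: float = 0.05
    ora_p: float = 0.05
    dmd_multiplier: float = 2.0
    dmd_absolute: float | None = None
    dc_min: float = 60.0
    bc_min: float = 645.0
    r_min: float = 0.3
    p_max: float = 0.05
    energy_max: float = -5.0
    hbond_min: int = 2
    # bookkeeping
    seed: int = 0
    out_dir: str = "herbnet_run"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_TYPES = {f.name: f for f in dataclasses.fields(RunConfig)}


def validate_config(raw: dict | RunConfig) -> RunConfig:
    """Check keys and types; unknown keys are rejected, missing ones default."""
    if isinstance(raw, RunConfig):
        raw = raw.to_dict()
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    coerced = {}
    for key, value in raw.items():
        f = _FIELD_TYPES[key]
        if value is None and key == "dmd_absolute":
            coerced[key] = None
        elif f.type in ("float", "float | None"):
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise TypeError(f"config key {key!r} must be a number, got {value!r}")
            coerced[key] = float(value)
        elif f.type == "int":
            if not isinstance(value, int) or isinstance(value, bool):
                raise TypeError(f"config key {key!r} must be an integer, got {value!r}")
            coerced[key] = value
        elif f.type == "str":
            if not isinstance(value, str):
                raise TypeError(f"config key {key!r} must be a string, got {value!r}")
            coerced[key] = value
        elif f.type.startswith("list"):
            if not isinstance(value, (list, tuple)):
                raise TypeError(f"config key {key!r} must be a list, got {value!r}")
            coerced[key] = [str(v) for v in value]
        else:  # pragma: no cover - no other field types declared
            coerced[key] = value
    return RunConfig(**coerced)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def write_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclass
class RunReport:
    """Machine-readable account of a pipeline run."""

    config: dict
    version: str = __version__
    stages: list[dict] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None

    def record(self, stage: str, n_in: int, n_out: int, threshold: str, seconds: float) -> None:
        self.stages.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out,
             "threshold": threshold, "seconds": round(seconds, 4)}
        )

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all eight stages, writing artifacts under config.out_dir."""
    config = validate_config(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=config.to_dict())

    def _finish(stage: str, exc: Exception) -> RunReport:
        report.failed_stage = stage
        report.error = f"{type(exc).__name__}: {exc}"
        report.to_json(out / "run_report.json")
        return report

    for path_key in ("components_path", "expression_path", "groups_path",
                     "target_map_path", "genesets_path", "ppi_path", "docking_path"):
        p = getattr(config, path_key)
        if p and not Path(p).exists():
            raise FileNotFoundError(f"configured input missing: {path_key} = {p}")

    # 1. component filter
    t0 = time.perf_counter()
    table = comp_mod.read_components(config.components_path)
    active = comp_mod.filter_components(table, ob_min=config.ob_min, dl_min=config.dl_min)
    comp_mod.write_components(active, out / "active_components.tsv")
    report.record("filter_components", len(table), len(active),
                  f"OB >= {config.ob_min:g} and DL >= {config.dl_min:g}",
                  time.perf_counter() - t0)

    # 2. differential expression
    t0 = time.perf_counter()
    matrix = deg_mod.ExpressionMatrix.read(config.expression_path, config.groups_path)
    degs_table = deg_mod.deg_table(matrix, lfc_thresh=config.lfc_thresh, q_thresh=config.q_thresh)
    deg_mod.write_deg_table(degs_table, out / "deg_table.tsv")
    up, down = deg_mod.call_degs(degs_table)
    deg_set = up | down
    report.record("deg", len(degs_table), len(deg_set),
                  f"|log2FC| > {config.lfc_thresh:g} and q < {config.q_thresh:g}",
                  time.perf_counter() - t0)

    # 3. target intersection + bipartite network
    t0 = time.perf_counter()
    target_map = tgt_mod.read_target_map(config.target_map_path)
    active_ids = set(active["mol_id"])
    drug_targets = {t for c, t in target_map if c in active_ids}
    common = tgt_mod.common_targets(drug_targets, deg_set)
    pd.DataFrame({"target": common}).to_csv(out / "common_targets.tsv", sep="\t", index=False)
    bip = tgt_mod.build_bipartite(target_map, active_ids, set(common))
    tgt_mod.write_sif(bip, out / "bipartite.sif", relation="ct")
    report.record("intersect", len(drug_targets), len(common),
                  "exact set intersection", time.perf_counter() - t0)

    # 4. enrichment (ORA)
    t0 = time.perf_counter()
    collection = enr_mod.read_gmt(config.genesets_path)
    ora_res = enr_mod.ora(set(common), collection, p_thresh=config.ora_p)
    ora_res.to_csv(out / "ora_results.tsv", sep="\t", index=False)
    pathway = enr_mod.pathway_genes(ora_res)
    report.record("enrich", len(collection), len(ora_res),
                  f"adjusted p < {config.ora_p:g}", time.perf_counter() - t0)

    # 5. PPI screening cascade
    t0 = time.perf_counter()
    net = ppi_mod.load_network(config.ppi_path)
    core, screen = ppi_mod.screen_cascade(
        net,
        dmd_multiplier=config.dmd_multiplier,
        dmd_absolute=config.dmd_absolute,
        dc_min=config.dc_min,
        bc_min=config.bc_min,
    )
    tgt_mod.write_sif(core, out / "core_network.sif")
    with open(out / "screen_report.json", "w") as fh:
        json.dump(screen.to_records(), fh, indent=1)
        fh.write("\n")
    report.record("screen", net.number_of_nodes(), core.number_of_nodes(),
                  f"DMD x{config.dmd_multiplier:g}; DC > {config.dc_min:g}, BC > {config.bc_min:g}",
                  time.perf_counter() - t0)

    # 6. hub selection
    t0 = time.perf_counter()
    hub_report = hub_mod.select_hubs(set(core.nodes()), drug_targets, pathway)
    pd.DataFrame(
        {
            "symbol": sorted(hub_report.core_active_targets),
            "is_hub": [s in hub_report.hub_targets for s in sorted(hub_report.core_active_targets)],
            "evidence": [";".join(hub_report.provenance[s]) for s in sorted(hub_report.core_active_targets)],
        }
    ).to_csv(out / "hub_targets.tsv", sep="\t", index=False)
    report.record("hubs", len(hub_report.core_active_targets), len(hub_report.hub_targets),
                  "core ∩ targets ∩ pathways", time.perf_counter() - t0)

    # 7. coexpression of hubs with indicator genes
    t0 = time.perf_counter()
    hubs_present = sorted(set(hub_report.hub_targets) & set(matrix.genes))
    inds_present = sorted(set(tgt_mod.normalize_symbol(i) for i in config.indicators) & set(matrix.genes))
    if hubs_present and inds_present:
        coex = hub_mod.coexpression(
            matrix, hubs_present, inds_present, r_min=config.r_min, p_max=config.p_max
        )
    else:
        coex = pd.DataFrame(columns=["hub", "indicator", "r", "p", "flagged", "reason"])
    coex.to_csv(out / "coexpression.tsv", sep="\t", index=False)
    report.record("coexpr", len(hubs_present) * len(inds_present),
                  int(coex["flagged"].sum()) if len(coex) else 0,
                  f"r > {config.r_min:g} and p < {config.p_max:g}",
                  time.perf_counter() - t0)

    # 8. docking-table ranking
    t0 = time.perf_counter()
    dock = dock_mod.read_docking(config.docking_path)
    best = dock_mod.best_modes(dock)
    good = dock_mod.apply_thresholds(best, energy_max=config.energy_max, hbond_min=config.hbond_min)
    ranked = dock_mod.rank_pairs(good, by="energy")
    ranked.to_csv(out / "docking_ranked.tsv", sep="\t", index=False)
    report.record("dock_rank", len(best), len(ranked),
                  f"energy <= {config.energy_max:g} kcal/mol, H-bonds >= {config.hbond_min:d}",
                  time.perf_counter() - t0)

    report.to_json(out / "run_report.json")
    return report


def simulate_bundle(out_dir: str | Path, seed: int = 0, scale: str = "small") -> RunConfig:
    """Generate a complete synthetic input bundle plus its truth ledger and
    return a RunConfig pointing at it.

    ``scale='small'`` is sized for quick runs (2 000 genes, 630-node PPI);
    ``scale='default'`` enlarges the expression matrix to 5 000 genes.
    """
    from . import synthetic as syn

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_genes = 2000 if scale == "small" else 5000

    table, truth_c = syn.gen_component_table(n_components=50, frac_passing=0.24, seed=seed)
    comp_mod.write_components(table, out / "components.tsv")

    matrix, truth_e = syn.gen_expression(
        n_genes=n_genes, n_case=30, n_control=9, n_de=100, lfc=2.0, sigma=0.5, seed=seed
    )
    matrix.write(out / "expression.tsv", out / "groups.tsv")

    # component targets drawn from a pool enriched for the planted DE genes,
    # so a sizeable common-target set exists by construction
    de_genes = sorted(truth_e.de_gene_ids_up | truth_e.de_gene_ids_down)
    gene_pool = de_genes + [f"G{i+1:05d}" for i in range(0, n_genes, 20)]
    target_map = syn.gen_target_map(
        sorted(truth_c.passing_component_ids), gene_pool,
        targets_per_component=(5, 15), seed=seed
    )
    tgt_mod.write_target_map(target_map, out / "target_map.tsv")

    targeted_de = sorted({t for _, t in target_map} & set(de_genes))
    universe = [f"G{i+1:05d}" for i in range(n_genes)]
    collection, truth_g = syn.gen_genesets(
        universe, n_sets=40, set_size_range=(10, 40),
        planted_list=targeted_de or de_genes, n_enriched=4, seed=seed
    )
    enr_mod.write_gmt(collection, out / "genesets.gmt")

    # planted PPI core nodes carry targeted-DE symbols so the hub stage has
    # genes supported by all three evidence layers
    core_labels = targeted_de[:30]
    net, truth_p = syn.gen_ppi(
        n_background=600, attach_m=2, core_size=len(core_labels), core_p=0.8,
        seed=seed, core_labels=core_labels,
    )
    tgt_mod.write_sif(net, out / "ppi.sif")

    dock, truth_d = syn.gen_docking_table(
        ligands=sorted(truth_c.passing_component_ids)[:5],
        receptors=targeted_de[:4] or de_genes[:4],
        seed=seed,
    )
    dock.to_csv(out / "docking.tsv", sep="\t", index=False)

    truth = truth_c.merge(truth_e).merge(truth_g).merge(truth_p).merge(truth_d)
    truth.to_json(out / "truth.json")

    return validate_config(
        {
            "components_path": str(out / "components.tsv"),
            "expression_path": str(out / "expression.tsv"),
            "groups_path": str(out / "groups.tsv"),
            "target_map_path": str(out / "target_map.tsv"),
            "genesets_path": str(out / "genesets.gmt"),
            "ppi_path": str(out / "ppi.sif"),
            "docking_path": str(out / "docking.tsv"),
            # indicator genes present in the synthetic matrix (DE genes that
            # are not planted core nodes), so the coexpression stage is live
            "indicators": [g for g in de_genes if g not in core_labels][:3],
            "seed": seed,
            "out_dir": str(out / "results"),
            # cascade thresholds sized for the 630-node synthetic regime
            "dc_min": 15.0,
            "bc_min": 0.0,
        }
    )
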