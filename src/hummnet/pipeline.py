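"""End-to-end orchestration: build -> degree fits -> nestedness + nulls ->
modularity -> biogeography -> GLM, with seeded reproducibility.

Each stage derives its own random stream by hashing (master seed, stage
name), so stages are independent and individually re-runnable; every
randomized output records its seed and replicate count.  Stage outputs are
written as CSV/JSON under the configured output directory plus one
consolidated ``summary.json``.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import biogeo as bg
from . import glm as niche
from .degree import cumulative_distribution, degree_sequence, fit_degree_models
from .matrix import BipartiteMatrix, TaxonMaps, build_matrix, read_interaction_records, read_tip_order
from .modules import SASchedule, bipartite_to_graph, consensus_partition, modularity_significance, node_roles
from .nodf import nodf
from .nulls import null_ensemble

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "read_map_csv"]

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2b(f"{master_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


def read_map_csv(path, key_field: str, value_field: str) -> dict:
    """Two-column lookup CSV (e.g. species -> clade, family -> syndrome)."""
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out[row[key_field].strip()] = row[value_field].strip()
    return out


@dataclass
class RunConfig:
    records_csv: str
    bird_clade_csv: str
    plant_family_csv: str
    syndrome_csv: str | None = None
    biogeo_csv: str | None = None
    native_only: bool = True
    row_order_newick: str | None = None  # plant-family tip order (fixed-order NODF)
    col_order_newick: str | None = None  # hummingbird-clade tip order
    nodf_null_reps: int = 1000
    mod_null_reps: int = 100
    sa_runs: int = 50
    consensus_threshold: float = 0.9
    sa_schedule: SASchedule = field(default_factory=SASchedule)
    glm_links: tuple = ("logit", "probit")
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        if self.nodf_null_reps < 2 or self.mod_null_reps < 2:
            raise ValueError("null replicate counts must be >= 2")
        if not (0.5 < self.consensus_threshold <= 1):
            raise ValueError("consensus threshold must be in (0.5, 1]")


def _stage(name):
    def wrap(func):
        def inner(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run every analysis stage; returns the summary dict (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"seed": config.seed, "native_only": config.native_only}

    # --- build ---------------------------------------------------------------
    records = read_interaction_records(config.records_csv)
    maps = TaxonMaps(
        read_map_csv(config.bird_clade_csv, "species", "clade"),
        read_map_csv(config.plant_family_csv, "species", "family"),
        read_map_csv(config.syndrome_csv, "family", "syndrome") if config.syndrome_csv else {},
    )
    matrix = _stage("build")(build_matrix)(records, maps, config.native_only)
    matrix.write_csv(out / "matrix.csv")
    summary["network"] = {
        "n_families": len(matrix.rows),
        "n_clades": len(matrix.cols),
        "n_links": matrix.n_links,
        "fill": matrix.fill,
    }

    # --- degree fits ---------------------------------------------------------
    dist = cumulative_distribution(degree_sequence(matrix, "combined"))
    fits, best = _stage("degfit")(fit_degree_models)(dist)
    pd.DataFrame([
        {"model": f.model, **{f"param_{k}": v for k, v in f.params.items()},
         "rss": f.rss, "aic": f.aic, "selected": name == best}
        for name, f in fits.items()
    ]).to_csv(out / "degree_fits.csv", index=False)
    summary["degree"] = {"best_model": best, "aic": {n: f.aic for n, f in fits.items()}}

    # --- nestedness + null ensembles ----------------------------------------
    nodf_sorted = nodf(matrix, "sorted").rounded()
    summary["nodf_sorted"] = {
        "total": nodf_sorted.nodf_total,
        "rows": nodf_sorted.nodf_rows,
        "cols": nodf_sorted.nodf_cols,
    }
    statistics = {"nodf_sorted": lambda m: nodf(m, "sorted").nodf_total}
    if config.row_order_newick or config.col_order_newick:
        from .matrix import order_matrix

        row_order = read_tip_order(config.row_order_newick) if config.row_order_newick else None
        col_order = read_tip_order(config.col_order_newick) if config.col_order_newick else None
        fixed = order_matrix(matrix, "given", row_order, col_order)
        nodf_fixed = nodf(fixed, "fixed").rounded()
        summary["nodf_fixed"] = {
            "total": nodf_fixed.nodf_total,
            "rows": nodf_fixed.nodf_rows,
            "cols": nodf_fixed.nodf_cols,
        }
        statistics["nodf_fixed"] = lambda m: nodf(
            order_matrix(m, "given", row_order, col_order), "fixed"
        ).nodf_total

    summary["nestedness_nulls"] = {}
    for stat_name, stat in statistics.items():
        for model in ("ER", "CE", "FF"):
            rng = np.random.default_rng(stage_seed(config.seed, f"null:{stat_name}:{model}"))
            ens = _stage("nulltest")(null_ensemble)(matrix, stat, model, config.nodf_null_reps, rng)
            summary["nestedness_nulls"][f"{stat_name}:{model}"] = {
                "observed": round(ens.observed, 3),
                "null_mean": round(ens.null_mean, 3),
                "null_sd": round(ens.null_sd, 3),
                "ses": round(ens.ses, 3),
                "p": round(ens.p_value, 4),
                "n_reps": ens.n_reps,
                "seed": stage_seed(config.seed, f"null:{stat_name}:{model}"),
            }

    # --- modularity ----------------------------------------------------------
    graph = bipartite_to_graph(matrix)
    rng = np.random.default_rng(stage_seed(config.seed, "modularity"))
    cons = _stage("modules")(consensus_partition)(
        graph, config.sa_runs, config.consensus_threshold, rng, config.sa_schedule
    )
    roles = node_roles(graph, cons.reference)
    sig = modularity_significance(
        matrix, cons, rng, config.mod_null_reps, config.mod_null_reps, config.sa_schedule
    )
    pd.DataFrame([
        {
            "node": u,
            "guild": graph.guild.get(u),
            "module": cons.reference.membership[u],
            "consensus_module": cons.assigned_modules[u],
            "z": roles[u].z,
            "c": roles[u].c,
            "role": roles[u].role,
        }
        for u in graph.nodes
    ]).to_csv(out / "modules.csv", index=False)
    summary["modularity"] = {
        "mean_m": round(cons.mean_m, 3),
        "sd_m": round(cons.sd_m, 3),
        "module_count_distribution": {str(k): v for k, v in cons.module_count_distribution.items()},
        "n_runs": config.sa_runs,
        "seed": stage_seed(config.seed, "modularity"),
        "significance": {
            model: {"null_mean": round(e.null_mean, 3), "ses": round(e.ses, 3),
                    "p": round(e.p_value, 4), "n_reps": e.n_reps}
            for model, e in sig.items()
        },
    }

    # --- syndromes -----------------------------------------------------------
    if maps.family_syndrome:
        summary["syndromes"] = _stage("biogeo")(bg.syndrome_summary)(maps, matrix)

    # --- biogeography + GLM --------------------------------------------------
    if config.biogeo_csv:
        table = bg.read_biogeo(config.biogeo_csv)
        summary["regions"] = _stage("biogeo")(bg.species_region_summary)(table)
        clades = _stage("biogeo")(bg.clade_summary)(table)
        pd.DataFrame([vars(c) for c in clades]).to_csv(out / "clade_summary.csv", index=False)

        model_table = [s for s in table if s.clade != "Patagona"]
        y = niche.make_response(model_table)
        centers = [s.diversification_center for s in model_table]
        summary["glm"] = {}
        for link in config.glm_links:
            full = _stage("glm")(niche.fit_binomial_glm)(
                y, {"center": centers}, link, references={"center": "South America"}
            )
            null = niche.fit_binomial_glm(y, None, link)
            chi, df, p = niche.lr_chi_test(full, null)
            ratio, flagged = niche.overdispersion_check(full)
            entry = {"lr_chi": round(chi, 3), "df": df, "p": p,
                     "dispersion": round(ratio, 3), "overdispersed": flagged}
            if link == "logit":
                entry["odds_ratio_north"] = round(
                    float(full.odds_ratios["center[North America]"]), 3
                )
            summary["glm"][link] = entry

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
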