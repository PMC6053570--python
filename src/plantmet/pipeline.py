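"""End-to-end orchestration of the metabolomics analysis.

Stages: normalize -> QC-RSD filter -> average triplicates -> spatial
predictors (distance matrix, PCNM) -> Bray-Curtis + NMDS ordination ->
variation partitioning (population-level blocks on per-plant means; leaf
area / herbivory on the within-plant paired differences) -> per-factor
conditional log-normal analyses with FDR and Tukey post hoc -> co-occurrence
network over region-significant features -> targeted screening.

A single master seed fans out to stage-specific seeds (stable hash of the
stage name), so every stage is independently reproducible and a rerun with
the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import cln as cln_mod
from . import feature_table as ft
from . import multivariate as mv
from . import network as net_mod
from . import spatial
from . import targeted as tg
from .synthetic import SimulationConfig, generate_study

__all__ = ["PipelineConfig", "RunReport", "derive_seed", "run_pipeline",
           "overlap_sets"]

DEFAULT_FACTORS = ["region", "distance", "habitat", "soil_ph", "light",
                   "phenology", "leaf_area", "leaf_status"]


def derive_seed(master_seed: int, stage: str) -> int:
    """Stage-specific seed: stable hash of the stage name and master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).hexdigest()
    return int(digest[:8], 16) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    """Paths, stage parameters and seeds for a full run."""

    # inputs: either paths to tables or a simulation config
    feature_table_path: str | None = None
    metadata_path: str | None = None
    targets_path: str | None = None
    simulation: SimulationConfig | None = None
    output_dir: str | None = None

    # stage parameters
    normalization_target: float = 10_000.0
    qc_rsd_threshold: float = 30.0
    factors: list = field(default_factory=lambda: list(DEFAULT_FACTORS))
    min_positive_per_level: int = 2
    min_total_positives: int = 5
    nmds_restarts: int = 10
    varpart_permutations: int = 999
    network_threshold: float = 0.372
    network_q_threshold: float = 0.20
    posthoc_q_threshold: float = 0.20
    run_cln: bool = True
    run_network: bool = True
    run_posthoc: bool = True
    seed: int = 0


@dataclass
class RunReport:
    """Machine-readable per-stage summaries of one pipeline run."""

    seed: int
    n_features_before: int = 0
    n_features_after: int = 0
    n_biological_injections: int = 0
    n_averaged_samples: int = 0
    n_paired_rows: int = 0
    nmds_stress: float = float("nan")
    varpart_population: dict = field(default_factory=dict)
    varpart_paired: dict = field(default_factory=dict)
    cln_summaries: dict = field(default_factory=dict)
    overlap: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    targeted: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (set, frozenset)):
                return sorted(o)
            raise TypeError(type(o))
        payload = {k: v for k, v in self.__dict__.items()}
        payload["overlap"] = {
            "union": self.overlap.get("union"),
            "cells": {"+".join(k): v
                      for k, v in sorted(self.overlap.get("cells", {}).items())},
        } if self.overlap else {}
        return json.dumps(payload, indent=2, sort_keys=True, default=default)


def overlap_sets(significant: dict) -> dict:
    """Venn cells over per-factor significant-feature lists.

    ``significant`` maps factor name -> iterable of feature ids.  Returns
    ``{"union": int, "cells": {(factors...): count}}`` where each cell counts
    features significant for exactly that combination of factors.
    """
    sets = {k: set(v) for k, v in significant.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 lists")
    union = set().union(*sets.values())
    cells: dict[tuple, int] = {}
    for feature in union:
        members = tuple(sorted(k for k, s in sets.items() if feature in s))
        cells[members] = cells.get(members, 0) + 1
    return {"union": len(union), "cells": cells}


def _population_blocks(meta_plants: pd.DataFrame) -> dict:
    return {
        "soil": meta_plants[["soil_ph", "soil_ec", "soil_cn"]],
        "region": meta_plants[["region"]],
        "phenology": meta_plants[["phenology"]],
    }


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    """Execute all configured stages; returns the report (and writes
    artifacts when ``cfg.output_dir`` is set)."""
    report = RunReport(seed=cfg.seed)
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        if out:
            path = out / name
            df.to_csv(path, sep="\t", float_format="%.6g", **kw)
            report.artifacts.append(str(path))

    # ---- input
    targets = None
    if cfg.simulation is not None:
        table, meta, truth = generate_study(cfg.simulation)
        if cfg.simulation.planted_targets:
            targets = [tg.TargetDefinition(f"standard_{i+1}", rt, mz)
                       for i, (rt, mz) in enumerate(cfg.simulation.planted_targets)]
    elif cfg.feature_table_path and cfg.metadata_path:
        table, meta = ft.read_feature_table(cfg.feature_table_path,
                                            cfg.metadata_path)
    else:
        raise ValueError("configure either input paths or a simulation")
    if cfg.targets_path:
        targets = tg.read_targets(cfg.targets_path)

    # ---- preprocessing: normalize -> QC filter -> average
    report.n_features_before = len(table.feature_ids)
    report.n_biological_injections = int((meta["role"] == ft.ROLE_BIOLOGICAL).sum())
    normalized = ft.normalize_total_intensity(table, cfg.normalization_target)
    qc_ids = meta.index[meta["role"] == ft.ROLE_QC]
    unfiltered = normalized
    filtered, removed = ft.qc_rsd_filter(normalized, qc_ids, cfg.qc_rsd_threshold)
    report.n_features_after = len(filtered.feature_ids)
    save(removed, "qc_removed_features.tsv", index=False)
    averaged, leaf_meta = ft.average_replicates(filtered, meta)
    report.n_averaged_samples = len(averaged.sample_ids)
    save(averaged.intensities, "averaged_intensities.tsv")
    paired = ft.paired_difference(averaged, leaf_meta)
    report.n_paired_rows = len(paired.plant_ids)

    # ---- spatial predictors
    pops = leaf_meta.groupby("population")[["latitude", "longitude"]].first()
    dist = spatial.euclidean_distance(pops)
    axes = spatial.pcnm(dist)
    pcnm_scores = axes.to_frame()
    save(dist.to_frame(), "population_distances.tsv")
    save(pcnm_scores, "pcnm_axes.tsv")

    # ---- ordination
    bc = mv.bray_curtis(averaged)
    ord_ = mv.nmds(bc, k=2, restarts=cfg.nmds_restarts,
                   seed=derive_seed(cfg.seed, "nmds"))
    report.nmds_stress = round(float(ord_.stress), 6)
    save(ord_.scores, "nmds_scores.tsv")

    # ---- variation partitioning
    plant_y = averaged.intensities.groupby(
        leaf_meta["plant_id"].astype(str).values).mean()
    plant_meta = leaf_meta.groupby(leaf_meta["plant_id"].astype(str).values).first()
    vp_pop = mv.varpart(plant_y.to_numpy(), _population_blocks(plant_meta),
                        n_perm=cfg.varpart_permutations,
                        seed=derive_seed(cfg.seed, "varpart_population"))
    report.varpart_population = _varpart_summary(vp_pop)
    vp_pair = mv.varpart(
        paired.diff_intensities.to_numpy(),
        {"leaf_area": paired.plant_meta[["diff_leaf_area_cm2"]],
         "damage": paired.plant_meta[["damage_pct"]]},
        n_perm=cfg.varpart_permutations,
        seed=derive_seed(cfg.seed, "varpart_paired"))
    report.varpart_paired = _varpart_summary(vp_pair)

    # ---- conditional log-normal analyses
    significant: dict[str, list] = {}
    if cfg.run_cln:
        design = cln_mod.prepare_design(leaf_meta, pcnm_scores)
        for factor in cfg.factors:
            spec = cln_mod.CLNSpec(
                factor=factor,
                min_positive_per_level=cfg.min_positive_per_level,
                min_total_positives=cfg.min_total_positives)
            res, fits = cln_mod.run_factor_analysis(averaged, design, spec)
            report.cln_summaries[factor] = cln_mod.significance_summary(res)
            significant[factor] = sorted(res.index[res["q"] < 0.20])
            save(res.drop(columns=[]), f"cln_{factor}.tsv")
            if cfg.run_posthoc and spec.kind == "categorical":
                ph_rows = []
                for fid in res.index[res["q"] < cfg.posthoc_q_threshold]:
                    ph = cln_mod.tukey_posthoc(fits[fid], spec)
                    ph.insert(0, "feature_id", fid)
                    ph_rows.append(ph)
                if ph_rows:
                    save(pd.concat(ph_rows, ignore_index=True),
                         f"posthoc_{factor}.tsv", index=False)
        if len(significant) >= 2:
            report.overlap = overlap_sets(significant)

    # ---- co-occurrence network
    if cfg.run_network and cfg.run_cln:
        nodes = significant.get("region", [])
        if len(nodes) >= 2:
            netw = net_mod.cooccurrence_network(
                averaged, leaf_meta, nodes, threshold=cfg.network_threshold)
            report.network = {
                "n_nodes": int(netw.graph.number_of_nodes()),
                "n_edges": int(netw.graph.number_of_edges()),
                "n_components": netw.n_components,
                "threshold": netw.threshold,
            }
            save(netw.nodes, "network_nodes.tsv")
            if out:
                netw.write_graphml(out / "network.graphml")
                report.artifacts.append(str(out / "network.graphml"))
        else:
            report.network = {"n_nodes": len(nodes), "n_edges": 0,
                              "n_components": len(nodes),
                              "threshold": cfg.network_threshold}

    # ---- targeted screening (on the unfiltered, normalized table)
    if targets:
        avg_unfilt, _ = ft.average_replicates(unfiltered, meta)
        screen = tg.screen_targets(avg_unfilt, leaf_meta, targets)
        report.targeted = screen.to_dict(orient="records")
        save(screen, "targeted_screen.tsv", index=False)

    if out:
        (out / "report.json").write_text(report.to_json())
        report.artifacts.append(str(out / "report.json"))
    return report


def _varpart_summary(vp: mv.VarpartResult) -> dict:
    return {
        "unique": {n: round(vp.unique(n), 6) for n in vp.block_names},
        "residual": round(vp.residual, 6),
        "tests": {n: {"F": round(t["F"], 4), "p": t["p"]}
                  for n, t in vp.tests.items()},
    }
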