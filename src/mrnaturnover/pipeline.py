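"""End-to-end orchestration: correction -> inversion -> prediction -> calls -> clusters.

The stages run in a fixed order on one replicate-averaged dataset:

1. average replicates per gene and time;
2. scale post-shift TR by the temperature factor (elongation speeds up
   with the upshift, so run-on polymerase densities under-report the
   post-shift synthesis rate);
3. invert the mass balance per interval for k_D and compute the
   steady-state k_D at time 0;
4. predict the theoretical RA trajectory with the time-0 k_D frozen;
5. classify each gene's stability from measured vs. theoretical RA and
   tally homodirectional vs. antagonistic TR/stability changes;
6. build ten-point profiles, cluster them, and summarize per-cluster
   mean relative k_D and RA curves;
7. optionally test clusters for gene-set enrichment.

Identical config and seed give identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, kinetics_core, profile_clustering, set_enrichment
from .io_formats import GeneSetCollection, KineticsTable
from .kinetics_core import GeneKinetics, StabilityCall

logger = logging.getLogger(__name__)

CELSIUS_OFFSET = 273.15

DEFAULT_CONFIG: dict = {
    "temperature.mode": "fixed_factor",  # fixed_factor | arrhenius | none
    "temperature.factor": 2.0,
    "temperature.Ea_kcal_mol": [13.0, 9.7],
    "temperature.T1_K": 25.0 + CELSIUS_OFFSET,
    "temperature.T2_K": 37.0 + CELSIUS_OFFSET,
    "stability.log2_threshold": 0.3,
    "solver.kd_max": 10.0,
    "clustering.enabled": True,
    "clustering.max_clusters": 16,
    "clustering.distance": "correlation",
    "enrichment.enabled": True,
    "enrichment.model": "binomial",  # binomial | montecarlo
    "enrichment.n_sims": 1000,
    "enrichment.p_cutoff": 1e-6,
}


@dataclass
class RunReport:
    """Machine-readable account of one pipeline run."""

    parameters: dict
    gene_counts: dict
    stability_tally: dict
    direction_tally: dict
    pearson_r_histogram: dict
    provenance: dict
    cluster_sizes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "gene_counts": self.gene_counts,
            "stability_tally": self.stability_tally,
            "direction_tally": self.direction_tally,
            "pearson_r_histogram": self.pearson_r_histogram,
            "cluster_sizes": self.cluster_sizes,
            "provenance": self.provenance,
        }


@dataclass
class PipelineResult:
    report: RunReport
    kinetics: KineticsTable  # averaged, TR-corrected
    decay_profiles: dict
    theoretical: dict
    calls: list[StabilityCall]
    tree: "profile_clustering.ClusterTree | None" = None
    cluster_kd: pd.DataFrame | None = None
    cluster_ra: pd.DataFrame | None = None
    enrichment: pd.DataFrame | None = None


def resolve_temperature_factor(cfg: dict) -> float:
    """TR correction factor from config: fixed, Arrhenius-derived, or 1."""
    mode = cfg["temperature.mode"]
    if mode == "none":
        return 1.0
    if mode == "fixed_factor":
        return float(cfg["temperature.factor"])
    if mode == "arrhenius":
        eas = cfg["temperature.Ea_kcal_mol"]
        if np.isscalar(eas):
            eas = [eas]
        factors = [
            kinetics_core.temperature_factor(ea, cfg["temperature.T1_K"], cfg["temperature.T2_K"])
            for ea in eas
        ]
        return float(np.mean(factors))
    raise ValueError(f"unknown temperature.mode {mode!r}")


def tr_direction(g: GeneKinetics, threshold: float) -> str:
    """Sign of the mean post-shift log2 TR change: up / down / flat."""
    if g.tr[0] <= 0 or np.any(g.tr[1:] <= 0):
        return "flat"
    mean_log = float(np.mean(np.log2(g.tr[1:] / g.tr[0])))
    if mean_log > threshold:
        return "up"
    if mean_log < -threshold:
        return "down"
    return "flat"


def homodirectional_tally(
    calls: list[StabilityCall],
    genes: dict[str, GeneKinetics],
    threshold: float = 0.3,
) -> dict:
    """Count genes whose TR change and stability change point the same way.

    Homodirectional: TR up & stabilized, or TR down & destabilized (the
    two effects cooperate on RA).  Antagonistic: the opposite pairings.
    Everything else (either axis flat/undefined) is neutral.
    """
    tally = {"homodirectional": 0, "antagonistic": 0, "neutral": 0}
    per_gene = {}
    for call in calls:
        if call.label == "undefined":
            tally["neutral"] += 1
            per_gene[call.gene_id] = "neutral"
            continue
        direction = tr_direction(genes[call.gene_id], threshold)
        if (direction == "up" and call.label == "stabilized") or (
            direction == "down" and call.label == "destabilized"
        ):
            cls = "homodirectional"
        elif (direction == "up" and call.label == "destabilized") or (
            direction == "down" and call.label == "stabilized"
        ):
            cls = "antagonistic"
        else:
            cls = "neutral"
        tally[cls] += 1
        per_gene[call.gene_id] = cls
    tally["per_gene"] = per_gene
    return tally


def run_pipeline(
    tables: list[KineticsTable],
    config: dict | None = None,
    gene_sets: GeneSetCollection | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis on replicate kinetics tables.

    ``gene_sets`` enables the enrichment stage; ``out_dir`` additionally
    writes all result tables and the JSON run summary to disk.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    threshold = float(cfg["stability.log2_threshold"])

    averaged = io_formats.average_replicates(tables)
    n_input = len(averaged.gene_ids)
    complete = averaged.complete_genes()
    excluded = sorted(set(averaged.gene_ids) - set(complete))
    if excluded:
        logger.info("excluded %d gene(s) with missing or non-positive RA", len(excluded))

    factor = resolve_temperature_factor(cfg)
    genes: dict[str, GeneKinetics] = {}
    for gid in complete:
        g = averaged.gene(gid)
        genes[gid] = kinetics_core.apply_tr_correction(g, factor) if factor != 1.0 else g

    decay_profiles, theoretical, calls = {}, {}, []
    invertible = []
    for gid, g in genes.items():
        if g.ra[0] <= 0 or g.tr[0] <= 0:
            continue
        invertible.append(gid)
        decay_profiles[gid] = kinetics_core.decay_profile(g, kd_max=cfg["solver.kd_max"])
        theoretical[gid] = kinetics_core.theoretical_ra(g, decay_profiles[gid].kd0)
        calls.append(kinetics_core.classify_stability(g, theoretical[gid], threshold))

    stab_tally = {label: 0 for label in ("stabilized", "destabilized", "unchanged", "undefined")}
    for c in calls:
        stab_tally[c.label] += 1
    n_classified = sum(stab_tally.values())
    stab_fractions = {
        k: (v / n_classified if n_classified else 0.0) for k, v in stab_tally.items()
    }

    dir_tally = homodirectional_tally(calls, genes, threshold)
    per_gene_direction = dir_tally.pop("per_gene")

    r_values = [c.pearson_r for c in calls if np.isfinite(c.pearson_r)]
    edges = np.linspace(-1.0, 1.0, 21)
    hist, _ = np.histogram(r_values, bins=edges)
    r_hist = {"bin_edges": edges.tolist(), "counts": hist.tolist()}

    tree = cluster_kd = cluster_ra = None
    if cfg["clustering.enabled"] and len(invertible) >= 2:
        pm = profile_clustering.build_profiles([genes[g] for g in invertible])
        params = profile_clustering.SotaParams(
            max_clusters=int(cfg["clustering.max_clusters"]),
            distance=cfg["clustering.distance"],
        )
        tree = profile_clustering.sota_cluster(pm, params)
        cluster_kd = profile_clustering.cluster_mean_kd(tree, decay_profiles)
        cluster_ra = profile_clustering.cluster_mean_ra(tree, genes, theoretical)

    enrich_df = None
    if cfg["enrichment.enabled"] and gene_sets is not None and tree is not None:
        assignments = tree.assignments()
        clusters = {
            str(cl): [g for g in members.index if g in set(gene_sets.universe)]
            for cl, members in assignments.groupby(assignments)
        }
        if cfg["enrichment.model"] == "montecarlo":
            results = set_enrichment.montecarlo_enrichment(
                clusters, gene_sets, n_sims=int(cfg["enrichment.n_sims"]), seed=seed
            )
        else:
            results = [
                set_enrichment.binomial_enrichment(
                    cg, gene_sets.sets[name], gene_sets.universe, cl, name,
                    p_cutoff=float(cfg["enrichment.p_cutoff"]),
                )
                for cl, cg in clusters.items()
                for name in gene_sets.sets
            ]
        enrich_df = set_enrichment.results_table(results)

    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = RunReport(
        parameters=dict(cfg, temperature_factor_used=factor),
        gene_counts={
            "input": n_input,
            "excluded": len(excluded),
            "inverted": len(invertible),
            "clustered": len(tree.gene_ids) if tree else 0,
        },
        stability_tally={"n": stab_tally, "fraction": stab_fractions},
        direction_tally=dir_tally,
        pearson_r_histogram=r_hist,
        provenance={"seed": seed, "config_hash": config_hash},
        cluster_sizes=(
            {cl: int(n) for cl, n in tree.assignments().value_counts().items()}
            if tree
            else {}
        ),
    )

    result = PipelineResult(
        report, averaged, decay_profiles, theoretical, calls,
        tree, cluster_kd, cluster_ra, enrich_df,
    )
    if out_dir is not None:
        _write_outputs(result, per_gene_direction, Path(out_dir))
    return result


def decay_profile_table(profiles: dict) -> pd.DataFrame:
    rows = [
        {
            "gene": gid,
            "interval_mid_time": iv.t_mid,
            "kd": iv.kd,
            "kd_relative": iv.kd_relative,
            "flag": iv.flag,
        }
        for gid, p in profiles.items()
        for iv in p.intervals
    ]
    return pd.DataFrame(rows, columns=["gene", "interval_mid_time", "kd", "kd_relative", "flag"])


def stability_table(calls: list[StabilityCall], per_gene_direction: dict | None = None) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene_id,
            "pearson_r": c.pearson_r,
            "mean_log2_ratio": c.mean_log_ratio,
            "label": c.label,
            "direction_class": (per_gene_direction or {}).get(c.gene_id, ""),
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["gene", "pearson_r", "mean_log2_ratio", "label", "direction_class"]
    )


def _write_outputs(result: PipelineResult, per_gene_direction: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    io_formats.write_results(
        decay_profile_table(result.decay_profiles), out_dir / "decay_profiles.tsv"
    )
    io_formats.write_results(
        stability_table(result.calls, per_gene_direction), out_dir / "stability_calls.tsv"
    )
    if result.tree is not None:
        assign = result.tree.assignments().rename_axis("gene").reset_index()
        io_formats.write_results(assign, out_dir / "cluster_assignments.tsv")
        (out_dir / "cluster_tree.nwk").write_text(result.tree.newick() + "\n")
        io_formats.write_results(result.cluster_kd, out_dir / "cluster_mean_kd.tsv")
        io_formats.write_results(result.cluster_ra, out_dir / "cluster_mean_ra.tsv")
    if result.enrichment is not None:
        io_formats.write_results(result.enrichment, out_dir / "enrichment.tsv")
    io_formats.write_run_summary(result.report.to_dict(), out_dir / "run_summary.json")
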