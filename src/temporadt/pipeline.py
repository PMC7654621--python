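"""End-to-end orchestration: simulate/read -> DTI -> DEGs -> dynamics ->
enrichment typing -> tradeoff -> network -> candidates, with a run manifest.

A single :class:`RunConfig` is the source of truth for every threshold; the
resolved configuration, row counts, and wall-clock are echoed into
``manifest.json`` so identical config + seed reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .data_model import (
    DROUGHT_TIMEPOINTS,
    ConfigError,
    ExperimentSet,
    read_experiment,
    write_results,
)
from . import degs as degs_mod
from . import dynamics as dyn
from . import enrichment as enr
from . import network as net
from . import simulate as sim
from . import tolerance as tol
from . import tradeoff as tro

__all__ = ["RunConfig", "run_all", "PipelineResult"]


@dataclass
class RunConfig:
    """All pipeline thresholds and stage toggles."""

    seed: int = 0
    input_dir: str | None = None        # None -> simulate
    out_dir: str = "temporadt_out"

    fdr_level: float = 0.05
    p_level: float = 0.05
    fc_threshold: float = 1.0
    pseudocount: float = 0.01
    min_freq: int = 2
    pcc_band: float = 0.4
    alpha: float = 0.05
    n_drought_clusters: int = 16
    soft_power: float = 6.0
    tau: float | None = None            # None -> density scan
    min_module_size: int = 30
    hub_fraction: float = 0.15
    enrichment_correction: str = "fdr_bh"
    dti_basis: str = "biomass"

    stages: dict = field(
        default_factory=lambda: dict(
            degs=True, dynamics=True, enrichment=True, tradeoff=True, network=True
        )
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    experiment: ExperimentSet
    profiles: pd.DataFrame
    groups: pd.Series
    calls: pd.DataFrame
    group_sets: pd.DataFrame | None = None
    ts_different: pd.DataFrame | None = None
    clusters: dict | None = None
    recovery_modes: pd.DataFrame | None = None
    term_timelines: pd.DataFrame | None = None
    classification_counts: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None
    regions: pd.Series | None = None
    modules: pd.Series | None = None
    eigengenes: pd.DataFrame | None = None
    module_traits: pd.DataFrame | None = None
    hubs: pd.DataFrame | None = None
    crosstalk: dict | None = None
    manifest: dict | None = None
    truth: sim.GroundTruth | None = None


def _stage_guard(config: RunConfig, stage: str, needed: str) -> None:
    if not config.stages.get(needed, True):
        raise ConfigError(
            f"stage '{stage}' requires stage '{needed}' which is toggled off"
        )


def run_all(config: RunConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Run every enabled stage in dependency order; write tables when
    ``out_dir`` (or ``config.out_dir``) is given a truthy path and return
    the in-memory result bundle."""
    t0 = time.time()
    truth = None
    if config.input_dir:
        es = read_experiment(config.input_dir)
    else:
        es, truth = sim.generate(seed=config.seed)

    # tolerance profiles and grouping
    profiles = tol.tolerance_profiles(es.traits, basis=config.dti_basis)
    dtiy = tol.tolerance_profiles(es.traits, basis="yield").set_index("genotype")["dti"]
    groups = tol.assign_groups(profiles, dti_yield=dtiy)
    group_comparisons = (
        tol.compare_trait_groups(es.trait_measurements, groups, alpha=config.alpha)
        if es.trait_measurements is not None
        else pd.DataFrame()
    )

    result = PipelineResult(
        experiment=es, profiles=profiles, groups=groups, calls=pd.DataFrame(), truth=truth
    )
    tables: dict[str, pd.DataFrame] = {
        "tolerance_profiles.tsv": profiles.assign(group=groups.reindex(profiles["genotype"]).to_numpy()),
        "group_comparisons.tsv": group_comparisons,
    }

    if config.stages.get("degs", True):
        raw = degs_mod.call_all_degs(
            es,
            fdr_level=config.fdr_level,
            p_level=config.p_level,
            fc_threshold=config.fc_threshold,
            pseudocount=config.pseudocount,
        )
        calls = degs_mod.final_deg_calls(raw, min_freq=config.min_freq)
        result.calls = calls
        summary, shared, presence, _ = degs_mod.summarize_genotypes(calls)
        tables["calls.tsv"] = calls[calls["is_deg"]]
        tables["genotype_summary.tsv"] = summary
        tables["shared_drg_ratio.tsv"] = shared.rename_axis("genotype").reset_index()
        tables["presence_absence.tsv"] = presence.rename_axis("gene").reset_index()

    if config.stages.get("dynamics", True):
        _stage_guard(config, "dynamics", "degs")
        result.group_sets = dyn.pool_group_sets(result.calls, groups)
        result.ts_different = dyn.ts_different_table(result.calls, groups)
        mats = dyn.group_mean_log2fc(result.calls, groups)
        clusters = {}
        similarity_rows = []
        for group, mat in mats.items():
            drg_genes = sorted(
                set(result.calls.loc[result.calls["is_drg"] &
                    (result.calls["genotype"].map(groups) == group), "gene"])
            )
            prof = mat.reindex(drg_genes)
            clusters[group] = dyn.cluster_temporal(prof, k=config.n_drought_clusters)
        common_genes = sorted(
            set(mats["tolerant"].dropna().index) & set(mats["susceptible"].dropna().index)
        )
        for gene in common_genes:
            pcc, cls = dyn.cross_group_similarity(
                mats["tolerant"].loc[gene], mats["susceptible"].loc[gene],
                band=config.pcc_band,
            )
            similarity_rows.append(dict(gene=gene, pcc=pcc, similarity=cls))
        result.clusters = clusters
        result.recovery_modes = dyn.recovery_mode_table(
            result.calls, groups, threshold=config.fc_threshold
        )
        tables["group_sets.tsv"] = result.group_sets
        tables["ts_different.tsv"] = result.ts_different
        tables["cross_group_similarity.tsv"] = pd.DataFrame(similarity_rows)
        tables["recovery_modes.tsv"] = result.recovery_modes
        tables["drought_clusters.tsv"] = pd.concat(
            [c.rename("cluster").to_frame().assign(group=g).rename_axis("gene").reset_index()
             for g, c in clusters.items()],
            ignore_index=True,
        ) if clusters else pd.DataFrame()

    if config.stages.get("enrichment", True):
        _stage_guard(config, "enrichment", "dynamics")
        population = set(es.genes[es.expressed])
        enrichments = {}
        calls = result.calls.copy()
        calls["group"] = calls["genotype"].map(groups)
        for group in dyn.GROUPS:
            for tp in DROUGHT_TIMEPOINTS + ("R",):
                study = set(
                    calls.loc[
                        calls["is_deg"] & (calls["group"] == group)
                        & (calls["timepoint"] == tp), "gene",
                    ]
                ) & population
                enrichments[(group, tp)] = enr.enrich(
                    study, population, es.gene_to_goterms,
                    correction=config.enrichment_correction,
                )
        result.term_timelines = enr.build_term_timelines(
            enrichments, criterion="fdr", level=config.fdr_level
        )
        enriched_cells = {
            f"{g}:{tp}": set(res.loc[res["fdr"] < config.fdr_level, "term"])
            for (g, tp), res in enrichments.items()
        }
        result.classification_counts = enr.count_classifications(
            enriched_cells, es.goterm_to_classification
        )
        tables["term_timelines.tsv"] = result.term_timelines
        tables["classification_counts.tsv"] = (
            result.classification_counts.reset_index()
        )

    if config.stages.get("tradeoff", True):
        _stage_guard(config, "tradeoff", "degs")
        drg_genes = sorted(set(result.calls.loc[result.calls["is_drg"], "gene"]))
        result.correlations = tro.correlate_gene_traits(
            result.calls[result.calls["timepoint"].isin(DROUGHT_TIMEPOINTS)],
            es, profiles, genes=drg_genes, alpha=config.alpha,
        )
        result.regions = tro.classify_regions(result.correlations)
        tables["gene_trait_correlations.tsv"] = result.correlations.reset_index()
        tables["tradeoff_regions.tsv"] = result.regions.rename("region").rename_axis("gene").reset_index()

    if config.stages.get("network", True):
        _stage_guard(config, "network", "tradeoff")
        _stage_guard(config, "network", "enrichment")
        drg_genes = sorted(set(result.calls.loc[result.calls["is_drg"], "gene"]))
        d_samples = [
            s for s in es.expression.columns if es.samples.loc[s, "condition"] == "D"
        ]
        if len(drg_genes) >= 3:
            import numpy as np

            log_expr = np.log2(es.expression.loc[drg_genes, d_samples] + config.pseudocount)
            adjacency, tom = net.build_network(log_expr, beta=config.soft_power)
            tau, scan = net.select_cutoff(tom, fixed=config.tau)
            modules = net.detect_modules(tom, tau, min_size=config.min_module_size)
            eig = net.module_eigengenes(log_expr, modules)
            trait_frame = _sample_traits(es, d_samples)
            module_traits = (
                net.module_trait_association(eig, trait_frame) if len(eig.columns) else pd.DataFrame()
            )
            k_intra = net.intramodular_connectivity(adjacency, modules)
            hubs = net.hub_and_candidates(
                modules, k_intra,
                result.correlations if result.correlations is not None else pd.DataFrame(),
                result.regions if result.regions is not None else pd.Series(dtype=object),
                result.term_timelines if result.term_timelines is not None else pd.DataFrame(columns=["term", "type"]),
                es.gene_to_goterms, hub_fraction=config.hub_fraction,
            )
            mats = dyn.group_mean_log2fc(result.calls, groups, timepoints=DROUGHT_TIMEPOINTS + ("R",))
            crosstalk = {
                g: net.hormone_crosstalk(mats[g].dropna(how="all"), es.gene_to_hormone,
                                         drg_genes=set(drg_genes))
                for g in dyn.GROUPS
            }
            result.modules = modules
            result.eigengenes = eig
            result.module_traits = module_traits
            result.hubs = hubs
            result.crosstalk = crosstalk
            tables["modules.tsv"] = modules.rename_axis("gene").reset_index()
            tables["tau_scan.tsv"] = scan
            tables["eigengenes.tsv"] = eig.rename_axis("sample_id").reset_index()
            tables["module_traits.tsv"] = module_traits
            tables["hubs.tsv"] = hubs
            for g, mat in crosstalk.items():
                tables[f"crosstalk_{g}.tsv"] = mat.rename_axis("hormone").reset_index()

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "wall_clock_s": round(time.time() - t0, 3),
        "n_genes": int(es.expression.shape[0]),
        "n_samples": int(es.expression.shape[1]),
    }
    target = out_dir if out_dir is not None else config.out_dir
    if target:
        written = write_results(tables, target, overwrite=True)
        manifest["files"] = written["files"]
        with open(Path(target) / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    result.manifest = manifest
    return result


def _sample_traits(es: ExperimentSet, sample_ids: list[str]) -> pd.DataFrame:
    """Per-sample physiology values matched on genotype/timepoint/replicate."""
    import numpy as np

    out = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    if es.trait_measurements is None:
        return out
    meta = es.samples.loc[sample_ids]
    for trait in ("osmotic_potential", "h2o2"):
        tm = es.trait_measurements
        tm = tm[tm["trait"] == trait]
        lookup = {
            (g, c, t, r): v
            for g, c, t, r, v in zip(
                tm["genotype"], tm["condition"], tm["timepoint"], tm["replicate"], tm["value"]
            )
        }
        out[trait] = [
            lookup.get((row["genotype"], row["condition"], row["timepoint"], row["replicate"]), np.nan)
            for _, row in meta.iterrows()
        ]
    return out
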