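"""End-to-end orchestration of the bilayer analysis.

Stage order: differential site screening → methylation correlation layer
(the "single network") → RNA layer → inter-layer edge filter (the bilayer
network) → layer metrics → hub ranking at each k for both centralities on
both networks → survival counts and chi-squared comparison → hub
comethylation → two-step DEG reachability → optional enrichment.  Every
stage writes its table under the run directory and the run manifest records
seeds, thresholds, a config hash and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import io as bio
from . import metrics as met
from .datatypes import BetaMatrix, ClinicalTable, ExpressionMatrix, GeneSetCollection, SiteGeneMap
from .differential import call_degs, call_differential_sites
from .enrichment import enrichment_frame, hypergeometric_enrichment
from .hubs import (
    chi_squared_2x2,
    deg_two_step_reachability,
    hub_correlation_matrix,
    survival_p_values,
    top_k,
)
from .network import build_methylation_layer, build_rna_layer, filter_methylation_edges
from .simulate import SimulationConfig, simulate_dataset, simulate_gene_sets, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

DEFAULT_K_LIST = (100, 200, 300, 400, 500)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All thresholds and inputs of a run.

    Either the five input paths are given, or ``simulate`` holds a
    SimulationConfig and the inputs are generated in the run directory.
    """

    beta_path: str | None = None
    labels_path: str | None = None
    site_gene_map_path: str | None = None
    interactions_path: str | None = None
    expression_path: str | None = None
    expression_labels_path: str | None = None
    clinical_path: str | None = None
    gene_sets_path: str | None = None
    simulate: SimulationConfig | None = None

    site_fdr: float = 0.01
    corr_cutoff: float = 0.8
    rna_confidence: float = 0.75
    deg_fdr: float = 0.05
    lfc_cutoff: float = 1.0
    survival_alpha: float = 0.05
    enrich_p: float = 0.05
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    seed: int = 0

    def __post_init__(self) -> None:
        for name, lo, hi in (
            ("site_fdr", 0, 1), ("corr_cutoff", 0, 1), ("rna_confidence", 0, 1),
            ("deg_fdr", 0, 1), ("survival_alpha", 0, 1), ("enrich_p", 0, 1),
        ):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.lfc_cutoff < 0:
            raise ValueError("lfc_cutoff must be non-negative")
        ks = tuple(int(k) for k in self.k_list)
        if any(k <= 0 for k in ks) or list(ks) != sorted(set(ks)):
            raise ValueError("k_list must be positive and strictly increasing")
        self.k_list = ks
        if self.simulate is None and self.beta_path is None:
            raise ValueError("either input paths or a simulate block is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(simulate=SimulationConfig(**sim) if sim is not None else None, **raw)
        return cfg

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _load_inputs(config: PipelineConfig, outdir: Path):
    if config.simulate is not None:
        dataset = simulate_dataset(config.simulate)
        write_dataset(dataset, outdir / "inputs")
        gene_sets = simulate_gene_sets(config.simulate)
        return (
            dataset.beta, dataset.site_gene_map, dataset.interactions,
            dataset.expression, dataset.clinical, gene_sets, dataset.manifest,
        )
    beta = bio.read_beta_matrix(config.beta_path, config.labels_path)
    sgmap = bio.read_site_gene_map(config.site_gene_map_path)
    interactions = bio.read_interactions(config.interactions_path, config.rna_confidence)
    expression = bio.read_expression(
        config.expression_path, config.expression_labels_path or config.labels_path
    )
    clinical = bio.read_clinical(config.clinical_path)
    gene_sets = bio.read_gene_sets(config.gene_sets_path) if config.gene_sets_path else None
    return beta, sgmap, interactions, expression, clinical, gene_sets, None


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage, writing outputs under ``outdir``; returns the results.

    The returned dict holds the in-memory objects tests and the acceptance
    script need: differential calls, both layers, centralities, hub lists,
    survival counts, comparison statistics, correlation summaries, DEG
    reachability and (when gene sets exist) enrichment results.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load_inputs"
    results: dict = {}
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "thresholds": {
            "site_fdr": config.site_fdr, "corr_cutoff": config.corr_cutoff,
            "rna_confidence": config.rna_confidence, "deg_fdr": config.deg_fdr,
            "lfc_cutoff": config.lfc_cutoff, "survival_alpha": config.survival_alpha,
            "enrich_p": config.enrich_p,
        },
        "stages": {},
    }
    try:
        beta, sgmap, interactions, expression, clinical, gene_sets, truth = _load_inputs(
            config, outdir
        )
        manifest["stages"][stage] = {
            "n_sites": len(beta.site_ids), "n_samples": len(beta.sample_ids),
            "n_interactions": len(interactions), "n_genes": len(expression.gene_ids),
            "n_patients": len(clinical),
        }
        results["truth"] = truth

        stage = "differential_sites"
        diff_sites, site_results = call_differential_sites(beta, config.site_fdr)
        pd.DataFrame([vars(r) for r in site_results]).to_csv(
            outdir / "differential_sites.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {"n_tested": len(site_results), "n_significant": len(diff_sites)}
        results["diff_sites"] = diff_sites

        stage = "differential_genes"
        degs, deg_results = call_degs(
            expression, config.deg_fdr, config.lfc_cutoff
        )
        pd.DataFrame([vars(r) for r in deg_results]).to_csv(
            outdir / "differential_genes.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {"n_tested": len(deg_results), "n_significant": len(degs)}
        results["degs"] = degs

        stage = "methylation_layer"
        single = build_methylation_layer(beta, diff_sites, config.corr_cutoff)
        manifest["stages"][stage] = {
            "n_nodes": single.number_of_nodes(), "n_edges": single.number_of_edges()
        }
        results["single"] = single

        stage = "rna_layer"
        rna = build_rna_layer(interactions)
        manifest["stages"][stage] = {
            "n_nodes": rna.number_of_nodes(), "n_edges": rna.number_of_edges()
        }
        results["rna"] = rna

        stage = "edge_filter"
        bilayer = filter_methylation_edges(single, sgmap, rna)
        edge_rows = [
            {"site_a": a, "site_b": b, "r": d.get("r"), "condition": d.get("condition")}
            for a, b, d in bilayer.methylation.edges(data=True)
        ]
        pd.DataFrame(edge_rows, columns=["site_a", "site_b", "r", "condition"]).to_csv(
            outdir / "bilayer_edges.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = bilayer.summary()
        results["bilayer"] = bilayer

        stage = "metrics"
        summaries = {}
        for name, graph in (("bilayer", bilayer.methylation), ("single", single), ("rna", rna)):
            summaries[name] = met.network_summary(graph).to_dict()
            summaries[name]["degree_distribution_right_skewed"] = met.degree_distribution(
                graph
            )["right_skewed"]
        with open(outdir / "network_summaries.json", "w") as fh:
            json.dump(summaries, fh, indent=1)
        manifest["stages"][stage] = {k: v["n_edges"] for k, v in summaries.items()}
        results["summaries"] = summaries

        stage = "centralities"
        centralities = {}
        for name, graph in (("bilayer", bilayer.methylation), ("single", single)):
            table = met.centrality_table(graph)
            table.to_csv(outdir / f"centrality_{name}.tsv", sep="\t")
            centralities[name] = table
        manifest["stages"][stage] = {k: len(v) for k, v in centralities.items()}
        results["centralities"] = centralities

        stage = "hubs_and_survival"
        pcache: dict[str, float] = {}

        def pvals_for(sites: list[str]) -> pd.Series:
            todo = [s for s in sites if s not in pcache]
            if todo:
                pcache.update(survival_p_values(todo, beta, clinical).to_dict())
            return pd.Series({s: pcache[s] for s in sites})

        hub_lists: dict[tuple[str, str, int], list[str]] = {}
        counts: dict[tuple[str, str, int], int] = {}
        for net in ("bilayer", "single"):
            for measure in ("degree_centrality", "betweenness_centrality"):
                series = centralities[net][measure]
                for k in config.k_list:
                    hubs = top_k(series, min(k, len(series)))
                    hub_lists[(net, measure, k)] = hubs
                    counts[(net, measure, k)] = int(
                        (pvals_for(hubs) < config.survival_alpha).sum()
                    )
        results["hub_lists"] = hub_lists
        results["survival_hub_counts"] = counts
        results["survival_p"] = dict(pcache)
        manifest["stages"][stage] = {
            f"{net}.{measure}.k{k}": c for (net, measure, k), c in counts.items()
        }

        stage = "network_comparison"
        comparisons = {}
        for measure in ("degree_centrality", "betweenness_centrality"):
            for k in config.k_list:
                a = counts[("bilayer", measure, k)]
                c = counts[("single", measure, k)]
                kk = len(hub_lists[("bilayer", measure, k)])
                table = [[a, kk - a], [c, kk - c]]
                try:
                    statistic, p = chi_squared_2x2(table)
                except ValueError:
                    statistic, p = 0.0, 1.0
                comparisons[f"{measure}.k{k}"] = {
                    "bilayer": a, "single": c, "k": kk, "chi2": statistic, "p": p
                }
        with open(outdir / "network_comparison.json", "w") as fh:
            json.dump(comparisons, fh, indent=1)
        results["comparisons"] = comparisons
        manifest["stages"][stage] = {key: v["chi2"] for key, v in comparisons.items()}

        stage = "hub_correlation"
        k0 = config.k_list[0]
        correlation = {}
        for measure in ("degree_centrality", "betweenness_centrality"):
            hubs = hub_lists[("bilayer", measure, k0)]
            if len(hubs) >= 2:
                _, summary = hub_correlation_matrix(hubs, beta, sgmap)
            else:
                summary = {"mean_abs_r": None, "same_gene_mean_abs_r": None}
            correlation[measure] = summary
        results["hub_correlation"] = correlation
        manifest["stages"][stage] = correlation

        stage = "deg_reachability"
        reach = {}
        for net in ("bilayer", "single"):
            for measure in ("degree_centrality", "betweenness_centrality"):
                hubs = hub_lists[(net, measure, k0)]
                flags, count = deg_two_step_reachability(hubs, sgmap, rna, degs)
                reach[f"{net}.{measure}"] = {"count": count, "k": len(hubs)}
        with open(outdir / "deg_reachability.json", "w") as fh:
            json.dump(reach, fh, indent=1)
        results["deg_reachability"] = reach
        manifest["stages"][stage] = {k: v["count"] for k, v in reach.items()}

        stage = "enrichment"
        if gene_sets is not None and len(gene_sets):
            bilayer_hubs = hub_lists[("bilayer", "betweenness_centrality", k0)]
            single_hubs = hub_lists[("single", "betweenness_centrality", k0)]
            bilayer_genes = {g for s in bilayer_hubs for g in sgmap.genes_of(s)}
            single_genes = {g for s in single_hubs for g in sgmap.genes_of(s)}
            query = sorted((bilayer_genes - single_genes) or bilayer_genes)
            enr = hypergeometric_enrichment(query, gene_sets, config.enrich_p)
            enrichment_frame(enr).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            results["enrichment"] = enr
            manifest["stages"][stage] = {
                "n_query": len(query),
                "n_significant": sum(r.significant for r in enr),
            }
        else:
            manifest["stages"][stage] = {"skipped": True}

    except Exception as exc:  # noqa: BLE001 - abort with stage context
        manifest["failed_stage"] = stage
        with open(outdir / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
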