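"""Synthetic dataset generator with the structure the pipeline assumes.

The generator emulates, at desk scale, the joint structure of a tumor
methylation/expression/survival study coupled to an RNA interactome:

* block-comethylated β values (latent-Gaussian factors pushed through the
  inverse logit) with an additive tumor shift at planted differential sites;
* an RNA layer in which noncoding RNAs act as high-degree bridges between
  mRNAs and direct mRNA-mRNA edges are rare;
* expression with planted log2 fold-changes on a recorded DEG list;
* exponential survival whose log-hazard follows the methylation of a
  designated hub module.

Comethylation modules are wired to genes so that every inter-layer
admissibility condition — same gene, direct RNA edge, shared RNA neighbor —
is exercised, together with planted violations: strongly correlated modules
whose sites sit on genes absent from the RNA layer, which a correlation-only
network cannot distinguish from the real thing.  The module plan, planted
truths and seeds are returned in a manifest so recovery tests can grade the
pipeline against ground truth.

Everything is deterministic given ``SimulationConfig.seed``; each generator
draws from its own named substream so enlarging one part of the dataset does
not perturb the others.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (
    TUMOR,
    BetaMatrix,
    ClinicalTable,
    ExpressionMatrix,
    RnaInteractionTable,
    SiteGeneMap,
)
__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "build_module_plan",
    "simulate_methylation",
    "simulate_rna_layer",
    "simulate_expression",
    "simulate_clinical",
    "simulate_dataset",
]

# substream tags: keep each generator on its own independent stream
_STREAMS = {"methylation": 1, "rna": 2, "expression": 3, "clinical": 4, "assignment": 5}


class ConfigError(ValueError):
    """Raised when a SimulationConfig is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study; defaults define the bundled dataset.

    The default geometry: 2,000 probes of which 348 sit in comethylation
    modules — 24 ordinary admissible modules of 6 sites, 9 hub modules of 11
    sites (dense, RNA-consistent; these are the planted hubs), and 7
    inadmissible modules of 15 sites (equally dense but wired to genes the
    RNA layer does not contain, so every one of their edges should be
    filtered out).  A quarter of all sites carry a tumor shift on the latent
    logit scale; survival hazard follows the mean hub-module methylation.
    """

    n_sites: int = 2000
    n_genes: int = 300
    n_tumor: int = 200
    n_normal: int = 50

    # ordinary admissible modules (kinds cycle same_gene / rna_edge / bridge)
    n_modules: int = 24
    module_size: int = 6
    rho: float = 0.9

    # planted hub modules (larger & denser, RNA-consistent wiring)
    n_hub_modules: int = 9
    hub_module_size: int = 11
    hub_rho: float = 0.97
    # hub modules share a common latent process (the hazard-relevant tumor
    # program): correlation between two hub-module factors
    hub_shared_rho: float = 0.5

    # planted violations: one gene per site, genes absent from the RNA layer
    n_inadmissible_modules: int = 7
    inadmissible_module_size: int = 15
    inadmissible_rho: float = 0.97

    # RNA layer
    n_ncRNA: int = 60
    n_community_ncRNA: int = 10
    ncRNA_degree_exponent: float = 2.5
    ncRNA_max_degree: int = 30
    mrna_edge_rate: int = 0  # extra random direct mRNA-mRNA edges

    # planted effects
    frac_diff_sites: float = 0.25
    frac_deg: float = 0.1
    effect_beta: float = 1.5  # latent logit shift in tumor at differential sites
    effect_lfc: float = 2.0  # planted log2 fold change
    hazard_gamma: float = 2.5  # log-hazard per sd of mean hub-module methylation
    censor_rate: float = 0.3
    baseline_survival_scale: float = 50.0

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_sites", "n_genes", "n_tumor", "n_normal"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("rho", "hub_rho", "inadmissible_rho"):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigError(f"{name} must be in [0, 1)")
        for name in ("frac_diff_sites", "frac_deg", "censor_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.module_sites_total > self.n_sites:
            raise ConfigError("module sites exceed n_sites; shrink modules or add sites")
        if self.n_community_ncRNA > self.n_ncRNA:
            raise ConfigError("n_community_ncRNA cannot exceed n_ncRNA")

    @property
    def module_sites_total(self) -> int:
        return (
            self.n_modules * self.module_size
            + self.n_hub_modules * self.hub_module_size
            + self.n_inadmissible_modules * self.inadmissible_module_size
        )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % (2**31), _STREAMS[stream]])


@dataclass
class Module:
    name: str
    kind: str  # same_gene | rna_edge | bridge | inadmissible
    sites: list[str]
    genes: list[str]  # genes used by this module (1, 2 or per-site)
    site_genes: dict[str, str]  # site -> gene
    rho: float
    is_hub: bool
    community: int | None  # index of the community ncRNA, None for inadmissible


@dataclass
class ModulePlan:
    modules: list[Module]
    site_ids: list[str]
    gene_ids: list[str]
    community_ncRNAs: list[str]
    bulk_ncRNAs: list[str]
    community_deg_genes: list[str]  # one DEG seed gene per community ncRNA
    background_genes: list[str]  # mRNAs not used by any module
    diff_sites: list[str]  # planted differential sites (modules first)
    hazard_sites: list[str]  # sites whose methylation drives survival

    @property
    def hub_sites(self) -> list[str]:
        return [s for m in self.modules if m.is_hub for s in m.sites]

    @property
    def inadmissible_sites(self) -> list[str]:
        return [s for m in self.modules if m.kind == "inadmissible" for s in m.sites]


def build_module_plan(config: SimulationConfig) -> ModulePlan:
    """Deterministically lay out modules, gene wiring and planted truths."""
    site_ids = [f"cg{i:08d}" for i in range(config.n_sites)]
    gene_ids = [f"GENE{i:04d}" for i in range(config.n_genes)]
    n_comm = config.n_community_ncRNA
    community_ncRNAs = [f"LNC{i:04d}" for i in range(n_comm)]
    bulk_ncRNAs = [
        (f"LNC{n_comm + i:04d}" if i % 2 == 0 else f"MIR{i:04d}")
        for i in range(config.n_ncRNA - n_comm)
    ]

    gene_cursor = 0

    def take_genes(k: int) -> list[str]:
        nonlocal gene_cursor
        if gene_cursor + k > config.n_genes:
            raise ConfigError("module wiring needs more genes than n_genes provides")
        out = gene_ids[gene_cursor : gene_cursor + k]
        gene_cursor += k
        return out

    site_cursor = 0

    def take_sites(k: int) -> list[str]:
        nonlocal site_cursor
        out = site_ids[site_cursor : site_cursor + k]
        site_cursor += k
        return out

    modules: list[Module] = []
    ordinary_kinds = ["same_gene", "rna_edge", "bridge"]
    for m in range(config.n_modules):
        kind = ordinary_kinds[m % 3]
        sites = take_sites(config.module_size)
        community = m % n_comm if n_comm else None
        if kind == "same_gene":
            genes = take_genes(1)
            site_genes = {s: genes[0] for s in sites}
        else:
            genes = take_genes(2)
            half = len(sites) // 2
            site_genes = {s: genes[0] for s in sites[:half]}
            site_genes.update({s: genes[1] for s in sites[half:]})
        modules.append(
            Module(f"mod{m:03d}", kind, sites, genes, site_genes, config.rho, False, community)
        )

    hub_kinds = ["same_gene", "bridge"]
    for m in range(config.n_hub_modules):
        kind = hub_kinds[m % 2]
        sites = take_sites(config.hub_module_size)
        community = m % n_comm if n_comm else None
        if kind == "same_gene":
            genes = take_genes(1)
            site_genes = {s: genes[0] for s in sites}
        else:
            genes = take_genes(2)
            half = len(sites) // 2
            site_genes = {s: genes[0] for s in sites[:half]}
            site_genes.update({s: genes[1] for s in sites[half:]})
        modules.append(
            Module(f"hub{m:03d}", kind, sites, genes, site_genes, config.hub_rho, True, community)
        )

    for m in range(config.n_inadmissible_modules):
        sites = take_sites(config.inadmissible_module_size)
        genes = take_genes(len(sites))  # one private gene per site, off the RNA layer
        site_genes = dict(zip(sites, genes))
        modules.append(
            Module(f"bad{m:03d}", "inadmissible", sites, genes, site_genes,
                   config.inadmissible_rho, False, None)
        )

    community_deg_genes = take_genes(n_comm)
    background_genes = gene_ids[gene_cursor:]
    if not background_genes:
        raise ConfigError("no background genes left; increase n_genes")

    module_sites = [s for mod in modules for s in mod.sites]
    n_diff = int(round(config.frac_diff_sites * config.n_sites))
    if n_diff < len(module_sites):
        diff_sites = module_sites[:n_diff]
    else:
        extra = [s for s in site_ids if s not in set(module_sites)][: n_diff - len(module_sites)]
        diff_sites = module_sites + extra

    # survival hazard follows the planted hub methylation as a whole: the
    # standardized mean β over every hub-module site drives the log-hazard,
    # so each planted hub is individually survival-associated
    hazard_sites = [s for mod in modules if mod.is_hub for s in mod.sites]

    return ModulePlan(
        modules=modules,
        site_ids=site_ids,
        gene_ids=gene_ids,
        community_ncRNAs=community_ncRNAs,
        bulk_ncRNAs=bulk_ncRNAs,
        community_deg_genes=community_deg_genes,
        background_genes=background_genes,
        diff_sites=diff_sites,
        hazard_sites=hazard_sites,
    )


def planted_deg_genes(config: SimulationConfig) -> list[str]:
    """The planted DEG list: one seed gene per community ncRNA, then random
    background mRNAs up to round(frac_deg * n_genes)."""
    plan = build_module_plan(config)
    n_deg = int(round(config.frac_deg * config.n_genes))
    degs = list(plan.community_deg_genes)[:n_deg]
    if len(degs) < n_deg:
        rng = config.rng("assignment")
        pool = [g for g in plan.background_genes if g not in set(degs)]
        extra = rng.choice(pool, size=min(n_deg - len(degs), len(pool)), replace=False)
        degs += [str(g) for g in extra]
    return degs


def simulate_methylation(config: SimulationConfig) -> tuple[BetaMatrix, SiteGeneMap]:
    """Draw the β matrix and the probe→gene annotation.

    Latent per-site values are ``mu_i + shift + factor``, where sites in a
    module share a latent factor with pairwise correlation rho and sites get
    a tumor-only latent shift of ``effect_beta`` when planted differential;
    β is the inverse logit of the latent value.
    """
    plan = build_module_plan(config)
    rng = config.rng("methylation")
    n_samples = config.n_tumor + config.n_normal
    sample_ids = [f"T{i:04d}" for i in range(config.n_tumor)] + [
        f"N{i:04d}" for i in range(config.n_normal)
    ]
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal, dtype=bool)

    mu = rng.uniform(-1.5, 1.5, size=config.n_sites)
    latent = np.empty((config.n_sites, n_samples))
    site_index = {s: i for i, s in enumerate(plan.site_ids)}

    in_module = np.zeros(config.n_sites, dtype=bool)
    shared = rng.standard_normal(n_samples)  # latent process shared by hub modules
    tau = config.hub_shared_rho
    for mod in plan.modules:
        idx = np.array([site_index[s] for s in mod.sites])
        in_module[idx] = True
        factor = rng.standard_normal(n_samples)
        if mod.is_hub and tau > 0:
            factor = np.sqrt(tau) * shared + np.sqrt(1 - tau) * factor
        noise = rng.standard_normal((len(idx), n_samples))
        latent[idx] = np.sqrt(mod.rho) * factor + np.sqrt(1 - mod.rho) * noise
    free = ~in_module
    latent[free] = rng.standard_normal((int(free.sum()), n_samples))

    shift = np.zeros(config.n_sites)
    diff_idx = np.array([site_index[s] for s in plan.diff_sites], dtype=int)
    if len(diff_idx):
        # alternate shift sign so differential sites move both ways
        signs = np.where(np.arange(len(diff_idx)) % 2 == 0, 1.0, -1.0)
        # within a module every site shifts the same way, or the shared factor
        # would decorrelate on the β scale; key the sign on the module instead
        sign_by_site = {}
        for k, mod in enumerate(plan.modules):
            for s in mod.sites:
                sign_by_site[s] = 1.0 if k % 2 == 0 else -1.0
        for j, s in enumerate(plan.diff_sites):
            signs[j] = sign_by_site.get(s, signs[j])
        shift[diff_idx] = signs * config.effect_beta

    latent = mu[:, None] + latent
    latent[:, is_tumor] += shift[:, None]
    beta_values = expit(latent)

    values = pd.DataFrame(beta_values, index=plan.site_ids, columns=sample_ids)
    labels = pd.Series(np.where(is_tumor, TUMOR, "normal"), index=sample_ids, name="group")
    beta = BetaMatrix(values=values, group_labels=labels)

    # annotation: module sites use the planned wiring; every remaining probe
    # is placed on a background mRNA so no network node is unannotated
    pairs = {(s, g) for mod in plan.modules for s, g in mod.site_genes.items()}
    assign_rng = config.rng("assignment")
    module_site_set = {s for mod in plan.modules for s in mod.sites}
    bg = plan.background_genes
    for s in plan.site_ids:
        if s not in module_site_set:
            pairs.add((s, bg[int(assign_rng.integers(len(bg)))]))
    return beta, SiteGeneMap(pairs=pairs)


def _truncated_power_law(rng, exponent: float, lo: int, hi: int, size: int) -> np.ndarray:
    degrees = np.arange(lo, hi + 1)
    weights = degrees.astype(float) ** (-exponent)
    weights /= weights.sum()
    return rng.choice(degrees, size=size, p=weights)


def simulate_rna_layer(config: SimulationConfig) -> RnaInteractionTable:
    """Draw the RNA interaction table.

    Community ncRNAs deterministically link the module genes of their
    community plus one dedicated DEG seed gene (making every admissible
    module gene at most two steps from a planted DEG); bulk ncRNAs attach to
    random mRNAs with truncated-power-law degrees; direct mRNA-mRNA edges
    come only from rna_edge modules plus ``mrna_edge_rate`` random extras.
    Genes of inadmissible modules never enter the layer.
    """
    plan = build_module_plan(config)
    rng = config.rng("rna")
    types: dict[str, str] = {}
    for g in plan.gene_ids:
        types[g] = "mRNA"
    for nc in plan.community_ncRNAs:
        types[nc] = "lncRNA"
    for nc in plan.bulk_ncRNAs:
        types[nc] = "lncRNA" if nc.startswith("LNC") else "miRNA"

    edges: set[tuple[str, str]] = set()

    def add(a: str, b: str) -> None:
        if a != b:
            edges.add((a, b) if a < b else (b, a))

    for mod in plan.modules:
        if mod.kind == "inadmissible":
            continue
        nc = plan.community_ncRNAs[mod.community] if plan.community_ncRNAs else None
        if nc is not None:
            for g in mod.genes:
                add(nc, g)
        if mod.kind == "rna_edge":
            add(mod.genes[0], mod.genes[1])

    for nc, seed_gene in zip(plan.community_ncRNAs, plan.community_deg_genes):
        add(nc, seed_gene)

    inadmissible_genes = {g for mod in plan.modules if mod.kind == "inadmissible" for g in mod.genes}
    mrna_pool = [g for g in plan.gene_ids if g not in inadmissible_genes]
    if config.n_ncRNA > config.n_community_ncRNA:
        max_deg = min(config.ncRNA_max_degree, len(mrna_pool))
        if max_deg < 2:
            raise ConfigError("not enough mRNAs for the requested ncRNA degrees")
        degs = _truncated_power_law(rng, config.ncRNA_degree_exponent, 2, max_deg,
                                    len(plan.bulk_ncRNAs))
        for nc, d in zip(plan.bulk_ncRNAs, degs):
            for g in rng.choice(mrna_pool, size=int(d), replace=False):
                add(nc, str(g))

    for _ in range(int(config.mrna_edge_rate)):
        a, b = rng.choice(mrna_pool, size=2, replace=False)
        add(str(a), str(b))

    edge_list = sorted(edges)
    if not edge_list:
        return RnaInteractionTable(
            rows=pd.DataFrame(columns=["rna_a", "rna_b", "type_a", "type_b", "confidence"])
        )
    conf = rng.uniform(0.7501, 1.0, size=len(edge_list))
    rows = pd.DataFrame(
        {
            "rna_a": [a for a, _ in edge_list],
            "rna_b": [b for _, b in edge_list],
            "type_a": [types[a] for a, _ in edge_list],
            "type_b": [types[b] for _, b in edge_list],
            "confidence": conf,
        }
    )
    return RnaInteractionTable(rows=rows)


def simulate_expression(
    config: SimulationConfig,
    site_gene_map: SiteGeneMap | None = None,
    deg_genes: list[str] | None = None,
) -> tuple[ExpressionMatrix, list[str]]:
    """Draw log-normal expression with planted fold changes.

    Returns the matrix and the planted DEG list (tumor mean multiplied by
    ``2**effect_lfc`` at those genes).
    """
    if deg_genes is None:
        deg_genes = planted_deg_genes(config)
    rng = config.rng("expression")
    n_samples = config.n_tumor + config.n_normal
    sample_ids = [f"T{i:04d}" for i in range(config.n_tumor)] + [
        f"N{i:04d}" for i in range(config.n_normal)
    ]
    is_tumor = np.array([1] * config.n_tumor + [0] * config.n_normal, dtype=bool)
    gene_ids = [f"GENE{i:04d}" for i in range(config.n_genes)]

    base = rng.uniform(3.0, 7.0, size=config.n_genes)  # natural-log scale
    noise = rng.normal(0.0, 0.5, size=(config.n_genes, n_samples))
    log_expr = base[:, None] + noise
    deg_idx = [i for i, g in enumerate(gene_ids) if g in set(deg_genes)]
    if deg_idx:
        signs = np.where(np.arange(len(deg_idx)) % 2 == 0, 1.0, -1.0)
        shift = signs * config.effect_lfc * np.log(2.0)
        log_expr[np.array(deg_idx)[:, None], np.where(is_tumor)[0][None, :]] += shift[:, None]
    values = pd.DataFrame(np.exp(log_expr), index=gene_ids, columns=sample_ids)
    labels = pd.Series(np.where(is_tumor, TUMOR, "normal"), index=sample_ids, name="group")
    return ExpressionMatrix(values=values, group_labels=labels), list(deg_genes)


def simulate_clinical(
    config: SimulationConfig, beta: BetaMatrix, hub_sites: list[str]
) -> ClinicalTable:
    """Draw exponential survival for tumor samples.

    log-hazard = ``hazard_gamma`` x (z-scored mean β of ``hub_sites``);
    a ``censor_rate`` fraction of patients is censored uniformly on (0, T).
    """
    missing = [s for s in hub_sites if s not in set(beta.site_ids)]
    if missing:
        raise ValueError(f"hub sites absent from the β matrix: {missing[:5]}")
    rng = config.rng("clinical")
    tumor_samples = beta.samples_in_group(TUMOR)
    if hub_sites:
        hub_beta = beta.values.loc[[s for s in hub_sites], tumor_samples].mean(axis=0)
        z = (hub_beta - hub_beta.mean()) / (hub_beta.std(ddof=0) or 1.0)
        z = z.to_numpy()
    else:
        z = np.zeros(len(tumor_samples))
    scale = config.baseline_survival_scale * np.exp(-config.hazard_gamma * z)
    times = rng.exponential(scale=scale)
    censored = rng.uniform(size=len(times)) < config.censor_rate
    obs_times = np.where(censored, rng.uniform(size=len(times)) * times, times)
    rows = pd.DataFrame(
        {
            "sample_id": tumor_samples,
            "time": obs_times,
            "event": (~censored).astype(int),
        }
    )
    return ClinicalTable(rows=rows)


@dataclass
class SimulatedDataset:
    """All generated tables plus the manifest of planted truths."""

    beta: BetaMatrix
    site_gene_map: SiteGeneMap
    interactions: RnaInteractionTable
    expression: ExpressionMatrix
    clinical: ClinicalTable
    manifest: dict = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig | None = None, **kwargs) -> SimulatedDataset:
    """Generate the full five-table dataset and its ground-truth manifest."""
    if config is None:
        config = SimulationConfig(**kwargs)
    plan = build_module_plan(config)
    beta, sgmap = simulate_methylation(config)
    interactions = simulate_rna_layer(config)
    expression, deg_genes = simulate_expression(config, sgmap)
    clinical = simulate_clinical(config, beta, plan.hazard_sites)
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "modules": [
            {
                "name": mod.name,
                "kind": mod.kind,
                "sites": mod.sites,
                "genes": mod.genes,
                "is_hub": mod.is_hub,
                "rho": mod.rho,
            }
            for mod in plan.modules
        ],
        "diff_sites": plan.diff_sites,
        "deg_genes": deg_genes,
        "hub_sites": plan.hub_sites,
        "hazard_sites": plan.hazard_sites,
        "inadmissible_sites": plan.inadmissible_sites,
        "n_sites": config.n_sites,
        "n_genes": config.n_genes,
    }
    return SimulatedDataset(beta, sgmap, interactions, expression, clinical, manifest)


def simulate_gene_sets(config: SimulationConfig, n_random_sets: int = 10):
    """Gene sets for enrichment tests, grounded in the RNA-layer wiring.

    One pathway per community ncRNA (its mRNA neighborhood — the genes it
    co-regulates) plus random background pathways; the background universe
    is every mRNA in the RNA layer.
    """
    from .datatypes import GeneSetCollection
    from .network import build_rna_layer

    plan = build_module_plan(config)
    rna = build_rna_layer(simulate_rna_layer(config))
    mrnas = sorted(
        n for n, t in nx_node_types(rna).items() if t == "mRNA"
    )
    background = frozenset(mrnas)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    for i, nc in enumerate(plan.community_ncRNAs):
        if nc not in rna:
            continue
        genes = frozenset(g for g in rna.adj[nc] if g in background)
        if genes:
            sets[f"PW{i:03d}"] = (f"community_{nc}", genes)
    rng = config.rng("assignment")
    for j in range(n_random_sets):
        size = int(rng.integers(5, 25))
        genes = frozenset(str(g) for g in rng.choice(mrnas, size=min(size, len(mrnas)), replace=False))
        sets[f"PWR{j:03d}"] = (f"random_{j}", genes)
    return GeneSetCollection(sets=sets, background=background)


def nx_node_types(rna_graph) -> dict[str, str]:
    return {n: d.get("rna_type", "other") for n, d in rna_graph.nodes(data=True)}


def write_dataset(dataset: SimulatedDataset, outdir) -> dict[str, str]:
    """Write the five TSV tables plus the JSON manifest; returns the paths."""
    from pathlib import Path

    from . import io as bio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "labels": outdir / "labels.tsv",
        "site_gene_map": outdir / "site_gene_map.tsv",
        "interactions": outdir / "interactions.tsv",
        "expression": outdir / "expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "manifest": outdir / "manifest.json",
    }
    bio.write_beta_matrix(dataset.beta, paths["beta"], paths["labels"])
    bio.write_site_gene_map(dataset.site_gene_map, paths["site_gene_map"])
    bio.write_interactions(dataset.interactions, paths["interactions"])
    bio.write_expression(dataset.expression, paths["expression"])
    bio.write_clinical(dataset.clinical, paths["clinical"])
    with open(paths["manifest"], "w") as fh:
        json.dump(dataset.manifest, fh, indent=1)
    return {k: str(v) for k, v in paths.items()}
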