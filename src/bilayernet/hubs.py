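"""Hub screening and evaluation.

Sites are ranked by degree or betweenness centrality; the top-k hubs are
evaluated three ways:

* survival — patients split into high/low groups at the mean β of the site,
  Kaplan-Meier curves compared by the Mantel-Cox log-rank test (unadjusted
  p < 0.05 flags a survival-associated site);
* bilayer-vs-single comparison — a 2x2 chi-squared test (no continuity
  correction, df = 1) of survival-associated counts between the filtered
  bilayer hub list and the unfiltered single-network hub list at equal k;
* proximity to differential expression — a hub counts as DEG-proximal when
  any of its genes is itself a DEG or lies within RNA-layer distance 2 of
  one (the noncoding-bridge pattern).

Hub comethylation is summarised as the mean |r| over all hub pairs and,
separately, over same-gene hub groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .datatypes import TUMOR, BetaMatrix, ClinicalTable, SiteGeneMap

logger = logging.getLogger(__name__)

__all__ = [
    "top_k",
    "km_logrank",
    "SurvivalFit",
    "count_survival_hubs",
    "chi_squared_2x2",
    "compare_networks",
    "hub_correlation_matrix",
    "deg_two_step_reachability",
    "hub_table",
]

SURVIVAL_ALPHA = 0.05


def top_k(centrality: dict[str, float] | pd.Series, k: int) -> list[str]:
    """The k nodes with the largest centrality, ties broken by node ID.

    Descending value, ascending ID within ties; truncated with a warning
    when k exceeds the node count.
    """
    if isinstance(centrality, pd.Series):
        centrality = centrality.to_dict()
    items = sorted(centrality.items(), key=lambda kv: (-kv[1], kv[0]))
    if k > len(items):
        logger.warning("requested top %d of %d nodes; truncating", k, len(items))
    return [node for node, _ in items[:k]]


@dataclass
class SurvivalFit:
    """Mean-β split KM curves and the Mantel-Cox log-rank comparison."""

    high_curve: pd.DataFrame  # columns: time, at_risk, events, survival
    low_curve: pd.DataFrame
    n_high: int
    n_low: int
    statistic: float
    p_value: float


def _km_curve(times, events) -> pd.DataFrame:
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    return pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
            "events": table["observed"].to_numpy(dtype=int),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(dtype=float),
        }
    )


def km_logrank(beta_row: pd.Series, clinical: ClinicalTable) -> SurvivalFit:
    """Split patients at the mean β of one site and compare survival.

    Patients with β >= mean form the high group.  Only patients present in
    both the β row and the clinical table are used.  Degenerate splits
    (an empty group, or no events anywhere) return p = 1 with a warning.
    """
    clin = clinical.rows.set_index("sample_id")
    common = [s for s in beta_row.index if s in clin.index]
    if len(common) < 4:
        raise ValueError("need at least 4 patients common to β matrix and clinical table")
    b = beta_row[common].to_numpy(dtype=float)
    times = clin.loc[common, "time"].to_numpy(dtype=float)
    events = clin.loc[common, "event"].to_numpy(dtype=int)
    high = b >= b.mean()

    if high.all() or (~high).all() or events.sum() == 0:
        logger.warning("degenerate mean-β split (empty group or no events); p=1")
        empty = pd.DataFrame(columns=["time", "at_risk", "events", "survival"])
        return SurvivalFit(
            high_curve=_km_curve(times[high], events[high]) if high.any() else empty,
            low_curve=_km_curve(times[~high], events[~high]) if (~high).any() else empty,
            n_high=int(high.sum()),
            n_low=int((~high).sum()),
            statistic=0.0,
            p_value=1.0,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = logrank_test(times[high], times[~high], events[high], events[~high])
    return SurvivalFit(
        high_curve=_km_curve(times[high], events[high]),
        low_curve=_km_curve(times[~high], events[~high]),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
    )


def survival_p_values(
    hubs: list[str], beta: BetaMatrix, clinical: ClinicalTable
) -> pd.Series:
    """Per-hub log-rank p-values for the mean-β split."""
    tumor_cols = beta.samples_in_group(TUMOR)
    out = {}
    for site in hubs:
        row = beta.values.loc[site, tumor_cols]
        out[site] = km_logrank(row, clinical).p_value
    return pd.Series(out, dtype=float)


def count_survival_hubs(
    hubs: list[str],
    beta: BetaMatrix,
    clinical: ClinicalTable,
    alpha: float = SURVIVAL_ALPHA,
) -> int:
    """Number of hub sites whose log-rank p is below alpha."""
    if not hubs:
        return 0
    return int((survival_p_values(hubs, beta, clinical) < alpha).sum())


def chi_squared_2x2(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df=1, no continuity correction.

    Computed directly as sum (f_o - f_e)^2 / f_e with expectations from the
    margins; a zero margin is an error.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-squared test needs positive margins")
    expected = np.outer(row, col) / total
    statistic = float(((obs - expected) ** 2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def compare_networks(
    hubs_bilayer: list[str],
    hubs_single: list[str],
    beta: BetaMatrix,
    clinical: ClinicalTable,
    alpha: float = SURVIVAL_ALPHA,
) -> tuple[np.ndarray, float, float]:
    """2x2 survival-associated comparison of two equal-k hub lists.

    Rows: bilayer / single; columns: survival-associated / not.  Returns
    (table, chi-square statistic, p-value).
    """
    if len(hubs_bilayer) != len(hubs_single):
        raise ValueError("hub lists must have equal k")
    k = len(hubs_bilayer)
    a = count_survival_hubs(hubs_bilayer, beta, clinical, alpha)
    c = count_survival_hubs(hubs_single, beta, clinical, alpha)
    table = np.array([[a, k - a], [c, k - c]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # all or none associated in both lists: no difference to test
        return table, 0.0, 1.0
    statistic, p = chi_squared_2x2(table)
    return table, statistic, p


def hub_correlation_matrix(
    hubs: list[str], beta: BetaMatrix, sgmap: SiteGeneMap | None = None
) -> tuple[pd.DataFrame, dict]:
    """Pairwise correlations among hub sites over tumor samples.

    Returns the correlation matrix and a summary with the overall mean |r|
    over distinct pairs and, when an annotation is given, the mean |r|
    within same-gene hub groups (>= 2 sites on one gene).
    """
    missing = [s for s in hubs if s not in set(beta.site_ids)]
    if missing:
        raise ValueError(f"hub sites absent from β matrix: {missing[:5]}")
    tumor = beta.tumor_values().loc[hubs]
    if len(hubs) < 2:
        corr = pd.DataFrame(np.ones((len(hubs), len(hubs))), index=hubs, columns=hubs)
        return corr, {"mean_abs_r": None, "same_gene_mean_abs_r": None}
    corr = pd.DataFrame(
        np.corrcoef(tumor.to_numpy(dtype=float)), index=hubs, columns=hubs
    )
    tri = np.triu_indices(len(hubs), k=1)
    mean_abs = float(np.nanmean(np.abs(corr.to_numpy()[tri])))

    same_gene_mean = None
    if sgmap is not None:
        gene_groups: dict[str, list[str]] = {}
        for s in hubs:
            for g in sgmap.genes_of(s):
                gene_groups.setdefault(g, []).append(s)
        vals: list[float] = []
        for sites in gene_groups.values():
            if len(sites) < 2:
                continue
            sub = corr.loc[sites, sites].to_numpy()
            t = np.triu_indices(len(sites), k=1)
            vals.extend(np.abs(sub[t]).tolist())
        if vals:
            same_gene_mean = float(np.mean(vals))
    return corr, {"mean_abs_r": mean_abs, "same_gene_mean_abs_r": same_gene_mean}


def deg_two_step_reachability(
    hubs: list[str],
    sgmap: SiteGeneMap,
    rna: nx.Graph,
    degs: list[str],
) -> tuple[dict[str, bool], int]:
    """Flag hubs whose genes are within RNA-layer distance 2 of a DEG.

    A hub qualifies if any of its genes is itself differentially expressed,
    or can reach one in at most two RNA-layer steps (one intermediate node,
    typically a noncoding RNA).  Unmapped hubs are flagged False.
    """
    deg_set = set(degs)
    # genes within distance <=2 of any DEG, computed once
    near: set[str] = {g for g in deg_set if g in rna}
    frontier1: set[str] = set()
    for g in deg_set & set(rna.nodes):
        frontier1 |= set(rna.adj[g])
    near |= frontier1
    for g in frontier1:
        near |= set(rna.adj[g])

    flags: dict[str, bool] = {}
    for site in hubs:
        genes = sgmap.genes_of(site)
        if not genes:
            logger.warning("hub %s has no gene annotation; flagged unreachable", site)
            flags[site] = False
            continue
        flags[site] = any(g in deg_set or g in near for g in genes)
    return flags, sum(flags.values())


def hub_table(
    centrality: dict[str, float],
    k: int,
    beta: BetaMatrix,
    clinical: ClinicalTable,
    sgmap: SiteGeneMap,
    rna: nx.Graph,
    degs: list[str],
    alpha: float = SURVIVAL_ALPHA,
) -> pd.DataFrame:
    """The full hub evidence table: rank, genes, survival, DEG proximity."""
    hubs = top_k(centrality, k)
    pvals = survival_p_values(hubs, beta, clinical)
    flags, _ = deg_two_step_reachability(hubs, sgmap, rna, degs)
    return pd.DataFrame(
        {
            "site_id": hubs,
            "rank": np.arange(1, len(hubs) + 1),
            "centrality": [centrality[s] for s in hubs],
            "genes": [",".join(sorted(sgmap.genes_of(s))) for s in hubs],
            "survival_p": [pvals[s] for s in hubs],
            "survival_associated": [bool(pvals[s] < alpha) for s in hubs],
            "deg_within_two_steps": [flags[s] for s in hubs],
        }
    )
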