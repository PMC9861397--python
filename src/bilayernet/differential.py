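"""Empirical-Bayes moderated two-group t-tests and differential calling.

The moderated t shrinks each feature's pooled variance s_g^2 (d residual
degrees of freedom) toward a prior s0^2 with prior degrees of freedom d0:

    s_post^2 = (d0 * s0^2 + d * s_g^2) / (d0 + d)
    t_g      = (mean_1 - mean_2) / sqrt(s_post^2 * (1/n1 + 1/n2))

with p-values from a t distribution on d0 + d degrees of freedom.  The
hyperparameters (d0, s0^2) are estimated by the method of moments on the
log sample variances: under the scaled-inverse-chi-square prior,
s_g^2 / s0^2 ~ F(d, d0), so

    E[log s_g^2]   = log s0^2 + psi(d/2) - psi(d0/2) + log(d0/d)
    Var[log s_g^2] = psi'(d/2) + psi'(d0/2)

and d0 follows by inverting the trigamma function psi'.

Thresholds used by the calling helpers: methylation sites at BH-FDR < 0.01;
expressed genes at BH-FDR < 0.05 and |log2 fold change| > 1, with the fold
change taken from group mean expression plus a pseudo-count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import NORMAL, TUMOR, BetaMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialResult",
    "moderated_t_test",
    "benjamini_hochberg",
    "call_differential_sites",
    "call_degs",
    "estimate_prior",
]

SITE_FDR = 0.01
DEG_FDR = 0.05
LFC_CUTOFF = 1.0
_MAX_PRIOR_DF = 1e6  # stands in for d0 = infinity (no residual variability)


@dataclass
class DifferentialResult:
    feature_id: str
    mean_tumor: float
    mean_normal: float
    log2fc: float
    t_stat: float
    p_value: float
    fdr: float
    significant: bool


def _trigamma_inverse(y: float) -> float:
    """Solve psi'(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return _MAX_PRIOR_DF
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments (d0, s0^2) from the log sample variances."""
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if len(positive) < 2:
        return 0.0, float(positive[0]) if len(positive) else 1.0
    z = np.log(positive)
    z_mean = z.mean()
    z_var = z.var(ddof=1)
    excess = z_var - special.polygamma(1, d / 2.0)
    if excess <= 0:
        d0 = _MAX_PRIOR_DF
    else:
        d0 = min(2.0 * _trigamma_inverse(float(excess)), _MAX_PRIOR_DF)
    if d0 >= _MAX_PRIOR_DF:
        # limit d0 -> inf: psi(d0/2) - log(d0/d) -> log(d/2)
        log_s0 = z_mean - special.polygamma(0, d / 2.0) + np.log(d / 2.0)
    else:
        log_s0 = (
            z_mean
            - special.polygamma(0, d / 2.0)
            + special.polygamma(0, d0 / 2.0)
            - np.log(d0 / d)
        )
    s0_2 = float(np.exp(log_s0))
    return float(d0), s0_2


def moderated_t_test(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    prior_df: float | None = None,
    log2fc_from: pd.DataFrame | None = None,
    pseudo_count: float = 1.0,
) -> list[DifferentialResult]:
    """Two-group empirical-Bayes moderated t-test per feature (row).

    Parameters
    ----------
    matrix
        features x samples values on the scale to be tested.
    group_labels
        per-sample {tumor, normal} labels.
    prior_df
        override for d0; ``0`` disables shrinkage (ordinary pooled t),
        ``None`` estimates (d0, s0^2) from the data.
    log2fc_from
        optional matrix (same rows) from which group-mean log2 fold changes
        are computed with ``pseudo_count``; when None the reported log2fc is
        the plain difference of group means of ``matrix`` (the convention
        for β values).
    """
    labels = group_labels.reindex(matrix.columns)
    t_cols = list(labels.index[labels == TUMOR])
    n_cols = list(labels.index[labels == NORMAL])
    n1, n2 = len(t_cols), len(n_cols)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got tumor={n1}, normal={n2}")

    x1 = matrix[t_cols].to_numpy(dtype=float)
    x2 = matrix[n_cols].to_numpy(dtype=float)
    m1 = x1.mean(axis=1)
    m2 = x2.mean(axis=1)
    d = n1 + n2 - 2
    ss = ((x1 - m1[:, None]) ** 2).sum(axis=1) + ((x2 - m2[:, None]) ** 2).sum(axis=1)
    s2 = ss / d

    # guard all-constant features: zero pooled variance would give infinite t
    zero_var = s2 <= 0
    if zero_var.any():
        positive = s2[~zero_var]
        floor = (positive.min() * 1e-3) if len(positive) else 1e-12
        constant = zero_var & (m1 == m2)
        if constant.any():
            logger.warning("%d all-constant features set to p=1", int(constant.sum()))
        s2 = np.where(zero_var, floor, s2)

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, d)
    else:
        d0 = float(prior_df)
        s0_2 = float(np.median(s2)) if d0 > 0 else 0.0
    if d0 > 0:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = min(d0 + d, _MAX_PRIOR_DF)
    else:
        s2_post = s2
        df_total = d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    constant = (ss == 0) & (m1 == m2)
    p = np.where(constant, 1.0, p)

    if log2fc_from is not None:
        f1 = log2fc_from[t_cols].mean(axis=1).to_numpy(dtype=float)
        f2 = log2fc_from[n_cols].mean(axis=1).to_numpy(dtype=float)
        log2fc = np.log2(f1 + pseudo_count) - np.log2(f2 + pseudo_count)
    else:
        log2fc = m1 - m2

    fdr = benjamini_hochberg(p)
    results = [
        DifferentialResult(
            feature_id=str(fid),
            mean_tumor=float(m1[i]),
            mean_normal=float(m2[i]),
            log2fc=float(log2fc[i]),
            t_stat=float(t[i]),
            p_value=float(p[i]),
            fdr=float(fdr[i]),
            significant=False,
        )
        for i, fid in enumerate(matrix.index)
    ]
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up BH-adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def results_to_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def call_differential_sites(
    beta: BetaMatrix, fdr_threshold: float = SITE_FDR, prior_df: float | None = None
) -> tuple[list[str], list[DifferentialResult]]:
    """Sites with BH-FDR below ``fdr_threshold`` (the layer node universe)."""
    if beta.values.empty:
        return [], []
    results = moderated_t_test(beta.values, beta.group_labels, prior_df=prior_df)
    for r in results:
        r.significant = r.fdr < fdr_threshold
    sites = [r.feature_id for r in results if r.significant]
    return sites, results


def call_degs(
    expression: ExpressionMatrix,
    fdr_threshold: float = DEG_FDR,
    lfc_cutoff: float = LFC_CUTOFF,
    pseudo_count: float = 1.0,
    prior_df: float | None = None,
) -> tuple[list[str], list[DifferentialResult]]:
    """Genes with BH-FDR < threshold and |log2 fold change| > cutoff.

    Testing is done on log2(x + pseudo_count); the fold change comes from
    the ratio of group mean raw expressions (same pseudo-count guard).
    """
    if expression.values.empty:
        return [], []
    log_expr = np.log2(expression.values + pseudo_count)
    results = moderated_t_test(
        log_expr,
        expression.group_labels,
        prior_df=prior_df,
        log2fc_from=expression.values,
        pseudo_count=pseudo_count,
    )
    for r in results:
        r.significant = (r.fdr < fdr_threshold) and (abs(r.log2fc) > lfc_cutoff)
    genes = [r.feature_id for r in results if r.significant]
    return genes, results
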