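"""Two-group negative-binomial differential expression, from first principles.

This is a deliberately simplified DESeq2-style stack: median-of-ratios size
factors, per-gene method-of-moments NB dispersion pooled within groups, a
per-gene NB log-link GLM with a group indicator fitted by IRLS, a Wald test
against the standard normal, and Benjamini-Hochberg adjustment. Results
carry a ``method=nb_wald_simple`` tag.

Simplifications relative to the full DESeq2 machinery, on purpose: no
dispersion-trend shrinkage, no Cook's-distance outlier filtering, no
independent filtering, no fold-change shrinkage. The comparative analyses
downstream only consume the significant-gene partition, for which this
plainer estimator is adequate and fully transparent.

The fold change is reported as log2(group A / group B); ``direction`` is
``up_in_A`` for positive significant changes and ``up_in_B`` for negative.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, GeneSet

METHOD_TAG = "nb_wald_simple"

#: Dispersion floor used inside the GLM variance function. A fitted
#: dispersion of exactly zero (sub-Poisson moment estimate) would make the
#: NB variance degenerate to Poisson with zero extra-variance allowance.
DISPERSION_FLOOR = 1e-8


class DEError(ValueError):
    """Raised on invalid designs or inputs."""


def _group_masks(groups: Sequence, group_a, group_b) -> tuple:
    labels = np.asarray(list(groups), dtype=object)
    mask_a = labels == group_a
    mask_b = labels == group_b
    if not mask_a.any() or not mask_b.any():
        raise DEError(f"groups {group_a!r}/{group_b!r} not both present")
    return mask_a, mask_b


def size_factors_median_of_ratios(matrix: CountMatrix) -> np.ndarray:
    """DESeq2-style median-of-ratios size factors, geometric-mean centred.

    For sample j the raw factor is the median over all-positive genes of
    count(g, j) / geomean_g, where geomean_g is the geometric mean of gene g
    across samples. Factors are rescaled so their geometric mean is 1.
    """
    counts = matrix.values
    if matrix.n_samples < 2:
        raise DEError("size factors need >= 2 samples")
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise DEError(
            "no gene has positive counts in every sample; a pseudo-reference "
            "fallback is not implemented — filter or merge samples upstream"
        )
    ref = counts[all_positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = ref / np.exp(log_geomean)[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def estimate_dispersion(
    matrix: CountMatrix,
    size_factors: np.ndarray,
    groups: Sequence,
    group_a,
    group_b,
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion on normalized counts.

    Within each group: alpha_k = (s2_k - mu_k) / mu_k^2 on size-factor
    normalized counts; the per-gene estimate is the df-weighted mean over
    the two groups, clipped below at zero. Each group needs >= 2 samples —
    pooling replicates across nuisance factors (as the sample design here
    assumes) must happen upstream.

    Constant or sub-Poisson genes give 0; the GLM floors at
    :data:`DISPERSION_FLOOR` when it uses these values.
    """
    mask_a, mask_b = _group_masks(groups, group_a, group_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise DEError("each group needs >= 2 samples for dispersion estimation")
    normalized = matrix.values / np.asarray(size_factors, dtype=float)[None, :]
    total_alpha = np.zeros(matrix.n_genes)
    total_df = 0
    for mask in (mask_a, mask_b):
        sub = normalized[:, mask]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = np.where(mu > 0, (s2 - mu) / np.where(mu > 0, mu, 1.0) ** 2, 0.0)
        df = mask.sum() - 1
        total_alpha += df * alpha
        total_df += df
    return np.maximum(total_alpha / total_df, 0.0)


def nb_wald_test(
    matrix: CountMatrix,
    size_factors: np.ndarray,
    dispersions: np.ndarray,
    groups: Sequence,
    group_a,
    group_b,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of group A versus group B.

    Model: counts_gj ~ NB(mu_gj, alpha_g), log mu_gj = log s_j + b0_g +
    b1_g x_j with x_j = 1 for group A. All genes are fitted simultaneously
    by vectorised IRLS (the design is shared, only the 2x2 normal equations
    differ per gene). Wald statistic b1/SE(b1), two-sided p from N(0, 1).

    All-zero genes get p = 1, log2 fold change 0 and ``all_zero=True``.

    Returns a DataFrame indexed by gene with columns base_mean,
    log2_fold_change, dispersion, stat, p_value, all_zero, method.
    """
    mask_a, mask_b = _group_masks(groups, group_a, group_b)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise DEError("each group needs >= 2 samples")
    counts = matrix.values[:, mask_a | mask_b]
    sf = np.asarray(size_factors, dtype=float)[mask_a | mask_b]
    x = mask_a[mask_a | mask_b].astype(float)

    n_genes = counts.shape[0]
    alpha = np.maximum(np.asarray(dispersions, dtype=float), DISPERSION_FLOOR)
    log_sf = np.log(sf)
    normalized = counts / sf[None, :]
    base_mean = normalized.mean(axis=1)
    all_zero = counts.sum(axis=1) == 0

    eps = 1e-8
    mean_a = normalized[:, x == 1].mean(axis=1)
    mean_b = normalized[:, x == 0].mean(axis=1)
    beta0 = np.log(np.maximum(mean_b, eps))
    beta1 = np.log(np.maximum(mean_a, eps)) - beta0

    for _ in range(max_iter):
        eta = beta0[:, None] + beta1[:, None] * x[None, :] + log_sf[None, :]
        eta = np.clip(eta, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - log_sf[None, :] + (counts - mu) / mu
        s00 = w.sum(axis=1)
        s01 = (w * x[None, :]).sum(axis=1)
        s11 = (w * x[None, :] ** 2).sum(axis=1)
        t0 = (w * z).sum(axis=1)
        t1 = (w * z * x[None, :]).sum(axis=1)
        det = s00 * s11 - s01**2
        det = np.where(det <= 0, np.nan, det)
        new_beta0 = (s11 * t0 - s01 * t1) / det
        new_beta1 = (s00 * t1 - s01 * t0) / det
        new_beta0 = np.where(np.isfinite(new_beta0), new_beta0, beta0)
        new_beta1 = np.where(np.isfinite(new_beta1), new_beta1, beta1)
        shift = np.maximum(np.abs(new_beta0 - beta0), np.abs(new_beta1 - beta1))
        beta0, beta1 = new_beta0, new_beta1
        if np.nanmax(shift, initial=0.0) < tol:
            break

    eta = np.clip(beta0[:, None] + beta1[:, None] * x[None, :] + log_sf[None, :], -30, 30)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    s00 = w.sum(axis=1)
    s01 = (w * x[None, :]).sum(axis=1)
    s11 = (w * x[None, :] ** 2).sum(axis=1)
    det = s00 * s11 - s01**2
    with np.errstate(divide="ignore", invalid="ignore"):
        var_beta1 = s00 / det
    se = np.sqrt(np.maximum(var_beta1, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = beta1 / se
    stat = np.where(np.isfinite(stat), stat, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(stat))

    stat[all_zero] = 0.0
    p[all_zero] = 1.0
    beta1 = np.where(all_zero, 0.0, beta1)
    p = np.clip(p, 0.0, 1.0)

    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2_fold_change": beta1 / np.log(2.0),
            "dispersion": np.asarray(dispersions, dtype=float),
            "stat": stat,
            "p_value": p,
            "all_zero": all_zero,
            "method": METHOD_TAG,
        },
        index=pd.Index(matrix.gene_ids, name="gene"),
    )


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending ordering, mapped
    back to the input order and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise DEError("p-values must be a 1-d vector")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise DEError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def differential_transcripts(results: pd.DataFrame, alpha: float = 0.05) -> tuple:
    """Split significant genes (q <= alpha) by fold-change sign.

    Returns ``(up_in_A, up_in_B)`` as :class:`GeneSet`. A significant gene
    with numerically zero fold change would fall in neither set; such genes
    are impossible by construction (a zero estimate implies a zero Wald
    statistic, hence p = 1) and are asserted against.
    """
    if "q_value" not in results.columns:
        raise DEError("results lack q_value; run adjust_bh first")
    significant = results[results["q_value"] <= alpha]
    zero_lfc = significant[significant["log2_fold_change"] == 0.0]
    if len(zero_lfc):
        raise DEError(
            f"significant genes with zero fold change (numerical flag): "
            f"{list(zero_lfc.index[:5])}"
        )
    up_a = frozenset(significant.index[significant["log2_fold_change"] > 0])
    up_b = frozenset(significant.index[significant["log2_fold_change"] < 0])
    return (
        GeneSet(name="up_in_A", genes=up_a, description=f"q<={alpha:g}, log2FC>0"),
        GeneSet(name="up_in_B", genes=up_b, description=f"q<={alpha:g}, log2FC<0"),
    )


#: Named two-group contrasts over the placental sample design. ``compartment``
#: pools across timepoints (avascular BOM versus vascularised TOM);
#: ``stage`` pools across compartments (early d21+d23 versus late d25).
CONTRAST_PRESETS = {
    "compartment": ("tissue_compartment", "BOM", "TOM"),
    "stage": ("stage_group", "early", "late"),
}

#: Timepoint labels folded into the ``early`` pool of the stage contrast.
EARLY_TIMEPOINTS = ("d21", "d23")


def run_de(
    matrix: CountMatrix,
    metadata: pd.DataFrame,
    contrast: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """End-to-end DE for a named contrast preset on one count matrix.

    Orders metadata by the matrix's samples, derives the group labels,
    estimates size factors and dispersions, runs the Wald test, adjusts
    with BH and annotates a ``direction`` column
    (up_in_A / up_in_B / ns).
    """
    if contrast not in CONTRAST_PRESETS:
        raise DEError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRAST_PRESETS)}")
    column, group_a, group_b = CONTRAST_PRESETS[contrast]
    meta = metadata.set_index("sample_id").loc[list(matrix.sample_ids)]
    if contrast == "stage":
        groups = np.where(
            meta["timepoint"].isin(EARLY_TIMEPOINTS), "early", "late"
        )
    else:
        groups = meta[column].to_numpy(dtype=object)
    sf = size_factors_median_of_ratios(matrix)
    disp = estimate_dispersion(matrix, sf, groups, group_a, group_b)
    results = nb_wald_test(matrix, sf, disp, groups, group_a, group_b)
    results["q_value"] = adjust_bh(results["p_value"].to_numpy())
    results["direction"] = "ns"
    sig = results["q_value"] <= alpha
    results.loc[sig & (results["log2_fold_change"] > 0), "direction"] = "up_in_A"
    results.loc[sig & (results["log2_fold_change"] < 0), "direction"] = "up_in_B"
    results.attrs["contrast"] = contrast
    results.attrs["group_a"] = group_a
    results.attrs["group_b"] = group_b
    return results
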