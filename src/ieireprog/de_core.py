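"""Two-group negative-binomial differential expression.

Median-of-ratios size factors, method-of-moments dispersion, a Wald-type
test on log2 fold changes of normalized group means, and step-up
Benjamini-Hochberg adjustment. This is a deliberately small, documented
engine: no dispersion trend fitting, no empirical-Bayes shrinkage of either
dispersions or fold changes, single-factor designs only. Externally
produced DE tables can be ingested instead via
:func:`ieireprog.io_formats.read_de_table`.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, DETable

__all__ = ["size_factors", "estimate_dispersion", "de_test", "bh_adjust"]

#: lower clamp for the NB dispersion (variance = mu + alpha * mu^2)
ALPHA_MIN = 1e-8
#: pseudocount added to group mean normalized counts before taking log2
PSEUDOCOUNT = 0.5

_LN2 = np.log(2.0)


def size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    For every gene with a positive count in all samples, form the ratio of
    each sample's count to the gene's geometric mean across samples; the
    sample's factor is the median of those ratios. Genes with a zero in any
    sample carry no information about relative depth and are excluded.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; filter the matrix "
            "to expressed genes before normalization"
        )
    logs = np.log(counts[all_positive])
    log_geo_mean = logs.mean(axis=1)
    ratios = np.exp(logs - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # convention: geomean 1
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def estimate_dispersion(
    cm: CountMatrix,
    sf: pd.Series,
    groups: pd.Series,
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion from within-group residuals.

    Normalized counts y = k / s are pooled across groups: with pooled
    within-group variance s2 and grand mean m, alpha = max((s2 - m) / m^2,
    alpha_min). Requires at least two samples per group.

    Parameters
    ----------
    groups
        sample_id -> group label for every column of ``cm``.
    """
    groups = groups.reindex(cm.sample_ids)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        small = sizes[sizes < 2].index.tolist()
        raise ValueError(f"group(s) {small} have fewer than 2 samples")

    y = cm.counts.to_numpy(dtype=float) / sf.reindex(cm.sample_ids).to_numpy()
    ss = np.zeros(y.shape[0])
    n_total = 0
    n_groups = 0
    for label in sizes.index:
        cols = np.asarray(groups.to_numpy() == label)
        yg = y[:, cols]
        ss += ((yg - yg.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        n_total += cols.sum()
        n_groups += 1
    s2 = ss / (n_total - n_groups)
    m = y.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (s2 - m) / m**2
    alpha = np.where(m > 0, alpha, alpha_min)
    alpha = np.maximum(alpha, alpha_min)
    return pd.Series(alpha, index=cm.gene_ids, name="dispersion")


def de_test(
    cm: CountMatrix,
    sf: pd.Series,
    disp: pd.Series,
    groups: pd.Series,
    contrast: tuple[str, str],
    pseudocount: float = PSEUDOCOUNT,
    dispersion_floor: float | str = "median",
) -> DETable:
    """Wald test of a two-group contrast on normalized NB counts.

    log2fc = log2((m_t + c) / (m_r + c)) for group-mean normalized counts
    m_t, m_r and pseudocount c; the standard error comes from the
    delta-method NB variance of each group mean, and z = log2fc / se is
    referred to a standard normal. At triplicate scale the raw per-gene
    moment dispersion is so noisy that a plug-in Wald test runs visibly
    anticonservative; each gene's dispersion is therefore floored at a
    single central value - the median of the per-gene estimates over genes
    with base mean above 5 (``dispersion_floor="median"``, the default; a
    float uses that value directly, ``None`` disables the floor). This is a
    scalar robustness floor, not a dispersion trend or empirical-Bayes
    shrinkage. BH adjustment runs over genes with positive base mean; genes
    with zero base mean get p = padj = 1.

    ``contrast`` is (treatment_label, reference_label) in the ``groups``
    labelling; swapping it negates every log2fc exactly.
    """
    treat, ref = contrast
    groups = groups.reindex(cm.sample_ids)
    t_cols = np.asarray(groups.to_numpy() == treat)
    r_cols = np.asarray(groups.to_numpy() == ref)
    if not t_cols.any() or not r_cols.any():
        raise ValueError(f"contrast {contrast} has an empty group")

    sfv = sf.reindex(cm.sample_ids).to_numpy()
    y = cm.counts.to_numpy(dtype=float) / sfv
    alpha = disp.reindex(cm.gene_ids).to_numpy()

    n_t, n_r = int(t_cols.sum()), int(r_cols.sum())
    m_t = y[:, t_cols].mean(axis=1)
    m_r = y[:, r_cols].mean(axis=1)
    base_mean = y[:, t_cols | r_cols].mean(axis=1)

    c = pseudocount
    # difference of logs (not log of ratio) so a swapped contrast negates exactly
    log2fc = np.log2(m_t + c) - np.log2(m_r + c)

    if dispersion_floor == "median":
        informative = base_mean > 5
        central = float(np.median(alpha[informative])) if informative.any() else float(np.median(alpha))
        alpha = np.maximum(alpha, central)
    elif dispersion_floor is not None:
        alpha = np.maximum(alpha, float(dispersion_floor))

    # Var(mean of k_i/s_i) with k_i ~ NB(mu_i = s_i * m, alpha):
    # (1/n^2) * sum_i (s_i*m + alpha*s_i^2*m^2) / s_i^2
    inv_s_t = (1.0 / sfv[t_cols]).sum()
    inv_s_r = (1.0 / sfv[r_cols]).sum()
    var_m_t = (m_t * inv_s_t) / n_t**2 + alpha * m_t**2 / n_t
    var_m_r = (m_r * inv_s_r) / n_r**2 + alpha * m_r**2 / n_r
    var_log2 = (var_m_t / (m_t + c) ** 2 + var_m_r / (m_r + c) ** 2) / _LN2**2
    se = np.sqrt(np.maximum(var_log2, 0.0))

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    p = np.where(
        (se > 0) & (base_mean > 0),
        2.0 * stats.norm.sf(np.abs(z)),
        1.0,
    )
    p = np.clip(p, 0.0, 1.0)

    padj = np.ones_like(p)
    expressed = base_mean > 0
    padj[expressed] = bh_adjust(p[expressed])

    table = pd.DataFrame(
        {
            "gene": cm.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "padj": padj,
            "padj_imputed": False,
        }
    )
    return DETable(table)


def bh_adjust(p: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, in input order.

    Monotone (order-preserving), never below the raw p, clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-d vector")
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out
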