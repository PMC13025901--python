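"""Expression filtering and a negative-binomial Wald test for DE calling.

The test is a deliberately small, self-contained two-group NB model:
median-of-ratios size factors, per-gene method-of-moments dispersion
pooled within groups (with a small-sample floor at the catalog-wide
median), a log-link two-group mean fit, and a Wald z on the log2 fold
change. DE genes are called with the raw-p rule |log2FC| >= 1 and
p < 0.05; Benjamini-Hochberg adjustment is available but off by
default because the calling rule uses unadjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import compute_cpm
from .model import ConfigError, ExpressionMatrix

_EPS = 1e-8


@dataclass
class DECall:
    gene_id: str
    base_mean_c1: float
    base_mean_c2: float
    log2fc: float
    p_value: float
    direction: str  # up / down / nodiff
    p_adjusted: Optional[float] = None


def filter_cpm(
    m: ExpressionMatrix,
    min_cpm: float = 1.0,
    min_libraries: int = 3,
) -> list:
    """Keep features with CPM >= min_cpm in >= min_libraries of one group."""
    for cond in m.conditions:
        n = len(m.condition_samples(cond))
        if n < min_libraries:
            raise ConfigError(
                f"condition {cond!r} has {n} samples, fewer than "
                f"min_libraries={min_libraries}"
            )
    cpm = compute_cpm(m).values
    keep = []
    for fid in m.feature_ids:
        row = cpm.loc[fid]
        for cond in m.conditions:
            samples = m.condition_samples(cond)
            if int((row[samples] >= min_cpm).sum()) >= min_libraries:
                keep.append(fid)
                break
    return keep


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization (geometric-mean reference)."""
    log_counts = np.log(counts.values + _EPS)
    log_ref = log_counts.mean(axis=1)
    usable = counts.values.min(axis=1) > 0
    if usable.sum() == 0:
        usable = np.ones(len(counts), dtype=bool)
    ratios = log_counts[usable] - log_ref[usable, None]
    sf = np.exp(np.median(ratios, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return pd.Series(sf, index=counts.columns)


def _dispersion_mom(norm: np.ndarray, groups: list) -> np.ndarray:
    """Pooled within-group method-of-moments NB dispersion per gene."""
    n_genes = norm.shape[0]
    num = np.zeros(n_genes)
    den = np.zeros(n_genes)
    df = 0
    for idx in groups:
        sub = norm[:, idx]
        mu = sub.mean(axis=1, keepdims=True)
        resid = ((sub - mu) ** 2).sum(axis=1)
        num += resid - (len(idx) - 1) * mu[:, 0]
        den += (len(idx) - 1) * mu[:, 0] ** 2
        df += len(idx) - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / np.maximum(den, _EPS), 0.0)
    return np.maximum(alpha, 0.0)


def nb_wald_test(
    m: ExpressionMatrix,
    adjust: bool = False,
    lfc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> list:
    """Two-group NB Wald test on a (filtered) count matrix.

    Deterministic given the input. The Wald statistic is the log2 fold
    change over its delta-method standard error under the NB variance
    ``mu + alpha * mu^2``; per-gene dispersions are floored at the
    catalog-wide median so the handful of genes whose moment estimate
    collapses to zero do not produce overconfident calls.
    """
    if m.unit != "counts":
        raise ConfigError(f"nb_wald_test requires counts, got {m.unit}")
    conds = m.conditions
    counts = m.values
    sf = size_factors(counts)
    norm = counts.values / sf.values[None, :]
    group_idx = [
        [list(counts.columns).index(s) for s in m.condition_samples(c)]
        for c in conds
    ]
    for c, idx in zip(conds, group_idx):
        if len(idx) < 2:
            raise ConfigError(f"condition {c!r} has < 2 replicates")

    alpha = _dispersion_mom(norm, group_idx)
    floor = float(np.median(alpha[alpha > 0])) if (alpha > 0).any() else _EPS
    alpha = np.maximum(alpha, max(floor, _EPS))

    mu = np.stack([norm[:, idx].mean(axis=1) for idx in group_idx], axis=1)
    # Var of the group mean of normalized counts under NB(mu*s, alpha):
    # Var(k_j/s_j) = mu/s_j + alpha*mu^2, averaged over replicates.
    var_mean = []
    for g, idx in enumerate(group_idx):
        inv_s = (1.0 / sf.values[idx]).sum()
        n = len(idx)
        var_mean.append((mu[:, g] * inv_s / n + alpha * mu[:, g] ** 2) / n)
    var_mean = np.stack(var_mean, axis=1)

    mu_safe = np.maximum(mu, _EPS)
    log2fc = np.log2(mu_safe[:, 1] / mu_safe[:, 0])
    ln2sq = np.log(2.0) ** 2
    se2 = (
        var_mean[:, 0] / (mu_safe[:, 0] ** 2)
        + var_mean[:, 1] / (mu_safe[:, 1] ** 2)
    ) / ln2sq
    se = np.sqrt(np.maximum(se2, _EPS))
    z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    padj = None
    if adjust:
        padj = _bh(p)

    calls = []
    for i, gid in enumerate(counts.index):
        p_use = padj[i] if adjust else p[i]
        if p_use < p_threshold and log2fc[i] >= lfc_threshold:
            direction = "up"
        elif p_use < p_threshold and log2fc[i] <= -lfc_threshold:
            direction = "down"
        else:
            direction = "nodiff"
        calls.append(
            DECall(
                gene_id=str(gid),
                base_mean_c1=float(mu[i, 0]),
                base_mean_c2=float(mu[i, 1]),
                log2fc=float(log2fc[i]),
                p_value=float(p[i]),
                direction=direction,
                p_adjusted=float(padj[i]) if adjust else None,
            )
        )
    return calls


def _bh(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def de_calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "base_mean_c1": round(c.base_mean_c1, 4),
                "base_mean_c2": round(c.base_mean_c2, 4),
                "log2fc": round(c.log2fc, 4),
                "p_value": c.p_value,
                "direction": c.direction,
            }
            for c in calls
        ]
    )
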