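"""Sporophyte-vs-gametophyte differential expression.

A self-contained negative-binomial two-group Wald test in the classical
RNA-seq mould: median-of-ratios size factors, a per-gene method-of-moments
dispersion pooled within groups, group means from the NB score equation with
size-factor offsets, and Benjamini-Hochberg adjustment.  "Preferentially
sporophyte-expressed" means padj <= 0.05 and log2 fold change >= 2
(sporophyte over gametophyte).

The model is NB2: Var(Y) = mu + alpha * mu^2 with dispersion alpha.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .datamodel import CountMatrix, EstimationError, GAMETOPHYTE, SPOROPHYTE

LOW_COUNT_MIN_TOTAL = 10  # genes summing below this across all samples are dropped
ALPHA_FLOOR = 1e-8
PSEUDO_MEAN = 0.5  # added to both group means for a bounded fold change


@dataclass
class DEResult:
    gene_id: str
    base_mean: float
    log2fc: float  # positive = higher in sporophyte
    se: float
    wald_p: float
    padj: float = float("nan")
    preferential: bool = False


def filter_low_counts(
    cm: CountMatrix, min_total: int = LOW_COUNT_MIN_TOTAL
) -> CountMatrix:
    """Drop genes whose summed count over all samples is below ``min_total``
    (default 10); survivor order is preserved."""
    totals = cm.counts.sum(axis=1)
    return CountMatrix(cm.counts.loc[totals >= min_total], list(cm.samples))


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    Reference genes are those with a nonzero count in every sample; each
    sample's factor is the median over reference genes of
    count / geometric-mean-across-samples.
    """
    counts = cm.counts.to_numpy(dtype=float)
    reference = (counts > 0).all(axis=1)
    if not reference.any():
        raise EstimationError(
            "no gene has nonzero counts in every sample; cannot estimate "
            "size factors"
        )
    ref = counts[reference]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geomean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=cm.sample_ids, name="size_factor")


def _nb_group_mean(y: np.ndarray, s: np.ndarray, alpha: float) -> float:
    """MLE of the per-unit-size-factor group mean q under NB2 with means
    mu_i = s_i * q, i.e. the root of sum_i (y_i - s_i q)/(1 + alpha s_i q)."""
    if y.sum() == 0:
        return 0.0

    def score(q: float) -> float:
        mu = s * q
        return float(((y - mu) / (1.0 + alpha * mu)).sum())

    hi = float((y / s).max()) * 2.0 + 1.0
    while score(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(score, 0.0, hi, xtol=1e-12, rtol=1e-12))


def _fisher_info(q: float, s: np.ndarray, alpha: float) -> float:
    """Fisher information for log q, evaluated at the pseudo-mean-adjusted
    group mean so that it stays finite when a group is all zero."""
    mu = s * (q + PSEUDO_MEAN)
    return float((mu / (1.0 + alpha * mu)).sum())


def _pooled_dispersion(z: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments NB2 dispersion on normalized counts, residual
    variance pooled within groups; floored at ALPHA_FLOOR."""
    n = z.size
    ss = 0.0
    for idx in groups:
        ss += float(((z[idx] - z[idx].mean()) ** 2).sum())
    dof = n - len(groups)
    if dof <= 0:
        return ALPHA_FLOOR
    variance = ss / dof
    mean = float(z.mean())
    if mean <= 0:
        return ALPHA_FLOOR
    return max((variance - mean) / mean**2, ALPHA_FLOOR)


def nb_wald_test(
    cm: CountMatrix,
    size_factors: pd.Series,
    group_labels: pd.Series | None = None,
    alpha_floor: float = ALPHA_FLOOR,
) -> pd.DataFrame:
    """Per-gene NB Wald test of sporophyte vs gametophyte expression.

    ``group_labels`` maps sample id to 'sporophyte'/'gametophyte'; by default
    it is taken from the sample metadata.  Returns a DataFrame with columns
    gene_id, base_mean, log2fc, se, wald_p, padj, preferential (padj filled
    by :func:`bh_adjust` downstream of the raw test).
    """
    if group_labels is None:
        group_labels = cm.phase_labels()
    group_labels = group_labels.reindex(cm.sample_ids)
    sporo = np.flatnonzero((group_labels == SPOROPHYTE).to_numpy())
    gameto = np.flatnonzero((group_labels == GAMETOPHYTE).to_numpy())
    if len(sporo) < 2 or len(gameto) < 2:
        raise ValueError("each phase group needs at least two samples")

    counts = cm.counts.to_numpy(dtype=float)
    s = size_factors.reindex(cm.sample_ids).to_numpy(dtype=float)
    normalized = counts / s

    rows = []
    for g, gene in enumerate(cm.gene_ids):
        y = counts[g]
        z = normalized[g]
        alpha = _pooled_dispersion(z, [sporo, gameto])
        alpha = max(alpha, alpha_floor)
        q_s = _nb_group_mean(y[sporo], s[sporo], alpha)
        q_g = _nb_group_mean(y[gameto], s[gameto], alpha)
        log2fc = float(np.log2((q_s + PSEUDO_MEAN) / (q_g + PSEUDO_MEAN)))
        info_s = _fisher_info(q_s, s[sporo], alpha)
        info_g = _fisher_info(q_g, s[gameto], alpha)
        se = float(np.sqrt(1.0 / info_s + 1.0 / info_g) / np.log(2))
        wald_z = log2fc / se
        wald_p = float(2.0 * stats.norm.sf(abs(wald_z)))
        rows.append(
            {
                "gene_id": gene,
                "base_mean": float(z.mean()),
                "log2fc": log2fc,
                "se": se,
                "wald_p": wald_p,
            }
        )
    result = pd.DataFrame(rows)
    result["padj"] = bh_adjust(result["wald_p"].to_numpy())
    return result


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def mark_preferential(
    results: pd.DataFrame, lfc_threshold: float = 2.0, fdr: float = 0.05
) -> pd.DataFrame:
    results = results.copy()
    results["preferential"] = (results["padj"] <= fdr) & (
        results["log2fc"] >= lfc_threshold
    )
    return results


def preferential_sporophyte_set(
    results: pd.DataFrame, lfc_threshold: float = 2.0, fdr: float = 0.05
) -> set[str]:
    """Genes called preferentially sporophyte-expressed: padj <= fdr and
    log2fc >= lfc_threshold."""
    marked = mark_preferential(results, lfc_threshold, fdr)
    return set(marked.loc[marked["preferential"], "gene_id"])
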