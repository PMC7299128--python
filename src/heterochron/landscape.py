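"""Stage-level expression summaries: normalized stage means, per-gene
standardization, PCA over gene subsets, and the cross-species Spearman
divergence matrix over one-to-one orthologs."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .datamodel import CountMatrix, OrthologPair, SPOROPHYTE

MIN_PAIRS_PER_CELL = 3


def stage_means(cm: CountMatrix, size_factors: pd.Series) -> pd.DataFrame:
    """Per gene and sporophyte stage, the mean of count / size_factor over
    replicates.  Returns a genes x stages DataFrame with integer stage
    columns."""
    sporo = [s for s in cm.samples if s.phase == SPOROPHYTE]
    if not sporo:
        raise ValueError("no sporophyte samples")
    stages = sorted({s.stage_number for s in sporo})
    columns = {}
    for stage in stages:
        ids = [s.sample_id for s in sporo if s.stage_number == stage]
        norm = cm.counts[ids].to_numpy(dtype=float) / size_factors[ids].to_numpy()
        columns[stage] = norm.mean(axis=1)
    return pd.DataFrame(columns, index=cm.counts.index)


def standardize_profiles(
    stage_matrix: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Row-wise z-scores (mean 0, sd 1 with the n-1 denominator).

    Genes with zero variance across stages cannot be standardized; they are
    dropped and returned as the second element.
    """
    values = stage_matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    dropped = list(stage_matrix.index[~keep])
    z = (values[keep] - values[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(z, index=stage_matrix.index[keep], columns=stage_matrix.columns), dropped


@dataclass
class PCAResult:
    scores: pd.DataFrame  # observations x components
    loadings: np.ndarray  # components x variables
    variance_explained: np.ndarray  # fractions summing to 1 over all components


def pca(matrix: pd.DataFrame, gene_subset: Sequence[str] | None = None) -> PCAResult:
    """PCA by SVD of the column-centered observation x gene matrix.

    Rows are observations (samples or stages), columns are genes, optionally
    restricted to ``gene_subset`` before centering.
    """
    if gene_subset is not None:
        keep = [g for g in matrix.columns if g in set(gene_subset)]
        if not keep:
            raise ValueError("gene subset is empty after intersection")
        matrix = matrix[keep]
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least two observations")
    model = PCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy(dtype=float))
    columns = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=columns),
        loadings=model.components_,
        variance_explained=model.explained_variance_ratio_,
    )


def spearman_divergence(
    stage_matrix_a: pd.DataFrame,
    stage_matrix_b: pd.DataFrame,
    pairs: Sequence[OrthologPair],
    min_pairs: int = MIN_PAIRS_PER_CELL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-species expression divergence matrix.

    For each (stage_a, stage_b) cell: Spearman's rho over one-to-one
    orthologs whose stage-mean normalized expression is nonzero in both
    species at those stages, computed on log2(value + 1) with average ranks
    for ties.  Cells with fewer than ``min_pairs`` usable pairs are NaN.
    Returns (rho matrix, n-genes-per-cell matrix) with species-A stages as
    rows.
    """
    pairs = [
        p
        for p in pairs
        if p.gene_a in stage_matrix_a.index and p.gene_b in stage_matrix_b.index
    ]
    if not pairs:
        raise ValueError("no ortholog pair is present in both stage matrices")
    a = stage_matrix_a.loc[[p.gene_a for p in pairs]].to_numpy(dtype=float)
    b = stage_matrix_b.loc[[p.gene_b for p in pairs]].to_numpy(dtype=float)
    stages_a, stages_b = list(stage_matrix_a.columns), list(stage_matrix_b.columns)
    rho = pd.DataFrame(np.nan, index=stages_a, columns=stages_b, dtype=float)
    n_used = pd.DataFrame(0, index=stages_a, columns=stages_b, dtype=int)
    for i, sa in enumerate(stages_a):
        for j, sb in enumerate(stages_b):
            mask = (a[:, i] > 0) & (b[:, j] > 0)
            n = int(mask.sum())
            n_used.loc[sa, sb] = n
            if n < min_pairs:
                continue
            x = np.log2(a[mask, i] + 1.0)
            y = np.log2(b[mask, j] + 1.0)
            rho.loc[sa, sb] = float(stats.spearmanr(x, y).statistic)
    return rho, n_used
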