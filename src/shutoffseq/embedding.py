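"""Exploratory views: condition-wise L2FC matrix, informative-gene
clustering, PCA of transformed counts, and seed-fixed exact t-SNE.

All embeddings are deterministic given their seed and inputs, so figures and
coordinate tables regenerate identically.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from . import conditions as cond


def condition_l2fc_matrix(
    condition_means: pd.DataFrame, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Gene x condition log2 fold changes vs untreated from normalized
    condition means: ``log2((mean_c + c)/(mean_untreated + c))``.

    The untreated column (identically zero) is excluded from the output.
    """
    if cond.UNTREATED not in condition_means.columns:
        raise ValueError("condition means must include the untreated control")
    ref = condition_means[cond.UNTREATED].to_numpy() + pseudocount
    out = {}
    for c in condition_means.columns:
        if c == cond.UNTREATED:
            continue
        out[c] = np.log2((condition_means[c].to_numpy() + pseudocount) / ref)
    return pd.DataFrame(out, index=condition_means.index)


def informative_gene_filter(matrix: pd.DataFrame, sd_threshold: float = 0.5) -> pd.DataFrame:
    """Rows whose across-condition L2FC standard deviation strictly exceeds
    the threshold (sample SD, ddof=1)."""
    sd = matrix.std(axis=1, ddof=1)
    return matrix.loc[sd > sd_threshold]


def hierarchical_cluster(matrix: pd.DataFrame):
    """Complete-linkage agglomerative clustering of rows and columns
    (Euclidean distance).

    Returns ``(row_linkage, col_linkage, row_order, col_order)`` where the
    orders are leaf label lists. Ties merge lower-index clusters first
    (scipy's deterministic convention). Raises on NaNs.
    """
    if matrix.isna().any().any():
        raise ValueError("clustering input contains NaN")
    if len(matrix) < 1:
        raise ValueError("clustering needs >= 1 row")
    if len(matrix) == 1:
        return None, None, list(matrix.index), list(matrix.columns)
    row_link = hierarchy.linkage(pdist(matrix.to_numpy()), method="complete")
    row_order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    if matrix.shape[1] >= 2:
        col_link = hierarchy.linkage(pdist(matrix.to_numpy().T), method="complete")
        col_order = [matrix.columns[i] for i in hierarchy.leaves_list(col_link)]
    else:
        col_link, col_order = None, list(matrix.columns)
    return row_link, col_link, row_order, col_order


def pca_embed(
    normalized: pd.DataFrame, top_n: int = 500
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on variance-stabilized expression of the most varying
    genes.

    The transform is ``log2(normalized + 1)`` (a simple variance-stabilizing
    stand-in for a regularized log); the ``top_n`` genes by transformed
    variance across samples enter a centered SVD. Returns sample coordinates
    and per-PC variance fractions.
    """
    if normalized.shape[1] < 3:
        raise ValueError("PCA needs >= 3 samples")
    x = np.log2(normalized.to_numpy(dtype=float) + 1.0)
    var = x.var(axis=1)
    if top_n > len(var):
        warnings.warn(f"top_n={top_n} exceeds gene count {len(var)}; using all genes")
        top_n = len(var)
    idx = np.argsort(var, kind="stable")[::-1][:top_n]
    sub = x[idx].T  # samples x genes
    n_comp = min(sub.shape[0] - 1, sub.shape[1], 10)
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(sub - sub.mean(axis=0))
    table = pd.DataFrame(
        coords,
        index=normalized.columns,
        columns=[f"PC{i+1}" for i in range(coords.shape[1])],
    )
    return table, pca.explained_variance_ratio_


def tsne_embed(
    matrix: pd.DataFrame,
    seed: int = 102,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> pd.DataFrame:
    """Exact (non Barnes-Hut) t-SNE of genes in effect-L2FC space.

    Deterministic given ``seed``; duplicate rows are permitted (no
    de-duplication). Requires at least ``3 * perplexity`` rows, mirroring the
    usual guidance; with fewer candidates lower the perplexity.
    """
    n = len(matrix)
    if n < 3 * perplexity:
        raise ValueError(
            f"{n} candidates is too few for perplexity {perplexity}; lower the perplexity"
        )
    tsne = TSNE(
        n_components=2,
        method="exact",
        perplexity=perplexity,
        random_state=seed,
        init="pca",
        max_iter=n_iter,
    )
    coords = tsne.fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(coords, index=matrix.index, columns=["tsne1", "tsne2"])
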