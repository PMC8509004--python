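"""Pearson co-expression of a region's age-regulated genes.

The correlation matrix R holds the sample Pearson correlation of raw
expression values between every pair of age-regulated genes within one
region's samples.  For display, genes are ordered by agglomerative
average-linkage clustering on the distance d = 1 - R, so that genes sharing
an age trajectory (e.g. all upregulated genes) appear as contiguous blocks.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data_io import ExpressionMatrix, as_samples_frame

log = logging.getLogger(__name__)


def pearson_matrix(
    matrix: ExpressionMatrix, samples, genes, region: str
) -> pd.DataFrame:
    """Pearson correlation matrix of ``genes`` over one region's samples.

    Genes with zero variance across the region's samples are dropped with a
    warning (a correlation is undefined for them).

    Raises
    ------
    ValueError
        If fewer than two usable genes remain.
    """
    sf = as_samples_frame(samples)
    ids = sf.loc[sf["region"] == region, "sample_id"].tolist()
    if not ids:
        raise ValueError(f"no samples in region {region!r}")
    genes = list(genes)
    sub = matrix.data.loc[genes, ids].to_numpy(dtype=float)
    variances = sub.var(axis=1)
    keep = variances > 0.0
    if not keep.all():
        dropped = [g for g, k in zip(genes, keep) if not k]
        log.warning(
            "dropping %d zero-variance genes from correlation: %s",
            len(dropped), dropped[:5],
        )
    usable = [g for g, k in zip(genes, keep) if k]
    if len(usable) < 2:
        raise ValueError("need at least 2 genes with nonzero variance")
    R = np.corrcoef(sub[keep])
    np.fill_diagonal(R, 1.0)
    return pd.DataFrame(R, index=usable, columns=usable)


def _leaf_score(R: np.ndarray) -> np.ndarray:
    # data-dependent orientation key: total correlation of each gene
    return R.sum(axis=1)


def cluster_order(R: pd.DataFrame | np.ndarray) -> list:
    """Display order of genes from average-linkage clustering on d = 1 - R.

    The dendrogram is traversed with a data-dependent orientation: at each
    internal node the child with the larger mean leaf score (total
    correlation) comes first, ties broken by smallest original index.  This
    makes the order equivariant under relabelling of the input genes.
    Returns gene labels if ``R`` is a DataFrame, else integer indices.
    """
    if isinstance(R, pd.DataFrame):
        labels = list(R.index)
        values = R.to_numpy(dtype=float)
    else:
        values = np.asarray(R, dtype=float)
        labels = list(range(values.shape[0]))
    n = values.shape[0]
    if n == 1:
        return labels
    dist = 1.0 - values
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    score = _leaf_score(values)

    # leaves of each cluster id, in canonical orientation
    leaves: dict[int, list[int]] = {i: [i] for i in range(n)}
    for k, (a, b, _, _) in enumerate(Z):
        ca, cb = leaves.pop(int(a)), leaves.pop(int(b))
        key_a = (-float(np.mean(score[ca])), min(ca))
        key_b = (-float(np.mean(score[cb])), min(cb))
        merged = ca + cb if key_a <= key_b else cb + ca
        leaves[n + k] = merged
    order = leaves[n + len(Z) - 1]
    return [labels[i] for i in order]


def reorder(R: pd.DataFrame, order) -> pd.DataFrame:
    """Apply a display order to both axes of a correlation matrix."""
    return R.loc[order, order]


def write_correlation(R: pd.DataFrame, path) -> Path:
    """Write a square correlation matrix as TSV with gene header row/col."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    R.to_csv(path, sep="\t", index_label="gene")
    return path
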