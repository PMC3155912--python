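"""Expression preprocessing, differential expression, ranking, clustering.

All statistics operate on :class:`~cnadose.formats.ExpressionMatrix`
objects holding log2 signal.  Two-group comparisons use the Welch
(unequal-variance) t-test; multiple testing is controlled with
Benjamini-Hochberg q-values.  The ranking metric for enrichment is the
GSEA-convention signal-to-noise ratio with a per-group standard-deviation
floor.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionMatrix

__all__ = [
    "quantile_normalize",
    "filter_low_expression",
    "differential_expression",
    "select_significant",
    "signal_to_noise_ranking",
    "cluster_samples",
]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the shared reference distribution given by
    the row means of the column-sorted matrix.

    After normalization each column's sorted values equal that reference
    vector exactly, so all samples share one empirical distribution.  Ties
    within a column are assigned reference values in stable (input-order)
    sequence rather than averaged, which keeps the sorted-columns-identical
    invariant exact.
    """
    if matrix.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = matrix.values.to_numpy(dtype=float)
    order = np.argsort(x, axis=0, kind="stable")
    reference = np.mean(np.take_along_axis(x, order, axis=0), axis=1)
    out = np.empty_like(x)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(x.shape[0])[:, None], axis=0)
    out = reference[ranks]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.annotations)


def filter_low_expression(matrix: ExpressionMatrix,
                          discard_fraction: float = 0.25) -> ExpressionMatrix:
    """Drop the ``discard_fraction`` of genes with the lowest mean signal.

    The default removes the lowest quartile, the conventional "not reliably
    expressed" filter for tumor arrays.  Nearest-rank semantics: with n
    genes, exactly floor(discard_fraction * n) genes are removed; ties on
    the mean are broken by gene_id so the result is deterministic.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    n = matrix.n_genes
    n_drop = int(math.floor(discard_fraction * n))
    if n_drop == 0:
        return matrix
    if n_drop >= n:
        raise ValueError("filter would remove every gene")
    means = matrix.values.mean(axis=1)
    order = sorted(matrix.gene_ids, key=lambda g: (means[g], g))
    keep = set(order[n_drop:])
    kept_ids = [g for g in matrix.gene_ids if g in keep]
    if not kept_ids:
        raise ValueError("filter would remove every gene")
    return matrix.subset_genes(kept_ids)


def _group_arrays(matrix: ExpressionMatrix, group_a: Sequence[str],
                  group_b: Sequence[str], min_per_group: int = 2
                  ) -> tuple[np.ndarray, np.ndarray]:
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if len(group_a) < min_per_group or len(group_b) < min_per_group:
        raise ValueError(f"each group needs at least {min_per_group} samples")
    a = matrix.values[group_a].to_numpy(dtype=float)
    b = matrix.values[group_b].to_numpy(dtype=float)
    return a, b


def differential_expression(matrix: ExpressionMatrix, group_a: Sequence[str],
                            group_b: Sequence[str]) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups.

    Returns a DataFrame indexed by gene_id with columns ``mean_a, mean_b,
    log2_fc, t, p, q`` where ``log2_fc = mean_a - mean_b`` (signals are
    log2, so the difference of means is the log2 fold change) and ``q`` is
    the Benjamini-Hochberg adjusted p-value over all tested genes.

    Degenerate genes: equal means with zero variance in both groups give
    t = 0, p = 1; unequal means with (near-)zero variance are handled with
    a machine-epsilon-scaled variance floor instead of reporting p = 0.
    """
    a, b = _group_arrays(matrix, group_a, group_b)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    scale = np.abs(np.concatenate([mean_a, mean_b])).mean() + 1.0
    floor = np.finfo(float).eps * scale**2
    var_a = np.maximum(var_a, floor)
    var_b = np.maximum(var_b, floor)

    se2 = var_a / na + var_b / nb
    t = (mean_a - mean_b) / np.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / ((var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # identical groups: define t = 0, p = 1 exactly
    same = (mean_a == mean_b)
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_fc": mean_a - mean_b,
            "t": t,
            "p": p,
            "q": q,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )


def select_significant(table: pd.DataFrame, q_max: float = 0.05,
                       min_abs_log2_fc: float = 0.6) -> dict[str, list[str]]:
    """Split a differential-expression table into up/down gene lists.

    ``up`` holds genes with q < q_max and log2_fc > min_abs_log2_fc; ``down``
    mirrors it at log2_fc < -min_abs_log2_fc.  The fold-change gate is
    applied symmetrically, so the two lists are disjoint by construction.
    """
    if q_max <= 0 or min_abs_log2_fc <= 0:
        raise ValueError("thresholds must be positive")
    sig = table["q"] < q_max
    up = table.index[sig & (table["log2_fc"] > min_abs_log2_fc)].tolist()
    down = table.index[sig & (table["log2_fc"] < -min_abs_log2_fc)].tolist()
    return {"up": up, "down": down}


def signal_to_noise_ranking(matrix: ExpressionMatrix, group_a: Sequence[str],
                            group_b: Sequence[str],
                            sd_floor_fraction: float = 0.2) -> pd.Series:
    """Rank genes by the signal-to-noise ratio between two groups.

    metric = (mean_a - mean_b) / (sd_a + sd_b), with each group's standard
    deviation floored at ``sd_floor_fraction * |group mean|`` (and at
    ``sd_floor_fraction`` itself when the mean is zero) following the usual
    GSEA convention.  Positive metric means higher in ``group_a``.  Returns
    a Series indexed by gene_id sorted descending, ties broken by gene_id.
    """
    a, b = _group_arrays(matrix, group_a, group_b)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = a.std(axis=1, ddof=1)
    sd_b = b.std(axis=1, ddof=1)

    def _floor(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
        lo = sd_floor_fraction * np.abs(mean)
        lo = np.where(lo == 0.0, sd_floor_fraction, lo)
        return np.maximum(sd, lo)

    metric = (mean_a - mean_b) / (_floor(sd_a, mean_a) + _floor(sd_b, mean_b))
    s = pd.Series(metric, index=pd.Index(matrix.gene_ids, name="gene_id"),
                  name="metric")
    order = sorted(s.index, key=lambda g: (-s[g], g))
    return s.loc[order]


def _linkage_to_newick(node: hierarchy.ClusterNode, labels: list[str]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _linkage_to_newick(node.left, labels)
    right = _linkage_to_newick(node.right, labels)
    bl_left = node.dist - node.left.dist
    bl_right = node.dist - node.right.dist
    return f"({left}:{bl_left:.6g},{right}:{bl_right:.6g})"


def cluster_samples(matrix: ExpressionMatrix, top_fraction: float = 0.75) -> str:
    """Hierarchically cluster samples on the most expressed genes.

    Genes are restricted to the top ``top_fraction`` by mean signal (the
    complement of the low-expression filter), sample distance is
    1 - Pearson correlation, and merging uses average linkage.  Returns a
    Newick string with branch lengths equal to differences of merge
    heights, so leaf-to-root distance reproduces each sample's merge
    height.
    """
    if matrix.n_samples < 3:
        raise ValueError("clustering needs at least 3 samples")
    sub = filter_low_expression(matrix, 1.0 - top_fraction)
    x = sub.values.to_numpy(dtype=float)
    sds = x.std(axis=0)
    for sd, sample in zip(sds, sub.sample_ids):
        if sd == 0.0:
            raise ValueError(f"sample '{sample}' is constant; correlation undefined")
    dist = 1.0 - np.corrcoef(x.T)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    tree = hierarchy.to_tree(link)
    return _linkage_to_newick(tree, sub.sample_ids) + ";"
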