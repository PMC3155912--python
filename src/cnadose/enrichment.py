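"""GSEA-style weighted running-sum enrichment with a permutation null.

A gene set is tested for concentration at either end of a ranked gene
list.  Walking the ranking, the running sum rises by
``|metric|^p / sum_set |metric|^p`` at set members and falls by
``1/(N - |set|)`` at non-members; the enrichment score (ES) is the
extremum of this walk by absolute value.  The null distribution of ES
comes from permutations — random same-size gene sets by default, or
re-shuffled phenotype labels — and yields the normalized score
(NES = ES / mean |null ES| of the matching sign), a nominal p-value, and a
sign-stratified FDR q computed from the pooled null-vs-observed NES
distributions.

Positional gene sets (one set per chromosome, arm, or cytoband) let the
same machinery detect coordinated regulation of genomic loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .expression import signal_to_noise_ranking
from .formats import ExpressionMatrix, GeneModelSet, GeneSetCollection

__all__ = [
    "EnrichmentResult",
    "enrichment_score",
    "gsea",
    "gsea_from_ranking",
    "positional_gene_sets",
]


# ---------------------------------------------------------------------------
# enrichment score


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, n_total: int
                       ) -> tuple[float, int]:
    """ES and extremum hit index from sorted 0-based hit positions.

    ``weights`` are the (already powered) |metric| weights at those
    positions, in ranking order.  Returns (es, t_star) where t_star indexes
    the hit at which the extremum is attained (for the leading edge).  The
    walk's extremes can only occur immediately after a hit (candidate
    maxima) or immediately before one (candidate minima), which makes the
    computation O(k) instead of O(N).
    """
    k = len(pos)
    n_miss = n_total - k
    if n_miss == 0:
        raise ValueError("gene set equals the whole ranked universe")
    nr = weights.sum()
    if nr == 0.0:
        # all-zero metric weights: fall back to equal hit increments
        hit_cum = np.arange(1, k + 1) / k
    else:
        hit_cum = np.cumsum(weights) / nr
    miss = 1.0 / n_miss
    # value right after hit t (1-based t): hit_cum[t-1] - (pos[t-1]+1-t)*miss
    t_idx = np.arange(1, k + 1)
    after = hit_cum - (pos + 1 - t_idx) * miss
    # value right before hit t: hit_cum[t-2] (0 for t=1) - (pos[t-1]-(t-1))*miss
    before = np.concatenate(([0.0], hit_cum[:-1])) - (pos - (t_idx - 1)) * miss
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    es_pos = float(after[i_max])
    es_neg = float(before[i_min])
    if abs(es_pos) >= abs(es_neg):
        return es_pos, i_max
    return es_neg, i_min


def enrichment_score(ranked: pd.Series, gene_set: Sequence[str],
                     weight_exponent: float = 1.0,
                     return_running_sum: bool = False) -> dict:
    """Weighted Kolmogorov-Smirnov-like enrichment of one gene set.

    ``ranked`` is a metric Series indexed by gene_id, sorted descending.
    Returns a dict with ``es``, ``leading_edge`` (set members at or before
    the extremum for positive ES, at or after it for negative ES) and,
    optionally, the full ``running_sum`` walk for plotting.
    """
    genes = ranked.index.to_numpy()
    n = len(genes)
    members = set(gene_set)
    hit_mask = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    pos = np.flatnonzero(hit_mask)
    if len(pos) == 0:
        raise ValueError("gene set has empty intersection with the ranked universe")
    if len(pos) == n:
        raise ValueError("gene set equals the whole ranked universe")
    metric = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    weights = metric[pos]
    es, t_star = _es_from_positions(pos, weights, n)
    if es >= 0:
        leading = [genes[p] for p in pos[: t_star + 1]]
    else:
        leading = [genes[p] for p in pos[t_star:]]
    out = {"es": es, "leading_edge": leading}
    if return_running_sum:
        nr = weights.sum()
        steps = np.where(
            hit_mask,
            (metric / nr) if nr > 0 else (hit_mask / hit_mask.sum()),
            -1.0 / (n - len(pos)),
        )
        out["running_sum"] = np.cumsum(steps)
    return out


# ---------------------------------------------------------------------------
# permutation machinery


def _null_es_gene_set(perm_orders: np.ndarray, k: int, metric_abs: np.ndarray
                      ) -> np.ndarray:
    """Null ES for random size-k sets drawn via shared permutation orders.

    ``perm_orders`` is (n_perm, N) of permuted rank indices; the first k
    entries of each row are a uniform random size-k subset of ranks.
    """
    n_perm, n = perm_orders.shape
    pos = np.sort(perm_orders[:, :k], axis=1)
    w = metric_abs[pos]
    out = np.empty(n_perm)
    for b in range(n_perm):
        out[b], _ = _es_from_positions(pos[b], w[b], n)
    return out


@dataclass
class EnrichmentResult:
    """Per-set enrichment table plus the ranking it was computed against."""

    table: pd.DataFrame
    ranking: pd.Series

    def __getitem__(self, set_name: str) -> pd.Series:
        return self.table.loc[set_name]


def _nes_p_fdr(observed: dict[str, float], nulls: dict[str, np.ndarray]
               ) -> tuple[dict, dict, dict]:
    """NES, nominal p and sign-stratified FDR q from per-set null ES.

    NES normalizes each ES by the mean |null ES| of its sign (from its own
    set's null).  FDR follows the standard sign-stratified ratio: for a set
    with NES*, q = (fraction of pooled null NES at least as extreme, same
    sign) / (fraction of observed NES at least as extreme, same sign),
    clipped to [0, 1].
    """
    nes: dict[str, float] = {}
    p_nom: dict[str, float] = {}
    null_nes_pool: list[np.ndarray] = []
    for name, es in observed.items():
        null = nulls[name]
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        if es >= 0:
            denom = pos_mean if np.isfinite(pos_mean) else np.abs(null).mean()
            same = null[null >= 0]
            p = float((same >= es).sum() / max(len(same), 1))
        else:
            denom = neg_mean if np.isfinite(neg_mean) else np.abs(null).mean()
            same = null[null < 0]
            p = float((same <= es).sum() / max(len(same), 1))
        if not np.isfinite(denom) or denom == 0.0:
            denom = 1.0
        nes[name] = es / denom
        p_nom[name] = p
        # normalize this set's null the same way for the FDR pool
        nn = np.where(
            null >= 0,
            null / (pos_mean if np.isfinite(pos_mean) and pos_mean > 0 else 1.0),
            null / (neg_mean if np.isfinite(neg_mean) and neg_mean > 0 else 1.0),
        )
        null_nes_pool.append(nn)
    pool = np.concatenate(null_nes_pool)
    obs = np.array(list(nes.values()))
    fdr: dict[str, float] = {}
    for name, v in nes.items():
        if v >= 0:
            null_frac = (pool >= v).sum() / max((pool >= 0).sum(), 1)
            obs_frac = (obs >= v).sum() / max((obs >= 0).sum(), 1)
        else:
            null_frac = (pool <= v).sum() / max((pool < 0).sum(), 1)
            obs_frac = (obs <= v).sum() / max((obs < 0).sum(), 1)
        fdr[name] = float(min(1.0, null_frac / obs_frac)) if obs_frac > 0 else 1.0
    return nes, p_nom, fdr


def gsea_from_ranking(ranked: pd.Series, sets: GeneSetCollection,
                      n_perm: int = 1000, seed: int | None = None,
                      min_size: int = 5, max_size: int = 500,
                      weight_exponent: float = 1.0) -> EnrichmentResult:
    """Gene-set-permutation enrichment against a precomputed ranking.

    The null for a set of (intersected) size k is the ES of random size-k
    subsets of the ranked universe; one pool of ``n_perm`` permuted rank
    orders is shared across sets so the run scales with the number of
    distinct set sizes, not sets.
    """
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = len(genes)
    metric_abs = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    gene_pos = {g: i for i, g in enumerate(genes)}

    used: dict[str, np.ndarray] = {}
    for name in sets.names():
        pos = np.sort([gene_pos[g] for g in set(sets[name]) if g in gene_pos])
        if min_size <= len(pos) <= max_size and len(pos) < n:
            used[name] = np.asarray(pos, dtype=np.int64)
    if not used:
        raise ValueError("no gene set within the size bounds after intersection")

    perm_orders = np.argsort(rng.random((n_perm, n)), axis=1)
    observed: dict[str, float] = {}
    leading: dict[str, list[str]] = {}
    nulls: dict[str, np.ndarray] = {}
    null_by_size: dict[int, np.ndarray] = {}
    for name, pos in used.items():
        es, t_star = _es_from_positions(pos, metric_abs[pos], n)
        observed[name] = es
        if es >= 0:
            leading[name] = [genes[p] for p in pos[: t_star + 1]]
        else:
            leading[name] = [genes[p] for p in pos[t_star:]]
        k = len(pos)
        if k not in null_by_size:
            null_by_size[k] = _null_es_gene_set(perm_orders, k, metric_abs)
        nulls[name] = null_by_size[k]

    nes, p_nom, fdr = _nes_p_fdr(observed, nulls)
    table = pd.DataFrame(
        {
            "size": {name: len(pos) for name, pos in used.items()},
            "es": observed,
            "nes": nes,
            "p_nominal": p_nom,
            "fdr_q": fdr,
            "leading_edge": {k: ",".join(v) for k, v in leading.items()},
        }
    )
    table.index.name = "set"
    return EnrichmentResult(table, ranked)


def gsea(matrix: ExpressionMatrix, group_a: Sequence[str], group_b: Sequence[str],
         sets: GeneSetCollection, n_perm: int = 1000,
         mode: str = "gene_set", seed: int | None = None,
         min_size: int = 5, max_size: int = 500,
         weight_exponent: float = 1.0) -> EnrichmentResult:
    """Enrichment of gene sets in a two-group expression comparison.

    Genes are ranked by the signal-to-noise metric (positive = higher in
    ``group_a``).  ``mode='gene_set'`` (default) draws random same-size
    sets for the null — appropriate for the small group sizes typical of
    xenograft designs, where distinct phenotype relabelings are too few.
    ``mode='phenotype'`` reshuffles group labels and recomputes the ranking
    for each permutation; prefer it with >= 7 samples per group.
    """
    ranked = signal_to_noise_ranking(matrix, group_a, group_b)
    if mode == "gene_set":
        return gsea_from_ranking(ranked, sets, n_perm=n_perm, seed=seed,
                                 min_size=min_size, max_size=max_size,
                                 weight_exponent=weight_exponent)
    if mode != "phenotype":
        raise ValueError(f"unknown permutation mode '{mode}'")
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("phenotype mode needs >= 2 samples per group")
    rng = np.random.default_rng(seed)
    genes = ranked.index.to_numpy()
    n = len(genes)
    metric_abs = np.abs(ranked.to_numpy(dtype=float)) ** weight_exponent
    gene_pos = {g: i for i, g in enumerate(genes)}
    used: dict[str, np.ndarray] = {}
    for name in sets.names():
        pos = np.sort([gene_pos[g] for g in set(sets[name]) if g in gene_pos])
        if min_size <= len(pos) <= max_size and len(pos) < n:
            used[name] = np.asarray(pos, dtype=np.int64)
    if not used:
        raise ValueError("no gene set within the size bounds after intersection")
    member_ids = {name: [genes[p] for p in pos] for name, pos in used.items()}

    observed: dict[str, float] = {}
    leading: dict[str, list[str]] = {}
    for name, pos in used.items():
        es, t_star = _es_from_positions(pos, metric_abs[pos], n)
        observed[name] = es
        leading[name] = ([genes[p] for p in pos[: t_star + 1]] if es >= 0
                         else [genes[p] for p in pos[t_star:]])

    all_samples = group_a + group_b
    na = len(group_a)
    nulls = {name: np.empty(n_perm) for name in used}
    for b in range(n_perm):
        shuffled = list(rng.permutation(all_samples))
        perm_rank = signal_to_noise_ranking(matrix, shuffled[:na], shuffled[na:])
        perm_genes = perm_rank.index.to_numpy()
        perm_abs = np.abs(perm_rank.to_numpy(dtype=float)) ** weight_exponent
        ppos = {g: i for i, g in enumerate(perm_genes)}
        for name, members in member_ids.items():
            pos = np.sort([ppos[g] for g in members])
            nulls[name][b], _ = _es_from_positions(pos, perm_abs[pos], n)

    nes, p_nom, fdr = _nes_p_fdr(observed, nulls)
    table = pd.DataFrame(
        {
            "size": {name: len(pos) for name, pos in used.items()},
            "es": observed,
            "nes": nes,
            "p_nominal": p_nom,
            "fdr_q": fdr,
            "leading_edge": {k: ",".join(v) for k, v in leading.items()},
        }
    )
    table.index.name = "set"
    return EnrichmentResult(table, ranked)


# ---------------------------------------------------------------------------
# positional sets


def _arm_of(cytoband: str, chrom: str) -> str:
    band = cytoband
    for arm_char in ("p", "q"):
        if arm_char in band:
            return f"{chrom}{arm_char}"
    return chrom


def positional_gene_sets(genes: GeneModelSet, level: str = "cytoband"
                         ) -> GeneSetCollection:
    """One gene set per genomic locus at the requested granularity.

    ``level`` is ``chromosome``, ``arm`` (cytoband labels split at the
    p/q character) or ``cytoband`` (chrom + band label, e.g. ``17q12``).
    Loci without genes are simply absent.
    """
    df = genes.genes
    if level == "chromosome":
        labels = df["chrom"]
    elif level in ("arm", "cytoband"):
        if (df["cytoband"] == "").all():
            raise ValueError(f"level='{level}' requires cytoband annotations")
        if level == "cytoband":
            labels = df["chrom"].str.replace("chr", "", regex=False) + df["cytoband"]
        else:
            labels = pd.Series(
                [_arm_of(b, c) for b, c in zip(df["cytoband"], df["chrom"])],
                index=df.index,
            )
    else:
        raise ValueError(f"unknown level '{level}'")
    sets: dict[str, list[str]] = {}
    for label, grp in df.groupby(labels, sort=False):
        if label == "":
            continue
        sets[str(label)] = grp["gene_id"].tolist()
    descriptions = {name: f"positional set ({level})" for name in sets}
    return GeneSetCollection(sets, descriptions)
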