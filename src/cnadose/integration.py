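"""Copy-number / expression integration.

Builds the expression-concordant CNA gene sets — amplified genes (gene
copy score above +0.3 in log10) that are also highly expressed, and
copy-loss genes (score below -0.3) with concordantly low expression — and
tests whether treatment preferentially moves them, by enriching the sets
against the treated-vs-naive signal-to-noise ranking.  Amplified,
dosage-driven genes that a drug down-regulates (negative gain-set
enrichment) are candidate tumor-maintenance drivers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import EnrichmentResult, enrichment_score, gsea_from_ranking
from .expression import signal_to_noise_ranking
from .formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "CnaGeneSets",
    "build_cna_gene_sets",
    "IntegrationReport",
    "run_integration",
    "candidate_driver_table",
]

logger = logging.getLogger(__name__)

GAIN_SET = "copy_gain_high_expression"
LOSS_SET = "copy_loss_low_expression"


@dataclass
class CnaGeneSets:
    """Copy-gain and copy-loss gene sets with the thresholds that built them."""

    gain: list[str]
    loss: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.gain) & set(self.loss):
            raise ValueError("gain and loss sets must be disjoint")

    def to_collection(self) -> GeneSetCollection:
        """Non-empty sets as a GeneSetCollection; provenance goes in the
        description field so exported GMTs are self-documenting."""
        desc = "; ".join(f"{k}={v}" for k, v in sorted(self.provenance.items()))
        sets, descriptions = {}, {}
        for name, members in ((GAIN_SET, self.gain), (LOSS_SET, self.loss)):
            if members:
                sets[name] = list(members)
                descriptions[name] = desc
        if not sets:
            raise ValueError("both CNA gene sets are empty")
        return GeneSetCollection(sets, descriptions)


def _nearest_rank_cutoff(sorted_values: np.ndarray, quantile: float) -> float:
    n = len(sorted_values)
    idx = max(int(np.ceil(quantile * n)) - 1, 0)
    return float(sorted_values[idx])


def build_cna_gene_sets(copy: pd.DataFrame, matrix: ExpressionMatrix,
                        gain_threshold: float = 0.3,
                        loss_threshold: float = -0.3,
                        high_expr_quantile: float = 0.75,
                        low_expr_quantile: float = 0.25,
                        expression_samples: Sequence[str] | None = None,
                        ) -> CnaGeneSets:
    """Select copy-gain / copy-loss genes with concordant expression.

    ``copy`` is a gene copy table (index gene_id, column
    ``mean_log10_ratio``); ``matrix`` should already be normalized and
    low-expression filtered, so the quantile gates refer to *expressed*
    genes.  gain = copy score > ``gain_threshold`` and mean expression at
    or above the ``high_expr_quantile`` nearest-rank quantile; loss
    mirrors it below ``loss_threshold`` / at or below the
    ``low_expr_quantile``.  Genes absent from either table are dropped
    with a logged count (array designs differ).
    """
    if not (loss_threshold < 0.0 < gain_threshold):
        raise ValueError("need loss_threshold < 0 < gain_threshold")
    for q in (high_expr_quantile, low_expr_quantile):
        if not 0.0 < q < 1.0:
            raise ValueError("expression quantiles must be in (0, 1)")
    if len(copy) == 0:
        raise ValueError("gene copy table is empty")
    samples = (list(expression_samples) if expression_samples is not None
               else [s for s in matrix.sample_ids
                     if not bool(matrix.annotations.loc[s, "excluded"])])
    mean_expr = matrix.values[samples].mean(axis=1)
    shared = [g for g in copy.index if g in mean_expr.index]
    dropped = len(copy) - len(shared)
    if dropped:
        logger.info("dropped %d copy-scored genes absent from the expression "
                    "matrix", dropped)
    sorted_means = np.sort(mean_expr.to_numpy())
    hi_cut = _nearest_rank_cutoff(sorted_means, high_expr_quantile)
    lo_cut = _nearest_rank_cutoff(sorted_means, low_expr_quantile)
    score = copy.loc[shared, "mean_log10_ratio"]
    expr = mean_expr.loc[shared]
    gain = sorted(score.index[(score > gain_threshold) & (expr >= hi_cut)])
    loss = sorted(score.index[(score < loss_threshold) & (expr <= lo_cut)])
    provenance = {
        "gain_threshold": gain_threshold,
        "loss_threshold": loss_threshold,
        "high_expr_quantile": high_expr_quantile,
        "low_expr_quantile": low_expr_quantile,
        "expression_samples": ",".join(samples),
        "n_gain": len(gain),
        "n_loss": len(loss),
    }
    for name, members in (("gain", gain), ("loss", loss)):
        if not members:
            logger.warning("%s set is empty and will be omitted downstream", name)
    return CnaGeneSets(gain=list(gain), loss=list(loss), provenance=provenance)


@dataclass
class IntegrationReport:
    """Everything one integration run produced."""

    cna_sets: CnaGeneSets
    enrichment: EnrichmentResult
    ranking: pd.Series
    running_sums: dict[str, np.ndarray]
    params: dict


def run_integration(matrix: ExpressionMatrix, treated: Sequence[str],
                    naive: Sequence[str], copy: pd.DataFrame,
                    gain_threshold: float = 0.3, loss_threshold: float = -0.3,
                    high_expr_quantile: float = 0.75,
                    low_expr_quantile: float = 0.25,
                    n_perm: int = 1000, seed: int | None = None,
                    min_size: int = 5, max_size: int = 500,
                    weight_exponent: float = 1.0) -> IntegrationReport:
    """Rank genes treated-vs-naive and enrich the CNA gene sets.

    The ranking metric is positive for genes higher in treated tumors, so
    a drug that shuts down dosage-driven amplified genes yields a negative
    gain-set enrichment and a positive loss-set enrichment.  Returns the
    per-set enrichment table (ES, NES, nominal p, FDR q, leading edge), the
    ranking, and the running-sum traces for plotting.
    """
    ranking = signal_to_noise_ranking(matrix, treated, naive)
    cna_sets = build_cna_gene_sets(
        copy, matrix, gain_threshold=gain_threshold,
        loss_threshold=loss_threshold, high_expr_quantile=high_expr_quantile,
        low_expr_quantile=low_expr_quantile,
    )
    collection = cna_sets.to_collection()
    enr = gsea_from_ranking(
        ranking, collection, n_perm=n_perm, seed=seed, min_size=min_size,
        max_size=max_size, weight_exponent=weight_exponent,
    )
    running = {}
    for name in enr.table.index:
        running[name] = enrichment_score(
            ranking, collection[name], weight_exponent=weight_exponent,
            return_running_sum=True,
        )["running_sum"]
    params = {
        "gain_threshold": gain_threshold,
        "loss_threshold": loss_threshold,
        "high_expr_quantile": high_expr_quantile,
        "low_expr_quantile": low_expr_quantile,
        "n_perm": n_perm,
        "seed": seed,
        "min_size": min_size,
        "max_size": max_size,
        "weight_exponent": weight_exponent,
        "treated": ",".join(treated),
        "naive": ",".join(naive),
    }
    return IntegrationReport(cna_sets=cna_sets, enrichment=enr,
                             ranking=ranking, running_sums=running,
                             params=params)


def candidate_driver_table(report: IntegrationReport, de_table: pd.DataFrame,
                           copy: pd.DataFrame) -> pd.DataFrame:
    """Join CNA-set members with their differential-expression evidence.

    One row per tested CNA-set gene: copy score, log2 fold change, q-value
    and a leading-edge membership flag, sorted leading-edge genes first and
    then by |log2_fc| descending — amplified-but-down-regulated leading-edge
    genes top the list as the candidate drivers.  Purely a deterministic
    join; a gene universe mismatch (set member missing from the DE or copy
    tables) is an error.
    """
    rows = []
    table = report.enrichment.table
    for set_name in table.index:
        members = set(table.loc[set_name, "leading_edge"].split(","))
        all_members = (report.cna_sets.gain if set_name == GAIN_SET
                       else report.cna_sets.loss)
        in_universe = [g for g in all_members if g in report.ranking.index]
        missing = [g for g in in_universe
                   if g not in de_table.index or g not in copy.index]
        if missing:
            raise ValueError(f"gene universe mismatch; offenders: {missing[:10]}")
        for g in in_universe:
            rows.append(
                {
                    "gene_id": g,
                    "set": set_name,
                    "copy_score": float(copy.loc[g, "mean_log10_ratio"]),
                    "log2_fc": float(de_table.loc[g, "log2_fc"]),
                    "q": float(de_table.loc[g, "q"]),
                    "leading_edge": g in members,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["gene_id", "set", "copy_score", "log2_fc", "q",
                     "leading_edge"]
        ).set_index("gene_id")
    df = pd.DataFrame(rows)
    df["abs_fc"] = df["log2_fc"].abs()
    df = df.sort_values(
        by=["leading_edge", "abs_fc", "gene_id"],
        ascending=[False, False, True], kind="stable",
    ).drop(columns="abs_fc")
    return df.set_index("gene_id")
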