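import numpy as np
import pandas as pd
import pytest

from cnadose.formats import ExpressionMatrix, ProbeTrack
from cnadose.simulate import (
    simulate_expression,
    simulate_genome,
    simulate_probe_track,
)


def make_matrix(values, sample_ids=None, gene_ids=None, groups=None):
    """Small ExpressionMatrix from a 2-D array; groups default to 'a'."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    groups = groups or ["a"] * n_samples
    ann = pd.DataFrame(
        {"group": groups, "day": 8, "replicate": "A", "excluded": False},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=sample_ids)
    return ExpressionMatrix(df, ann)


def make_track(chrom, starts, ratios, width=50):
    df = pd.DataFrame(
        {
            "chrom": chrom if isinstance(chrom, list) else [chrom] * len(starts),
            "start": starts,
            "end": [s + width for s in starts],
            "ratio": ratios,
        }
    )
    return ProbeTrack(df)


@pytest.fixture(scope="session")
def small_truth():
    """Reduced-scale simulated study shared by unit tests."""
    truth = simulate_genome(n_chrom=2, genes_per_chrom=250,
                            probes_per_chrom=900, n_cna_segments=2,
                            cna_genes_min=20, cna_genes_max=25, seed=11)
    return truth


@pytest.fixture(scope="session")
def small_track(small_truth):
    return simulate_probe_track(small_truth, seed=12)


@pytest.fixture(scope="session")
def small_expression(small_truth, small_track):
    return simulate_expression(small_truth, seed=13)
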