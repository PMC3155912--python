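"""Synthetic xenograft data: genome, copy-number truth, probes, expression.

The generator emulates the structure of a small treated-vs-naive tumor
xenograft study profiled on expression and aCGH arrays:

* a genome of a few chromosomes tiled with non-overlapping genes, with
  segmental copy-number aberrations whose log10 states sit in the ranges
  typical of single-copy gain/loss in a near-diploid line
  (+0.3 to +0.6 and -0.5 to -0.3);
* probe-level log10 ratios with Gaussian noise and occasional single-probe
  hybridization outliers;
* log2 expression partly driven by gene dosage, a two-arm design of 5-6
  tumors per arm, and a treatment effect that preferentially down-regulates
  amplified/high-expressed genes and up-regulates copy-loss genes.

Everything is deterministic under a fixed seed, and every generated object
passes the validators in :mod:`cnadose.formats`.

Scale note: CNA segments are kept short relative to each chromosome (well
under 2.5% of its probes per sign) so that the outlier-smoothing step's
trimmed dispersion estimate reflects probe noise rather than the
aberrations themselves — the regime the smoothing method assumes, and a
fair mimic of a cell line with a modest CNA burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import ExpressionMatrix, GeneModelSet, ProbeTrack

__all__ = [
    "SimulationTruth",
    "simulate_genome",
    "simulate_probe_track",
    "simulate_expression",
]

LOG2_PER_LOG10 = float(np.log2(10.0))  # expression lives on log2, copy on log10

_GENE_WIDTH = 10_000
_GENE_GAP = 1_000
_PROBE_WIDTH = 60
_BAND_GENES = 75  # genes per simulated cytoband


@dataclass
class SimulationTruth:
    """Ground truth of one simulated study.

    ``genes`` holds per-gene coordinates, log10 copy state (0 = neutral),
    dosage coupling, treatment shift and the driver flag (gene planted as a
    drug-responsive CNA gene: non-neutral copy state with a treatment shift
    opposing its sign).  ``segments`` lists the planted CNA intervals.
    ``probe_truth`` is filled by :func:`simulate_probe_track`.
    """

    genes: pd.DataFrame
    segments: pd.DataFrame
    params: dict = field(default_factory=dict)
    probe_truth: pd.DataFrame | None = None

    def gene_model_set(self) -> GeneModelSet:
        return GeneModelSet(self.genes[["gene_id", "chrom", "start", "end",
                                        "strand", "cytoband"]].copy())


def simulate_genome(n_chrom: int = 5, genes_per_chrom: int = 600,
                    probes_per_chrom: int = 2000, n_cna_segments: int = 8,
                    cna_genes_min: int = 12, cna_genes_max: int = 15,
                    gain_range: tuple[float, float] = (0.3, 0.6),
                    loss_range: tuple[float, float] = (-0.5, -0.3),
                    seed: int | None = None) -> SimulationTruth:
    """Lay out genes on chromosomes and plant CNA segments.

    Genes are 10 kb, tiled with 1 kb gaps; cytobands are blocks of 75 genes
    labelled p1..pk / q1..qk per arm.  CNA segments alternate gain/loss,
    are distributed round-robin over chromosomes (at most one gain and one
    loss per chromosome), and span ``cna_genes_min``..``cna_genes_max``
    genes; their log10 states are drawn uniformly from ``gain_range`` /
    ``loss_range``.  Genes inherit the state of their containing segment.
    """
    if min(n_chrom, genes_per_chrom, probes_per_chrom) <= 0:
        raise ValueError("counts must be positive")
    per_chrom_segments = [0] * n_chrom
    for s in range(n_cna_segments):
        per_chrom_segments[s % n_chrom] += 1
    margin = 30  # genes kept clear between segments
    capacity = genes_per_chrom // (cna_genes_max + margin)
    if max(per_chrom_segments) > capacity:
        raise ValueError(
            f"{max(per_chrom_segments)} segments exceed the capacity "
            f"({capacity}) of a {genes_per_chrom}-gene chromosome"
        )
    rng = np.random.default_rng(seed)
    pitch = _GENE_WIDTH + _GENE_GAP
    chrom_len = genes_per_chrom * pitch

    gene_rows = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        half = genes_per_chrom // 2
        for i in range(genes_per_chrom):
            start = i * pitch
            arm = "p" if i < half else "q"
            band = (i if arm == "p" else i - half) // _BAND_GENES + 1
            gene_rows.append(
                {
                    "gene_id": f"{chrom}_g{i:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + _GENE_WIDTH,
                    "strand": "+" if (i % 2 == 0) else "-",
                    "cytoband": f"{arm}{band}",
                }
            )
    genes = pd.DataFrame(gene_rows)
    genes["cn_state"] = 0.0

    seg_rows = []
    used: dict[int, list[tuple[int, int]]] = {c: [] for c in range(n_chrom)}
    for s in range(n_cna_segments):
        c = s % n_chrom
        chrom = f"chr{c + 1}"
        length = int(rng.integers(cna_genes_min, cna_genes_max + 1))
        placed = False
        for _ in range(200):
            start_idx = int(rng.integers(0, genes_per_chrom - length + 1))
            ok = all(
                start_idx + length + margin <= lo or start_idx >= hi + margin
                for lo, hi in used[c]
            )
            if ok:
                placed = True
                break
        if not placed:
            raise ValueError(f"could not place CNA segment {s} on {chrom}")
        used[c].append((start_idx, start_idx + length))
        if s % 2 == 0:
            state = float(rng.uniform(*gain_range))
        else:
            state = float(rng.uniform(loss_range[0], loss_range[1]))
        start_bp = start_idx * pitch - _GENE_GAP // 2
        end_bp = (start_idx + length) * pitch - _GENE_GAP // 2
        seg_rows.append(
            {
                "chrom": chrom,
                "start_bp": max(0, start_bp),
                "end_bp": min(chrom_len, end_bp),
                "cn_state": state,
                "n_genes": length,
            }
        )
        in_seg = (
            (genes["chrom"] == chrom)
            & (genes["start"] >= start_idx * pitch)
            & (genes["end"] <= (start_idx + length) * pitch)
        )
        genes.loc[in_seg, "cn_state"] = state

    segments = pd.DataFrame(
        seg_rows, columns=["chrom", "start_bp", "end_bp", "cn_state", "n_genes"]
    )
    params = {
        "n_chrom": n_chrom,
        "genes_per_chrom": genes_per_chrom,
        "probes_per_chrom": probes_per_chrom,
        "n_cna_segments": n_cna_segments,
        "chrom_len": chrom_len,
        "seed_genome": seed,
    }
    return SimulationTruth(genes=genes, segments=segments, params=params)


def simulate_probe_track(truth: SimulationTruth, probe_noise_sd: float = 0.08,
                         outlier_rate: float = 0.002, outlier_sd: float = 5.0,
                         seed: int | None = None) -> ProbeTrack:
    """Probe-level log10 ratios: segment state + noise + sparse outliers.

    Probes are evenly spaced along each chromosome.  A regular probe reads
    ``cn_state + N(0, probe_noise_sd)``; with probability ``outlier_rate``
    a probe is replaced by an outlier at exactly
    ``cn_state +/- outlier_sd * probe_noise_sd`` (random sign) — the
    single-probe artifact the smoothing step exists to remove.  Per-probe
    ground truth (state, outlier flag) is stored on ``truth.probe_truth``.
    """
    if not (0.0 <= outlier_rate < 1.0):
        raise ValueError("outlier_rate must be in [0, 1)")
    if probe_noise_sd < 0:
        raise ValueError("probe_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n_chrom = truth.params["n_chrom"]
    probes_per_chrom = truth.params["probes_per_chrom"]
    chrom_len = truth.params["chrom_len"]
    pitch = chrom_len // probes_per_chrom
    rows = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        segs = truth.segments[truth.segments["chrom"] == chrom]
        seg_start = segs["start_bp"].to_numpy()
        seg_end = segs["end_bp"].to_numpy()
        seg_state = segs["cn_state"].to_numpy()
        order = np.argsort(seg_start)
        seg_start, seg_end, seg_state = (
            seg_start[order], seg_end[order], seg_state[order],
        )
        starts = np.arange(probes_per_chrom, dtype=np.int64) * pitch
        ends = starts + min(_PROBE_WIDTH, pitch)
        state = np.zeros(probes_per_chrom)
        if len(seg_start):
            idx = np.searchsorted(seg_start, starts, side="right") - 1
            valid = idx >= 0
            hit = np.zeros(probes_per_chrom, dtype=bool)
            hit[valid] = starts[valid] < seg_end[idx[valid]]
            state[hit] = seg_state[idx[hit]]
        noise = rng.normal(0.0, probe_noise_sd, probes_per_chrom)
        is_outlier = rng.random(probes_per_chrom) < outlier_rate
        signs = rng.choice([-1.0, 1.0], size=probes_per_chrom)
        ratio = state + noise
        ratio[is_outlier] = (state + signs * outlier_sd * probe_noise_sd)[is_outlier]
        for s, e, r, st, o in zip(starts, ends, ratio, state, is_outlier):
            rows.append((chrom, int(s), int(e), float(r), float(st), bool(o)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio",
                                     "cn_state", "is_outlier"])
    truth.probe_truth = df
    truth.params.update(
        probe_noise_sd=probe_noise_sd, outlier_rate=outlier_rate,
        outlier_sd=outlier_sd, seed_probes=seed,
    )
    return ProbeTrack(df[["chrom", "start", "end", "ratio"]].copy())


def _sample_names(n_treated: int, n_naive: int) -> tuple[list[str], pd.DataFrame]:
    """Sample ids in the style T8A / N16B: arm letter, day, replicate."""
    rows = []
    for group, prefix, n in (("naive", "N", n_naive), ("treated", "T", n_treated)):
        for i in range(n):
            day = 8 if i < (n + 1) // 2 else 16
            rep = chr(ord("A") + (i if day == 8 else i - (n + 1) // 2))
            rows.append(
                {
                    "sample_id": f"{prefix}{day}{rep}",
                    "group": group,
                    "day": day,
                    "replicate": rep,
                    "excluded": False,
                }
            )
    ann = pd.DataFrame(rows).set_index("sample_id")
    return list(ann.index), ann


def simulate_expression(truth: SimulationTruth, n_treated: int = 5,
                        n_naive: int = 6, base_mean: float = 7.0,
                        base_sd: float = 1.5, dosage_beta: float = 1.0,
                        treatment_effect: float = 0.6,
                        responder_fraction: float = 0.8,
                        background_de_fraction: float = 0.02,
                        expr_noise_sd: float = 0.25,
                        gain_eligible_quantile: float = 0.60,
                        loss_eligible_quantile: float = 0.45,
                        outlier_sample: bool = False,
                        seed: int | None = None) -> ExpressionMatrix:
    """Two-arm log2 expression with dosage coupling and a treatment effect.

    Per gene g and sample s:

        y[g, s] = baseline_g + dosage_beta * cn_state_g * log2(10)
                  + 1[s treated] * delta_g + N(0, expr_noise_sd)

    baseline_g ~ N(base_mean, base_sd) gives enough spread that quartile
    expression gates bind.  The treatment shift delta_g is
    ``-treatment_effect`` for a ``responder_fraction`` of amplified genes
    whose dosage-driven expression puts them in the upper expression range
    (above the ``gain_eligible_quantile`` of all genes), and
    ``+treatment_effect`` for responder copy-loss genes expressed below the
    ``loss_eligible_quantile`` — i.e. the treatment preferentially reverses
    dosage-driven expression.  Those responders carry ``driver = True`` in
    the truth table.  A ``background_de_fraction`` of neutral genes get a
    treatment shift of random sign, emulating copy-independent response.

    ``outlier_sample=True`` appends an extra treated sample ("T16C"-like)
    with a large global perturbation, pre-flagged ``excluded`` in the
    annotations to exercise the declarative exclusion workflow.
    """
    if n_treated < 2 or n_naive < 2:
        raise ValueError("each arm needs at least 2 samples")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = truth.genes
    n_genes = len(genes)
    cn = genes["cn_state"].to_numpy()
    baseline = rng.normal(base_mean, base_sd, n_genes)
    dosage = dosage_beta * cn * LOG2_PER_LOG10
    latent = baseline + dosage

    delta = np.zeros(n_genes)
    driver = np.zeros(n_genes, dtype=bool)
    hi_cut = np.quantile(latent, gain_eligible_quantile)
    lo_cut = np.quantile(latent, loss_eligible_quantile)
    gain_eligible = (cn > 0) & (latent >= hi_cut)
    loss_eligible = (cn < 0) & (latent <= lo_cut)
    responds = rng.random(n_genes) < responder_fraction
    delta[gain_eligible & responds] = -treatment_effect
    delta[loss_eligible & responds] = treatment_effect
    driver = (gain_eligible | loss_eligible) & responds
    neutral = cn == 0.0
    bg = neutral & (rng.random(n_genes) < background_de_fraction)
    delta[bg] = rng.choice([-1.0, 1.0], size=int(bg.sum())) * treatment_effect

    sample_ids, ann = _sample_names(n_treated, n_naive)
    treated_mask = (ann["group"] == "treated").to_numpy()
    y = (
        baseline[:, None]
        + dosage[:, None]
        + np.outer(delta, treated_mask.astype(float))
        + rng.normal(0.0, expr_noise_sd, (n_genes, len(sample_ids)))
    )
    if outlier_sample:
        perturb = rng.normal(0.0, 1.5, n_genes)
        extra = baseline + dosage + delta + perturb + rng.normal(
            0.0, expr_noise_sd, n_genes
        )
        y = np.column_stack([y, extra])
        ann = pd.concat(
            [ann, pd.DataFrame(
                {"group": ["treated"], "day": [16], "replicate": ["C"],
                 "excluded": [True]},
                index=pd.Index(["T16C"], name="sample_id"),
            )]
        )
        sample_ids = sample_ids + ["T16C"]

    values = pd.DataFrame(
        y, index=pd.Index(genes["gene_id"], name="gene_id"), columns=sample_ids
    )
    g = truth.genes
    g["dosage_beta"] = dosage_beta
    g["treatment_delta"] = delta
    g["driver"] = driver
    g["baseline"] = baseline
    truth.params.update(
        n_treated=n_treated, n_naive=n_naive, base_mean=base_mean,
        base_sd=base_sd, dosage_beta=dosage_beta,
        treatment_effect=treatment_effect,
        responder_fraction=responder_fraction,
        background_de_fraction=background_de_fraction,
        expr_noise_sd=expr_noise_sd, seed_expression=seed,
    )
    return ExpressionMatrix(values, ann)
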