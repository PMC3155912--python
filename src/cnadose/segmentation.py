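"""aCGH smoothing, circular binary segmentation, gene-level copy scores.

The segmentation follows the classic recursive change-point scheme for
array CGH: probe-level log10 tumor/reference ratios are first cleaned of
single-probe outliers (which reflect hybridization artifacts, not copy
number), then each chromosome is recursively split at the circular-arc
boundary maximizing a two-sample t-like statistic, with split significance
assessed by permuting the chromosome's values.  Per-probe values are
replaced by their segment mean, and genes are scored by averaging the
segment-assigned values of the probes overlapping them; genes supported by
fewer than three probes are dropped.

Numerical notes
---------------
* The max statistic is exact: all O(n^2) circular arc boundaries are
  scanned (in a compiled kernel).  An arc wrapping the chromosome end is
  the complement of a non-wrapping arc and yields the identical statistic,
  so scanning non-wrapping arcs covers the circular formulation; ties are
  broken toward the smallest (i, j).
* The permutation test is sequential: it stops early once the decision at
  level alpha is settled — exactly, when the exceedance count already
  guarantees p > alpha, and with a 99.9% Clopper-Pearson bound when the
  observed statistic is clearly significant.  ``early_stop=False`` forces
  all ``n_perm`` shuffles.  Results are deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import beta as beta_dist

from .formats import GeneModelSet, ProbeTrack

__all__ = [
    "SegmentationResult",
    "smooth_outliers",
    "cbs_max_statistic",
    "cbs_segment",
    "gene_copy_scores",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# outlier smoothing


def _trimmed_sd(values: np.ndarray, trim: float = 0.025) -> float:
    """SD after trimming ``trim`` of the mass from each tail."""
    v = np.sort(values)
    k = int(np.floor(trim * len(v)))
    core = v[k: len(v) - k] if k > 0 else v
    if len(core) < 2:
        return 0.0
    return float(core.std(ddof=1))


def smooth_outliers(track: ProbeTrack, region: int = 10, outlier_sd: float = 4.0,
                    shrink_sd: float = 2.0) -> ProbeTrack:
    """Replace single-probe outliers by a shrunk neighborhood value.

    For each probe the neighborhood is the ``region`` probes on each side
    (at most 2*region total, excluding the probe itself).  A probe whose
    ratio deviates from the neighborhood median by more than
    ``outlier_sd * sigma`` — sigma being the trimmed (2.5% per tail) SD of
    the chromosome's ratios — is pulled in to
    ``median +/- shrink_sd * sigma``, signed toward the original value.
    All decisions are made against the input ratios, so the operation is
    idempotent: a second pass changes nothing.
    """
    if region < 1:
        raise ValueError("region must be >= 1")
    df = track.probes.copy()
    out = df["ratio"].to_numpy(dtype=float).copy()
    for chrom, grp in df.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        r = grp["ratio"].to_numpy(dtype=float)
        n = len(r)
        if n < 2:
            warnings.warn(f"chromosome {chrom} has < 2 probes; smoothing skipped")
            continue
        sigma = _trimmed_sd(r)
        if sigma == 0.0:
            continue
        for k in range(n):
            lo, hi = max(0, k - region), min(n, k + region + 1)
            neigh = np.delete(r[lo:hi], k - lo)
            med = float(np.median(neigh))
            dev = r[k] - med
            if abs(dev) > outlier_sd * sigma:
                out[idx[k]] = med + np.sign(dev) * shrink_sd * sigma
    df["ratio"] = out
    return ProbeTrack(df)


# ---------------------------------------------------------------------------
# CBS max statistic


@njit(cache=True)
def _max_t_kernel(x):  # pragma: no cover - exercised via cbs_max_statistic
    # For a fixed arc length k the statistic is strictly increasing in
    # |mean(arc) - mean(complement)|, which is affine in the arc's window
    # sum; so per k only the extreme window sums can attain the maximum.
    # That turns the O(n^2) candidate scan into O(n^2) additions with two
    # statistic evaluations per k, exactly equivalent to the full scan.
    n = x.shape[0]
    cs = np.empty(n + 1)
    cs[0] = 0.0
    for i in range(n):
        cs[i + 1] = cs[i] + x[i]
    tot = cs[n]
    mean = tot / n
    tss = 0.0
    for i in range(n):
        d = x[i] - mean
        tss += d * d
    best_t = -1.0
    best_i = 0
    best_j = 1
    for k in range(1, n):
        wmax = -1.0e300
        wmin = 1.0e300
        imax = 0
        imin = 0
        for i in range(n - k + 1):
            w = cs[i + k] - cs[i]
            if w > wmax:
                wmax = w
                imax = i
            if w < wmin:
                wmin = w
                imin = i
        g = k * (n - k) / n
        for c in range(2):
            if c == 0:
                w = wmax if imax <= imin else wmin
                i = imax if imax <= imin else imin
            else:
                w = wmin if imax <= imin else wmax
                i = imin if imax <= imin else imax
            m1 = w / k
            m2 = (tot - w) / (n - k)
            d = m1 - m2
            ss = tss - g * d * d
            if ss < 0.0:
                ss = 0.0
            s2 = ss / (n - 2)
            denom = s2 * (1.0 / k + 1.0 / (n - k))
            if denom <= 0.0:
                if d == 0.0:
                    t = 0.0
                else:
                    t = np.inf
            else:
                t = abs(d) / np.sqrt(denom)
            j = i + k
            if t > best_t or (t == best_t and (i < best_i or
                                               (i == best_i and j < best_j))):
                best_t = t
                best_i = i
                best_j = j
    return best_i, best_j, best_t


@njit(cache=True)
def _perm_exceeds_kernel(x, dthresh2):  # pragma: no cover
    """True if the permuted series attains max T >= the observed statistic.

    ``dthresh2[k]`` is the squared mean-difference threshold equivalent to
    the observed T at arc length k (derived once per segment; the total sum
    of squares is permutation-invariant, so thresholds carry over).
    """
    n = x.shape[0]
    cs = np.empty(n + 1)
    cs[0] = 0.0
    for i in range(n):
        cs[i + 1] = cs[i] + x[i]
    tot = cs[n]
    for k in range(1, n):
        wmax = -1.0e300
        wmin = 1.0e300
        for i in range(n - k + 1):
            w = cs[i + k] - cs[i]
            if w > wmax:
                wmax = w
            if w < wmin:
                wmin = w
        c = 1.0 / k + 1.0 / (n - k)
        off = tot / (n - k)
        d1 = c * wmax - off
        d2 = c * wmin - off
        dd = d1 * d1
        if d2 * d2 > dd:
            dd = d2 * d2
        if dd >= dthresh2[k]:
            return True
    return False


def cbs_max_statistic(values: np.ndarray) -> tuple[int, int, float]:
    """Maximal circular binary-split statistic for one chromosome.

    Over all arc boundaries 0 <= i < j <= n (arc = values[i:j], complement
    the rest, both non-empty),

        T(i, j) = |mean(arc) - mean(complement)|
                  / (s * sqrt(1/k + 1/(n-k)))

    with k the arc length and s the pooled (two-group) standard deviation.
    Returns the maximizing ``(i, j, T)``; ties go to the smallest i, then
    the smallest j.  A perfectly constant input yields T = 0 at (0, 1).
    """
    x = np.ascontiguousarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("cbs_max_statistic needs a 1-D array with n >= 4")
    i, j, t = _max_t_kernel(x)
    return int(i), int(j), float(t)


# ---------------------------------------------------------------------------
# permutation test with sequential early stopping

_CHECK_EVERY = 25
_CP_CONFIDENCE = 0.999


def _dthresh2(t_obs: float, tss: float, n: int) -> np.ndarray:
    """Per-arc-length squared mean-difference threshold equivalent to T >= t_obs.

    From T^2 = d^2 (n-2) / (c_k TSS - d^2) with c_k = 1/k + 1/(n-k):
    T >= t  <=>  d^2 >= t^2 c_k TSS / (n - 2 + t^2).  An infinite observed
    statistic (a perfect split) corresponds to d^2 >= c_k TSS, i.e. zero
    pooled variance.
    """
    k = np.arange(n, dtype=float)
    k[0] = np.nan  # unused slot
    c = 1.0 / k + 1.0 / (n - k)
    if np.isinf(t_obs):
        return c * tss
    return (t_obs**2) * c * tss / (n - 2 + t_obs**2)


def _perm_test(x: np.ndarray, t_obs: float, alpha: float, n_perm: int,
               rng: np.random.Generator, early_stop: bool) -> tuple[float, bool]:
    """Permutation p-value for the observed max statistic.

    The p-value is the add-one permutation estimator (e + 1) / (m + 1)
    with e the count of shuffles whose max statistic reaches t_obs; it is
    never exactly zero, so a vanishing alpha always yields "no split".
    With ``early_stop`` the loop terminates as soon as (a) the exceedance
    count already implies the final p would exceed alpha (an exact stop),
    or (b) the 99.9% Clopper-Pearson upper bound on the exceedance
    probability drops below alpha (declare significant).  Returns
    (p_estimate, significant).
    """
    n = len(x)
    tss = float(((x - x.mean()) ** 2).sum())
    thresh = _dthresh2(t_obs, tss, n)
    # smallest e for which (e + 1) / (n_perm + 1) > alpha no matter what
    e_stop = int(np.floor(alpha * (n_perm + 1)))
    e = 0
    m = 0
    while m < n_perm:
        block = min(_CHECK_EVERY, n_perm - m)
        for _ in range(block):
            perm = rng.permutation(x)
            if _perm_exceeds_kernel(perm, thresh):
                e += 1
        m += block
        if not early_stop:
            continue
        if e >= e_stop:
            return (e + 1) / (m + 1), False
        if e < m:
            upper = beta_dist.ppf(_CP_CONFIDENCE, e + 1, m - e)
            if upper < alpha:
                return (e + 1) / (m + 1), True
    p = (e + 1) / (n_perm + 1)
    return p, p <= alpha


# ---------------------------------------------------------------------------
# recursive segmentation


@dataclass
class SegmentationResult:
    """Per-chromosome constant-mean segments plus per-probe assigned values.

    ``segments`` has one row per segment (chrom, start/end probe indices
    inclusive within the chromosome, genomic bp bounds, probe count, mean);
    ``probe_values`` aligns with the track's probe table and holds each
    probe's segment mean.
    """

    segments: pd.DataFrame
    probe_values: np.ndarray


def cbs_segment(track: ProbeTrack, alpha: float = 0.05, n_perm: int = 1000,
                seed: int | None = None, early_stop: bool = True) -> SegmentationResult:
    """Recursively segment each chromosome's (smoothed) ratios.

    At each level the maximal circular-split statistic is found and its
    significance assessed by permuting the values within the current
    segment; a significant split partitions the segment into the implied
    2-3 sub-segments, each recursed on.  Segments shorter than 4 probes are
    emitted as-is.  Per-probe values are the enclosing segment's mean.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ss = np.random.SeedSequence(seed)
    probe_values = np.empty(len(track), dtype=float)
    rows: list[dict] = []
    offset = 0
    for chrom, child_ss in zip(track.chromosomes,
                               ss.spawn(len(track.chromosomes))):
        grp = track.chromosome(chrom)
        r = grp["ratio"].to_numpy(dtype=float)
        rng = np.random.default_rng(child_ss)
        bounds: list[tuple[int, int]] = []  # [lo, hi) within chromosome

        def _recurse(lo: int, hi: int) -> None:
            n = hi - lo
            if n < 4:
                bounds.append((lo, hi))
                return
            seg = r[lo:hi]
            i, j, t = cbs_max_statistic(seg)
            _, significant = _perm_test(seg, t, alpha, n_perm, rng, early_stop)
            if not significant:
                bounds.append((lo, hi))
                return
            cuts = sorted({lo, lo + i, lo + j, hi})
            for a, b in zip(cuts[:-1], cuts[1:]):
                _recurse(a, b)

        _recurse(0, len(r))
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        for lo, hi in bounds:
            mean = float(r[lo:hi].mean())
            probe_values[offset + lo: offset + hi] = mean
            rows.append(
                {
                    "chrom": chrom,
                    "start_probe": lo,
                    "end_probe": hi - 1,
                    "start_bp": int(starts[lo]),
                    "end_bp": int(ends[hi - 1]),
                    "n_probes": hi - lo,
                    "mean": mean,
                }
            )
        offset += len(r)
    segments = pd.DataFrame(
        rows, columns=["chrom", "start_probe", "end_probe", "start_bp",
                       "end_bp", "n_probes", "mean"],
    )
    return SegmentationResult(segments, probe_values)


# ---------------------------------------------------------------------------
# gene scoring


def gene_copy_scores(seg: SegmentationResult, track: ProbeTrack,
                     genes: GeneModelSet, min_probes: int = 3,
                     containment: bool = False) -> pd.DataFrame:
    """Average segment-assigned probe values over each gene's span.

    For every gene, the probes overlapping [start, end) are collected (any
    base-pair overlap by default; ``containment=True`` requires the probe
    to lie wholly inside the gene).  Genes with at least ``min_probes``
    supporting probes get the mean of those probes' segment values; the
    rest are omitted.  Returns a DataFrame indexed by gene_id with columns
    ``mean_log10_ratio`` and ``n_probes``.
    """
    if len(seg.probe_values) != len(track):
        raise ValueError("segmentation does not correspond to this probe track")
    probes = track.probes
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    offset = 0
    for chrom in track.chromosomes:
        grp = probes[probes["chrom"] == chrom]
        n = len(grp)
        by_chrom[chrom] = (
            grp["start"].to_numpy(),
            grp["end"].to_numpy(),
            seg.probe_values[offset: offset + n],
        )
        offset += n
    rows = []
    skipped_chroms: set[str] = set()
    for rec in genes.genes.itertuples(index=False):
        if rec.chrom not in by_chrom:
            if rec.chrom not in skipped_chroms:
                logger.info("gene %s on chromosome %s absent from probe track",
                            rec.gene_id, rec.chrom)
                skipped_chroms.add(rec.chrom)
            continue
        starts, ends, vals = by_chrom[rec.chrom]
        if containment:
            lo = int(np.searchsorted(starts, rec.start, side="left"))
            hi = int(np.searchsorted(ends, rec.end, side="right"))
        else:
            # any overlap: probe.end > gene.start and probe.start < gene.end
            lo = int(np.searchsorted(ends, rec.start, side="right"))
            hi = int(np.searchsorted(starts, rec.end, side="left"))
        count = hi - lo
        if count >= min_probes:
            sel = vals[lo:hi]
            # a gene wholly inside one segment gets that segment's mean
            # exactly, not a re-averaged float
            score = float(sel[0]) if (sel == sel[0]).all() else float(sel.mean())
            rows.append(
                {
                    "gene_id": rec.gene_id,
                    "mean_log10_ratio": score,
                    "n_probes": count,
                }
            )
    out = pd.DataFrame(rows, columns=["gene_id", "mean_log10_ratio", "n_probes"])
    return out.set_index("gene_id")
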