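# Methods

This note documents the statistical models behind `cnadose`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Expression preprocessing and differential expression

All samples are quantile-normalized **together** (treated and naive share
one reference distribution: the row means of the column-sorted matrix).
Ties within a column are assigned reference values in stable input order
rather than averaged; this keeps the defining invariant — identical
sorted-value vectors in every column — exact to the last bit, at the cost
of splitting tied raw values across adjacent reference values. Total
matrix mean is preserved.

The lowest quartile of genes by mean signal is discarded as unexpressed
(`discard_fraction = 0.25`). Quantiles use nearest-rank semantics with
gene-id tie-breaks, so the filter is deterministic and removes exactly
`floor(0.25 n)` genes; at least one gene always survives.

Differential expression is a per-gene **Welch** (unequal-variance) t-test
with Welch–Satterthwaite degrees of freedom. Welch was chosen over the
pooled-variance test because the intended designs are small, unbalanced
groups of heterogeneous tumors. Genes with equal means and zero variance
in both groups get t = 0, p = 1; unequal means with vanishing variance are
handled with a machine-epsilon-scaled variance floor rather than p = 0, so
degenerate synthetic genes cannot produce infinities. Multiple testing is
controlled with Benjamini–Hochberg q-values (the method is isolated behind
one call and swappable). Significance gates default to q < 0.05 and
|log2 FC| > 0.6, applied symmetrically to both directions.

The enrichment ranking metric is the GSEA-convention signal-to-noise
ratio (mean_A − mean_B)/(sd_A + sd_B), each group's sd floored at
0.2·|group mean| (0.2 when the mean is zero). The floor makes the metric
insensitive to near-constant genes; with log2 signals around 7 it
compresses the metric range, but ordering — the only thing enrichment
uses — is preserved. Ties are broken by gene id.

Sample clustering restricts to the top 75% of genes by mean signal (the
complement of the expression filter; the alternative reading "top 75% by
variance" was considered and not taken — the mean-signal reading makes
the clustering universe identical to the analysis universe), uses
1 − Pearson correlation and average linkage, and emits Newick with branch
lengths equal to differences of merge heights. A constant sample vector is
an error naming the sample, since its correlation is undefined.

## aCGH smoothing and segmentation

Probe log10 tumor/reference ratios are carried as log10 end-to-end; no
log-base conversion happens anywhere.

**Outlier smoothing.** For each probe, the neighborhood is up to 10 probes
on each side (20 total). A probe deviating from the neighborhood median by
more than 4σ — σ being the trimmed SD (2.5% per tail) of the chromosome's
ratios — is pulled to median ± 2σ, signed toward the original value. All
decisions are made against the input values, so the pass is idempotent.
The trimmed SD presumes CNAs occupy a small fraction of each chromosome
(they land in the trimmed tails); on chromosomes where aberrations span a
large fraction of probes the dispersion estimate inflates and real
outliers inside such regions may survive — a known property of this
family of smoothers, not a defect of the fit.

**CBS.** Each chromosome is recursively split at the circular-arc
boundary maximizing

T(i, j) = |mean(arc) − mean(complement)| / (s · sqrt(1/k + 1/(n−k))),

s the pooled two-group SD, over all 0 ≤ i < j ≤ n. Arcs wrapping the
chromosome end are complements of non-wrapping arcs and give identical T,
so scanning non-wrapping arcs covers the circular formulation exactly;
ties break to the smallest (i, j). The implementation reduces the scan,
for each arc length, to the two extreme window sums (T is strictly
increasing in the mean difference at fixed length — an exact algebraic
reduction, verified against brute force), in a compiled kernel.

Split significance uses a permutation test: the segment's values are
shuffled and the max statistic recomputed. The p-value is the add-one
estimator (e+1)/(m+1), which is never exactly zero — so a vanishing alpha
always yields a single segment. The test is sequential: it stops exactly
when the exceedance count already forces p > alpha, and stops early for
clearly significant splits when the 99.9% Clopper–Pearson upper bound on
the exceedance probability drops below alpha (`early_stop=False` forces
all permutations). Stage seeds make results reproducible; per-chromosome
generators are spawned from one seed sequence so results do not depend on
chromosome processing order. A significant arc splits the segment into
the implied 2–3 pieces, each recursed on; pieces shorter than 4 probes
are emitted as-is. No pruning/undo step is applied. Segment means are the
exact arithmetic means of the smoothed probe ratios.

**Gene copy scores.** A gene's score is the mean of the segment-assigned
values of the probes overlapping it; any base-pair overlap counts
(containment-only available behind a flag), coordinates are 0-based
half-open everywhere, and a probe ending exactly at a gene's start does
not overlap it. Genes with fewer than 3 supporting probes are omitted.
A gene wholly inside one segment receives the segment mean exactly (no
re-averaging round-off).

## Enrichment

The running sum rises by |r|^p / Σ_set |r|^p at set members (p = 1 by
default; p = 0 gives the classic Kolmogorov–Smirnov walk, which provably
closes at 0) and falls by 1/(N − k) at non-members; ES is the extremum by
absolute value (positive preferred on an exact tie), and the leading edge
contains the members at or before (after, for negative ES) the extremum.
A set equal to the whole universe is rejected (the decrement is
undefined). The implementation evaluates the walk only at hit positions
(its extremes can occur nowhere else), which makes the permutation null
cheap; tests verify it against a literal step-by-step walk.

The null is **gene-set permutation** by default — random same-size sets
drawn from the ranked universe — because with 5–6 samples per arm the
number of distinct phenotype relabelings is far too small for a useful
phenotype null. Phenotype permutation (relabel arms, recompute the
ranking) is available and preferable with ≥ 7 samples per arm. One pool
of permuted orders is shared across sets, so cost scales with the number
of distinct set sizes. NES = ES / mean |null ES| of the matching sign;
the nominal p is the same-sign null exceedance fraction; FDR q follows
the sign-stratified pooled-null-vs-observed ratio, clipped to [0, 1].
Set-size bounds default to 5–500 after intersection with the universe.

Positional gene sets (one per chromosome, arm, or cytoband) feed the same
machinery to detect coordinated regulation of loci.

## CNA gene-set construction and integration

Gain set: gene copy score > +0.3 (log10) and mean expression at or above
the top-quartile nearest-rank cutoff of the **expressed** (post-filter)
genes. Loss set: score < −0.3 and expression at or below the
bottom-quartile cutoff — the loss gate mirrors the gain gate; an ungated
mode is available since "concordantly low expression" admits other
readings. Expression gating uses the mean over all non-excluded samples
(configurable). The thresholds, gates and sample list are recorded in the
sets' provenance and exported in the GMT description field. Genes present
in only one of the copy/expression universes are dropped with a logged
count (array designs differ); this is deliberate, with strictness
available by passing an explicit sample list and pre-matched tables.

`run_integration` ranks genes treated-vs-naive, enriches both sets, and
returns the enrichment table, ranking, and running-sum traces. The
candidate table joins every tested set member with its copy score, log2
fold change and q-value, flagged by leading-edge membership and sorted
(leading edge first, then |log2 FC|): amplified-but-down-regulated
leading-edge genes are the candidate dosage drivers.

## The synthetic-data generator

What it emulates: a few chromosomes tiled with non-overlapping 10 kb
genes; segmental CNAs with log10 states in ±0.3–0.6 (single-copy
gain/loss territory in a near-diploid line), alternating gain/loss and
at most one of each per chromosome; evenly spaced probes with Gaussian
noise (σ = 0.08) and sparse single-probe outliers placed at exactly
±5σ from the segment state; log2 expression with baseline N(7, 1.5),
dosage coupling β·log2(10)·log10-ratio (so copy ratio and expression stay
on their native scales), arm sizes 5 treated / 6 naive split over two
collection days, and a treatment effect of −0.6 log2 on 80% of
amplified/high-expressed genes and +0.6 on 80% of copy-loss/low-expressed
genes (the drug opposes dosage), plus a 2% background of copy-independent
responders of random sign. Planted responders carry a driver flag in the
truth tables. A "late-outlier" sample option appends an excluded,
globally perturbed treated sample to exercise the declarative exclusion
workflow.

Deliberate scale choices: CNA segments are 12–15 genes (~40–50 probes),
keeping each chromosome's aberrant probes inside the 2.5% tails of the
smoother's trimmed-SD estimate — the regime the smoothing method assumes
and a fair mimic of a line with modest CNA burden; probe pitch gives every
gene 3–4 probes, so the ≥ 3-probe rule binds only on sparser real
designs. Responder planting uses latent-expression quantile gates (0.60
for gains, 0.45 for losses) chosen so that planted responders populate
the expression bands the pipeline's quartile gates select after the
lowest-quartile filter (top quartile of retained genes = 62.5th overall
percentile; bottom quartile of retained = 25–43.75th).

What it does **not** emulate: probe-level hybridization physics, GC/wave
artifacts, mouse-cell contamination or necrosis, intra-tumor
heterogeneity, ploidy/purity shifts, and correlated (co-regulated) genes
— expression noise is independent across genes. Passing tests therefore
demonstrate that the algorithms recover the planted structure under
idealized noise, not that real arrays would behave as cleanly; on real
data the dosage–expression coupling is weaker and the candidate lists
correspondingly noisier.

With the default effect size (0.6 log2) and noise (0.25), the per-gene
t-tests are underpowered at n = 5–6 (few genes pass the q < 0.05 gate) —
faithful to small xenograft designs; the set-level enrichment is what
carries the signal, which is the point of the method.

## Numerical conventions and reproducibility

Coordinates 0-based half-open everywhere; quantiles nearest-rank;
ranking and quantile ties broken by gene id; the dendrogram, rankings,
set memberships and output files are byte-deterministic given config +
seed (no timestamps in outputs; the log file carries them). Stage seeds
derive from the master seed through named spawn keys, so `all` and the
individual subcommands agree exactly. `--threads` is accepted for
interface compatibility but inert: all hot loops are vectorized or
compiled, and results never depend on it.

Default problem sizes (3000 genes, 10 000 probes, 1000 permutations for
both CBS and enrichment) run end-to-end in well under a minute on one
CPU; the multi-seed recovery experiment in `scripts/acceptance.py` uses
20 seeds at these sizes.

## Known limitations

* No segment pruning/undo; CBS can emit short boundary segments around
  sharp features (visible as 1–5 probe fragments next to true edges).
* The gene-set permutation null ignores inter-gene correlation; on real
  arrays it is anti-conservative relative to a phenotype null. Use
  phenotype mode when the design allows.
* BH q-values assume independence/PRDS across genes.
* The sequential permutation test's early-significance stop carries a
  ≤ 0.1% per-checkpoint error relative to running all permutations;
  `early_stop=False` removes it.
* Copy scores are relative log ratios; no purity/ploidy correction or
  integer-state calling is attempted.
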