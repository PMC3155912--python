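"""Domain containers and file I/O for the pipeline.

All genomic coordinates are 0-based half-open (BED convention): a probe
whose ``end`` equals a gene's ``start`` does not overlap that gene.

External representations
------------------------
* expression matrix: TSV, first column ``gene_id``, one column per sample
* sample annotations: TSV with columns ``sample_id, group, day, replicate,
  excluded``
* aCGH probes: BED4 (chrom, start, end, ratio) carrying log10
  tumor/reference ratios in the score column
* gene models: BED6 (chrom, start, end, name, score, strand) with an
  optional seventh cytoband column
* gene sets: standard GMT (name, description, members)

Readers skip lines starting with ``#`` so that files written by this
package (which carry a commented provenance header) round-trip.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeTrack",
    "GeneModelSet",
    "GeneSetCollection",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_probe_track",
    "write_probe_track",
    "read_gene_bed",
    "write_gene_bed",
    "read_gmt",
    "write_gmt",
]

ANNOTATION_COLUMNS = ("group", "day", "replicate", "excluded")


@dataclass
class ExpressionMatrix:
    """Log2 expression signal, genes x samples, with per-sample annotations.

    ``values`` is a DataFrame indexed by unique gene_id with one column per
    sample; ``annotations`` is indexed by sample_id and carries at least a
    ``group`` column plus optional ``day``, ``replicate`` and ``excluded``
    (boolean) columns.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dup = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dup[:5]}")
        if v.columns.has_duplicates:
            dup = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dup}")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        ann = self.annotations
        if "group" not in ann.columns:
            raise ValueError("annotations must carry a 'group' column")
        missing = [s for s in v.columns if s not in ann.index]
        if missing:
            raise ValueError(f"samples missing from annotations: {missing}")
        if "excluded" not in ann.columns:
            ann = ann.copy()
            ann["excluded"] = False
            self.annotations = ann
        # align annotation order to the matrix header
        self.annotations = self.annotations.loc[list(v.columns)]
        self.values = v.astype(float)

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str, include_excluded: bool = False) -> list[str]:
        """Sample ids carrying a group label, by default dropping samples
        flagged ``excluded`` in the annotations."""
        ann = self.annotations
        mask = ann["group"] == group
        if not include_excluded:
            mask &= ~ann["excluded"].astype(bool)
        return list(ann.index[mask])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.annotations)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values[list(sample_ids)], self.annotations.loc[list(sample_ids)]
        )


@dataclass
class ProbeTrack:
    """Ordered aCGH probes: chrom, start, end (0-based half-open), and
    log10 tumor/reference ratio.

    Probes are grouped by chromosome (first-appearance order) and sorted by
    start within each chromosome on construction; overlapping probes on the
    same chromosome are rejected.
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes.reset_index(drop=True)
        required = ["chrom", "start", "end", "ratio"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"probe table missing column '{col}'")
        df = df[required].copy()
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["ratio"] = df["ratio"].astype(float)
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"]].iloc[0]
            raise ValueError(
                f"probe with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}"
            )
        if not np.isfinite(df["ratio"]).all():
            raise ValueError("probe ratios must be finite")
        # stable per-chromosome sort keeping chromosome first-appearance order
        chrom_order = {c: i for i, c in enumerate(df["chrom"].unique())}
        df = df.sort_values(
            by=["chrom", "start", "end"],
            key=lambda s: s.map(chrom_order) if s.name == "chrom" else s,
            kind="stable",
        ).reset_index(drop=True)
        for chrom, grp in df.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            overlap = starts[1:] < ends[:-1]
            if overlap.any():
                k = int(np.argmax(overlap))
                raise ValueError(
                    f"overlapping probes on {chrom}: "
                    f"{starts[k]}-{ends[k]} and {starts[k + 1]}-{ends[k + 1]}"
                )
        self.probes = df

    def __len__(self) -> int:
        return len(self.probes)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.probes["chrom"].unique())

    def chromosome(self, chrom: str) -> pd.DataFrame:
        return self.probes[self.probes["chrom"] == chrom]


@dataclass
class GeneModelSet:
    """Gene models: gene_id, chrom, start, end (0-based half-open), strand
    (+/-/.) and optional cytoband label."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.genes.reset_index(drop=True).copy()
        for col in ("gene_id", "chrom", "start", "end"):
            if col not in df.columns:
                raise ValueError(f"gene table missing column '{col}'")
        if "strand" not in df.columns:
            df["strand"] = "."
        if "cytoband" not in df.columns:
            df["cytoband"] = ""
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if df["gene_id"].duplicated().any():
            dup = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
            raise ValueError(f"duplicate gene names: {dup[:5]}")
        if (df["start"] >= df["end"]).any():
            bad = df.loc[df["start"] >= df["end"], "gene_id"].tolist()
            raise ValueError(f"gene with start >= end: {bad[:5]}")
        self.genes = df[["gene_id", "chrom", "start", "end", "strand", "cytoband"]]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set '{name}' is empty")
        for name in self.sets:
            self.descriptions.setdefault(name, "")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# header helper


def _header_lines(params: Mapping[str, object] | None) -> str:
    from . import __version__

    lines = [f"# cnadose v{__version__}"]
    if params:
        for k in sorted(params):
            lines.append(f"# {k} = {params[k]}")
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path: str | Path, params: Mapping[str, object] | None = None,
              index: bool = False) -> None:
    """Write a TSV with a commented provenance header naming the package
    version and the parameters of the producing step."""
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(_header_lines(params) + buf.getvalue())


# ---------------------------------------------------------------------------
# expression matrix


def read_expression_matrix(path: str | Path, annotation_path: str | Path,
                           log2_transform: bool = False) -> ExpressionMatrix:
    """Load a gene-by-sample TSV plus a sample annotation TSV.

    The first matrix column is ``gene_id``; remaining columns are samples in
    header order.  Every sample in the matrix must appear in the annotation
    file (extra annotation rows are an error too, so stale annotation files
    are caught).  With ``log2_transform`` linear-scale signals are converted
    with log2(x + 1).
    """
    mat = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if mat.index.has_duplicates:
        dup = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene row(s) in expression matrix: {dup[:5]}")
    try:
        mat = mat.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric expression value: {exc}") from exc
    ann = pd.read_csv(path_or := annotation_path, sep="\t", comment="#")
    if "sample_id" not in ann.columns:
        raise ValueError(f"annotation file {path_or} lacks a 'sample_id' column")
    ann = ann.set_index("sample_id")
    extra = [s for s in ann.index if s not in mat.columns]
    if extra:
        raise ValueError(f"annotation rows without a matching sample: {extra}")
    if "excluded" in ann.columns:
        ann["excluded"] = ann["excluded"].astype(bool)
    if log2_transform:
        mat = np.log2(mat + 1.0)
    mat.index.name = "gene_id"
    return ExpressionMatrix(mat, ann)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path,
                            annotation_path: str | Path | None = None,
                            params: Mapping[str, object] | None = None) -> None:
    df = em.values.copy()
    df.index.name = "gene_id"
    write_tsv(df, path, params, index=True)
    if annotation_path is not None:
        ann = em.annotations.copy()
        ann.index.name = "sample_id"
        write_tsv(ann, annotation_path, params, index=True)


# ---------------------------------------------------------------------------
# probe track


def read_probe_track(path: str | Path) -> ProbeTrack:
    """Load a BED4 probe file: chrom, start, end, log10 ratio."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "ratio"], dtype={"chrom": str},
    )
    try:
        df["ratio"] = df["ratio"].astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric probe ratio: {exc}") from exc
    return ProbeTrack(df)


def write_probe_track(track: ProbeTrack, path: str | Path,
                      params: Mapping[str, object] | None = None) -> None:
    buf = io.StringIO()
    track.probes.to_csv(buf, sep="\t", index=False, header=False)
    Path(path).write_text(_header_lines(params) + buf.getvalue())


# ---------------------------------------------------------------------------
# gene BED


def read_gene_bed(path: str | Path) -> GeneModelSet:
    """Load genes from BED4/BED6 with an optional seventh cytoband column."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    ncol = df.shape[1]
    if ncol < 4:
        raise ValueError("gene BED needs at least chrom/start/end/name")
    names = ["chrom", "start", "end", "gene_id", "score", "strand", "cytoband"][:ncol]
    df.columns = names
    out = df[["gene_id", "chrom", "start", "end"]].copy()
    out["strand"] = df["strand"] if "strand" in df.columns else "."
    out["cytoband"] = df["cytoband"].fillna("") if "cytoband" in df.columns else ""
    return GeneModelSet(out)


def write_gene_bed(genes: GeneModelSet, path: str | Path,
                   params: Mapping[str, object] | None = None) -> None:
    df = genes.genes
    bed = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["start"],
            "end": df["end"],
            "gene_id": df["gene_id"],
            "score": 0,
            "strand": df["strand"],
            "cytoband": df["cytoband"],
        }
    )
    buf = io.StringIO()
    bed.to_csv(buf, sep="\t", index=False, header=False)
    Path(path).write_text(_header_lines(params) + buf.getvalue())


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno} has fewer than 3 fields")
        name, desc, *members = fields
        members = [m for m in members if m]
        if not members:
            raise ValueError(f"GMT set '{name}' (line {lineno}) has no members")
        if name in sets:
            raise ValueError(f"duplicate GMT set name '{name}'")
        sets[name] = members
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name in collection.names():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *collection.sets[name]]))
    Path(path).write_text("\n".join(lines) + "\n")
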