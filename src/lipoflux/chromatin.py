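"""Integration of differential chromatin accessibility with expression.

Genes are classified Up / Down / Unchanged from a differential-expression
table (|log2FC| >= 0.58 i.e. |fold change| >= 1.5, p <= 0.05, thresholds
inclusive).  Differentially accessible regions (DARs) are classified,
strand-aware, by position relative to each gene: promoter (up to 3 kb
upstream of the TSS), gene body, downstream (3 kb past the gene end), or
distal when no gene qualifies; when a DAR overlaps several windows of one
gene the precedence is promoter > gene_body > downstream.  The stratified
association table reports, per gene class × region × DAR direction, the
percentage of genes carrying at least one such DAR.

All coordinates are 0-based half-open (BED convention); overlap means >= 1
shared base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneModel",
    "DARRecord",
    "classify_deg",
    "annotate_dar",
    "stratified_association",
    "read_genes_bed",
    "read_genes_gtf",
    "read_dars_tsv",
    "read_de_tsv",
]

REGIONS = ("promoter", "gene_body", "downstream")
GENE_CLASSES = ("Up", "Down", "Unchanged")
DAR_DIRECTIONS = ("Up", "Down")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription start site position (strand-aware)."""
        return self.start if self.strand == "+" else self.end - 1

    def region_window(self, region: str, promoter_bp: int = 3000, downstream_bp: int = 3000):
        """Half-open genomic window of a region class for this gene."""
        if region == "gene_body":
            return (self.start, self.end)
        if region == "promoter":
            if self.strand == "+":
                return (max(0, self.start - promoter_bp), self.start)
            return (self.end, self.end + promoter_bp)
        if region == "downstream":
            if self.strand == "+":
                return (self.end, self.end + downstream_bp)
            return (max(0, self.start - downstream_bp), self.start)
        raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class DARRecord:
    chrom: str
    start: int
    end: int
    log2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"DAR {self.chrom}:{self.start}-{self.end}: start must be < end")
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"DAR {self.chrom}:{self.start}-{self.end}: fdr outside [0, 1]")

    @property
    def direction(self) -> str:
        return "Up" if self.log2fc > 0 else "Down"


def classify_deg(
    de_table: pd.DataFrame,
    lfc_threshold: float = 0.58,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Classify genes Up / Down / Unchanged, thresholds inclusive.

    Expects columns ``gene_id``, ``log2FC``, ``p``; returns the table with a
    ``gene_class`` column added.  Duplicate gene ids are an error.
    """
    required = {"gene_id", "log2FC", "p"}
    if not required <= set(de_table.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    if de_table["gene_id"].duplicated().any():
        dupes = sorted(de_table.loc[de_table["gene_id"].duplicated(), "gene_id"])
        raise ValueError(f"duplicate gene ids in DE table: {dupes}")
    lfc = de_table["log2FC"].to_numpy(dtype=float)
    p = de_table["p"].to_numpy(dtype=float)
    if not (np.isfinite(lfc).all() and np.isfinite(p).all()):
        raise ValueError("log2FC and p must be finite")
    cls = np.where(
        (lfc >= lfc_threshold) & (p <= p_threshold),
        "Up",
        np.where((lfc <= -lfc_threshold) & (p <= p_threshold), "Down", "Unchanged"),
    )
    out = de_table.copy()
    out["gene_class"] = cls
    return out


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def annotate_dar(
    dar: DARRecord,
    genes: list[GeneModel],
    promoter_bp: int = 3000,
    downstream_bp: int = 3000,
) -> list[tuple[str, str | None]]:
    """Region classes of one DAR: ``(region, gene_id)`` per qualifying gene.

    Precedence within a gene is promoter > gene_body > downstream; a DAR
    qualifying for no gene returns ``[("distal", None)]``.  A chromosome
    absent from the gene set is distal with a warning.
    """
    chrom_genes = [g for g in genes if g.chrom == dar.chrom]
    if not chrom_genes and not any(g.chrom == dar.chrom for g in genes):
        if dar.chrom not in {g.chrom for g in genes}:
            warnings.warn(f"DAR chromosome {dar.chrom!r} has no annotated genes")
    hits: list[tuple[str, str | None]] = []
    for g in chrom_genes:
        for region in REGIONS:
            w = g.region_window(region, promoter_bp, downstream_bp)
            if _overlaps(dar.start, dar.end, *w):
                hits.append((region, g.gene_id))
                break
    return hits if hits else [("distal", None)]


def stratified_association(
    dars: list[DARRecord],
    genes: list[GeneModel],
    deg: pd.DataFrame,
    promoter_bp: int = 3000,
    downstream_bp: int = 3000,
) -> pd.DataFrame:
    """Percentage of genes per class with >= 1 DAR per region × direction.

    ``deg`` must be a classified table (see :func:`classify_deg`) covering
    every gene.  Denominators are the class sizes; a gene counts once per
    (region, direction) cell no matter how many DARs hit it; Up and Down
    DARs are tabulated independently.  Empty classes give missing
    percentages.  Output is long-format with columns gene_class, region,
    dar_direction, n_genes, n_with_dar, percent.
    """
    class_of = dict(zip(deg["gene_id"], deg["gene_class"]))
    missing = [g.gene_id for g in genes if g.gene_id not in class_of]
    if missing:
        raise ValueError(f"genes missing from the DE classification: {sorted(missing)}")

    # per chromosome, vectorized window-overlap with per-gene precedence
    hit: dict[tuple[str, str, str], set[str]] = {
        (cls, region, direction): set()
        for cls in GENE_CLASSES
        for region in REGIONS
        for direction in DAR_DIRECTIONS
    }
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    dars_by_chrom: dict[str, list[DARRecord]] = {}
    for d in dars:
        dars_by_chrom.setdefault(d.chrom, []).append(d)

    for chrom, chrom_genes in genes_by_chrom.items():
        chrom_dars = dars_by_chrom.get(chrom, [])
        if not chrom_dars:
            continue
        ds = np.array([d.start for d in chrom_dars])
        de = np.array([d.end for d in chrom_dars])
        direction = np.array([d.direction for d in chrom_dars])
        windows = {
            region: np.array(
                [g.region_window(region, promoter_bp, downstream_bp) for g in chrom_genes]
            )
            for region in REGIONS
        }
        overlap = {
            region: (windows[region][:, [0]] < de[None, :])
            & (ds[None, :] < windows[region][:, [1]])
            for region in REGIONS
        }
        pair_class = {
            "promoter": overlap["promoter"],
            "gene_body": overlap["gene_body"] & ~overlap["promoter"],
            "downstream": overlap["downstream"]
            & ~overlap["promoter"]
            & ~overlap["gene_body"],
        }
        for region in REGIONS:
            for dir_label in DAR_DIRECTIONS:
                mask = pair_class[region][:, direction == dir_label].any(axis=1)
                for gi in np.nonzero(mask)[0]:
                    g = chrom_genes[gi]
                    hit[(class_of[g.gene_id], region, dir_label)].add(g.gene_id)

    class_sizes = {cls: 0 for cls in GENE_CLASSES}
    for g in genes:
        class_sizes[class_of[g.gene_id]] += 1
    records = []
    for direction in DAR_DIRECTIONS:
        for cls in GENE_CLASSES:
            for region in REGIONS:
                n = class_sizes[cls]
                k = len(hit[(cls, region, direction)])
                percent = 100.0 * k / n if n else np.nan
                records.append((cls, region, direction, n, k, percent))
    return pd.DataFrame(
        records,
        columns=["gene_class", "region", "dar_direction", "n_genes", "n_with_dar", "percent"],
    )


# ---------------------------------------------------------------------------
# readers (BED6 / GTF genes, BED-like DAR TSV, DE TSV)


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (chrom, start, end, name, score, strand)."""
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns")
        genes.append(
            GeneModel(
                gene_id=parts[3],
                chrom=parts[0],
                start=int(parts[1]),
                end=int(parts[2]),
                strand=parts[5],
            )
        )
    return genes


def read_genes_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene features from GTF (1-based closed, converted to half-open)."""
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"{path}:{lineno}: GTF requires 9 columns")
        if parts[2] != "gene":
            continue
        attrs = dict(
            (kv.strip().split(" ", 1)[0], kv.strip().split(" ", 1)[1].strip('"'))
            for kv in parts[8].rstrip(";").split(";")
            if kv.strip()
        )
        if "gene_id" not in attrs:
            raise ValueError(f"{path}:{lineno}: gene feature lacks gene_id attribute")
        genes.append(
            GeneModel(
                gene_id=attrs["gene_id"],
                chrom=parts[0],
                start=int(parts[3]) - 1,
                end=int(parts[4]),
                strand=parts[6],
            )
        )
    return genes


def read_dars_tsv(path: str | Path) -> list[DARRecord]:
    """Read DARs from a BED-like TSV: chrom, start, end, log2FC, fdr."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "log2FC", "fdr"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return [
        DARRecord(
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            log2fc=float(row.log2FC),
            fdr=float(row.fdr),
        )
        for row in df.itertuples()
    ]


def read_de_tsv(path: str | Path) -> pd.DataFrame:
    """Read a DE gene table: gene_id, log2FC, p (extra columns kept)."""
    df = pd.read_csv(path, sep="\t")
    if "pvalue" in df.columns and "p" not in df.columns:
        df = df.rename(columns={"pvalue": "p"})
    required = {"gene_id", "log2FC", "p"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df
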