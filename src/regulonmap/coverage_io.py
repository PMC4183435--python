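"""I/O and depth normalization for strand-specific ChIP-seq coverage.

All in-memory coordinates are 1-based inclusive, matching the convention of
bacterial genome annotations (NC_000913.2-style positions).  A dense per-base
depth vector indexed ``depth[pos - 1]`` represents one strand of one dataset;
bacterial genomes are small enough (<= ~5 Mb) that dense storage is cheap.
Conversions to 0-based half-open coordinates happen only at file boundaries
(bedGraph, BED).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

PLUS = "+"
MINUS = "-"
STRANDS = (PLUS, MINUS)


@dataclass
class StrandCoverage:
    """Per-base read-pileup depth for one strand of one dataset.

    ``total_reads`` is the library size of the dataset the strand belongs to
    (the quantity sequencing depth is normalized on); both strands of a
    dataset share it.
    """

    strand: str
    depth: np.ndarray
    total_reads: float
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be a 1-D per-position vector")
        if np.any(self.depth < 0):
            raise ValueError("depth must be non-negative everywhere")
        if self.total_reads < 0:
            raise ValueError("total_reads must be non-negative")

    @property
    def genome_length(self) -> int:
        return self.depth.size


@dataclass(frozen=True)
class NormalizationConfig:
    """Depth normalization target: every dataset is rescaled to the same
    effective library size (100 million reads by default)."""

    target_reads: float = 100_000_000.0

    def __post_init__(self) -> None:
        if self.target_reads <= 0:
            raise ValueError("target_reads must be > 0")


def normalize_to_depth(
    coverages: Sequence[StrandCoverage],
    cfg: NormalizationConfig = NormalizationConfig(),
) -> list[StrandCoverage]:
    """Rescale all strands of one dataset to the target library size.

    Both strands share a single factor ``target_reads / total_reads`` so the
    relative shape within the dataset is preserved exactly.
    """
    if not coverages:
        return []
    totals = {c.total_reads for c in coverages}
    if len(totals) != 1:
        raise ValueError("all strands of a dataset must share one total_reads")
    total = totals.pop()
    if total <= 0:
        raise ValueError("cannot normalize a dataset with total_reads = 0")
    factor = cfg.target_reads / total
    return [
        replace(c, depth=c.depth * factor, total_reads=cfg.target_reads)
        for c in coverages
    ]


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_strand_coverage(
    path: str | Path, strand: str, genome_length: int, total_reads: float = 0.0,
    dataset_id: str = "",
) -> StrandCoverage:
    """Load a 4-column bedGraph (0-based half-open) into a dense 1-based vector.

    Unspecified positions get depth 0.  Overlapping intervals with conflicting
    values and out-of-bounds intervals are errors.
    """
    depth = np.zeros(genome_length, dtype=float)
    seen = np.zeros(genome_length, dtype=bool)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph record") from exc
            if start < 0 or end > genome_length or start >= end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside genome "
                    f"of length {genome_length}"
                )
            overlap = seen[start:end]
            if overlap.any() and np.any(depth[start:end][overlap] != value):
                raise ValueError(
                    f"{path}:{lineno}: overlapping intervals with conflicting values"
                )
            depth[start:end] = value
            seen[start:end] = True
    return StrandCoverage(strand=strand, depth=depth, total_reads=total_reads,
                          dataset_id=dataset_id)


def write_strand_coverage(cov: StrandCoverage, path: str | Path,
                          chrom: str = "genome") -> None:
    """Write coverage as bedGraph, run-length-compressing constant stretches
    and omitting zero runs (the bedGraph convention)."""
    d = cov.depth
    with open(path, "w") as fh:
        if d.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(d)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [d.size]))
        for s, e in zip(starts, ends):
            v = d[s]
            if v != 0:
                # repr round-trips floats exactly; integers print bare
                text = str(int(v)) if v == int(v) else repr(float(v))
                fh.write(f"{chrom}\t{s}\t{e}\t{text}\n")


# ---------------------------------------------------------------------------
# BED (called peaks)
# ---------------------------------------------------------------------------

def write_peaks_bed(peaks: Iterable, path: str | Path, chrom: str = "genome") -> None:
    """Write called peaks as BED6: 0-based half-open region, name = site id,
    score = integer FAT summary."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for p in peaks:
            start, end = p.region
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{p.site_id}\t{p.fat}\t.\n")


def read_peaks_bed(path: str | Path) -> pd.DataFrame:
    """Read a peaks BED6 back into a table with 1-based inclusive coordinates
    and the center recomputed as the floor midpoint."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise ValueError(f"{path}:{lineno}: expected >=5 BED columns")
            start0, end = int(parts[1]), int(parts[2])
            rows.append(
                dict(site_id=parts[3], start=start0 + 1, end=end,
                     center=(start0 + 1 + end) // 2, fat=float(parts[4]))
            )
    return pd.DataFrame(rows, columns=["site_id", "start", "end", "center", "fat"])


# ---------------------------------------------------------------------------
# GFF3 gene annotation
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from a GFF3 file into a (gene, start, end, strand)
    table with 1-based inclusive coordinates."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = []
    for feat in db.features_of_type("gene", order_by="start"):
        gene = feat.attributes.get("ID", [feat.id])[0]
        rows.append(dict(gene=gene, start=feat.start, end=feat.end,
                         strand=feat.strand))
    if not rows:
        raise ValueError(f"no gene features found in {path}")
    return pd.DataFrame(rows)


def write_gff3_genes(genes: pd.DataFrame, path: str | Path,
                     chrom: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples():
            fh.write(
                f"{chrom}\tregulonmap\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene}\n"
            )


# ---------------------------------------------------------------------------
# Expression tables
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression TSV: gene, one normalized-expression
    column per strain, and a q_value column."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene", "q_value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.shape[1] < 4:
        raise ValueError(f"{path}: expected at least two strain expression columns")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
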