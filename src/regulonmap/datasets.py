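"""Packaged in-study fixtures.

``flia_sites.tsv`` transcribes the 52 sigma-factor (FliA) binding sites of
the study: averaged ChIP peak center, integer FAT score, motif center, the
28-nt motif in motif orientation, the adjacent locus (parenthesized when the
peak center is intragenic), a likely-false-positive flag for the two sites
the study italicized, and normalized expression in the motile wild type and
the deletion strain with its significance flag.

The genomic strand of each motif is not printed in the source table; it was
resolved once, under the study's own convention that canonical promoter
motifs sit upstream of the peak center in motif orientation (minus strand
iff motif center > peak center), and stored in the fixture.

``flhdc_sites.tsv`` transcribes the master-regulator (FlhDC) binding-site
table: averaged peak centers, per-subunit FAT scores, associated
genes/operons (first gene per operon) and their expression in wild-type and
deletion strains.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .coverage_io import MINUS, PLUS
from .motif_localization import MotifOccurrence


def _load(name: str) -> pd.DataFrame:
    with resources.files("regulonmap.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_flia_sites() -> pd.DataFrame:
    """The 52-row sigma-factor binding-site fixture."""
    df = _load("flia_sites.tsv")
    assert len(df) == 52
    return df


def load_flhdc_sites() -> pd.DataFrame:
    """The master-regulator binding-site/expression fixture (one row per
    site-gene pair; the undetected-by-ChIP-seq promoter row has no center)."""
    return _load("flhdc_sites.tsv")


def flia_motif_pairs(df: pd.DataFrame | None = None,
                     ) -> list[tuple[int, MotifOccurrence]]:
    """(peak center, linked motif occurrence) pairs for the 52-site fixture,
    ready for offset summarization."""
    if df is None:
        df = load_flia_sites()
    pairs = []
    for row in df.itertuples():
        occ = MotifOccurrence(
            motif_center=int(row.motif_center), strand=row.motif_strand,
            sequence=row.motif, peak_id=str(row.peak_center),
        )
        pairs.append((int(row.peak_center), occ))
    return pairs


def synthetic_gene_spans_for_flia_sites(
    df: pd.DataFrame | None = None, half_span: int = 200
) -> pd.DataFrame:
    """SYNTHETIC stand-in gene spans consistent with the fixture's
    intragenic/intergenic labels.

    The study classified sites against the complete genome annotation, which
    is not packaged; this constructs a minimal non-overlapping annotation in
    which every intragenic site is covered by a host gene span of
    ``2 * half_span + 1`` bp on the motif strand and no gene covers an
    intergenic site.  It supports classifier checks against the published
    labels, not positional realism.
    """
    if df is None:
        df = load_flia_sites()
    rows = []
    intra = df[df.intragenic == 1].sort_values("peak_center")
    centers = intra.peak_center.to_numpy()
    if np.any(np.diff(centers) <= 2 * half_span):
        raise ValueError("half_span too large: host spans would overlap")
    inter_centers = df.loc[df.intragenic == 0, "peak_center"].to_numpy()
    for k, row in enumerate(intra.itertuples(), start=1):
        start, end = row.peak_center - half_span, row.peak_center + half_span
        if np.any((inter_centers >= start) & (inter_centers <= end)):
            raise ValueError("host span would swallow an intergenic site")
        host = row.locus.split(")")[0].lstrip("(")
        rows.append(dict(gene=host, start=start, end=end,
                         strand=row.motif_strand))
    return pd.DataFrame(rows)
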