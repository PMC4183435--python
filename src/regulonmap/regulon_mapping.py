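"""Overlay binding sites on annotation and differential expression.

Classifies each binding site's genomic location (intragenic vs intergenic,
sense vs antisense), links sites to the genes/operons they can plausibly
drive, partitions the gene universe into direct / indirect /
bound-unregulated / unaffected, compares the magnitude of direct vs indirect
regulation, and assigns each target to a tier of the transcription cascade
(class 2 = master-regulator only, class 3 = sigma-factor only, dual = both).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coverage_io import MINUS, PLUS

REGULATION_CLASSES = ("direct", "indirect", "bound_unregulated", "unaffected")


@dataclass(frozen=True)
class AnnotationConfig:
    upstream_window: int = 300  # bp; "<300 bp upstream of a start codon"
    association_window: int = 300  # bp for site->promoter linking

    def __post_init__(self) -> None:
        if min(self.upstream_window, self.association_window) <= 0:
            raise ValueError("windows must be positive")


def fold_change(a: float, b: float, pseudocount: float = 1.0) -> float:
    """Symmetric fold change (max+psi)/(min+psi) >= 1; the pseudocount keeps
    zero expression values (common for collapsed direct targets) finite."""
    hi, lo = max(a, b), min(a, b)
    return (hi + pseudocount) / (lo + pseudocount)


def significant_de(
    rec: Mapping[str, float] | pd.Series,
    wt: str,
    mutant: str,
    q_max: float = 0.01,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
) -> bool:
    """Differential-expression call: q <= q_max AND fold change >= min_fold
    between the wild-type and mutant strain columns."""
    for col in (wt, mutant, "q_value"):
        if col not in rec or pd.isna(rec[col]):
            raise KeyError(f"record missing value for {col!r}")
    fold = fold_change(float(rec[wt]), float(rec[mutant]), pseudocount)
    return bool(rec["q_value"] <= q_max and fold >= min_fold)


def _start_codon(row) -> int:
    return row.start if row.strand == PLUS else row.end


def classify_site_location(
    center: int,
    genes: pd.DataFrame,
    cfg: AnnotationConfig = AnnotationConfig(),
    site_strand: str | None = None,
) -> dict:
    """Locate a binding-site center relative to the gene annotation.

    intragenic iff the center lies inside a gene span (1-based closed
    intervals; overlapping genes resolve to the nearest midpoint).  When the
    site's motif strand is known, orientation is sense iff it matches the
    host gene's strand.  ``upstream_of_start`` is the distance to the start
    codon of the nearest gene transcribed away from the site.
    """
    if genes.empty:
        raise ValueError("empty annotation")
    hosts = genes[(genes.start <= center) & (genes.end >= center)]
    if len(hosts) > 0:
        mid = (hosts.start + hosts.end) / 2.0
        host = hosts.loc[(mid - center).abs().idxmin()]
        location = "intragenic"
        if site_strand is None:
            orientation = "n/a"
        else:
            orientation = "sense" if site_strand == host.strand else "antisense"
        nearest = host.gene
    else:
        location, orientation, nearest = "intergenic", "n/a", None

    # distance to the nearest appropriately oriented start codon
    plus_d = genes.loc[(genes.strand == PLUS) & (genes.start >= center),
                       "start"] - center
    minus_d = center - genes.loc[(genes.strand == MINUS) & (genes.end <= center),
                                 "end"]
    dists = pd.concat([plus_d, minus_d])
    upstream_of_start = int(dists.min()) if len(dists) else None
    if nearest is None and len(dists):
        nearest = genes.loc[dists.idxmin(), "gene"]
    return dict(location_class=location, orientation=orientation,
                nearest_gene=nearest, upstream_of_start=upstream_of_start)


def associate_sites_with_genes(
    sites: pd.DataFrame,
    genes: pd.DataFrame,
    cfg: AnnotationConfig = AnnotationConfig(),
) -> pd.DataFrame:
    """Link each site (columns: site_id, center, optional strand) to the genes
    it can drive.

    An intergenic site links to every gene whose start codon lies within the
    association window downstream of it, on either side (divergent gene pairs
    yield two links).  An intragenic site links to its host gene (sense or
    antisense recorded) and to the immediately downstream gene when within
    the window.  Windows are inclusive.
    """
    w = cfg.association_window
    rows = []
    for site in sites.itertuples():
        strand = getattr(site, "strand", None)
        loc = classify_site_location(site.center, genes, cfg, site_strand=strand)
        linked: set[str] = set()
        if loc["location_class"] == "intragenic":
            rows.append(dict(site_id=site.site_id, gene=loc["nearest_gene"],
                             link_type=f"host_{loc['orientation']}"))
            linked.add(loc["nearest_gene"])
        near = genes[
            ((genes.strand == PLUS) & (genes.start >= site.center)
             & (genes.start - site.center <= w))
            | ((genes.strand == MINUS) & (genes.end <= site.center)
               & (site.center - genes.end <= w))
        ]
        for g in near.itertuples():
            if g.gene not in linked:
                rows.append(dict(site_id=site.site_id, gene=g.gene,
                                 link_type="promoter"))
                linked.add(g.gene)
    return pd.DataFrame(rows, columns=["site_id", "gene", "link_type"])


def apply_operon_first_gene(
    links: pd.DataFrame, operons: pd.DataFrame | None
) -> pd.DataFrame:
    """Map each linked gene to its operon's first gene (the gene whose
    expression stands for the operon).  ``operons`` columns: operon, gene,
    position (1 = first)."""
    if operons is None or links.empty:
        return links
    first = operons[operons.position == 1].set_index("operon").gene
    gene_to_operon = operons.set_index("gene").operon
    out = links.copy()
    out["gene"] = [
        first.get(gene_to_operon.get(g, None), g) for g in out.gene
    ]
    return out.drop_duplicates(subset=["site_id", "gene"])


def classify_regulation(
    links: pd.DataFrame,
    de: pd.DataFrame,
    wt: str,
    mutant: str,
    q_max: float = 0.01,
    min_fold: float = 2.0,
) -> tuple[pd.DataFrame, dict]:
    """Partition the DE gene universe.

    significant & linked to a site -> direct; significant & unlinked ->
    indirect; linked & not significant -> bound_unregulated; otherwise
    unaffected.  Returns per-gene assignments plus category counts (which sum
    to the universe size).
    """
    bound = set(links.gene) if len(links) else set()
    site_of = (links.groupby("gene").site_id.apply(list).to_dict()
               if len(links) else {})
    rows = []
    for _, rec in de.iterrows():
        sig = significant_de(rec, wt, mutant, q_max=q_max, min_fold=min_fold)
        is_bound = rec.gene in bound
        if sig and is_bound:
            reg = "direct"
        elif sig:
            reg = "indirect"
        elif is_bound:
            reg = "bound_unregulated"
        else:
            reg = "unaffected"
        hi, lo = max(rec[wt], rec[mutant]), min(rec[wt], rec[mutant])
        direction = ("activation" if rec[wt] >= rec[mutant] else "repression")
        rows.append(dict(
            gene=rec.gene, regulation=reg,
            sites=";".join(site_of.get(rec.gene, [])),
            fold=fold_change(rec[wt], rec[mutant]),
            direction=direction if reg == "direct" else
            ("potential" if reg == "bound_unregulated" else "n/a"),
        ))
    assignments = pd.DataFrame(rows)
    counts = {c: int((assignments.regulation == c).sum())
              for c in REGULATION_CLASSES}
    return assignments, counts


def compare_magnitude(
    *groups: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Rank-based comparison of regulation magnitudes (absolute log2 fold
    changes): Mann-Whitney U for two groups (exact for small untied samples),
    Kruskal-Wallis for more."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if len(arrays) == 2:
        a, b = arrays
        pooled = np.concatenate([a, b])
        no_ties = np.unique(pooled).size == pooled.size
        method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*arrays)
    return float(res.statistic), float(res.pvalue)


def classify_network(
    master_assignments: pd.DataFrame,
    sigma_assignments: pd.DataFrame,
) -> pd.DataFrame:
    """Combine per-gene regulon assignments of the master regulator and the
    sigma factor into network classes.

    bound by master only -> class2; sigma only -> class3; both -> dual;
    neither -> none.  Edge labels follow the assignment direction
    (activation / repression for direct targets, potential for bound sites
    without detectable regulation).
    """
    def bound_map(df: pd.DataFrame) -> dict[str, str]:
        out = {}
        for row in df.itertuples():
            if row.regulation in ("direct", "bound_unregulated"):
                out[row.gene] = row.direction
        return out

    m, s = bound_map(master_assignments), bound_map(sigma_assignments)
    rows = []
    for gene in sorted(set(master_assignments.gene) | set(sigma_assignments.gene)):
        in_m, in_s = gene in m, gene in s
        if in_m and in_s:
            cls = "dual"
        elif in_m:
            cls = "class2"
        elif in_s:
            cls = "class3"
        else:
            cls = "none"
        rows.append(dict(gene=gene, network_class=cls,
                         master_edge=m.get(gene, "n/a"),
                         sigma_edge=s.get(gene, "n/a")))
    return pd.DataFrame(rows)


def network_edge_list(network: pd.DataFrame) -> pd.DataFrame:
    """Flatten a network classification into regulator->gene edges."""
    rows = []
    for row in network.itertuples():
        if row.master_edge != "n/a":
            rows.append(dict(regulator="master", gene=row.gene,
                             label=row.master_edge))
        if row.sigma_edge != "n/a":
            rows.append(dict(regulator="sigma", gene=row.gene,
                             label=row.sigma_edge))
    return pd.DataFrame(rows, columns=["regulator", "gene", "label"])
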