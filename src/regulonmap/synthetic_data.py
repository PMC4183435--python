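"""Synthetic data generation for the whole pipeline.

Emulates the statistical structure a bacterial ChIP-seq + RNA-seq regulon
study assumes, on a small toy genome:

* near-zero Poisson background with a handful of sharply enriched, bimodal,
  strand-offset binding sites shared by two tagged replicates;
* an untagged control sharing a few artifact regions with the tagged data;
* a gene annotation tiling the genome with a configurable intergenic
  fraction (~11% by default, the E. coli value);
* differential-expression tables in which directly activated genes collapse
  to near zero in regulator-deletion strains while indirect targets change
  modestly;
* qPCR Ct tables generated as the exact inverse of the efficiency-corrected
  relative-quantification formula.

Coverage is emitted near the normalized depth scale, with per-dataset
library sizes jittered around 100 million reads, so that downstream
normalization performs a modest rescale as it does on real libraries of
unequal depth.  Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage_io import (
    MINUS,
    PLUS,
    StrandCoverage,
    write_expression_tsv,
    write_gff3_genes,
    write_strand_coverage,
)

GENE_CLASSES = ("direct_activated", "direct_repressed", "indirect", "unregulated")


@dataclass(frozen=True)
class SimulationConfig:
    genome_length: int = 200_000
    n_sites: int = 10
    site_enrichment: float = 100.0  # mean summit depth, normalized-read units
    strand_offset: int = 50  # bp between plus- and minus-strand summits
    peak_half_width: int = 50  # triangular sub-peak half-width, bp
    background_rate: float = 0.5  # Poisson mean depth per position
    n_artifacts: int = 2
    intergenic_fraction: float = 0.11
    replicate_correlation: float = 0.9  # shared fraction of site signal
    summit_jitter: int = 5  # per-replicate site-center jitter, bp
    base_reads: float = 100_000_000.0  # nominal library size
    seed: int = 17
    site_centers: tuple[int, ...] | None = None  # explicit placement override

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be > 0")
        if not (0 <= self.intergenic_fraction < 1):
            raise ValueError("intergenic_fraction must be in [0, 1)")
        if not (0 <= self.replicate_correlation <= 1):
            raise ValueError("replicate_correlation must be in [0, 1]")
        if self.n_sites < 0 or self.n_artifacts < 0:
            raise ValueError("site counts must be >= 0")
        if self.site_enrichment < 0 or self.background_rate < 0:
            raise ValueError("rates must be >= 0")
        if self.site_centers is not None and len(self.site_centers) != self.n_sites:
            raise ValueError("site_centers must match n_sites when given")

    @property
    def min_site_separation(self) -> int:
        # spiked centers must not interleave: two strand offsets plus the
        # full (2 * half_width) footprint of a sub-peak
        return 2 * self.strand_offset + 2 * self.peak_half_width


@dataclass
class TruthTable:
    site_centers: list[int]
    artifact_centers: list[int]
    gene_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls in self.gene_classes.values():
            if cls not in GENE_CLASSES:
                raise ValueError(f"unknown gene class {cls!r}")


@dataclass
class ChipExperiment:
    """Tagged and control replicate pairs plus the generating truth."""

    tagged: dict[int, dict[str, StrandCoverage]]
    control: dict[int, dict[str, StrandCoverage]]
    truth: TruthTable
    config: SimulationConfig


def _place_centers(rng: np.random.Generator, cfg: SimulationConfig,
                   n: int) -> np.ndarray:
    """Place n centers with pairwise separation >= min_site_separation and a
    margin from the genome edges, by rescaling sorted uniforms."""
    if n == 0:
        return np.array([], dtype=int)
    margin = cfg.strand_offset + cfg.peak_half_width + 1
    sep = cfg.min_site_separation
    free = cfg.genome_length - 2 * margin - (n - 1) * sep
    if free <= 0:
        raise ValueError(
            f"cannot place {n} sites with separation >= {sep} bp on a "
            f"{cfg.genome_length} bp genome (margin {margin} bp each side)"
        )
    u = np.sort(rng.uniform(0, free, size=n))
    centers = (margin + u + np.arange(n) * sep).astype(int)
    return centers


def _add_site(depth_plus: np.ndarray, depth_minus: np.ndarray, center: int,
              height: float, cfg: SimulationConfig) -> None:
    """Add a bimodal site: triangular plus-strand sub-peak upstream of the
    center and minus-strand sub-peak downstream, summits strand_offset apart."""
    half = cfg.strand_offset // 2
    for depth, summit in (
        (depth_plus, center - half),
        (depth_minus, center - half + cfg.strand_offset),
    ):
        w = cfg.peak_half_width
        lo = max(summit - w, 1)
        hi = min(summit + w, depth.size)
        pos = np.arange(lo, hi + 1)
        depth[lo - 1 : hi] += height * (1.0 - np.abs(pos - summit) / w)


def sample_site_centers(config: SimulationConfig, n: int,
                        seed: int | None = None) -> list[int]:
    """Draw n well-separated candidate site centers (public helper for
    building scenarios with explicit, possibly shared, placements)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return [int(c) for c in _place_centers(rng, config, n)]


def generate_chip_experiment(config: SimulationConfig) -> ChipExperiment:
    """Simulate tagged and untagged-control replicate pairs of strand-specific
    coverage, with ground truth for recovery tests."""
    rng = np.random.default_rng(config.seed)
    if config.site_centers is None:
        all_centers = _place_centers(rng, config,
                                     config.n_sites + config.n_artifacts)
        perm = rng.permutation(all_centers.size)
        site_centers = np.sort(all_centers[perm[: config.n_sites]])
        artifact_centers = np.sort(all_centers[perm[config.n_sites :]])
    else:
        site_centers = np.sort(np.asarray(config.site_centers, dtype=int))
        margin = config.strand_offset + config.peak_half_width + 1
        if site_centers.size and (
            site_centers[0] < margin
            or site_centers[-1] > config.genome_length - margin
            or (site_centers.size > 1
                and np.diff(site_centers).min() < config.min_site_separation)
        ):
            raise ValueError(
                f"explicit site_centers violate the >= "
                f"{config.min_site_separation} bp separation or edge margin"
            )
        for _ in range(1000):
            artifact_centers = np.sort(
                _place_centers(rng, config, config.n_artifacts))
            if not site_centers.size or not artifact_centers.size:
                break
            gaps = np.abs(artifact_centers[:, None] - site_centers[None, :])
            if gaps.min() >= config.min_site_separation:
                break
        else:
            raise ValueError("could not place artifacts clear of the given "
                             "site_centers")

    # site heights shared across replicates up to replicate_correlation
    def heights(n: int) -> np.ndarray:
        if n == 0:
            return np.array([])
        return rng.gamma(shape=4.0, scale=config.site_enrichment / 4.0, size=n)

    shared_site_h = heights(config.n_sites)
    shared_art_h = heights(config.n_artifacts)

    def replicate(centers: np.ndarray, shared_h: np.ndarray,
                  dataset_id: str) -> dict[str, StrandCoverage]:
        g = config.genome_length
        plus = rng.poisson(config.background_rate, size=g).astype(float)
        minus = rng.poisson(config.background_rate, size=g).astype(float)
        indep_h = heights(centers.size)
        rho = config.replicate_correlation
        for k, c in enumerate(centers):
            jitter = int(rng.integers(-config.summit_jitter,
                                      config.summit_jitter + 1))
            h = rho * shared_h[k] + (1.0 - rho) * indep_h[k]
            _add_site(plus, minus, int(c) + jitter, h, config)
        total = float(round(config.base_reads * rng.uniform(0.85, 1.2)))
        return {
            PLUS: StrandCoverage(PLUS, plus, total, dataset_id),
            MINUS: StrandCoverage(MINUS, minus, total, dataset_id),
        }

    tagged_centers = np.concatenate([site_centers, artifact_centers])
    tagged_h = np.concatenate([shared_site_h, shared_art_h])
    tagged = {r: replicate(tagged_centers, tagged_h, f"tagged_rep{r}")
              for r in (1, 2)}
    control = {r: replicate(artifact_centers, shared_art_h, f"control_rep{r}")
               for r in (1, 2)}
    truth = TruthTable(
        site_centers=[int(c) for c in site_centers],
        artifact_centers=[int(c) for c in artifact_centers],
    )
    return ChipExperiment(tagged=tagged, control=control, truth=truth,
                          config=config)


def generate_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Generate a non-overlapping gene annotation whose realized intergenic
    fraction lies within +/-0.02 of the configured value.

    Gene lengths are drawn around ~1 kb (a bacterial gene-length scale) until
    the coding target is met; the remaining sequence is split into randomly
    sized intergenic gaps.  Coordinates are 1-based inclusive.
    """
    rng = np.random.default_rng(config.seed + 1)
    g = config.genome_length
    coding_target = int(round((1.0 - config.intergenic_fraction) * g))
    lengths: list[int] = []
    total = 0
    while total < coding_target:
        ln = int(np.clip(rng.lognormal(mean=math.log(950.0), sigma=0.45),
                         90, 6000))
        ln = min(ln, coding_target - total)
        lengths.append(ln)
        total += ln
    n_genes = len(lengths)
    if n_genes == 0:
        raise ValueError("intergenic_fraction leaves no room for genes")
    intergenic_total = g - total
    if intergenic_total > 0:
        props = rng.dirichlet(np.ones(n_genes + 1))
        gaps = np.floor(props * intergenic_total).astype(int)
        gaps[-1] += intergenic_total - gaps.sum()
    else:
        gaps = np.zeros(n_genes + 1, dtype=int)
    rows = []
    pos = 1
    for i, ln in enumerate(lengths):
        pos += int(gaps[i])
        rows.append(
            dict(gene=f"g{i + 1:04d}", start=pos, end=pos + ln - 1,
                 strand=PLUS if rng.random() < 0.5 else MINUS)
        )
        pos += ln
    genes = pd.DataFrame(rows)
    assert abs(realized_intergenic_fraction(genes, g)
               - config.intergenic_fraction) <= 0.02
    return genes


def realized_intergenic_fraction(genes: pd.DataFrame, genome_length: int) -> float:
    """Fraction of the genome not covered by (non-overlapping) genes."""
    return 1.0 - (genes.end - genes.start + 1).sum() / genome_length


def assign_gene_classes(
    truth: TruthTable,
    genes: pd.DataFrame,
    config: SimulationConfig,
    n_indirect: int = 10,
    activated_fraction: float = 0.8,
    association_window: int = 300,
) -> TruthTable:
    """Label genes as direct (downstream of a spiked site), indirect, or
    unregulated, completing the ground truth for regulon-recovery tests."""
    rng = np.random.default_rng(config.seed + 2)
    classes = {gene: "unregulated" for gene in genes.gene}
    direct: list[str] = []
    for c in truth.site_centers:
        plus_ok = genes[(genes.strand == PLUS) & (genes.start >= c)
                        & (genes.start - c <= association_window)]
        minus_ok = genes[(genes.strand == MINUS) & (genes.end <= c)
                         & (c - genes.end <= association_window)]
        cands = pd.concat([plus_ok, minus_ok])
        if cands.empty:
            # fall back to the nearest gene start so every site regulates one
            dist = np.minimum(np.abs(genes.start - c), np.abs(genes.end - c))
            cands = genes.iloc[[int(dist.idxmin())]]
        direct.append(cands.iloc[0].gene)
    for gene in direct:
        classes[gene] = ("direct_activated"
                         if rng.random() < activated_fraction
                         else "direct_repressed")
    free = [gn for gn in genes.gene if classes[gn] == "unregulated"]
    for gene in rng.choice(free, size=min(n_indirect, len(free)),
                           replace=False):
        classes[gene] = "indirect"
    truth.gene_classes = classes
    return truth


def generate_expression_table(
    truth: TruthTable,
    strains: Sequence[str] = ("WT", "delta"),
    seed: int = 17,
) -> pd.DataFrame:
    """Simulate a normalized-expression table for a wild type and deletion
    strains, honoring the truth classes: direct_activated genes collapse to
    near zero in the deletion (fold >= 100 with the pseudocount convention),
    indirect genes change 2-4-fold, unregulated genes stay within 2-fold."""
    if len(strains) < 2:
        raise ValueError("need a wild-type and at least one deletion strain")
    if not truth.gene_classes:
        raise ValueError("truth has no gene classes; run assign_gene_classes")
    rng = np.random.default_rng(seed)
    wt_name, deletions = strains[0], strains[1:]
    rows = []
    for gene, cls in truth.gene_classes.items():
        if cls not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {cls!r}")
        row: dict = {"gene": gene}
        if cls == "direct_activated":
            wt = int(rng.integers(300, 3000))
            mut = lambda: int(rng.integers(0, 2))
            q = rng.uniform(0.0, 0.009)
        elif cls == "direct_repressed":
            wt = int(rng.integers(3, 40))
            mut = lambda: int(round((wt + 1) * rng.uniform(6.0, 15.0)))
            q = rng.uniform(0.0, 0.009)
        elif cls == "indirect":
            wt = int(rng.integers(50, 800))
            if rng.random() < 0.5:
                mut = lambda: int(round(wt / rng.uniform(2.2, 4.0)))
            else:
                mut = lambda: int(round(wt * rng.uniform(2.2, 4.0)))
            q = rng.uniform(0.0, 0.009)
        else:
            wt = int(rng.integers(5, 800))
            mut = lambda: int(round(wt * rng.uniform(0.75, 1.3)))
            q = rng.uniform(0.02, 1.0)
        row[wt_name] = wt
        for d in deletions:
            row[d] = mut()
        row["q_value"] = q
        rows.append(row)
    return pd.DataFrame(rows)


def generate_ct_table(
    true_ratios: Mapping[str, float],
    reference_gene: str = "mreB",
    target_gene: str = "target",
    calibrator_sample: str | None = None,
    seed: int = 17,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    base: float = 1.9,
) -> pd.DataFrame:
    """Generate a qPCR Ct table whose efficiency-corrected relative
    quantification recovers ``true_ratios`` (expression relative to the
    calibrator sample, the first key by default).

    Inverse construction: dCt_s = -log(ratio_s) / log(base) (+ noise), with
    reference Ct around 20 cycles and a per-sample loading shift.
    """
    samples = list(true_ratios)
    if not samples:
        raise ValueError("true_ratios is empty")
    for s, r in true_ratios.items():
        if r <= 0:
            raise ValueError(f"non-positive expression ratio for sample {s!r}")
    calibrator_sample = calibrator_sample or samples[0]
    rng = np.random.default_rng(seed)
    rows = []
    for s in samples:
        shift = rng.normal(0.0, 0.3)
        ct_ref = 20.0 + shift
        dct = -math.log(true_ratios[s]) / math.log(base)
        for rep in range(1, n_replicates + 1):
            rows.append(dict(sample=s, gene=reference_gene, replicate=rep,
                             ct=ct_ref + rng.normal(0.0, noise_sd),
                             role="reference",
                             calibrator=s == calibrator_sample))
            rows.append(dict(sample=s, gene=target_gene, replicate=rep,
                             ct=ct_ref + dct + rng.normal(0.0, noise_sd),
                             role="target",
                             calibrator=s == calibrator_sample))
    return pd.DataFrame(rows)


def write_experiment(exp: ChipExperiment, genes: pd.DataFrame,
                     expression: pd.DataFrame, out_dir: str | Path) -> None:
    """Write an experiment to disk: 4 bedGraph tracks per condition,
    GFF3 annotation, truth TSV, expression TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for label, reps in (("tagged", exp.tagged), ("control", exp.control)):
        for r, strands in reps.items():
            for strand, cov in strands.items():
                name = "plus" if strand == PLUS else "minus"
                write_strand_coverage(cov, out / f"{label}.rep{r}.{name}.bedGraph")
    write_gff3_genes(genes, out / "annotation.gff3")
    write_expression_tsv(expression, out / "expression.tsv")
    truth = pd.DataFrame(
        [dict(kind="site", center=c) for c in exp.truth.site_centers]
        + [dict(kind="artifact", center=c) for c in exp.truth.artifact_centers]
    )
    truth.to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    pd.Series(exp.truth.gene_classes, name="class").rename_axis("gene") \
        .to_csv(out / "truth_genes.tsv", sep="\t")
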