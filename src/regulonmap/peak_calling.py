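"""Dual-replicate, strand-aware ChIP-seq peak calling with empirical FDR
threshold selection.

The caller works on normalized per-base coverage of two biological replicates.
Per strand, an integer threshold pair (T1, T2) is chosen from a grid by
exhaustive scan: among all pairs whose estimated false discovery rate under a
no-enrichment null is below the configured bound, the pair maximizing the
estimated number of true-positive positions is kept.  Enriched runs on the
plus and minus strand are then paired into bimodal binding sites, scored as
Fold Above Threshold (FAT = summit depth / threshold), and filtered against
peaks called in an untagged-control experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .coverage_io import MINUS, PLUS, StrandCoverage


@dataclass(frozen=True)
class ThresholdPair:
    """Selected calling thresholds for a replicate pair on one strand."""

    t1: float
    t2: float
    strand: str = PLUS
    fdr: float = math.nan
    n_positions: int = 0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class PeakCallingConfig:
    t_min: int = 1
    t_max: int = 1000
    fdr_max: float = 0.01
    pair_distance: int = 100
    merge_gap: int = 20
    control_exclusion_distance: int = 50

    def __post_init__(self) -> None:
        if not (0 < self.t_min <= self.t_max):
            raise ValueError("need 0 < t_min <= t_max")
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must be in (0, 1)")
        if min(self.pair_distance, self.control_exclusion_distance) <= 0:
            raise ValueError("distances must be positive")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")


@dataclass
class StrandRegion:
    """A maximal jointly-enriched run on one strand."""

    start: int  # 1-based inclusive
    end: int
    summit: int
    max_depth1: float
    max_depth2: float
    strand: str


@dataclass
class PeakCall:
    """A called binding site: paired plus/minus sub-peaks around a center."""

    center: int
    plus_summit: int
    minus_summit: int
    region: tuple[int, int]
    fat: int = 0
    fat_replicates: tuple[float, float] = (0.0, 0.0)
    site_id: str = ""

    def __post_init__(self) -> None:
        if self.plus_summit > self.minus_summit:
            raise ValueError("plus_summit must be <= minus_summit")
        if self.center != (self.plus_summit + self.minus_summit) // 2:
            raise ValueError("center must be the floor midpoint of the summits")


def _check_pair(rep1: StrandCoverage, rep2: StrandCoverage) -> None:
    if rep1.genome_length != rep2.genome_length:
        raise ValueError("replicate coverages must have equal length")


def estimate_fdr(
    rep1: StrandCoverage,
    rep2: StrandCoverage,
    t: ThresholdPair,
    method: str = "independence",
    n_shifts: int = 20,
    seed: int = 0,
) -> float:
    """Empirical FDR of a threshold pair under the no-enrichment null.

    O = number of positions jointly >= (T1, T2).  Under the default
    independence null the expected null count is E = G * p1 * p2 with p_i the
    marginal exceedance fraction of replicate i; the estimate is E / O.
    ``method="circular"`` instead averages the joint count over random
    circular shifts of replicate 2.  Returns +inf when O = 0.
    """
    _check_pair(rep1, rep2)
    d1, d2 = rep1.depth, rep2.depth
    m1 = d1 >= t.t1
    m2 = d2 >= t.t2
    observed = int(np.count_nonzero(m1 & m2))
    if observed == 0:
        return math.inf
    g = d1.size
    if method == "independence":
        expected = g * (np.count_nonzero(m1) / g) * (np.count_nonzero(m2) / g)
    elif method == "circular":
        rng = np.random.default_rng(seed)
        shifts = rng.integers(1, g, size=n_shifts)
        expected = float(
            np.mean([np.count_nonzero(m1 & np.roll(m2, int(s))) for s in shifts])
        )
    else:
        raise ValueError(f"unknown FDR method {method!r}")
    return expected / observed


def _joint_exceedance_counts(
    d1: np.ndarray, d2: np.ndarray, t_max: int
) -> np.ndarray:
    """O[a, b] = #positions with d1 >= a and d2 >= b for integer a, b in
    [0, t_max].  Computed via a joint histogram of floored depths and a 2-D
    suffix cumulative sum."""
    f1 = np.minimum(np.floor(d1), t_max).astype(np.int64)
    f2 = np.minimum(np.floor(d2), t_max).astype(np.int64)
    n = t_max + 1
    joint = np.bincount(f1 * n + f2, minlength=n * n).reshape(n, n)
    suffix = np.flip(np.cumsum(np.cumsum(np.flip(joint), axis=0), axis=1))
    return suffix


def select_thresholds(
    rep1: StrandCoverage,
    rep2: StrandCoverage,
    cfg: PeakCallingConfig = PeakCallingConfig(),
) -> ThresholdPair | None:
    """Exhaustively scan the integer (T1, T2) grid for one strand.

    Among pairs with estimated FDR strictly below ``cfg.fdr_max``, return the
    pair maximizing the estimated true-positive position count O * (1 - FDR);
    ties broken by smaller T1 + T2, then smaller T1.  None when no pair
    qualifies.
    """
    _check_pair(rep1, rep2)
    g = rep1.genome_length
    suffix = _joint_exceedance_counts(rep1.depth, rep2.depth, cfg.t_max)
    # marginal exceedance counts: row/column 0 of the suffix table
    n1 = suffix[:, 0].astype(float)
    n2 = suffix[0, :].astype(float)
    lo, hi = cfg.t_min, cfg.t_max + 1
    observed = suffix[lo:hi, lo:hi].astype(float)
    expected = np.outer(n1[lo:hi], n2[lo:hi]) / g
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(observed > 0, expected / observed, math.inf)
    qualifying = fdr < cfg.fdr_max
    if not qualifying.any():
        return None
    score = np.full_like(fdr, -math.inf)
    score[qualifying] = observed[qualifying] * (1.0 - fdr[qualifying])
    best = score.max()
    ties = np.argwhere(score == best)
    order = np.lexsort((ties[:, 0], ties[:, 0] + ties[:, 1]))
    i, j = ties[order[0]]
    t1, t2 = int(i + lo), int(j + lo)
    return ThresholdPair(
        t1=t1, t2=t2, strand=rep1.strand,
        fdr=float(fdr[i, j]), n_positions=int(observed[i, j]),
    )


def call_strand_regions(
    rep1: StrandCoverage,
    rep2: StrandCoverage,
    t: ThresholdPair,
    merge_gap: int = 20,
) -> list[StrandRegion]:
    """Maximal runs of positions jointly above threshold in both replicates;
    runs separated by <= merge_gap unenriched positions are merged.  Summit =
    leftmost position maximizing depth1 + depth2 within the region."""
    _check_pair(rep1, rep2)
    mask = (rep1.depth >= t.t1) & (rep2.depth >= t.t2)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2] + 1, edges[1::2]  # 1-based inclusive
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        if s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    combined = rep1.depth + rep2.depth
    regions = []
    for s, e in merged:
        window = combined[s - 1 : e]
        summit = s + int(np.argmax(window))
        regions.append(
            StrandRegion(
                start=s, end=e, summit=summit,
                max_depth1=float(rep1.depth[s - 1 : e].max()),
                max_depth2=float(rep2.depth[s - 1 : e].max()),
                strand=rep1.strand,
            )
        )
    return regions


def pair_strand_peaks(
    plus_regions: Sequence[StrandRegion],
    minus_regions: Sequence[StrandRegion],
    pair_distance: int = 100,
) -> list[PeakCall]:
    """Greedy nearest-summit pairing of plus- and minus-strand regions.

    A pair is admissible when the plus summit lies at or left of the minus
    summit (the strand asymmetry of ChIP fragments) and the summits are
    within ``pair_distance``.  Each region is used at most once; unpaired
    regions are discarded.
    """
    candidates = []
    for i, p in enumerate(plus_regions):
        for j, m in enumerate(minus_regions):
            dist = m.summit - p.summit
            if 0 <= dist <= pair_distance:
                candidates.append((dist, p.summit, i, j))
    candidates.sort()
    used_p: set[int] = set()
    used_m: set[int] = set()
    peaks = []
    for _, _, i, j in candidates:
        if i in used_p or j in used_m:
            continue
        used_p.add(i)
        used_m.add(j)
        p, m = plus_regions[i], minus_regions[j]
        center = (p.summit + m.summit) // 2
        peaks.append(
            PeakCall(
                center=center, plus_summit=p.summit, minus_summit=m.summit,
                region=(min(p.start, m.start), max(p.end, m.end)),
            )
        )
    peaks.sort(key=lambda pk: pk.center)
    for k, pk in enumerate(peaks, start=1):
        pk.site_id = f"peak_{k:03d}"
    return peaks


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compute_fat(
    peak: PeakCall,
    rep1: StrandCoverage | Mapping[str, StrandCoverage],
    rep2: StrandCoverage | Mapping[str, StrandCoverage],
    t: ThresholdPair | Mapping[str, ThresholdPair],
) -> int:
    """Fold Above Threshold for a called peak.

    Per replicate, FAT_i = (max depth inside the peak region, across the
    strands provided) / T_i; when per-strand thresholds are given the ratio is
    maximized over strands.  The summary score is the per-replicate mean
    rounded to an integer (raw values are stored on the peak).
    """
    s, e = peak.region

    def ratios(rep, which: int) -> float:
        covs = rep.values() if isinstance(rep, Mapping) else [rep]
        best = 0.0
        for cov in covs:
            if isinstance(t, Mapping):
                tp = t[cov.strand]
            else:
                tp = t
            thr = tp.t1 if which == 1 else tp.t2
            best = max(best, float(cov.depth[s - 1 : e].max()) / thr)
        return best

    fat1, fat2 = ratios(rep1, 1), ratios(rep2, 2)
    peak.fat_replicates = (fat1, fat2)
    peak.fat = _round_half_up((fat1 + fat2) / 2.0)
    return peak.fat


def adjust_thresholds_for_control(
    t: ThresholdPair,
    tagged_totals: tuple[float, float],
    control_totals: tuple[float, float],
) -> ThresholdPair:
    """Rescale the selected thresholds to the control experiment's library
    sizes (T_i scaled by control_total_i / tagged_total_i)."""
    if min(tagged_totals) <= 0 or min(control_totals) <= 0:
        raise ValueError("read totals must be > 0")
    return ThresholdPair(
        t1=t.t1 * control_totals[0] / tagged_totals[0],
        t2=t.t2 * control_totals[1] / tagged_totals[1],
        strand=t.strand,
    )


def exclude_control_artifacts(
    peaks: Sequence[PeakCall],
    control_peaks: Sequence[PeakCall],
    exclusion_distance: int = 50,
) -> list[PeakCall]:
    """Drop tagged peaks whose center lies within ``exclusion_distance``
    (inclusive) of any control peak center."""
    if not control_peaks:
        return list(peaks)
    centers = np.array([c.center for c in control_peaks])
    return [
        p for p in peaks
        if np.abs(centers - p.center).min() > exclusion_distance
    ]


def merge_factor_peaks(
    peaks_a: Sequence[PeakCall],
    peaks_b: Sequence[PeakCall],
    max_distance: int = 100,
) -> list[dict]:
    """Merge peak lists of two co-binding factors (e.g. the two subunits of a
    heteromeric regulator) for reporting: colocalized peaks are averaged into
    one center and their FAT scores reported side by side."""
    rows = []
    used_b: set[int] = set()
    for p in peaks_a:
        match = None
        for j, q in enumerate(peaks_b):
            if j not in used_b and abs(q.center - p.center) <= max_distance:
                match = j
                break
        if match is None:
            rows.append(dict(center=p.center, fat_a=p.fat, fat_b=None))
        else:
            used_b.add(match)
            q = peaks_b[match]
            rows.append(
                dict(center=(p.center + q.center) // 2, fat_a=p.fat, fat_b=q.fat)
            )
    for j, q in enumerate(peaks_b):
        if j not in used_b:
            rows.append(dict(center=q.center, fat_a=None, fat_b=q.fat))
    rows.sort(key=lambda r: r["center"])
    return rows
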