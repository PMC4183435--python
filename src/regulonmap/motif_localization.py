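"""Motif-to-peak-center offset analysis.

A sigma factor that binds DNA only as part of RNA polymerase holoenzyme
leaves a characteristic signature: its promoter motif does not sit under the
ChIP peak center but a fixed distance upstream of it, measured in the motif's
own orientation.  The oriented offset is

    plus-strand motif:   offset = peak_center - motif_center
    minus-strand motif:  offset = motif_center - peak_center

so positive values mean the motif lies upstream of the peak center.  Sites
whose offset deviates strongly from the cluster median are flagged as likely
false positives.  A small log-odds PWM scanner is included to locate motif
occurrences near synthetic peaks; motif discovery itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .coverage_io import MINUS, PLUS

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MotifOccurrence:
    """An oriented motif instance linked to a called peak."""

    motif_center: int
    strand: str
    sequence: str = ""
    peak_id: str | None = None


@dataclass
class MotifOffsetSummary:
    peak_ids: list[str]
    offsets: np.ndarray
    median_offset: float
    flagged_sites: list[str] = field(default_factory=list)


def motif_offset(peak_center: int, occ: MotifOccurrence) -> int:
    """Signed upstream distance (nt) of a motif from its peak center, in the
    motif's orientation; positive = motif upstream."""
    if occ.peak_id is None:
        raise ValueError("occurrence is not linked to a peak")
    if occ.strand == PLUS:
        return peak_center - occ.motif_center
    if occ.strand == MINUS:
        return occ.motif_center - peak_center
    raise ValueError(f"bad strand {occ.strand!r}")


def summarize_offsets(
    pairs: Sequence[tuple[int, MotifOccurrence]]
) -> MotifOffsetSummary:
    """Oriented offsets for a set of (peak center, occurrence) pairs and
    their median (even counts: mean of the central two)."""
    if not pairs:
        raise ValueError("no (peak, motif) pairs supplied")
    offsets = np.array([motif_offset(c, o) for c, o in pairs], dtype=float)
    ids = [o.peak_id for _, o in pairs]
    return MotifOffsetSummary(
        peak_ids=ids, offsets=offsets, median_offset=float(np.median(offsets))
    )


def flag_noncanonical(
    summary: MotifOffsetSummary, max_deviation: float = 25.0
) -> list[str]:
    """Flag sites whose offset deviates from the median by more than
    ``max_deviation`` nt; the flags are recorded on the summary."""
    dev = np.abs(summary.offsets - summary.median_offset)
    flagged = [pid for pid, d in zip(summary.peak_ids, dev) if d > max_deviation]
    summary.flagged_sites = flagged
    return flagged


# ---------------------------------------------------------------------------
# PWM scanning (plumbing for synthetic data)
# ---------------------------------------------------------------------------

def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_center_index(length: int) -> int:
    """Index of the 'center' base within a motif window: the left-of-middle
    base for even lengths (e.g. 13 for a 28-mer), the middle base for odd."""
    return (length - 1) // 2 if length % 2 else length // 2 - 1


def scan_pwm(
    window: str,
    pwm: np.ndarray,
    window_start: int = 1,
    pseudocount: float = 0.0,
) -> MotifOccurrence:
    """Best log-odds hit of a PWM (rows = positions, columns = ACGT
    probabilities summing to 1) against a uniform background, scanning both
    strands of ``window``.  Ties resolve to the leftmost position and then the
    plus strand.  ``window_start`` is the 1-based genome coordinate of the
    window's first base; the returned occurrence center is reported on the
    forward coordinate of the matched slice regardless of strand.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must have shape (motif_length, 4)")
    if pseudocount > 0:
        pwm = pwm + pseudocount
        pwm = pwm / pwm.sum(axis=1, keepdims=True)
    if np.any(pwm <= 0):
        raise ValueError("pwm has zero entries; set a pseudocount")
    length = pwm.shape[0]
    window = window.upper()
    if len(window) < length:
        raise ValueError("window shorter than the motif")
    logodds = np.log2(pwm / 0.25)

    def score(seq: str) -> float:
        return float(sum(logodds[i, _BASE_INDEX[b]] for i, b in enumerate(seq)))

    best: tuple[float, int, int] | None = None  # (score, start, strand_rank)
    for strand_rank, strand in enumerate((PLUS, MINUS)):
        for s in range(len(window) - length + 1):
            sub = window[s : s + length]
            if strand == MINUS:
                sub = reverse_complement(sub)
            sc = score(sub)
            if best is None or sc > best[0] + 1e-12:
                best = (sc, s, strand_rank)
    assert best is not None
    sc, s, strand_rank = best
    strand = PLUS if strand_rank == 0 else MINUS
    center = window_start + s + motif_center_index(length)
    matched = window[s : s + length]
    if strand == MINUS:
        matched = reverse_complement(matched)
    return MotifOccurrence(motif_center=center, strand=strand, sequence=matched)


def consensus_pwm(consensus: str, match_prob: float = 0.94) -> np.ndarray:
    """PWM concentrated on a consensus sequence (plumbing for simulations)."""
    off = (1.0 - match_prob) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus.upper()):
        pwm[i, _BASE_INDEX[b]] = match_prob
    return pwm
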