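"""End-to-end peak-calling pipeline over a two-replicate experiment.

Order of operations: normalize the tagged replicate datasets to the target
library size; per strand, select the (T1, T2) threshold pair by FDR-bounded
grid search; call jointly enriched runs per strand and pair them into
bimodal peaks; score peaks as Fold Above Threshold; rescale the thresholds
to the untagged control's library sizes, call peaks in the control the same
way, and drop tagged peaks within the exclusion distance of a control peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coverage_io import (
    MINUS,
    PLUS,
    NormalizationConfig,
    StrandCoverage,
    normalize_to_depth,
)
from .peak_calling import (
    PeakCall,
    PeakCallingConfig,
    ThresholdPair,
    adjust_thresholds_for_control,
    call_strand_regions,
    compute_fat,
    exclude_control_artifacts,
    pair_strand_peaks,
    select_thresholds,
)


@dataclass
class PeakCallResult:
    peaks: list[PeakCall]
    thresholds: dict[str, ThresholdPair]
    control_peaks: list[PeakCall] = field(default_factory=list)
    excluded: list[PeakCall] = field(default_factory=list)


def _normalize_replicates(
    reps: dict[int, dict[str, StrandCoverage]], norm: NormalizationConfig
) -> dict[int, dict[str, StrandCoverage]]:
    out: dict[int, dict[str, StrandCoverage]] = {}
    for r, strands in reps.items():
        normalized = normalize_to_depth(list(strands.values()), norm)
        out[r] = {c.strand: c for c in normalized}
    return out


def _call_peaks_for_pair(
    reps: dict[int, dict[str, StrandCoverage]],
    thresholds: dict[str, ThresholdPair],
    cfg: PeakCallingConfig,
) -> list[PeakCall]:
    regions = {
        strand: call_strand_regions(
            reps[1][strand], reps[2][strand], thresholds[strand], cfg.merge_gap
        )
        for strand in (PLUS, MINUS)
    }
    peaks = pair_strand_peaks(regions[PLUS], regions[MINUS], cfg.pair_distance)
    for p in peaks:
        compute_fat(p, reps[1], reps[2], thresholds)
    return peaks


def call_peaks(
    tagged: dict[int, dict[str, StrandCoverage]],
    control: dict[int, dict[str, StrandCoverage]] | None = None,
    cfg: PeakCallingConfig = PeakCallingConfig(),
    norm: NormalizationConfig = NormalizationConfig(),
) -> PeakCallResult:
    """Run the full caller on tagged (and optionally control) replicate
    pairs keyed as {replicate: {strand: coverage}}."""
    tagged_n = _normalize_replicates(tagged, norm)
    thresholds: dict[str, ThresholdPair] = {}
    for strand in (PLUS, MINUS):
        t = select_thresholds(tagged_n[1][strand], tagged_n[2][strand], cfg)
        if t is None:
            return PeakCallResult(peaks=[], thresholds=thresholds)
        thresholds[strand] = t
    peaks = _call_peaks_for_pair(tagged_n, thresholds, cfg)

    control_peaks: list[PeakCall] = []
    if control is not None:
        # the control stays at raw scale; thresholds are rescaled to its
        # library sizes instead
        ctrl_thresholds = {
            strand: adjust_thresholds_for_control(
                thresholds[strand],
                tagged_totals=(norm.target_reads, norm.target_reads),
                control_totals=(
                    control[1][strand].total_reads,
                    control[2][strand].total_reads,
                ),
            )
            for strand in (PLUS, MINUS)
        }
        control_peaks = _call_peaks_for_pair(control, ctrl_thresholds, cfg)
    kept = exclude_control_artifacts(
        peaks, control_peaks, cfg.control_exclusion_distance
    )
    excluded = [p for p in peaks if p not in kept]
    return PeakCallResult(peaks=kept, thresholds=thresholds,
                          control_peaks=control_peaks, excluded=excluded)
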