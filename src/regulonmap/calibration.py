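"""Null calibration of the threshold-selection procedure.

Repeatedly simulates pure-background replicate pairs (no enriched sites, no
artifacts), runs per-strand threshold selection with the default
configuration, and records every threshold pair the procedure accepts along
with its estimated FDR.  On data where nothing is enriched the procedure
should essentially never accept thresholds, and any pair it does accept must
carry an estimated FDR below the configured bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .coverage_io import MINUS, PLUS, NormalizationConfig, normalize_to_depth
from .peak_calling import PeakCallingConfig, ThresholdPair, select_thresholds
from .pipeline import call_peaks
from .synthetic_data import SimulationConfig, generate_chip_experiment


@dataclass
class NullStudyResult:
    n_simulations: int
    accepted: list[tuple[int, str, ThresholdPair]] = field(default_factory=list)
    n_simulations_with_peaks: int = 0
    fdr_bound: float = 0.01

    @property
    def max_accepted_fdr(self) -> float:
        """Largest estimated FDR among accepted threshold pairs (0.0 when the
        procedure accepted none)."""
        return max((t.fdr for _, _, t in self.accepted), default=0.0)


def null_fdr_study(
    n_simulations: int = 200,
    base_seed: int = 1,
    sim_config: SimulationConfig | None = None,
    peak_config: PeakCallingConfig = PeakCallingConfig(),
    norm: NormalizationConfig = NormalizationConfig(),
) -> NullStudyResult:
    """Run ``n_simulations`` pure-null simulations (seeds base_seed,
    base_seed+1, ...) and collect every accepted threshold pair; when a
    simulation accepts thresholds on both strands the full caller is run to
    count spurious peaks."""
    template = sim_config or SimulationConfig(
        genome_length=200_000, background_rate=0.5,
    )
    result = NullStudyResult(n_simulations=n_simulations,
                             fdr_bound=peak_config.fdr_max)
    for i in range(n_simulations):
        cfg = SimulationConfig(
            genome_length=template.genome_length, n_sites=0, n_artifacts=0,
            background_rate=template.background_rate,
            seed=(base_seed + i) % 2**31,
        )
        exp = generate_chip_experiment(cfg)
        accepted_both = True
        for strand in (PLUS, MINUS):
            (r1,) = normalize_to_depth([exp.tagged[1][strand]], norm)
            (r2,) = normalize_to_depth([exp.tagged[2][strand]], norm)
            t = select_thresholds(r1, r2, peak_config)
            if t is None:
                accepted_both = False
            else:
                result.accepted.append((cfg.seed, strand, t))
        if accepted_both:
            peaks = call_peaks(exp.tagged, exp.control, peak_config, norm).peaks
            if peaks:
                result.n_simulations_with_peaks += 1
    return result
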