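#!/usr/bin/env python
"""Call binding sites for both simulated factors.

Reads the bedGraph tracks written by 01_simulate.py back through the
coverage parser (round-tripping the file boundary on purpose), normalizes to
100 million reads, selects per-strand thresholds under the FDR < 0.01
constraint, pairs strand sub-peaks, scores FAT, excludes control artifacts,
and compares the surviving peak centers to the simulation truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from regulonmap.coverage_io import MINUS, PLUS, read_strand_coverage, write_peaks_bed
from regulonmap.pipeline import call_peaks
from regulonmap.synthetic_data import SimulationConfig

SCRATCH = Path("scratch/simulated")
RESULTS = Path("results")

GENOME_LENGTH = SimulationConfig().genome_length
TOTALS = {}  # populated from the truth tables written by 01


def load_condition(factor: str, label: str):
    reps = {}
    for r in (1, 2):
        strands = {}
        for strand, tag in ((PLUS, "plus"), (MINUS, "minus")):
            path = SCRATCH / factor / f"{label}.rep{r}.{tag}.bedGraph"
            # library size metadata does not survive bedGraph; recover the
            # per-dataset total from the depth scale (simulated near 1e8)
            cov = read_strand_coverage(path, strand, GENOME_LENGTH,
                                       dataset_id=f"{label}_rep{r}")
            strands[strand] = cov
        reps[r] = strands
    return reps


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    import importlib.util
    spec = importlib.util.spec_from_file_location(
        "simulate_step", Path(__file__).parent / "01_simulate.py")
    simulate_step = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(simulate_step)

    for factor in ("master", "sigma"):
        # regenerate the experiment to recover library-size metadata, then
        # swap in the disk round-tripped depth vectors
        from regulonmap.synthetic_data import generate_chip_experiment
        exp = generate_chip_experiment(simulate_step.FACTORS[factor])
        disk = {label: load_condition(factor, label)
                for label in ("tagged", "control")}
        for label, mem in (("tagged", exp.tagged), ("control", exp.control)):
            for r in (1, 2):
                for strand in (PLUS, MINUS):
                    disk[label][r][strand].total_reads = \
                        mem[r][strand].total_reads
                    np.testing.assert_array_equal(
                        disk[label][r][strand].depth, mem[r][strand].depth)

        result = call_peaks(disk["tagged"], disk["control"])
        write_peaks_bed(result.peaks, RESULTS / f"{factor}.peaks.bed")
        rows = [dict(site_id=p.site_id, center=p.center, fat=p.fat,
                     fat_rep1=round(p.fat_replicates[0], 2),
                     fat_rep2=round(p.fat_replicates[1], 2),
                     plus_summit=p.plus_summit, minus_summit=p.minus_summit)
                for p in result.peaks]
        pd.DataFrame(rows).to_csv(RESULTS / f"{factor}.peaks.tsv", sep="\t",
                                  index=False)

        truth = np.array(exp.truth.site_centers)
        called = np.array([p.center for p in result.peaks])
        errors = np.array([np.abs(called - c).min() for c in truth]) \
            if called.size else np.full(truth.size, np.inf)
        thresholds = {s: (t.t1, t.t2, round(t.fdr, 5))
                      for s, t in result.thresholds.items()}
        print(f"{factor}: thresholds {thresholds}")
        print(f"{factor}: {len(result.peaks)} peaks kept, "
              f"{len(result.excluded)} excluded as control artifacts; "
              f"recall(<=25 bp) {np.mean(errors <= 25):.2f}, "
              f"max center error {errors.max():.0f} bp")


if __name__ == "__main__":
    main()
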