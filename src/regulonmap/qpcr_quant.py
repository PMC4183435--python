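"""Efficiency-corrected relative quantification for qRT-PCR.

The classic 2^-ddCt scheme assumes perfect doubling per cycle.  Real
amplification is slightly less efficient, so the method here uses a
configurable base (1.9 by default, i.e. 90% efficiency): technical-replicate
Ct values are averaged per (sample, gene), normalized to a reference gene
(mreB by default) to give dCt, converted to base^-dCt, and finally divided by
the mean base^-dCt of the calibrator sample group, whose mean relative
expression is therefore exactly 1.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "gene", "ct", "role")


def _summarize_ct(values: pd.Series, how: str) -> float:
    if how == "mean":
        return float(values.mean())
    if how == "median":
        return float(values.median())
    raise ValueError(f"unknown technical-replicate summary {how!r}")


def relative_expression(
    measurements: pd.DataFrame,
    reference_gene: str = "mreB",
    calibrator_samples: Sequence[str] | None = None,
    base: float = 1.9,
    replicate_summary: str = "mean",
    no_rt_floor: float | None = 30.0,
) -> pd.DataFrame:
    """Relative expression per (sample, target gene).

    ``measurements`` columns: sample, gene, ct, role in {target, reference,
    noRT} (an optional boolean ``calibrator`` column may replace
    ``calibrator_samples``).  no-RT controls are validated against a Ct floor
    and excluded from quantification.  Output columns: sample, gene,
    delta_ct, raw (base^-dCt) and relative (calibrator-normalized).
    """
    for col in REQUIRED_COLUMNS:
        if col not in measurements.columns:
            raise ValueError(f"measurements missing column {col!r}")
    if base <= 1.0:
        raise ValueError("amplification base must exceed 1")
    df = measurements.copy()
    if not np.isfinite(df.ct).all() or (df.ct <= 0).any():
        raise ValueError("Ct values must be finite and positive")

    no_rt = df[df.role == "noRT"]
    if no_rt_floor is not None and len(no_rt) and (no_rt.ct < no_rt_floor).any():
        bad = no_rt[no_rt.ct < no_rt_floor].iloc[0]
        raise ValueError(
            f"no-RT control below Ct floor ({bad.ct:.2f} < {no_rt_floor}) "
            f"for sample {bad.sample!r}"
        )
    df = df[df.role != "noRT"]

    if calibrator_samples is None:
        if "calibrator" not in df.columns:
            raise ValueError("need calibrator_samples or a calibrator column")
        calibrator_samples = sorted(df.loc[df.calibrator, "sample"].unique())
    if not len(calibrator_samples):
        raise ValueError("calibrator sample group is empty")

    ct = df.groupby(["sample", "gene"]).ct.apply(
        lambda v: _summarize_ct(v, replicate_summary)
    )
    rows = []
    for sample in df["sample"].unique():
        if (sample, reference_gene) not in ct.index:
            raise ValueError(f"sample {sample!r} lacks reference gene "
                             f"{reference_gene!r} measurements")
        ref_ct = ct[(sample, reference_gene)]
        for gene in df.loc[df["sample"] == sample, "gene"].unique():
            if gene == reference_gene:
                continue
            dct = ct[(sample, gene)] - ref_ct
            rows.append(dict(sample=sample, gene=gene, delta_ct=dct,
                             raw=base ** (-dct)))
    out = pd.DataFrame(rows)
    if out.empty:
        raise ValueError("no target-gene measurements")
    missing = set(calibrator_samples) - set(out["sample"])
    if missing:
        raise ValueError(f"calibrator samples absent from data: {missing}")
    for gene, sub in out.groupby("gene"):
        cal = sub[sub["sample"].isin(calibrator_samples)]
        denom = cal.raw.mean()
        out.loc[sub.index, "relative"] = sub.raw / denom
    return out


def group_summary(relative: pd.DataFrame,
                  groups: pd.Series | dict) -> pd.DataFrame:
    """Mean and SD of relative expression per experimental group (convenience
    for plotting / two-sample tests on biological replicates)."""
    rel = relative.copy()
    rel["group"] = rel["sample"].map(groups)
    return (rel.groupby(["group", "gene"]).relative
            .agg(["mean", "std", "count"]).reset_index())
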