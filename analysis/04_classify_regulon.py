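#!/usr/bin/env python
"""Overlay called binding sites on annotation and differential expression.

For each simulated factor: classify site locations, link sites to candidate
target genes, partition the gene universe into direct / indirect /
bound-unregulated / unaffected, and test whether direct regulation is larger
in magnitude than indirect.  Finally combine the two factors into network
classes (class 2 = master only, class 3 = sigma only, dual = both).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from regulonmap.coverage_io import read_peaks_bed
from regulonmap.regulon_mapping import (
    associate_sites_with_genes,
    classify_network,
    classify_regulation,
    classify_site_location,
    compare_magnitude,
    network_edge_list,
)

RESULTS = Path("results")


def main() -> None:
    genes = pd.read_csv(RESULTS / "simulated/annotation.tsv", sep="\t")
    assignments = {}
    for factor in ("master", "sigma"):
        peaks = read_peaks_bed(RESULTS / f"{factor}.peaks.bed")
        expression = pd.read_csv(RESULTS / f"simulated/{factor}.expression.tsv",
                                 sep="\t")
        mutant = f"delta_{factor}"
        sites = peaks.rename(columns={"center": "center"})[["site_id", "center"]]
        locs = [classify_site_location(c, genes)["location_class"]
                for c in sites.center]
        links = associate_sites_with_genes(sites, genes)
        assign, counts = classify_regulation(links, expression, "WT", mutant)
        assignments[factor] = assign
        assign.to_csv(RESULTS / f"{factor}.assignments.tsv", sep="\t",
                      index=False)
        with open(RESULTS / f"{factor}.regulon_counts.json", "w") as fh:
            json.dump(counts, fh, indent=2)

        mag = np.abs(np.log2((expression.WT + 1) / (expression[mutant] + 1)))
        direct_mag = mag[expression.gene.isin(
            assign.loc[assign.regulation == "direct", "gene"])]
        indirect_mag = mag[expression.gene.isin(
            assign.loc[assign.regulation == "indirect", "gene"])]
        stat, p = compare_magnitude(direct_mag, indirect_mag,
                                    alternative="greater")
        print(f"{factor}: {sum(l == 'intragenic' for l in locs)}/"
              f"{len(locs)} sites intragenic; counts {counts}; "
              f"direct > indirect magnitude p = {p:.2e}")

    net = classify_network(assignments["master"], assignments["sigma"])
    net.to_csv(RESULTS / "network_classes.tsv", sep="\t", index=False)
    network_edge_list(net).to_csv(RESULTS / "network_edges.tsv", sep="\t",
                                  index=False)
    summary = net.network_class.value_counts().to_dict()
    print(f"network classes: {summary}")


if __name__ == "__main__":
    main()
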