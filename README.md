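# regulonmap

Tools for mapping a bacterial transcription-factor regulon by combining
ChIP-seq binding locations with RNA-seq differential expression, modeled on
the analysis of the *Escherichia coli* flagellar cascade (the master
regulator FlhDC and the alternative sigma factor FliA, σ²⁸).

The package reimplements, as a tested library plus a sequence of analysis
scripts, the bespoke computations such a study needs:

- **Dual-replicate, strand-aware peak calling.** Per strand, per-base depth
  of two biological replicates is compared to an integer threshold pair
  (T₁, T₂) ∈ [1, 1000]². The empirical false discovery rate of a pair is
  estimated under the null hypothesis that no region is enriched:
  FDR = E/O, with O the number of positions jointly ≥ (T₁, T₂) and
  E = G·p₁·p₂ the count expected from the marginal exceedance fractions of
  each replicate on a genome of G positions. The pair maximizing the
  estimated true-positive positions O·(1 − FDR) subject to FDR < 0.01 is
  selected; jointly enriched runs on the plus and minus strand are paired
  into bimodal binding sites (plus-strand summit upstream of the
  minus-strand summit, as single-end ChIP fragments dictate), and each peak
  is scored as **FAT (Fold Above Threshold)** = summit depth / threshold,
  averaged over replicates. Peaks within 50 bp of a peak called in an
  untagged-control experiment (with thresholds rescaled to the control's
  library sizes) are discarded as artifacts.
- **Depth normalization** of every dataset to 100 million reads.
- **Motif-offset localization.** For each binding site the oriented offset
  between motif center and peak center (positive = motif upstream, in the
  motif's direction) is summarized by its median; sites whose offset
  deviates from the median by more than 25 nt are flagged as likely false
  positives. A packaged 52-site fixture for FliA reproduces the
  characteristic ~25 nt upstream clustering that indicates the sigma factor
  binds only within RNA polymerase holoenzyme.
- **Regulon classification.** Sites are classified intragenic/intergenic
  (with sense/antisense orientation) against a GFF3 annotation, linked to
  genes whose start codon lies within 300 bp downstream, and combined with
  differential expression (significant iff q ≤ 0.01 and ≥ 2-fold) into
  direct / indirect / bound-unregulated / unaffected calls; two factors'
  calls combine into network classes (class 2 = master only, class 3 =
  sigma only, dual = both). Magnitudes of direct vs indirect regulation are
  compared with rank-based tests (Mann-Whitney / Kruskal-Wallis).
- **qPCR quantification** with the efficiency-corrected relative-expression
  scheme 1.9^(−ΔCt), normalized to a reference gene (*mreB*) and a
  calibrator sample group.
- **Synthetic data** for every stage: strand-offset bimodal coverage spikes
  over Poisson background, shared control artifacts, an annotation with
  ~11% intergenic sequence (the *E. coli* value), expression tables with
  calibrated effect sizes, and Ct tables built as the exact inverse of the
  quantification formula.

## Worked example

`analysis/` contains the study as numbered drivers over the library:

```sh
python analysis/01_simulate.py       # two factors, shared annotation
python analysis/02_call_peaks.py     # thresholds, FAT scores, artifact removal
python analysis/03_motif_offsets.py  # packaged 52-site offset analysis
python analysis/04_classify_regulon.py
python analysis/05_qpcr.py
```

Typical output (seeds fixed in the scripts):

```
master: thresholds {'+': (3, 5, 0.00864), '-': (4, 4, 0.00916)}
master: 12 peaks kept, 2 excluded as control artifacts; recall(<=25 bp) 1.00, max center error 4 bp
52 sites; median oriented offset 26.5 nt upstream of peak centers
flagged as unusually localized (|offset - median| > 25 nt): insB-4/cspH_convergent, (proK)
master: 11/12 sites intragenic; counts {'direct': 12, 'indirect': 10, 'bound_unregulated': 3, 'unaffected': 147}; direct > indirect magnitude p = 1.55e-06
network classes: {'none': 148, 'class2': 11, 'class3': 9, 'dual': 4}
```

Read: both replicates agreed on thresholds around 4 normalized reads with
estimated FDR just under the 0.01 bound; all planted sites were recovered
within 5 bp and both control-shared artifacts were excluded; on the packaged
FliA fixture the motif cluster sits ~25 nt upstream of peak centers and the
two known outliers are flagged; direct targets change far more than indirect
ones; and the four sites planted for both factors come out as dual-regulated.
Tables land under `results/`, large coverage tracks under `scratch/`.

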