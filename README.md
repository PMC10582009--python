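# erosure

Post-variant-calling analysis of genomic erosion in wild populations:
runs of homozygosity (ROH) and the dating of the inbreeding events behind
them, genome-wide diversity, genetic-load accounting, Z(F_ST) selection
scans, and three-level genetic-diversity indicators for conservation
monitoring.

The package is aimed at conservation and population genomicists who already
have a filtered multi-sample VCF (plus a sample sheet, optional BED masks
and a GFF3 annotation) and want the downstream statistics as a tested,
scriptable Python library rather than a chain of shell tools. A synthetic
cohort generator with full ground truth is included, so every stage can be
validated on data whose correct answer is known.

## What it computes

**Inbreeding from ROH.** Homozygous segments are called per individual with
a PLINK-style scanning window (window of 100 SNPs, at most 1 heterozygous
and 5 missing calls per homozygous window, 5 % hit-rate threshold, segments
of ≥ 25 SNPs spanning ≥ 100 kb at ≥ 1 SNP / 50 kb, gaps ≤ 1000 kb, ≤ 750
heterozygotes per segment). F_ROH is the fraction of the autosomal genome
in ROH. A segment of length *L* Mb dates the inbreeding event that created
it to

&nbsp;&nbsp;&nbsp;&nbsp;*g* = 100 / (2 *r* *L*)

generations ago (*r* the recombination rate in cM/Mb, default 1.04;
generation time default 7 years): long ROH mean recent inbreeding.

**Diversity.** Heterozygous sites per kb per individual; nucleotide
diversity π in 50 kb windows; two-population F_ST in sliding windows with
the Weir–Cockerham variance-components estimator (window value
Σa / Σ(a+b+c)) or Hudson's estimator as a ratio of averages.

**Genetic load.** Variants are stratified by SnpEff-style impact (High /
Moderate / Synonymous) and oriented by an outgroup ancestral allele. Total
load counts sites carrying ≥ 1 derived allele per category (normalised by
the individual's synonymous count); realised load is the fraction of a
category's segregating sites an individual exposes homozygous-derived (≤
0.5 by construction). R_xy = Σ f_x(1−f_y) / Σ f_y(1−f_x), normalised by the
same ratio on synonymous sites, compares a category's aggregate derived
frequency between populations x and y; uncertainty comes from a delete-one
jackknife over contiguous genomic blocks.

**Selection scans.** Window F_ST is standardised, Z = (F_ST − μ)/σ;
windows with Z > 5 are outliers, and genes whose spans overlap outlier
windows are candidates.

**Indicators.** ΔH (annualised change in heterozygosity, π or F_ROH, gated
on significance; loss ≤ 0.05 %/yr Acceptable, 0.05–0.3 Warning, > 0.3
Alarm), Ne against the 50/500 rule, and ΔF_ST converted to expected
migrants Nm = (1 − F_ST)/(4 F_ST), with migration reduced ≥ 25 %/≥ 50 % (or
inflated ≥ 50 %/≥ 100 %) classified Warning/Alarm.

## Worked example

`examples/` holds one short script per capability. For instance
`python examples/03_diversity_and_fst.py` simulates two populations of 30
diploids at 50,000 Balding–Nichols sites with divergence parameter
F = 0.10 and prints:

```
mean heterozygosity: 0.206 het sites / kb (counted over 80 Mb of spanned genome)
nucleotide diversity (North): 2.05e-04 per bp over 1600 non-overlapping 50 kb windows
genome-wide Weir-Cockerham F_ST: 0.0996 (simulated divergence parameter: 0.10)
```

The genome-wide weighted Weir–Cockerham estimate (0.0996) recovers the
simulated divergence parameter (0.10) — the closed-form expectation of the
Balding–Nichols model makes this an exact end-to-end check. Similarly,
`python examples/02_roh_and_dating.py` plants homozygous tracts covering
15 % of a simulated genome, recovers them (per-sample F_ROH 0.150–0.151)
and dates each segment, and `python examples/06_indicators.py` classifies a
programmed 0.5 %/yr heterozygosity decline as `Alarm`:

```
Delta-HET: 0.091 -> 0.073 het/kb, -0.49 %/yr (t-test p = 1.67e-18) => Alarm
Ne indicator South: Ne = 353 => Warning
```

A thin CLI mirrors the library
(`erosure simulate|roh|diversity|load|rxy|scan|indicators|run`); `erosure
run --config cfg.yaml` executes the whole pipeline and writes every table
plus a JSON run report.

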