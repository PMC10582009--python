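# Methods

This note documents the statistical procedures the package implements, the
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Genotype representation and input conventions

All statistics operate on a dense samples × sites matrix of diploid
genotype codes (0 hom-reference, 1 heterozygous, 2 hom-alternate, −1
missing) built from a biallelic multi-sample VCF. Multi-allelic records are
dropped rather than split: every downstream statistic assumes two alleles,
and splitting would create artificial haplotype structure. Coordinates stay
in each format's native convention — VCF/GFF3 1-based inclusive, BED
half-open 0-based — converted only at the read boundary. Masks (repeats,
CpG sites, sex-linked scaffolds) are supplied as BED and applied at read
time; masking is idempotent. A complete-case filter (keep only sites called
in every individual) mirrors the common practice of analysing the
intersection callable in all genomes, at the cost of discarding sites —
acceptable when per-sample callability is high and uniform. No further
site-level QC (depth, allelic balance) is applied: that belongs to variant
calling, upstream of this package.

SnpEff-style ANN annotations map to impact categories: protein-truncating
effects (stop gained, splice donor/acceptor, start lost) are High,
missense-class effects Moderate, synonymous Low/Synonymous; everything
intergenic/intronic is Other and excluded from load accounting. When
several effects annotate one site the most severe wins — the convention
SnpEff itself uses for its summary fields. The derived allele is oriented
by the ancestral-allele INFO field (AA) where present; without AA the
reference is assumed ancestral, which is the correct default when reads
were mapped to an outgroup reference assembled for exactly this purpose.

## Runs of homozygosity

The caller reproduces the PLINK scanning-window procedure from hard
genotype calls, with the strict parameterisation used for wild-ungulate
data as defaults: window 100 SNPs, ≤ 1 heterozygous and ≤ 5 missing calls
per homozygous window, hit-rate threshold 0.05, minimum 25 SNPs and 100 kb
per segment, density ≥ 1 SNP/50 kb, gap ≤ 1000 kb, ≤ 750 heterozygotes per
segment. The window-missing limit of 5 is the PLINK default (the other
parameters are commonly reported without it) and is exposed in the
configuration. Three conventions the scanning-window description leaves
open are fixed as follows and enforced by an independent brute-force oracle
in the test suite:

* only windows that fit entirely on the chromosome enter a SNP's hit-rate
  denominator (SNPs near ends use fewer windows; a chromosome with fewer
  SNPs than the window size yields no calls);
* segment boundaries are reported at the outermost passing SNP positions,
  not window edges;
* no heterozygote trimming beyond the pass/fail mechanics — the per-segment
  heterozygote cap exists precisely to keep sequencing errors from cutting
  long ROH.

F_ROH is the summed segment length over the autosomal length, optionally
restricted to a length class (≥ 100 kb, ≥ 2 Mb). Dating uses
g = 100/(2 r L): the expected IBD-segment age for a tract of L Mb under
recombination rate r cM/Mb, multiplied by a generation time (defaults
r = 1.04, 7 years — red-deer estimates appropriate for cervids). Values are
reported unrounded; presentation rounding is the caller's business.

## Diversity statistics

Heterozygosity is the direct count of heterozygous calls per 1000 bp of
callable sequence — deliberately not a maximum-likelihood θ estimator,
since with hard genotypes from uniformly filtered data the count is the
quantity of interest and ML corrections need read-level input. π per site
is 2·c_ref·c_alt/(n(n−1)) over called allele counts, summed in 50 kb
non-overlapping windows and divided by the window length; a callability
track can replace the denominator (whether masked bases should be excluded
from the denominator is a genuine choice; full window length is the
default, matching the usual practice of reporting π against total span).

F_ST uses the Weir–Cockerham variance components a (among populations), b
(among individuals within), c (within individuals) computed per site from
genotype counts, with window values the "weighted" ratio of sums
Σa/Σ(a+b+c); the genome-wide estimate is the same ratio over all sites.
Hudson's estimator (ratio of averages, with the standard finite-sample
correction) is available because SFS-based scans in the literature are
closer to Hudson than to Weir–Cockerham; reproducing a genotype-likelihood
scan exactly from hard calls is not possible, so both estimators are
offered behind one interface. Negative window values are retained —
clamping would bias the Z-transformation that consumes these tracks.
Windows without informative sites are missing (NaN), never zero.

## Genetic load

Sites fixed homozygous-derived in every individual are removed first: they
carry no between-individual information and would inflate every count
equally. Total load counts, per individual and category, the sites
carrying at least one derived allele (an allele-dosage mode is available;
the site-count reading is the default because carrier counts are the usual
published quantity). Normalising by the individual's synonymous count
corrects for mapping/reference bias. Realised load is the number of
homozygous-derived sites over twice the category's segregating-site count,
bounded by 0.5; it measures the exposed fraction of potential load.

R_xy sums f_x(1−f_y) and f_y(1−f_x) over a category's sites and takes the
ratio, then divides by the same ratio over synonymous sites (the
normaliser is a parameter; synonymous is the default for symmetry with the
total-load correction). R_xy = 1 means no frequency difference; the
statistic is exactly reciprocal, rxy(X,Y) = 1/rxy(Y,X). The standard error
is a delete-one jackknife over contiguous genomic blocks — one block per
chromosome by default, or any requested number of contiguous site blocks —
because sites in linkage are not independent; at least three non-empty
blocks are required, and the 95 % interval is ±1.96 SE.

## Selection scan

Z = (F_ST − μ)/σ per window, with μ and σ (sample standard deviation, n−1)
over all non-missing windows; the outlier rule is one-sided Z > 5 by
default ("values outside 5 standard deviations" is read as the upper tail,
since differentiation scans target elevated F_ST; a two-sided flag
exists). Missing windows do not enter μ, σ and cannot be outliers. Gene
intersection reports every gene whose span overlaps an outlier window by
at least 1 bp, comparing gene and window spans on the same coordinate axis
with the gene treated as half-open — a gene starting exactly at a window's
exclusive end does not overlap. Temporal scans (cohort vs cohort within a
population) reuse the identical machinery with cohorts as populations.

## Indicators

Annual change is linear — 100 (m₂ − m₁)/(m₁ · years) — not compound,
matching the framing of thresholds as an annual share of the total change.
Only significant changes count: a Welch t-test decides at α = 0.05, a
Wilcoxon rank-sum test runs alongside, and the report carries a
concordance flag (statuses are computed from the t-test even when the
tests disagree, with the discordance visible). For heterozygosity and
F_ROH the test is unpaired across individuals; for π it compares window
values. F_ROH uses the loss-when-increasing direction: rising inbreeding
is erosion. Band comparisons apply a 10⁻⁹ relative tolerance so a loss
exactly at a threshold at working precision classifies into the milder
band.

Ne thresholds follow the 50/500 rule with the strict inequalities taken
literally: Ne ≥ 500 Acceptable, 50 < Ne < 500 Warning, Ne ≤ 50 Alarm (so
the boundary value 50 is an Alarm). Ne is consumed as an external estimate
(e.g. from LD-based methods); the package does not estimate it.

ΔF_ST pairs windows by coordinates, tests with a paired Wilcoxon
signed-rank, and on a significant change converts the genome-wide mean
window F_ST (median available) at each time point to expected migrants
under Wright's island model, Nm = (1 − F)/(4F) — an explicit modelling
assumption, recorded here because the conversion formula is a choice, not
a law. Migration reduced by ≥ 25 %/≥ 50 % (or inflated by ≥ 50 %/≥ 100 %)
is Warning/Alarm; any population extinct is an Alarm outright. A
significant change whose mean F_ST leaves (0, 1) — complete fixation — is
also an Alarm, as the island model's domain is exceeded.

## Synthetic cohorts

The generator produces exactly the structure the pipeline assumes, with
ground truth. Population allele frequencies follow the Balding–Nichols
model: p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral frequency
p ~ Uniform(0.05, 0.95) (bounded away from fixation so ratio statistics
are not dominated by near-fixed sites; configurable). Genotypes are
Binomial(2, p_k). This gives a closed-form expected F_ST equal to F — the
basis of the estimator-recovery checks — without an external coalescent
simulator. Impact categories are assigned i.i.d. per site with proportions
defaulting to 15 % synonymous, 8 % moderate, 2 % high, 75 % other, the
rough shape of an exome-wide SnpEff tally; per-population multipliers on a
category's derived frequency plant a known R_xy signal. A second time
point either drifts frequencies with per-generation variance p(1−p)/(2Ne)
or applies a programmed annual change in expected heterozygosity by moving
each frequency toward the nearer boundary so 2p(1−p) scales exactly —
deterministic erosion for indicator-recovery tests. Planted ROH overwrite
a sample's genotypes with the population-major homozygote inside random
non-overlapping tracts (exponential lengths above a minimum, last tract
trimmed so the realised fraction matches the target within 10 %).

What the generator does **not** emulate: linkage between sites (sites are
independent; ROH structure is planted, not emergent), sequencing error and
depth variation, allele-frequency spectra under demography, gene
conversion, or selection. Tests passing on this generator therefore
demonstrate correctness of the statistics under their own model
assumptions — estimator consistency, classification logic, oracle
equivalence — not robustness to the artefacts of real resequencing data.

## Problem sizes and determinism

The bundled checks use sizes chosen to make the statistical targets sharp
at interactive cost: 50,000 sites and 30+30 diploids for F_ST recovery
(sampling error well below the ±0.01 target), 20 replicates of 2000 windows
for the neutral outlier count, 50 replicates of 20,000 sites for the
indicator-recovery rate, and 100 replicates of 3000 sites (20 jackknife
blocks) for R_xy interval coverage. All randomness flows through numpy
Generator streams from explicit integer seeds; reruns are bit-identical.
The pipeline orchestrator adds no computation — every output table equals
the corresponding library call — and writes a JSON report with parameters,
stage row counts and indicator statuses.

## Known limitations

* Estimators consume hard genotype calls only; genotype likelihoods, and
  with them coverage-aware estimation, are out of scope.
* The ROH caller is the scanning-window heuristic, not an HMM/IBD model;
  its conventions at chromosome ends follow the choices documented above.
* R_xy block-jackknife intervals are approximate (normal, ±1.96 SE) and
  degrade with very few blocks; the implementation refuses fewer than
  three.
* The island-model Nm conversion inherits all island-model assumptions
  (equilibrium, symmetric migration, no selection); it is a monitoring
  heuristic, not a migration estimate.
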