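# Methods

This note documents the models, parameter choices and numerical decisions
behind `rohvar`, and what the synthetic-data checks do and do not
establish about real data.

## Pedigree model and gene-dropping

Families are built from canonical union types with every ancestor needed
for transmission materialised as a founder:

* `trio` — unrelated parents (offspring *F* = 0);
* `first_cousin` — the parents' fathers (or a father and a mother) are
  full siblings sharing one grandparental couple; parental kinship, and
  hence offspring inbreeding *F*, is 1/16;
* `double_first_cousin` — the parents share both grandparental couples;
  *F* = 1/8.

Kinship and *F* are computed by the standard recursive pedigree
algorithm (`Pedigree.kinship`), which serves as the analytic oracle for
all autozygosity recovery checks.

Gene-dropping assigns each founder chromosome copy a unique integer
ancestry label and transmits recombinant mosaics down the pedigree.
Crossover counts per meiosis are Poisson(length(Mb) × rate/100) with
positions uniform — a uniform genetic map at **1 cM/Mb with no
interference**. A uniform map keeps the analytic expectations exact
(the autozygous fraction of a child is determined by label identity,
whose expectation is *F* regardless of map shape, but segment-length
expectations stay closed-form); chromosome-specific maps can be supplied
via `GenomeModel.recombination_rate` only as a single global rate — map
heterogeneity is deliberately out of scope. Truth autozygosity is the
exact set of intervals where a child's two mosaics carry the same founder
label.

**X chromosome.** Females carry two recombining X's; males carry the
maternal X hemizygously outside the pseudoautosomal regions (PARs). As a
simplification, a son's second copy *within* the PARs is the father's X
restricted to those intervals — X–Y PAR crossover is not simulated. PAR
coordinates default to a scaled GRCh37 convention and are configurable.
Truth autozygosity skips the male X.

## Genome profiles and site synthesis

Two stock profiles: `full_scale_model()` — 22 autosomes in GRCh37
proportions totalling ~2,700 Mb (plus an optional X) — used for
cohort-scale recovery runs; `test_scale_model()` — 4 × 75 Mb autosomes +
60 Mb X — used by the unit tests. The test profile uses few *long*
chromosomes rather than 22 short ones so that autozygous segments (mean
≈ 100/6 cM ≈ 17 Mb for first-cousin offspring at 1 cM/Mb) are not
dominated by chromosome-end truncation.

Variant sites are placed uniformly at the model's density (default
100/Mb; the recovery and fidelity runs use this value, unit fixtures use
10/Mb for speed). Founder alternate alleles are Bernoulli draws at
frequencies uniform on [0.10, 0.50] by default: common enough to pass
the ROH site filter's cohort-MAF > 5% cut with margin, and giving a
non-autozygous heterozygosity of ≈ 0.40 so that ROHs stand out sharply.
Database allele-frequency stamps (1000G/gnomAD/GME columns) are the true
simulated frequency with ±10% relative jitter, clipped to ≥ 0.02, so
background sites are never "rare"; a concordance parameter can make a
fraction of database entries report 0 to exercise the absent-vs-zero
logic. Planted variants are stamped AF 0 in all three databases.

The generator emulates genotype *truth*, not sequencing: GQ is 99,
depths are clean (30×), there is no genotyping error, missingness,
allele-frequency spectrum realism, or linkage disequilibrium among
founder haplotypes. Passing recovery tests therefore demonstrate the
correctness of the algorithms under the stated models, not robustness to
real-data noise; the QC, missingness and PHOM parameters that absorb
such noise in real cohorts are all exposed and tested at their
documented defaults.

## Planted candidate variants

`PlantSpec` inserts events whose attributes sit inside the passing
ranges of the corresponding caller: de novo (child het, parents
hom-ref, allele balance 16/30 ≈ 0.53, QD 12, ReadPosRankSum 0, AF 0,
outside repeat tracks), compound het (two het sites in one synthetic
gene, one transmitted from each parent), hom-in-ROH (child hom-alt
inside a ≥ 1 Mb truth autozygous segment, both parents het), and
X-linked (male child hemizygous-alt with allele balance 29/30, carrier
mother, non-carrier father). When a hom-in-ROH plant targets a child
with no qualifying segment, that child's meioses are redrawn (bounded
retries); this conditions that one child's genome on carrying ≥ 1 Mb of
autozygosity and is used only for planting fixtures, never for the
recovery estimates.

## ROH detection

Sites first pass cohort-level filters: Hardy–Weinberg exact test
P ≥ 0.001, cohort MAF > 5%, missingness ≤ 25%. The HWE test is the
two-sided conditional exact test (sum of configuration probabilities
≤ the observed one), computed with a log-gamma closed form per
heterozygote configuration; an exact-integer enumeration oracle verifies
it to 10⁻⁹ in the tests. A chi-square alternative is intentionally not
provided — at cohort sizes of tens of samples the exact test is the
standard choice.

Detection slides a **100-variant window** allowing ≤ 30 heterozygous and
≤ 30 missing calls; a site joins a candidate run when ≥ 5% of the
windows covering it pass (the hit-fraction convention of the
sliding-window homozygosity tools). The window length is counted in
variants, not base pairs: a 30-heterozygote allowance inside 100 bp
would be unsatisfiable at any realistic density, so the variant-count
reading is the only coherent one; the unit is a parameter
(`window_sites`) and is stated prominently here because other readings
exist. Thresholds of 50/70/80% for PHOM are reachable via `ROHParams`;
the default is **PHOM ≥ 75%** with segments **> 1 Mb**, and per-genome
metrics use autosomal segments only.

**Boundary refinement.** With 30 hets tolerated per window, candidate
runs extend well past a true autozygous boundary (eligibility reaches
flank sites whose covering windows still lean on the homozygous
interior — ~0.6 Mb at 100 sites/Mb and 40% flank heterozygosity).
Emitted segments therefore retract each end until the outermost
`end_refine_sites` (default 15) contain no heterozygote, then snap to
the first/last homozygous site. Against a fully heterozygous flank this
is exact; against realistic flanks the residual bias of the detector's
genome fraction vs truth autozygosity measured +0.01 percentage points
(60 first-cousin children, full-scale genome), with truth-vs-called
Jaccard 0.994 at 100 sites/Mb. The probability that the refinement
falsely retracts into a clean homozygous interior is zero (the interior
contains no heterozygote); in noisy real data with het error rate ε the
expected retraction is ~1/(1−(1−ε)^15) sites, negligible for ε ≤ 5%.
Segment boundaries are reported at observed homozygous sites, never
extrapolated into unobserved flanks.

Merging of ROHs shared by ≥ 2 affected individuals uses single-linkage
chaining of strictly overlapping intervals (1-based inclusive; intervals
that merely touch end-to-start are distinct), with the carrier count of
a merged interval the number of affected individuals whose segment
intersects it. Parental subtraction removes a child segment on *any*
overlap with a parental segment — the conservative reading, since a
partially parental ROH is not evidence of child-specific autozygosity.
Variant-in-ROH partitioning is inclusive on both bounds.

The callable-bases denominator for genome fractions is the total
simulated (autosomal) genome length in the synthetic setting; for real
data a coverage summary (bases at ≥ 1×) should be supplied instead.

## Inheritance calling

All calls require per-genotype QC (FILTER PASS, GQ ≥ 99, called-allele
depth ≥ 10). The depth rule applies to alt-supporting reads for
alt-carrying genotypes (reference reads otherwise); whether the original
filter meant alt or total depth is ambiguous, so the alternative
(`ad_mode="total"`) is one flag away. Allele-balance denominators are
AD ref+alt, not DP. A site with a missing genotype in a required family
member is disqualified for that mode and logged with a reason — no
imputation. De novo cohort-uniqueness is read literally: no sample
outside the child's own family may carry the allele among rare variants.
Compound-het pairing uses transmission phase only; sites where both
parents carry the allele are phase-ambiguous and excluded. Inherited
homozygotes require both parents heterozygous (a homozygous parent
violates full penetrance) and exclude sites homozygous in an unaffected
sibling. X-linked calls require a hemizygous male child, carrier mother
and non-carrier father, and exclude pseudoautosomal sites heterozygous
in the male child.

## Regulatory annotation

BED tracks are 0-based half-open on disk, 1-based inclusive internally;
an SNV at VCF position p overlaps [s, e) iff s < p ≤ e, and indels use
their REF footprint (an indel spanning an element boundary counts as
overlapping — the permissive choice, flagged per call). Brain-promoter
status is membership in any prefrontal-cortex H3K4me3 peak, upgraded to
brain-*specific* when no chromatin-state record labelled
`1_Active_Promoter` from any of the nine non-neuronal cell lines
overlaps the position; enhancers work identically with predicted
regulatory elements and `4_/5_Strong_Enhancer` states. "Any of the nine
cell lines" is existential over the tracks provided; fewer than nine
triggers a warning, not an error. A variant inside both a peak and a
pRE receives both categories. Gene linking reports the target genes of
interaction pairs with one anchor containing the variant and the other
anchor overlapping the target gene's promoter (promoter map optional).
Other chromatin-state labels are carried as free-text notes.

## Burden statistics

ND = exonic synonymous SNVs + non-frameshift indels; LoF = splice site,
stopgain, stoploss, frameshift; MD = nonsynonymous SNVs meeting ≥ 2 of
SIFT < 0.05, PolyPhen-2 HumVar > 0.15, PROVEAN < −2.5,
MutationAssessor > 2.26 (missing scores fail their criterion —
conservative). Nonsynonymous variants failing MD are "unclassified" and
excluded from the ND/MD/LoF tables with counts logged; both tabulations
are available. Burden rates are per 10⁸ bp with the inside denominator
each individual's total ROH length and the outside denominator the
remaining callable genome (the inside-only denominator is printed in the
source analysis; a per-10⁸-bp outside bar forces the dual-denominator
reading). Group contrasts default to Welch's unequal-variance t-test
(`equal_var=True` recovers Student's); identical constant groups return
p = 1 by convention rather than NaN. Raw p-values are reported without
multiplicity correction, matching the descriptive use of these tests.

## Prioritization

Candidate calls are filtered to potentially pathogenic effects
(frameshift, stopgain/stoploss, splicing, unknown — kept to retain
splice-site variants with unannotated protein effect — and deleterious
nonsynonymous). Subpopulation deprioritization: coding MAF ≥ 1%, or
noncoding MAF > 0.1% or any homozygote, in any subpopulation relevant to
the family's ancestry (relevant subpopulations are supplied per family).
Tiers are a pure function of an ordered rationale vector, so every tier
is recomputable from the emitted evidence: excluded if deprioritized;
high for a known ASD/NDD gene, for brain-expressed + deleterious
(coding), or for a validated brain-specific element (noncoding); medium
for exactly one of those evidence legs; low otherwise. The precedence
between partial-evidence combinations is not uniquely determined by the
source description; this codification ships as the default rule table
and is deliberately small enough to audit or replace. Conservation
scores (CADD/phastCons/phyloP/GERP++) are carried as evidence but do not
gate tiers by default because no cutoffs are printed for them; the
per-sample report falls back to medium-priority variants for individuals
with no high-priority call. CNVs are retained when they intersect a
known ASD CNV locus and exceed that locus's median size in ASD cases.

## Problem sizes used in the shipped checks

Autozygosity recovery runs 100–200 independent single-child families
per union type on the full-scale genome (truth estimator and ROH
detector both ~seconds per hundred children); replicate children come
from independent families because children of one couple share the
parents' realized grandparental mosaics, correlating their autozygous
fractions and invalidating the naive standard error. Caller-fidelity
Jaccard uses 6 full-scale children at 100 sites/Mb; oracle-equivalence
suites use ~10³ random fixtures per operation; the exact-test oracle
enumerates all genotype configurations up to n = 15 plus 500 random
configurations to n = 50. All randomness flows from single integer
seeds through `numpy.random.SeedSequence` substreams, so any stage is
independently reproducible.

## Known limitations

No read-level simulation, genotyping error, LD structure, mutation-rate
realism, or map heterogeneity; no statistical (likelihood-based) de novo
caller or mosaicism handling; no X-chromosome ROH metrics; annotation
(effects, damage scores) is consumed as input, never computed; CNV
segmentation and significance testing are upstream of this package.
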