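# Methods

This note documents the statistical models, decision rules, and numerical
choices behind `wes_reanalysis`, and what the synthetic cohorts do and do
not establish about behaviour on real exomes.

## Problem setting

A clinical whole-exome trio (proband plus parents) that remains unsolved
after a first diagnostic pass can often be resolved by systematic
reanalysis: exhaustive coverage of Mendelian inheritance models, explicit
treatment of failure modes of standard pipelines (low-fraction parental
mosaicism, uniparental disomy, single-exon deletions, dinucleotide
substitutions split into two calls), and cohort-level variant burden. The
package implements each of these analyses over a multi-sample VCF (GT and
allelic depths required), a 6-column PED pedigree, and a per-exon read
count table.

## De novo detection

Parental variants are subtracted in silico from the proband's variant
set: a site survives only if the proband's genotype carries the alternate
allele and neither parent's genotype does. Sites where a parent's
genotype is missing are excluded — subtraction requires evidence of
absence — and counted in the log. Survivors then pass four allelic-depth
criteria, all strict inequalities:

1. proband alternate reads > 5;
2. proband alternate/reference read ratio > 30%;
3. reference reads > 10 in both parents;
4. alternate/reference read ratio < 5% in both parents.

Ratios here are alt/ref, not alt/total; the mosaicism analysis below
deliberately uses alt/total. Division-by-zero conventions are ours: a
proband with zero reference reads has ratio +∞ and passes criterion 2; a
parent with zero reference reads fails criterion 3 and renders its
criterion 4 indeterminate (reported as such, never silently passed).
Raising any threshold never adds candidates (monotonicity, property
tested).

## Stepwise inheritance workflow

Variants are first prioritized by annotated population frequency
(MAF < 0.5%, strict; an absent annotation means novel and is retained —
the semantics differ from MAF = 0 in reporting) and consequence class.
Four steps then always run to completion, so a hit in an early step never
hides a second diagnosis:

1. **AR-homozygous** (LOF — stop-gain, frameshift, splice-site — and/or
   missense): proband hom-alt with both parents het. A proband hom-alt
   whose parent lacks the allele is classed `mendelian_inconsistent` and
   routed to the UPD and deletion analyses rather than dropped. Male
   chrX hemizygotes are handled here: mother het or hom yields
   `xl_hemizygous`; maternal absence routes the site through the de novo
   criteria.
2. **Compound heterozygous** (LOF and/or missense): pairs of proband-het
   variants in one gene, one transmitted only by each parent (trans).
   Pairs involving a variant carried by both parents are undecidable and
   reported `phase_unknown`; same-parent pairs are cis and excluded. In
   proband-only mode every rare het pair per gene is `phase_unknown`.
3. **Het-LOF** (LOF only, by design): targets truncating de novo
   candidates. With parents available, only het LOF absent from both
   parents qualifies; proband-only mode reports all rare het LOF.
4. **De novo + mosaic screen**: the de novo detector above, restricted to
   non-synonymous/LOF/splice classes, plus a screen for subtracted sites
   that fail only criterion 4 — the signature of a transmitting parent
   with intermediate alternate reads, i.e. possible mosaicism.

Candidate ordering is deterministic (step, chromosome, position, class);
duplicates by (site, class, sample) are removed.

## Parental mosaicism

The variant allele fraction is the exact rational alt/total. Deviation
from the constitutional-heterozygote expectation of 50% is tested with
the exact two-sided binomial (minimum-likelihood definition: the sum of
probabilities of all outcomes no more probable than the observed count),
delegated to `scipy.stats.binomtest` and cross-checked in the tests
against direct pmf enumeration for all n ≤ 60. A parent is flagged iff:

* at least `require_affected_carriers` (default 1) affected children
  carry the variant;
* the parent has ≥ `min_total_reads` (default 20) total reads and
  ≥ `min_parent_alt_reads` (default 3) alternate reads — carrier
  evidence; a parent with ~zero alternate reads deviates wildly from 50%
  but is a non-carrier, not a mosaic;
* the parent's p-value < α (default 0.01) with the fraction **below**
  50% — mosaicism of a transmitting parent is depletion; an enriched or
  homozygous parent is reported unflagged (`not_depleted`) however
  extreme its p-value — while every carrier child's p-value ≥ α
  (children consistent with constitutional heterozygosity).

α = 0.01 is a conservative default between fractions this analysis
treats as clearly deviant and clearly balanced. The p-values are
per-site; the standalone genome-wide screen applies no multiple-testing
correction, so at depth ~40 a fraction of a percent of ordinary het
parent sites reach p < α by chance — within the pipeline the screen is
restricted to sites the de novo subtraction already surfaced. Percent rendering is the
reporting module's concern. At mosaic fraction 0.15 and mean depth 40 the
flagging sensitivity over seeded replicates is ≈ 0.9; the dominant loss
is the carrier-evidence minimum (about 5% of Binomial(40, 0.15) draws
produce ≤ 2 alternate reads).

## B-allele frequency, AOH, and UPD

BAF at a site is alt/total for the sample; sites with ≥ `min_total_reads`
(default 15) are informative. AOH segments are maximal runs of
consecutive informative markers with BAF outside the heterozygous band
[0.15, 0.85], reported at ≥ 50 markers; low-depth markers neither extend
nor break a run. This run-length formulation is the simplest method
matching the signal; a windowed heterozygosity rate would be an
alternative.

An autosome is flagged as UPD-like when AOH covers ≥ 80% of its
informative markers ("almost the entire chromosome" is not quantified in
the literature; 0.80 is this package's threshold) while AOH on all other
autosomes stays ≤ 10% — the single-region condition. Marker-count
fractions are used rather than base-pair spans because they are robust
to uneven marker grids; segments still record their span fraction.
Multiple qualifying chromosomes indicate consanguinity, not UPD, and
nothing is flagged. chrX is excluded (a male's single X mimics AOH).
Heterodisomic UPD produces no AOH and is undetectable by this method.
Parental origin is inferred from Mendelian-inconsistent homozygous sites:
the parent carrying the proband's allele while the other parent lacks it,
at ≥ 90% of informative inconsistent sites, contributed both homologs.

## Exon-dropout deletions

Per-exon coverage is normalized within each sample —
(read_count / exon_length) divided by the sample's median length-corrected
rate — which is invariant to library-size differences. An exon is a
dropout for a sample when its normalized coverage is ≤ 0.10 of the cohort
median for that exon and that median is ≥ 0.30 (a reliably covered
reference). Maximal contiguous dropout runs of ≥ `min_exons` become
calls; the default of 1 admits single-exon dropout alleles, while setting
3 reproduces the windowed-caller behaviour this method improves on (the
regression suite asserts single-exon events are then missed). Zygosity is
hemizygous for chrX genes in males, homozygous otherwise; exon
coordinates are per-gene indices, keeping the module independent of a
transcript model. Heterozygous-dosage calling is out of scope — it needs
a calibrated diploid baseline.

## Cohort stop-gain scan

Rare (MAF < 0.5% or unannotated) stop-gain variants carried hom-alt or
hemi-alt are tallied per gene as distinct carriers (an individual counts
once per gene; the variant count is reported alongside), sorted by
carrier count with lexicographic tie-breaks. Hemizygous male chrX
stop-gains count as homozygous-equivalent single-allele loss of function.

## Yield reporting

Family outcomes fall into known-gene, novel-gene (more than one family),
candidate-gene (a single family), and unsolved categories; a family is
"solved" under any of the first three. Rates are reported per structure
and phenotype group. The two-stage projection is
`combined = initial + (1 − initial) × residual`, algebraically
`1 − (1 − initial)(1 − residual)`. Percentages round to nearest with
halves away from zero; the bundled 74-family example outcome table
exercises every reported rate. Het candidate SNVs sharing a gene with a
deletion call in the same proband are annotated
`possible_compound_SNV_del` (potential compound SNV + deletion in trans).

## Synthetic cohorts: what they model

The generator emulates the inputs every stage consumes, with no external
data:

* **Site grid**: evenly spaced positions on chromosomes 1–22 and X
  (5 kb spacing from 1 Mb), genes of 10 consecutive sites, background
  allele frequencies from a mixture of point masses at 0.5/0.25/0.10
  (20% each) and a 40% uniform tail on [0, 0.05]. The common component
  keeps heterozygous markers dense enough (per-site het rate ≈ 0.23)
  that 50-marker AOH runs are vanishingly rare outside true AOH. A
  chromosome carrying a planted UPD is padded to ≥ 200 markers.
* **Genotypes**: parental haplotypes are Hardy–Weinberg draws; children
  inherit one allele from each parental haplotype, so background sites
  are Mendelian-consistent by construction. Males are hemizygous on X;
  pseudoautosomal regions are not simulated.
* **Depths**: total reads Poisson(mean depth, default 40); alternate
  reads binomial at the genotype's allele fraction perturbed by a
  substitution-error rate (default 0.005) in which an erroneous base
  lands on the specific alternate with probability e/3 — the standard
  three-alternative substitution model. This is the simplest model
  matching the read-ratio statistics the decision rules consume; no
  mapping artifacts, indel realignment noise, or GC bias are simulated,
  so passing tests bound performance under idealized noise only.
* **Planted events**: de novo (proband het, parents hom-ref), AR
  homozygous, trans compound het, male X hemizygous, mosaic parent
  (parent genotype hom-ref — the caller misses low-fraction mosaicism —
  with depths at the planted fraction), whole-chromosome isodisomic UPD
  (the proband carries two copies of one parental haplotype, with one
  forced site where the excluded parent is hom-ref), and exon dropouts
  (zeroed proband counts over the span). Every event yields exactly one
  truth record.
* **Coverage table**: 30 genes × 8 exons, exon lengths 90–210 bp,
  per-sample library factors uniform on [0.7, 1.3], Poisson counts.
* **MAF annotations are assigned, not recomputed from cohort genotypes**,
  because the pipeline consumes frequency as an annotation.

Identical configuration and seed reproduce byte-identical VCF/PED/TSV
outputs (single `numpy` Generator, fixed draw order, deterministic
writers).

## Problem sizes and numerical choices

The default verification cohort is 10 trios × 20,000 sites at depth 40
with one planted event per class — large enough that AOH, UPD and
deletion statistics are meaningful, small enough that simulation plus the
full pipeline runs in seconds. The de novo rule check enumerates the full
(alt, ref) 0–15 grid for all three trio members (16.7M combinations)
against an exact integer-arithmetic oracle; binomial p-values are checked
against pmf enumeration for all n ≤ 60; AOH segmentation is checked
against an independent regex-based maximal-run oracle on inputs up to
10⁴ markers. Merged dinucleotide variants take the per-sample elementwise
minimum of the member depths (conservative support) and the minimum MAF
when both are annotated, otherwise absent.

## Known limitations

* Read counts come from the VCF AD field, not BAM pileups.
* No ACMG classification, knowledge-base filtering, phenotype matching,
  or pathogenicity prediction: scores arrive as annotations and are
  never hard-filtered on.
* Genotypes are treated as unphased; phase is inferred from parents only.
* Segmental UPD, heterodisomy, and heterozygous deletions are out of
  scope, as is multi-tissue mosaicism modelling.
* Indel left-alignment and reference normalization are assumed done
  upstream.
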