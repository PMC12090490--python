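# Methods

This note documents the models implemented in `recmap`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions used throughout.

## Problem setting

A recessive lethal variant segregating at low frequency in a closed,
AI-bred livestock population is localised and characterised from four data
streams: pedigree records, phased SNP-array genotypes of affected and
control animals, whole-genome variant calls of a few sequenced cases with
control-panel presence flags, and routine mortality and performance
records keyed by sire and maternal-grandsire genotype.  All coordinates
are 1-based inclusive; phased genotypes are assumed imputed (the readers
reject missing alleles rather than imputing silently).

## Pedigree contributions

The expected genetic contribution of ancestor *a* to individual *i* is the
probability that a uniformly chosen autosomal gene copy of *i* descends
from *a* through any path: c(i)=1 if i=a, otherwise
c(i) = (c(sire)+c(dam))/2, with an unknown parent contributing 0 (its gene
mass is booked to "unknown").  This is the standard probability-of-gene-origin
semantics; the recursion is exact and memoised, and is cross-checked in the
tests against vectorised Monte-Carlo gene dropping.  Contributions to a
population are means over members, hence linear in population membership,
and contributions of a complete founder set sum to 1.

Ancestors are ranked by the ratio of contributions to cases versus
controls, with a 1% reporting floor on both contributions; the floor and
the mean/SD summary are report statistics only and never affect the
computation.  One caveat worth knowing: a carrier bull that was itself
heavily used contributes heavily to the *controls* too, so his ratio is
elevated but not necessarily the strict maximum — the robust signature is
a maximal case contribution together with a high ratio.

## Homozygosity mapping

Windows of 20 consecutive informative markers (MAF > 0.01 across the
scanned animals), advanced one marker at a time within each chromosome.
An individual is homozygous for a window haplotype when its two phased
haplotypes are identical across the window and equal that haplotype;
heterozygous carriers therefore count as "any other genotype".  One test
is enumerated per (window, distinct haplotype homozygous in ≥1 case) —
haplotypes homozygous only in controls are not tested — and the Bonferroni
threshold −log10(α/n) uses exactly that test count.

The two-sided Fisher exact p is the conventional point-probability
summation (the sum of hypergeometric probabilities no larger than the
observed table's), delegated to `scipy.stats.fisher_exact` and verified
against exhaustive enumeration for all tables with margins ≤ 30.  At the
observed extremes (all cases homozygous, no controls) sidedness is
immaterial.

Windows in which **all** cases and **no** controls are homozygous merge,
when overlapping, into maximal marker runs.  Fisher p-values tie exactly
whenever tables coincide, so the scan's minimum is generally a plateau of
adjacent windows; `top_windows` returns the full plateau, and among
qualifying runs the mapped one is chosen by best p first and, at exact
ties, by run length.  The mapping interval is bounded by the most proximal
informative markers outside the run; at a chromosome edge it is truncated
at the run boundary (this is the one situation in which the interval does
not strictly contain the merged span).  Carrier status is predicted as the
number of an individual's haplotypes identical to the risk haplotype over
the merged run.

## Variant filtering

Stages applied in order: (i) inside the mapping interval, (ii) homozygous
for the alternate allele in every sequenced case (a missing genotype
fails, and is counted in the trace), (iii) absent from the within-breed
control panel, (iv) absent from the multi-breed panel.  Panel absence is
consumed as precomputed flags — a panel of ~1,900 genomes is not
desk-recomputable — and "not segregating at all" is read absolutely: one
heterozygous control disqualifies.  Counts per stage are monotone
non-increasing by construction and the filter is idempotent.  Structural
variants are accepted when at least two tools report the same type in the
same individual with reciprocal overlap ≥ 0.70 (the threshold must hold in
both directions, which resolves the ambiguity of "mutual overlap").

## Mating-type mortality and penetrance

Mating types are sire × maternal-grandsire risk-allele dosages (1×1, 1×0,
0×1, 0×0), the maternal grandsire standing proxy for ungenotyped dams.
Mortality per period (0–2, 3–14, 15–55, 56–365 days, plus the 0–14
combination computed on the 0–2 at-risk base) is deaths over calves
present at the period start; calves dead earlier are not at risk, censored
calves are excluded.  The one-way fixed-effect model is fitted on 0/100
indicators so means and contrasts print in percent; with mating type the
only factor, each contrast equals the raw-mean difference exactly and its
standard error comes from the pooled residual variance.

The expected excess mortality of at-risk matings under complete penetrance
is (1/(4(2−fA)))(1−μ): a surviving daughter of a carrier bull is
heterozygous with probability 1/(2−fA) (the homozygous class having died,
the wild-type/heterozygous probabilities renormalise to (1−fA)/(2−fA) and
1/(2−fA)), and a homozygous calf requires two independent transmissions of
probability 1/2.  The function is increasing in fA and decreasing in μ.

`penetrance_check` compares the realised fraction of that expectation with
the fraction of cases officially registered, converting both to integer
count pairs out of the reported cases.  It returns **both** a Pearson
chi-squared goodness-of-fit p (df 1) and a Fisher 2×2 p: at such small
counts the two conventions differ materially (≈0.65 versus 1.0 on a 12:9
versus 13:8 comparison), and the package deliberately reports both rather
than choosing silently.

## Mixed-model association

The GRM is VanRaden method 1, G = WW′/(2Σp(1−p)) with W the dosage matrix
centred at sample allele frequencies, markers of the target chromosome
excluded and monomorphic markers dropped; rows of G sum to zero at the
sample frequencies.  For y = 1μ + xb + u + e with u ~ N(0, G σ²ᵤ), the
heritability is estimated by REML under the null model (no x) via a
deterministic 1-D profile-likelihood optimisation on the eigenbasis of G —
no stochastic steps, so results are exactly reproducible and the (costly)
eigendecomposition can be shared across repeated tests on one cohort.
Fixed effects are then estimated by generalised least squares at that
heritability; the residual scale is re-estimated from the full-model
residuals and the test uses a t reference on residual degrees of freedom,
which is indistinguishable from the normal Wald test at cohort sizes and
makes the model collapse exactly to ordinary least squares when h² = 0.
Carrier dosage is coded 0/1: homozygotes of a fully penetrant lethal do
not appear in phenotyped cohorts.  Effect sizes are additionally reported
as |b| divided by the trait's genetic standard deviation.

Benjamini–Hochberg q-values implement the step-up q(k) = min over j ≥ k of
p(j)·n/j, capped at 1, through `statsmodels`' `fdr_bh` corrected p-values.
The hypothesis family is whatever the caller passes — the analyses here
legitimately use several different families (all period × mating-type
contrasts, the at-risk contrasts alone, the performance traits) — and no
global family is assumed.

## Splicing consequences

A gene model is a list of exons in transcription order with CDS bounds in
transcript coordinates.  `build_isoform` splices an inserted segment (a
cryptic exon or retained intron portion) in at an exon junction and
returns the mutant model, so downstream code knows the isoform's own
junction coordinates.  `orf_consequence` translates from the (possibly
shifted) start codon, flags a frameshift when the inserted length is not a
multiple of 3, calls the first stop premature when it yields a protein
shorter than the reference, and predicts nonsense-mediated decay by the
canonical 50-nt rule — the stop must start ≥ 50 nt (configurable) upstream
of the isoform's final exon–exon junction, which is why a PTC in the last
exon of a minigene escapes NMD while the same PTC in the full-length gene
does not.  The truncation fraction is 1 − (mutant amino acids before the
stop / reference amino acids).  The ESE scanner scores additive
position-weight matrices at every offset with no background correction;
matrices are user configuration, and allelic score deltas are antisymmetric
under allele swap.

## The synthetic population generator

The generator emulates the data structure of a closed beef breed under AI:

- **Pedigree**: 1,000 founders, 4 discrete generations, each generation
  bred from all surviving dams mated once (2 offspring per mating) to a
  panel of 25 sires — effective size ≈ 95, within the 12–150 range typical
  of cattle breeds — ~5,000 individuals in total.
- **Genome**: 2,000 markers on four 20-Mb chromosomes, uniform grid with
  jitter (~40 kb spacing, so a 20-marker window spans ~0.8–1 Mb, the
  window scale of a 50K array).  The grid is slightly denser than a real
  50K array relative to map length so that the identical-by-descent core
  shared by an ascertained case series — a few meioses deep — remains
  wider than one window; at a literal 60-kb spacing and deep pedigrees the
  all-case core is frequently shorter than 20 markers and no pedigree
  could map it.  Recombination is Poisson with 1 cM/Mb (the cattle-genome
  convention); founder marker frequencies are uniform above the MAF floor
  (default 0.01) and founders are in Hardy–Weinberg proportions.
- **Risk allele**: seeded on exactly one founder chromosome so that all
  carriers share a single-origin flanking haplotype.  That founder is
  treated as a heavily used AI sire in generation 1 (siring a fraction
  4·fA of matings), which puts the expected allele frequency at its target
  immediately; afterwards the allele drifts, and the population is
  resampled with an incremented seed when the realised final-generation
  frequency misses the target by more than 25% (relative) or fewer than
  `min_cases` homozygotes were born.  Homozygotes die per the
  period-penetrance table (default: complete 0–2-day lethality), so with
  full penetrance no homozygote ever becomes a parent.
- **Case series**: real case series are ascertained — a fixed number of
  reported cases against a birth cohort orders of magnitude larger than is
  simulated — so `n_ascertained_cases` affected offspring are generated
  from carrier × carrier matings drawn from the earliest generations of
  surviving heterozygotes (recent inbreeding loops; distinct dams, sires
  reusable as in AI).  These cases are ordinary pedigree members built by
  the same meiosis code.  The scan studies use a series of 8.
- **Trait**: dosage-additive with the heterozygote effect only (−1.0
  points by default on a trait with genetic variance 22.75, i.e. genetic
  SD 4.77, and residual variance 53.1, h² ≈ 0.3); polygenic values follow
  the midparent + Mendelian-sampling recursion, and dead homozygotes carry
  no phenotype.
- **Mating-type mortality** is simulated separately and vectorised
  (`simulate_matings`): dam genotypes follow the conditional probabilities
  of a surviving carrier's daughter, offspring segregate Mendelianly, and
  homozygotes die with probability μ + penetrance·(1−μ) versus μ for all
  others.  The variant table emulator reproduces the structural counts of
  a sequenced-case candidate list (by default 3,115 in-interval
  case-homozygous variants, 7 absent from the within-breed panel, 1 absent
  from all panels) plus decoys for the earlier stages.

What the generator does **not** emulate: genotyping or imputation error
(phased truth is emitted directly, so carrier-status prediction accuracy
on synthetic data is an upper bound), overlapping generations and
selection, linkage-disequilibrium structure beyond what drift and the
bottlenecks induce, sequence-level reads, and real-genome coordinates.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the study's design assumptions, not performance on real
array data.

## Problem sizes and numerical conventions

The simulation-backed checks run at the scale the analyses are designed
for: 20 seeded populations of ~5,000 individuals × 2,000 markers for scan
localisation; 10⁶ matings per type for the mortality expectation (agreement
within 3 Monte-Carlo SE); n = 5,000 with 50 replicates for mixed-model
effect recovery plus 200 permutations for the 5% type-I error (the GRM
eigendecomposition is computed once and shared); exhaustive Fisher
enumeration over all margins ≤ 30; and 10⁵ gene drops for the contribution
oracle.  Determinism: every stochastic routine takes an explicit integer
seed for a `numpy` PCG64 generator; REML uses bounded scalar minimisation
(tolerance 1e-8) on an exact profile likelihood; eigenvalues are clipped at
zero with a relative PSD tolerance of 1e-6; degenerate inputs (all-zero
contingency tables, zero-length structural variants, zero at-risk counts,
monomorphic markers) are handled explicitly and logged rather than
propagated as NaN.  Display rounding is two decimals for percentages,
matching the tabular conventions of the field; all internal computation is
double precision.
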