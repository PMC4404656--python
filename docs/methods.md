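# Methods

`ncoscan` detects de novo non-crossover (NCO) gene conversion in
three-generation pedigrees genotyped on SNP arrays, and estimates the rate
at which a base pair is covered by a conversion tract, the strength of
GC-biased transmission, and the association of events with recombination
hotspots.  This note records the models, the choices made where the design
was genuinely open, and what the synthetic-data generator does and does not
emulate.

## Detection model

A conversion tract copies a short stretch of sequence from one parental
homolog onto the other during meiosis.  On a transmitted haplotype it
appears as one or more adjacent markers whose alleles derive from the
opposite homolog relative to the flanking background — a double switch
(switch and revert) in the transmission vector, as opposed to the single
non-reverting switch of a crossover (CO).

**Phasing.** Each nuclear family is phased by minimum-recombinant
parsimony: among all ordered-haplotype/transmission assignments consistent
with every genotype, one minimizing the total number of transmission
switches summed over children.  The implementation is an exact dynamic
program over the joint per-child transmission states (4^k states for k
children) with per-marker consistency masks that take the free per-parent
phase labelings into account; the min-plus Hamming relaxation is computed
bit by bit, so a chromosome costs O(markers x 4^k x k).  Exactness is
verified against an independent exhaustive-search oracle in the test
suite.  Forward and backward value tables yield, per transmission and
marker, whether the *received allele* is forced among all minimum-
recombinant solutions; sites where it is not (e.g. markers where every
family member is heterozygous) are ambiguous and excluded from analysis.
Ties between minimum solutions are broken deterministically (continue the
previous state, then lowest state index).  The phase labeling of the first
heterozygous marker of a chromosome is arbitrary.

Families are chained across generations: each analyzed second-generation
child is phased again as a parent in its own nuclear family, and the two
frames are aligned at the first heterozygous marker.  Isolated markers
whose cross-family phase disagrees are masked; runs of 10 or more
successively disagreeing informative markers are interpreted as an
undetected crossover and the phase is inverted from that point on (greedy,
left to right).

**Informative sites.** A site is informative for a (parent, child)
transmission when a conversion there would be detected *and retained*, and
the converted sites (numerator) and informative sites (denominator) of the
rate are ascertained identically.  Requirements whose outcome depends on
the recipient's genotype are therefore evaluated on the *converted*
genotype: the observed one at putative-NCO sites, the counterfactual
allele flip elsewhere (propagated to grandchildren along the recipient's
transmitting-parent chromatid).  Six requirements apply:

* R1 - the parent is heterozygous.
* R2 - a grandchild carries the recipient's chromatid derived from the
  transmitting parent (where a conversion would sit), with its
  allele-from-recipient determinable from genotypes under the converted
  configuration (recipient or partner homozygous, or the grandchild itself
  homozygous) and consistent with the converted allele.
* R3 - not the first or last otherwise-qualifying site of the chromosome
  (detection needs flanking informative sites).
* R4 - siblings attest both parental haplotypes at the site: one shares
  the recipient's background haplotype (validating the allele a conversion
  would replace) and one carries the opposite haplotype (so the parental
  het call does not rest on the putative conversion alone).
* R5 - phase unambiguous across both generations, and still unambiguous
  under the conversion: when the other first-generation parent is
  heterozygous, a conversion is unambiguously placeable only if the
  converted genotype is homozygous and at least two homozygous siblings
  pin the parental phase (a single one yields a minimum-recombinant tie:
  either the recipient or that sibling recombined).
* R6 - when the converted genotype is homozygous, third-generation
  attestation is vacuous (every transmission trivially carries the
  converted allele) and a single het-to-hom miscall in the recipient can
  mimic a conversion; the site counts only if the partner is homozygous
  (forcing grandchild allele attributions, so a suppressed allele would
  surface as a Mendelian conflict) and a grandchild demonstrably received
  the transmitting parent's chromatid.

Requirements referencing conversion status are resolved in two passes
(provisional detection, then final flags).

R4's both-haplotypes form deserves a note.  A rule requiring only a
sibling on the same haplotype leaves a one-error channel open: a
genotyping error in the *other* parent can reinterpret every sibling's
received allele and fabricate a conversion supported by a haplotype the
parent never demonstrably transmitted.  Requiring that siblings attest
both parental haplotypes closes the channel (this is the "parent transmits
only one haplotype" failure mode), and applying it to numerator and
denominator alike keeps the rate estimator unbiased.  The cost is a
somewhat smaller denominator (sites where all siblings happen to share one
haplotype are uninformative).  With this rule the design guarantee holds:
a retained standard call requires at least two genotyping errors, which
the test suite verifies empirically with >= 10,000 single-error injections.

**Event calling.** The transmission vector restricted to informative sites
is segmented into maximal constant runs.  Runs longer than the scan window
(20 informative sites, configurable) and the terminal runs are anchors;
short runs between equal-valued anchors are conversion candidates, and
short runs between opposite-valued anchors are crossover-adjacent and
ambiguous — either the runs matching the left anchor or those matching the
right are the converted sites, and both orientations are kept with weight
0.5 per site.  Ambiguity lapses (weight 1) when the competing orientation
would itself require a conversion of >= 3 sites spanning more than the NCO
span limit.  Tract bounds: the lower bound is the inclusive bp span of the
converted sites, the upper bound the span between the flanking informative
background sites minus one.  Events with lower bound below 5 kb are
classified NCO; larger ones long-range.  Pedigree-level filters then drop
events called in the same interval in two or more children, events at one
site from both parents to one child, events whose grandchild transmission
shows a partial (hence undetected multi-SNP) conversion, and long-range
events lacking clean full-tract transmission to the third generation.
Single-site conversions in grandchild transmissions mask the site for the
whole pedigree, as do sites with any missing genotype.

**Non-standard ascertainment.** At markers where every family member
except one homozygous child is heterozygous, phase within the family is
ambiguous and the site is excluded from both sides of the rate.  A
conversion in the homozygous child can still be recognised when a
sibling's own nuclear family pins the parental phase and the child's
received allele contradicts its background haplotype.  Such events are
flagged `nonstandard`; they enter GC-transmission tallies (allelic
composition is unbiased) but never the rate.

## Rate estimation

SNP-array content is enriched for high-recombination sequence relative to
the genome, so the rate is stratified: sites are annotated with the local
recombination rate (map cM spanned by the surrounding 10 kb divided by
0.01 Mb, linearly interpolated between anchors; sites outside the map span
are dropped), binned into six half-open intervals (default edges 0, 0.1,
0.5, 1, 3, 10, inf cM/Mb — configurable; the edge set is a package
default), and combined as R = sum_b w_b n_b / m_b with w_b the fraction of
mappable genome bp in bin b (evaluated on a 1 kb grid).  Confidence
intervals come from a percentile block bootstrap (default 40,000 reps in
the CLI's headline configuration is impractical at desk scale; the default
here is 1,000) over contiguous genomic blocks (default 10 Mb), with n_b,
m_b and w_b all recomputed per resample, since blocks carry both exposure
and genome composition.

Derived quantities: for coverage rate R, genome length G, mean tract
length l and heterozygosity pi, R*G sites, R*G/l tracts and R*G*pi
heterozygous sites are affected per generation (defaults G = 2.9e9 bp,
l = 75 bp, pi = 1e-3).  The sperm-typing cross-check computes
R = (NCO:CO ratio) x (CO rate per bp) x l.  For clustered events in a
window of genetic length d cM, the expected number of independent
initiations is r = (d / c) x R / l with c = 1.2 cM/Mb the genome-average
CO rate, and the probability of two independent tracts is P = r^2
(no interference assumed).  A chi-square test (bins minus one degrees of
freedom) compares observed converted-site counts per bin with expectations
proportional to informative-site exposure times the bin's mean annotated
rate.

## GC bias and motif scanning

Among converted heterozygous AT/GC sites of unambiguous and non-standard
events, the GC-transmission proportion is tested against 1/2 with the
exact two-sided binomial test (summing outcome probabilities no larger
than the observed outcome's) and summarised with a Clopper-Pearson
interval — chosen over the normal approximation because the exact interval
reproduces whole-percent endpoints correctly at n ~ 100.  Strand-ambiguous
A/T and C/G SNPs are retained for detection but carry no GC information
and are excluded from tallies; 2 x k chi-square tests compare strata (sex,
CpG status, rate bins).  Converted SNPs sitting on a predictive
(non-degenerate) position of a >= 6/8 match to the degenerate 13-mer bound
by PRDM9 A/B (default `CCNCCNTNNCCNC`, both strands, configurable) are
excluded from GC tallies, since transmission distortion there may reflect
binding-site initiation bias rather than repair bias; equally good matches
within +-2 kb are annotated as weakening that reading.

## Hotspot overlap

An event overlaps an interval track when any converted site falls inside
an interval.  Significance is assessed by permutation: for each observed
event a uniformly random informative site is drawn and the same number of
adjacent informative sites (in the informative-site ordering of one
transmission, same chromosome by default) forms a pseudo-event; p uses
add-one smoothing, p = (1 + exceedances) / (1 + permutations), and a
zero-exceedance result is reported as the bound 1/permutations.

## Synthetic-data generator

The generator emulates the study design: three-generation pedigrees (two
founding parents, four children of whom two are analyzed, each with a
married-in partner and three grandchildren — 14 members, matching the
source cohort's mean pedigree size), ~3 kb marker spacing as on a ~1M SNP
array, 99% of markers AT/GC-class, founder allele frequencies uniform on
(0.1, 0.9) with no linkage disequilibrium, map-driven crossovers without
interference, and NCO tracts as a Poisson process with per-bp coverage
rate R (default 5.9e-6), geometric tract lengths (mean 75 bp, minimum 1),
and GC bias b = 0.68.

GC bias is implemented as biased selection of the conversion's host
homolog: proposed tracts are thinned with weight 2b when the donor
homolog carries G/C at a covered heterozygous AT/GC marker and 2(1-b)
when it carries A/T (the first four such markers enter the weight; the
proposal intensity is pre-inflated so post-thinning coverage is exactly
R).  Under this construction every heterozygous marker inside a tract
converts observably, the per-informative-site conversion probability is
exactly R, and the marginal GC-transmission probability at converted AT/GC
sites is exactly b.  A per-site allele redraw (the textbook biased-repair
picture) would instead leave half of in-tract heterozygous sites
unconverted and decouple the observable conversion rate from tract
coverage; the initiation-bias formulation is indistinguishable from biased
repair for every statistic this pipeline measures, and keeps the
generator's R parameter identified with the quantity the estimator
targets.

Genotyping errors perturb calls independently (het to either homozygote
with probability 1/2 each; homozygote to het or to the opposite homozygote
with probability 1/2 each); missingness is independent per call.  Every
tract, crossover, error and missing call is recorded in a truth set.
Tracts never span a same-meiosis crossover; an optional split probability
fragments a tract into two sub-tracts with restored background between
them, emulating clustered discontinuous conversions.  Not emulated: linkage
disequilibrium among founders, array ascertainment beyond density and
allele-class mix, mutation, sex-specific maps by default (distinct maps per
parent sex can be supplied), and structural variation.  Passing recovery
tests on these simulations therefore demonstrates correctness of the
inference machinery under the stated generative model, not robustness to
artefacts absent from it (cryptic duplications, batch effects, LD-driven
phasing shortcuts).

## Verification problem sizes

The packaged experiments use desk-scale problem sizes chosen so each
completes in minutes on one core: parameter recovery uses 100 seeded
datasets of 30 pedigrees x 20 Mb at R = 5e-5 (inflated so tens of events
are expected per dataset), l = 300 bp, b = 0.68, with 1,000-replicate
bootstrap over 2 Mb blocks; the error audit injects 10,000 single errors
into a clean 5-pedigree, 30 Mb, 50k-marker dataset and re-analyzes a
marker window around each injection (windowing is itself validated against
full re-analysis on a subsample); null calibrations use >= 200 seeded
replicates.  The defaults of the generator itself remain the study-scale
values (R = 5.9e-6, l = 75, b = 0.68).

## Interval calibration at low event counts

The percentile block bootstrap is well calibrated at study scale (hundreds
of events over hundreds of genomic blocks) but mildly anti-conservative
when a dataset carries only a handful of events: with ~5 expected events
over a 20 Mb desk-scale genome, the realised coverage of the nominal 95%
interval is ~88-92% rather than 95%, essentially because the percentile
method inherits the skew and discreteness of a small Poisson count and
because event and exposure counts co-vary within blocks.  The effect is a
property of the prescribed interval, not of the estimator (the point
estimate is unbiased — verified over 100 seeded datasets — and refining
the resampling unit from genomic blocks to per-pedigree genomic blocks
changes coverage by only ~1-2 points).  At the rates the method is meant
for (thousands of events genome-wide, or the ~100-event scale of a real
array cohort), the interval is calibrated; for very small studies a
count-based exact interval would be preferable.

## Numerical choices and degenerate inputs

Internal coordinates are 1-based inclusive bp; BED input is converted on
read.  Rate annotations are rounded to 1e-6 cM/Mb before binning so
interpolation jitter cannot scatter exact-edge values across bins.  Bins
with zero informative exposure contribute zero to R (logged).  Empty GC
tallies report NaN proportions and are flagged rather than raising.  A
genetic map shorter than its chromosome is fatal in simulation; sites
whose 10 kb window leaves the map span are annotated missing and excluded
from numerator, denominator and weights alike.  Mendelian-inconsistent
markers are masked per family and logged.  The exact-DP phasing is
exponential in family size and refuses families with more than six
children per nuclear family.

## Known limitations

The detector shares the design's blind spots: conversions that never meet
an informative site are invisible (with array spacing ~3 kb and tracts of
~10^2 bp, the large majority); tract-length bounds are interval censored;
ambiguous crossover-adjacent events are weight-split rather than resolved;
and the rate is a coverage rate, not an initiation rate — converting
between the two requires an assumed mean tract length.  Sex-specific rates
are deliberately not a headline output (array composition confounds the
sex comparison); per-sex counts and positions are reported instead.
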