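# Methods

`camlkit` implements a case–control discovery pipeline for cancer-associated
microsatellite loci (CAML) from germline short-read data, together with a
synthetic-data generator that makes every stage testable without access to
the controlled-access cohorts such studies are normally built on.  This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the simulations do and do not demonstrate.

## Locus model and tandem-repeat scanning

A microsatellite locus is a maximal tandem tract of a primitive 1–7 nt motif
on a reference contig, held as 0-based half-open coordinates with a 1-based
inclusive display form (`chr15:63040517-63040532`).  Motifs are normalised
to the lexicographically least string over all rotations of the motif and of
its reverse complement, so AC/CA/GT/TG name one locus class.

The scanner enumerates, for each motif length `k`, maximal intervals in
which every base equals the base one period earlier, keeps intervals of at
least `min_tract_length` (default 6 nt) and at least two motif copies whose
repeat unit is primitive and N-free, and resolves competition between
overlapping candidates deterministically: longest first, ties to the smaller
start, then the shorter motif.  This replaces heuristic alignment-scoring
repeat finders with an exactly specified, reproducible criterion; matching
any particular external scanner's scores is a non-goal.  An explicit
`min_purity` parameter (matching positions / tract length, default 1.0)
admits interrupted repeats when lowered; note that some interrupted
low-order repeats are equally well described as perfect higher-order
tandems (e.g. `ACACA·ACACA` is a perfect 5-mer repeat) and the scanner
reports whichever wins the deterministic competition.

The default minimum tract of 6 nt with **no** maximum reflects the tension
in the field's informal "6–12 nt" definition: observed disease-linked loci
routinely exceed 12 nt, so the upper bound is configuration, not default.

Catalog filtering keeps the scan a pure subset operation: loci are dropped
when their tract length violates configured bounds, when a flank contains N
or is empty, or when the exact flank pair (left flank followed within a
bounded window by the right flank) occurs more than once in the reference —
such loci cannot be anchored uniquely by flank matching, which is how the
genotyper measures them.

## Read-level genotyping

An allele is a tract length in nucleotides; a genotype is the unordered
pair of allele lengths in one sample.  Tract length is measured per read by
exact anchor matching: the `flank_match_len` (10 nt) word of flank adjacent
to each tract boundary must occur, in order, in the read, and the distance
between the anchors is the observed allele.  Measuring on the read sequence
rather than through CIGAR arithmetic makes the call independent of how an
aligner places indels inside the repeat.  Reads that are unmapped,
duplicate, secondary, supplementary or below MAPQ 20 are excluded.

Per locus-sample, observations are aggregated by length and passed through
a stutter gate — an allele needs `min_allele_reads` (2) reads and
`min_allele_fraction` (0.2) of spanning reads — chosen so a balanced
heterozygote at the minimum depth (expected 7.5/7.5 reads at 15×) survives
while single slipped reads do not.  A call requires `min_depth` (15)
surviving reads; more than two surviving lengths voids the locus-sample as
ambiguous.  The ambiguity rule is applied **after** the stutter gate:
applied before it, PCR stutter would void nearly every real locus.  One
surviving length is reported as a homozygote `(L, L)`.

## Cohort contrast and signature construction

The control cohort defines, per locus, the predominant (consensus)
genotype: the modal unordered pair among called controls, requiring at
least `min_called` (10) calls for the locus to be evaluable.  Ties are
broken to the smaller total allele length, then the smaller first allele,
and flagged.  Variant status is genotype-level — a sample is a
non-predominant carrier when its whole pair differs from the predominant
pair — rather than allele-level, because the contrast is defined on
genotypes.

Each cancer cohort is contrasted with the control at every jointly
evaluable locus through a 2×2 table (non-predominant vs predominant
carriers, cancer vs control) tested with a two-sided Fisher exact test
under the classical point-probability rule: the p-value sums the
probabilities of all tables with the observed margins whose probability
does not exceed the observed table's, with a relative tolerance of 1e-7 on
the comparison (the convention of mainstream statistical software).  The
hypergeometric mass function comes from scipy; the summation rule is
implemented here and verified against exact-rational enumeration.

P-values are Benjamini–Hochberg adjusted (step-up with monotonicity
enforcement, implemented directly so that adjusted values are bit-exact
against the sorted reference definition, and cross-checked against
statsmodels).  A locus enters the cancer's **signature** when p ≤ alpha
(0.01) and its adjusted p-value is below `1/X`, where `X` is the number of
tested loci with p < 1; significant loci failing that cutoff form the
**non-signature** set, suggestive loci that larger cohorts might confirm.
`X` is counted over all tested loci.  Relative risk is the ratio of
non-predominant carrier fractions, cancer over control, reported as `Inf`
when only the cancer cohort carries variants and `NA` when neither does.

## Cross-cancer overlap

Pairwise sharing between two signatures is reported as
`100·|A∩B| / |A∪B|` (Jaccard×100).  The percentage denominator for such
tables is not standardised; the union is documented as the default and
`min(|A|,|B|)` is available so both readings can be probed.  The shared
non-signature proportion between two cancers takes the intersection of
their significant loci (signature ∪ non-signature) and reports the percent
that are non-signature in **at least one** of the two — a shared locus may
be signature in one cancer and non-signature in the other, and that case
must count.

The three-set test asks how likely an intersection at least as large as the
observed `|A∩B∩C|` is when each set is an independent uniform draw of its
size from a universe of jointly tested loci.  It is computed exactly by
conditioning: `|A∩B|` is hypergeometric; given `|A∩B| = j`, those j loci
form the draw pool against C, so the triple count is again hypergeometric;
the p-value is the tail sum over j.  The construction is validated against
a 10⁵-draw Monte-Carlo oracle.  When one set is the whole universe the
two-stage form collapses to the single-stage hypergeometric tail, which is
asserted in the tests.

## Synthetic data

The generator emulates the three inputs the pipeline needs.

**Reference.**  Contigs are random background with planted tracts
(primitive 1–3 nt motifs repeated to 8–18 nt) separated by `locus_spacing`
(60 nt) background.  Background chunks are rejection-sampled to contain no
tract of their own, and the assembled contig is re-verified with the
package's scanner: any spurious or boundary-extended detection triggers
resampling of exactly the chunks involved, so by construction the scanner
output equals the planted catalog and every flank pair is unique.

**Genotypes.**  The predominant genotype at each locus is the homozygous
reference-length pair.  A sample is a variant carrier with its cohort's
variant-genotype frequency; variant genotypes draw two alleles i.i.d.
(Hardy–Weinberg pairing) from a ladder centred on the reference length
with steps of one motif unit, modal probability 0.6 and geometric decay 0.5
over ±2 steps, conditioned on the pair differing from the predominant pair.
The ladder is the simplest slippage-like population model; frequencies are
specified at the genotype level so planted case/control differences are
exact.  Default cohort sizes (390 controls, 252 cases) mirror a realistic
control arm and a large single-disease cohort.

**Reads.**  Spanning reads (default 100 nt) carry one of the sample's two
alleles — balanced-random assignment: the reads at a locus split evenly
between the two alleles and are randomly permuted, so each read is
marginally 50/50 but a noise-free heterozygote at calling depth always
passes the stutter gate (an independent per-read coin flip can starve one
allele below it); with probability `noise_epsilon` a read slips one
motif unit in either direction — larger jumps are rare in real stutter and
add no test power.  Depth follows a mean/dispersion model (variance-to-mean
ratio: 0 = constant, 1 = Poisson, >1 = negative binomial).  Reads are
emitted pre-placed with valid CIGARs into coordinate-sorted, indexed BAM;
substitution errors, base qualities and capture bias are out of scope.
Roughly half the reads carry the reverse-strand flag; genotype calls are
asserted invariant to read order and strand.

**What the simulations show.**  Passing tests demonstrate that the
pipeline's statistics behave as designed under the stated generative model:
exact type-I behaviour of the discrete Fisher test, recovery of planted
frequency differences at realistic cohort sizes, and ≥96% genotype
concordance under 2% per-read slippage at 30× (the property analogue of
the genotyper's published validation figure, asserted on simulation only).
They do not certify performance on real exomes, where alignment artefacts,
capture bias, population structure and locus-specific stutter exceed the
model.

## Study sizes used in validation

The statistical suite uses 1000 loci with 200 cases vs 390 controls over
20 replicates for the null and recovery checks (planted effects 0.30 vs
0.05 among 0.05-background nulls), ≥500 locus-samples for genotyper
concordance, 1000 random 2×2 tables (margins ≤ 60) for Fisher oracle
agreement, 500 random sequences (≤200 nt) for scanner oracle agreement,
and a 3×2 grid of set/universe sizes for overlap calibration.  The
desk-scale end-to-end fixture is 300 loci with 60 cases vs 60 controls and
10 planted loci at variant frequency 0.55 vs 0.05 — an analytic power
calculation puts per-locus recovery above 99% at those sizes, so the
fixture's ≥9/10 signature recall is a stable regression baseline rather
than a coin flip.  `scripts/acceptance.py` re-measures all of the above
(null/recovery at 5 replicates) from scratch at a user-supplied seed.

## Numerical conventions and degenerate inputs

- Fisher: if every table in the support is included by the point-probability
  rule the p-value is exactly 1; an all-zero table is an error.
- BH: adjusted values are `p·n/rank` with a running minimum from the
  largest rank, clipped at 1; ties receive equal adjusted values.
- Signature cutoff with `X = 0` (all p = 1) yields an empty signature, not
  an error.
- Relative risk requires both cohort margins positive.
- Empty sequence scans to an empty catalog; characters outside ACGTN are
  rejected with the offending offset.
- A flank clipped to fewer than `flank_match_len` nt makes a read
  non-spanning rather than mis-anchored; catalog filtering drops loci with
  empty flanks.
- All simulation stages derive independent generators from
  `(seed, stage, sample)` seed sequences: outputs are byte-identical
  (text) and record-identical (BAM) under a fixed seed.

## Known limitations

- The genotyper assumes unique flank anchors; highly degenerate flank
  neighbourhoods are excluded at the catalog stage rather than handled.
- The two-stage overlap p-value models sets as uniform draws; it ignores
  heterogeneous per-locus testability across cohorts.
- No covariate adjustment, population-structure correction, or somatic
  (tumor–normal) contrast: the design is germline case–control only.
- The interrupted-repeat (`min_purity < 1`) scanner is greedy per start
  position; it is deterministic but not guaranteed to maximise purity-weighted
  coverage in pathological cases.
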