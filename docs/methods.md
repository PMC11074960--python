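# Methods

This note documents the models, parameter choices and numerical
behaviour of `kinid`, and what the synthetic-data suite does and does not
establish about real data.

## Pedigree arithmetic

A pedigree is a validated DAG of sexed individuals.  The kinship
coefficient φ uses the classical founder recursion — φ(x, x) =
(1 + F_x)/2, otherwise averaging over the parents of the individual with
the greater generation depth — in exact rational arithmetic
(`fractions.Fraction`) for pedigrees of at most 64 members, floats above
that.  Exactness matters because the quantities of interest are small
dyadic rationals (1/32, 1/1024) whose inflation under pedigree collapse
must be asserted exactly in tests.

Meiosis paths climb parent links (optionally fathers-only or
mothers-only) from each individual to a common ancestor; the count is the
minimal total number of transmissions.  The degree label of a pair is the
meiosis count of the closest path, minus one when two parallel closest
paths run through both members of a mated couple (full relationships):
this reproduces the standard forensic table (uncle = 2nd degree via 3
meioses, great-great-grandfather = 4th via 4).  Collapse deliberately
affects φ but never the degree label.

The bundled Washington fixture encodes only documented edges; unknown
spouses are distinct founders.  One known collapse path (the cross-cousin
marriage joining the two brothers' branches) is represented; a second
documented lineage lacks printed structure and is omitted, so the
fixture's collapse effect (Δφ = 1/1024 for both male burials) is a lower
bound on the real pedigree's.  Directional claims only are asserted
against it.

## Synthetic data

The generator emulates a 95K-style hybridization capture experiment.

* **Panel.**  Autosomal sites are allocated to chromosomes 1–22
  proportionally to genetic length and evenly spaced in cM; X sites
  likewise; Y sites carry no map position.  Alternate-allele frequencies
  are uniform(0.05, 0.95) per population by default — flatter than a real
  site-frequency spectrum, which makes sites on average more informative
  per SNP than a real panel; recovery rates quoted by the tests are
  therefore specific to these conditions.  Allele pairs are drawn with a
  2/3 transition fraction so that a realistic share of sites is
  deamination-prone.
* **Genetic map.**  One sex-averaged map with per-chromosome total
  lengths at published human magnitudes (≈3545 cM autosomal).  No
  sex-specific maps and no minimum segment length anywhere, matching the
  study's simulation settings.
* **Recombination.**  The chi2 interference model is a stationary gamma
  renewal chiasma process of integer shape m (default 4): every m-th
  point of a Poisson process at 2m per Morgan with uniform random phase,
  each chiasma thinned onto the sampled chromatid with probability 1/2.
  Shape m is exposed because the study names the model family but not its
  shape.  A Poisson (Haldane) baseline is provided; tests verify the
  chi2 process under-disperses crossover counts and shrinks the spread of
  sibling segment counts.
* **Gene drop.**  Founder haplotypes carry unique integer labels;
  recombinant mosaics are composed per meiosis and IBD states are derived
  by label matching, so true IBD segments are exact, not inferred.  X
  transmission is sex-aware (fathers pass their X intact to daughters and
  nothing to sons); the Y follows the patriline unrecombined.
* **Reads.**  Site coverage is Poisson (negative binomial optional,
  dispersion 2) around the mean depth; fragment lengths are truncated
  normal (mean 60 bp, sd 15, minimum 30), a read's end distance is the
  distance to the nearer fragment end.  Damage converts a true C to an
  observed T (5′; G→A at 3′) with probability amplitude·exp(−d/λ),
  default amplitude 0.2 and λ = 3 bp — magnitudes typical of
  century-scale, non-UDG-treated skeletal libraries — after a symmetric
  base error (default 0.001).  Orientation-level read simulation is out
  of scope: damage-susceptibility is a property of the site's allele
  pair, which is the panel-level abstraction the likelihood also uses.
* **Y-STR / mito.**  Y-STR transmission mutates each locus per meiosis at
  its supplied rate with symmetric ±1 steps.  Mito pileups place the
  haplotype's bases at Poisson depth with symmetric read error and
  optional per-position deamination (C→T/G→A at a configurable rate on a
  configurable set or fraction of C/G positions).  No rCRS sequence is
  bundled; callers supply a reference string (tests use synthetic ones).

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give byte-identical outputs across processes (pedigree member
ordering is kept insertion-stable for exactly this reason).

## Damage profile estimation

At C/T sites the T-read fraction mixes true T alleles with damaged Cs.
Each site's true product-allele fraction is estimated from reads on the
*opposite* (undamaged) fragment end, lightly shrunk toward the population
frequency; the pooled per-distance excess over that baseline estimates
the conversion probability δ(d), summarised by a weighted least-squares
fit of A·exp(−d/s) (bounds A ∈ [0,1], s ∈ [0.1, 100]).  Beyond the
15-base window the fitted curve's asymptote (zero) is used.  On data
simulated at amplitude 0.3, scale 3, the estimator recovers both within
±0.05 and ±1 respectively.  With no damage-prone sites in the input a
zero profile with a warning flag is returned; with no reads at all the
estimation errors out.

## Genotype likelihoods

Per read, P(obs | true) is 1−ε / ε for the matching/mismatching allele;
at a damage-prone site, reads on the damaged end with true source base C
are observed as T with δ + (1−δ)ε and retained with (1−δ)(1−ε) — never
the reverse direction.  Heterozygotes mix the two true alleles evenly.
Everything is accumulated in log space; 10⁴+ reads per site are safe.
Zero coverage yields the equal (uninformative) triple.

## Pairwise kinship

Overlap is defined as coverage ≥ 1 in both samples at autosomal sites
with reference frequencies (X sites are handled only by the forced-
haploid test; frequency-less sites are excluded).  Greedy left-to-right
LD pruning within a 50-kept-site chromosome window drops a site iff its
squared correlation with a kept site strictly exceeds r² = 0.2 in a
reference genotype matrix; r² is rounded to 12 decimals first so
boundary pairs are retained; monomorphic reference sites warn and stay.
The window size and greedy strategy are this package's choices — the
study's tooling does not specify its algorithm.

The IBD1 joint genotype table comes from the shared-allele construction
(one allele of the second genotype copied from the first, the other an
independent HWE draw), which is symmetric in the pair.  Per-site linear
likelihoods are normalised before mixing, each site's category likelihood
is floored at 1e-300 (a structurally impossible pair under "self"
otherwise zeroes the whole product), and all sums, ratios and posteriors
live in log10 space end to end because realistic LRs (10²⁹–10⁷³⁴) do not
fit a float.  Ties in the most likely category break toward the more
distant relationship.  Ancestry proportions come from a per-site latent
mixture fitted by EM over the panel's population frequency columns;
the argmax population's frequencies feed kinship.

Category recovery ≥ 90% is demonstrated for degrees ≤ 3 at 5,000
unlinked sites and 5X; degree 4–5 and unrelated confuse with their
neighbours, exactly the overlap regime the mismatch and IBD analyses are
meant to arbitrate.  Sites are simulated unlinked there, so the quoted
recovery excludes linkage-induced variance; gene-dropped (linked) data
put O(1)-log10 noise on calls near category boundaries, which is why the
collapse analysis works with simulation clouds rather than single calls.

## Forced-haploid mismatch

Pseudo-haploid calls take one uniformly chosen read per covered site.
The closed-form expectation `mean(2p(1−p))·(1−φ)` (φ = 1/2 for the
same-individual comparison) serves as the independent oracle for the
simulator, which draws genotype pairs per relationship (sex-aware on the
X: a son's X is maternal, a daughter carries the father's X intact),
flips each final call with probability ε (0 and 0.005 by convention;
call-level injection is this package's reading of the unspecified error
model), and records mismatch proportions over exactly the observed site
set.  Classification reports empirical two-sided tail probabilities with
the (r+1)/(n+1) correction and withholds a hard call when the runner-up
hypothesis stays plausible at the 0.05 level.  Distributions must be
built on the observed pair's exact site count or a consistency error is
raised.

## IBD simulation and ellipses

Each replicate gene-drops only the pair's ancestor closure and records
two axes: total length of maximal IBD≥1 runs (merged across IBD1/IBD2
transitions) and their count.  The kinship-weighted length (IBD1/2 +
IBD2), whose expectation is 2φ·L, is exported alongside for calibration
checks; the unweighted total has expectation (k1+k2)·L — for a
parent-child pair the full map in exactly 22 segments.  Ellipses are
sample-mean/covariance with the chi-square(2) quantile at the requested
level (default 0.99); near-singular covariance (determinant ≤ 1e-12)
raises a degeneracy error.  Hypothesis comparison reports pairwise
cloud-in-ellipse overlap fractions and directional mean shifts; 1000
replicates is the default.  Under the partial fixture the collapse shift
for burial B is ≈ +14 cM and ≈ +1.4 segments — the segment-count axis
carries most of the statistical power, so the directional acceptance
check runs 2000 replicates per hypothesis; the Lucy Payne comparison is
asserted shift-free within 3 SE.

## Lineage markers

Reportability is strictly > 70 RFU; a replicate qualifies with ≥ 4
reportable loci and a composite needs ≥ 2 qualifying replicates.  Allele
status: confirmed (reportable in ≥ 2 replicates), below-threshold
(replicated, at least one event under threshold, recorded down to an
analytic minimum of 30 RFU — the recording floor is configurable since
no value is published), unreplicated (seen once), not-reported
(contradictory replicated single-allele calls).  Below-threshold alleles
do not count toward the ≥ 4-locus gate but do count in distance
calculations.  Genetic difference sums absolute repeat steps over shared
typed loci; multi-copy loci use minimal-cost assignment
(`linear_sum_assignment`) with unpaired copies adding their nearest-step
cost; microvariants compare on their numeric designation.  On fully-typed
single-copy profiles the distance is a metric (asserted by brute force
and property tests).

Y-haplogroup placement walks from the root, descending into a child only
when ≥ 1 covered defining SNP is derived and none is ancestral; zero-
coverage branches stop resolution (the "finest level due to zero
coverage" behaviour); multiple simultaneously supported children halt
the walk and are reported, with any other unreachable derived calls, as
conflicts.

Mitochondrial calling gates on coverage strictly > 10X, variant
frequency ≥ 10% and variant count ≥ 4 (the quoted wording read
literally); positions where the reference base also passes become mixed
calls rendered as IUPAC codes and flagged heteroplasmic.  Insertions use
rCRS point-suffix positions taken as given in the pileup (no
realignment); deletions come from the gap column.  Haplotype comparison
counts differing positions within the shared covered range, with mixed
positions matching any state containing one of their components when
heteroplasmy is ignored (the default, following forensic convention).
Controls are clean strictly below 2X average coverage.

## Pipeline and reproducibility

`RunConfig` holds the operating thresholds with the study's values as
defaults (r² 0.2, 70 RFU, 10X/10%/4, LR 10⁴, posterior 99.99%, 1000
replicates, 0.99 ellipses).  Each stage derives its seed as
SeedSequence(master, crc32(stage)), so stages rerun independently and a
rerun with an identical configuration is bitwise identical, manifest
included (the manifest records the configuration hash and seed, never
timestamps).

## Problem sizes in the test suite

The suites run at desk scale by design: 3,000–5,000-site panels, 5–25X
synthetic coverage, 200 pairs per category for recovery, 400–2,000
gene-drop replicates per hypothesis, 10⁵-point ellipse calibration.
Panel-count bookkeeping is exercised once at the full 94,752-site scale.
These sizes keep the whole suite within a few minutes on one CPU while
leaving every Monte-Carlo assertion at ≥ 3 standard errors of headroom.

## Known limitations

* The likelihood treats pruned sites as independent; residual linkage
  makes reported LRs anti-conservative in absolute terms (rank order of
  categories is much less affected).  No inbreeding-adjusted k-triples.
* The synthetic generator omits contamination, mapping artifacts,
  capture bait efficiency variation, and sequence-level reads; passing
  tests validate the statistical machinery, not robustness to those
  real-data failure modes.
* The Washington fixture is intentionally partial (documented edges
  only), so simulated collapse shifts understate the real pedigree's.
* Y-STR→haplogroup prediction from repeat profiles is external to this
  package; tree placement uses SNP calls only.
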