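# Methods

This note documents the models and procedures implemented in `captor`,
their assumptions, the parameters that matter, and the design choices
made where the design was genuinely open.  Conventions first: all
genomic coordinates are 0-based half-open throughout the package;
file formats using other conventions are converted at their I/O
boundary.  Recognition sites are scanned on the forward strand only and
must be palindromic (HindIII `AAGCTT` and MboI `GATC` both are), so no
information is lost; overlapping site occurrences all cut, and
ambiguity codes never match.

## In-silico digestion and the resolution constant

The unit of analysis is the restriction fragment.  Cut positions are
every occurrence of the recognition site offset by the enzyme's
within-site cut position (HindIII `A^AGCTT`: offset 1; MboI `^GATC`:
offset 0); fragments tile each chromosome exactly.  On i.i.d. uniform
DNA a fixed k-mer recurs every `4^k` bp in expectation, so a six-cutter
yields ~4096 bp fragments — the fragment-level resolution of a HindIII
library — and a four-cutter ~256 bp.  `scripts/acceptance.py` measures
this by digesting ten simulated 10-Mb genomes (a single 10-Mb genome
gives the mean to only ~2% standard error, so the measurement averages
100 Mb).

## Pair QC

Input is mapped read pairs (4DN `.pairs` text); alignment and read
truncation are upstream concerns and deliberately out of scope.  Ends
are stored in canonical order.  Classification is three-way:
same-fragment, adjacent re-ligation (fragment index difference of one on
the same chromosome), else valid — a coarser taxonomy than read-level
pipelines use, because insert-size information is not present in
`.pairs`.  Duplicates are detected among otherwise-valid pairs by exact
identity of both coordinates and both strands (ligation-product
identity).  Capture filtering keeps pairs with at least one baited end;
capture efficiency uses the post-deduplication denominator, and the
trans fraction is reported over captured pairs (the convention in which
library statistics are usually quoted).

## Contact matrices and reproducibility

Matrices are genome-wide, sparse, upper-triangular, at a fixed bin size
(1 Mb / 250 kb / 100 kb are the conventional choices).  Normalization is
either per-million library scaling or iterative marginal balancing of
the symmetric matrix (tolerance 1e-5, 200 iterations).  Case/control
log2 ratio maps use per-million-normalized counts with a pseudocount.

Reproducibility uses the stratum-adjusted correlation coefficient:
within each chromosome, Pearson correlations are computed separately per
genomic-distance stratum (diagonal) of the mean-filter-smoothed matrices
and combined with weights `N_k * sd_a,k * sd_b,k`; chromosomes are
averaged weighted by bin count.  Smoothing half-width defaults to 1
(3x3) below 1 Mb resolution and 0 otherwise, and strata are capped at
5 Mb by default — beyond that they are too sparse at capture-library
depth to inform the comparison.  Both parameters are exposed.

## Interaction calling

The background has two components.  The biological component `f(d)` is
the mean count per *possible* bait–other-end pair in geometric distance
bins (20 bins by default), made monotone non-increasing by isotonic
regression; counting per possible pair makes unobserved (zero-count)
pairs part of the estimate.  The technical component `lambda_tech` is
the mean trans count per possible bait x trans-fragment pair.
Per-fragment activity factors multiply both components: observed totals
are compared to their expectation under `f` and shrunk toward a
fragment-length prior (capture activity is strongly length-dependent;
shrinking toward 1 instead leaves length effects in the residuals and
costs calibration), truncated to [0.1, 10] and renormalized to mean 1.
Trans expectations are scaled by the same factors — a trans ligation is
random collision, so its rate also tracks fragment activity.

Counts are tested against the negative-binomial upper tail at the
expected mean.  Dispersion is pooled method-of-moments over
expected-mean strata; when no overdispersion is detected the model falls
back to Poisson.  P-values are weighted by
`w(d) = 1 / (1 + (d/d_mid)^k)` — logistic in log distance with
`w(0) = 1` and `w(d_max) = 0.01` — and the score is `-log(min(1, p/w))`,
floored at 0; the significance threshold is 5.  The weight counters the
multiplicity structure of capture Hi-C: possible pairs grow with
distance while true contacts become rarer, so unweighted genome-wide
testing would spend all of its budget at long range.  Bait-to-bait pairs
are scored from each bait's perspective and carry a flag.

Replicates may be pooled by summing fragment-pair counts, gated on
pairwise SCC (default 0.75 at 100 kb, overridable), which mirrors the
practice of calling on merged libraries only after checking
reproducibility.

Calibration semantics: "fraction of significant pairs" is measured
against the full universe of possible fragment pairs — an unobserved
pair has score 0 by definition.  Among *observed* pairs the fraction is
necessarily higher (observation conditions on N >= 1, which at small
expected counts is itself a tail event).

## Interactome comparison

The peak matrix holds asinh-transformed scores of every interaction
significant in at least one cell type (missing scores are 0 before the
transform).  Interactions are clustered with a diagonal-covariance
Gaussian mixture, the number of components chosen by BIC — a
reproducible stand-in, from the same model family, for legacy Bayesian
mixture classification; results are deterministic given the seed.
Cluster specificity is the cluster's mean score per cell type, centered
and scaled across types (epsilon 1e-8), so each cluster's scores sum to
zero and the maximum marks the type the cluster is most active in.
Sample-level structure uses PCA over cell types and average-linkage
hierarchical clustering on Euclidean distances, serialized to newick.

## Structural variants

**Detection.**  A translocation inflates contacts between two
chromosomes locally by orders of magnitude over the flat trans
background.  Per chromosome pair, trans counts are normalized by the
product of genome-wide bin coverages, averaged in a sliding window
(3 bins), and compared against random within-chromosome bin-label
permutations (pooled mean/sd; at least 100 permutations).  Connected
blocks with z >= 8 are calls; the strict default reflects the ~1e4–1e5
window tests per genome.  Two blocks meeting at a shared corner in
opposite quadrants merge into one balanced ("butterfly") call — the
signature of a reciprocal event, which leaves a derivative on each side
of the junction.

**Breakpoint refinement** works at fragment resolution on the raw trans
count plane.  A single global two-segment step fit is biased on real
capture data: the junction signal decays with distance from the corner,
and bait fragments carry multiplicative spikes, so constant-rate models
prefer splits inside the contact blob.  The implementation therefore
(i) locates the blob by smoothed argmax; (ii) for each of the four
possible hot-quadrant orientations, alternates one-dimensional
change-point fits on marginals over the partner's hot half-plane, using
the distal cold half-plane as a per-bin exposure offset so bait spikes
cancel (a guard band of one window width around the current split keeps
the opposite derivative's signal out of the exposure); (iii) lets the
orientations vote (clusters of agreeing corners, quadrant-contrast
tie-break); and (iv) polishes each dimension with the sum of the two
opposing views' step-likelihood curves, which uses both derivatives'
evidence when the event is reciprocal.  On simulated reciprocal
translocations breakpoints localize to within one fragment; one-sided
(unbalanced) junctions carry half the evidence and localize more
coarsely (typically within tens of fragments).  Pattern classification
compares the rate of the quadrant opposite the hot one against the two
adjacent quadrants (factor 5 by default): both hot means balanced.  A
uniform plane fails the minimum likelihood-gain check (30 log-likelihood
units) and raises rather than returning a guess.

**Derivatives.**  A derivative chromosome is the kept segment of one
partner joined to the kept segment of the other, with an invertible
coordinate transform; same-side joins reverse the second segment
(inversion-type junction).  Junction-spanning contacts re-project to cis
contacts on the derivative with distance equal to the sum of the two
ends' distances to the junction.  Note that the *number of possible*
junction-spanning locus pairs at separation s grows linearly in s, so
decay comparisons must normalize per possible pair, exactly as cis decay
curves do.

**CNVs.**  Case and control end coverages are counted in 200-kb windows
(cis pairs only: a trans ligation scales with the dosage of both of its
endpoints and dilutes the copy-ratio signal), normalized per million,
log2-ratioed with a pseudocount, and median-centered so the diploid
baseline sits at zero even when a large aberration shifts library
totals.  Segments are maximal runs of at least 3 windows beyond ±0.3 —
midway between 0 and log2(3/2), the single-copy-gain signal on a diploid
background.  Swapping case and control flips gains and losses with
negated ratios.

## GWAS integration

Preprocessing drops genome-wide-significant SNPs (p < 5e-8) with no
support — no LD partner at r² > 0.6 and no neighbor within 50 kb at
p < 1e-5 — excludes the MHC interval (chr6:25–35 Mb on GRCh38
coordinates by default), and applies poor-man's imputation: an untyped
reference SNP inherits the p-value of its best typed proxy at r² >= 0.6
within the same 1-cM region.  LD regions are cut from the genetic map at
every centimorgan.

Fine-mapping assumes one causal variant per region.  Wakefield
approximate Bayes factors use prior effect variance W = 0.04; when betas
and standard errors are absent, the z-score is reconstructed from p and
the standard error from the minor allele frequency and sample size.
Posteriors are `ABF_i / (sum_j ABF_j + 1)`; the +1 term is the
no-causal-variant share, so region posteriors sum to at most one.

Blockshifter contrasts the mean SNP posterior inside PIRs exclusive to
one tissue group against the other group's exclusive PIRs.  The null
circularly rotates the PIR annotation across position-ordered SNPs
within each 1-cM region (jointly for both groups), preserving LD-block
structure; z is the observed statistic standardized by the rotation
null.  Identical annotations return a zero statistic; a single group
with no exclusive SNPs is an error.  Calibration was verified on null
panels (z mean ~0, sd ~1 over hundreds of simulated traits).

COGS sums SNP posteriors over the union of a gene's coding, promoter
and PIR intervals per region (no double counting), and combines regions
as `1 - prod(1 - block score)`; genes at score >= 0.5 are prioritized.
PIR link sets from multiple cell types are pooled by union by default;
a per-cell-type maximum mode is available.

## Network features

PIR mark enrichment compares observed overlap counts against
length-preserving uniform re-placement within chromosomes (5000
randomizations by default), per expression-quartile group.

Chromatin assortativity is the Pearson correlation of a per-fragment
feature over the edge list with both orientations included.  The default
null circularly rotates the feature track along each chromosome: it
preserves the network, every edge's genomic distance and the feature's
spatial autocorrelation, and it is exactly calibrated by symmetry.
Stratified edge rewiring (within chromosome and log-distance bins, no
self-pairings) is available as an alternative null, but because hub
fragments participate in many edges its z-scores are over-dispersed
(measured sd ~1.17 on i.i.d. features), which is why it is not the
default.  A zero-variance feature yields an explicitly undefined result,
not zero.

## The synthetic-data generators

The generators emulate the statistical structure of capture Hi-C, not
its sequence content: i.i.d. uniform genomes (3 chromosomes x 10 Mb by
default), a random 5% of fragments baited, cis contacts with power-law
distance decay (exponent 1.0 by default) between 5 kb (roughly one
fragment — real libraries retain abundant short-range contacts) and half
a chromosome, bait-anchored capture (61% capture probability), uniform
dosage-weighted trans background (24% of captured contacts), explicit
artifact classes (40% of unique events), and PCR duplicates re-emitted
from records that will classify as valid (12% by default).  The default
depth is 2 million read pairs.  Spiked loops multiply a pair's base rate
by a stated fold.  Rearranged libraries are drawn on explicit derivative
haplotypes (one normal copy of each partner plus the derivative(s)) and
mapped back to reference coordinates; copy-number changes are realized
as haplotype dosage — an extra duplicated-segment haplotype for gains, a
region-deleted copy for losses — so coverage ratios are exactly copy/2.
GWAS panels draw blockwise z-scores from an AR(1) LD correlation
(rho = 0.9, 20 SNPs per 100-kb block) with causal non-centrality
`effect * sqrt(2 n f (1-f))` propagated through the LD.

What the generators do *not* emulate: sequence mappability and GC bias,
polymer physics beyond a power law, chromatin compartments and domains,
cell-type mixtures, or multi-causal GWAS loci.  Passing tests therefore
demonstrate the estimators' correctness and calibration under the stated
generative assumptions, not performance on every property of real data.

## Problem sizes used in the tests

The test suite runs the full pipeline at the default toy scale
(3 x 10 Mb genomes, 1–2 M read pairs; twenty seeded replicates for
rearrangement recovery; 500 simulated traits for enrichment
calibration; 300 feature draws for assortativity calibration), chosen so
every statistical check retains adequate resolution while the whole
suite stays desk-scale.

## Known limitations

- Artifact taxonomy is coarser than read-level pipelines (no
  insert-size classes), by design of the `.pairs` input boundary.
- The caller is faithful in structure to two-component capture Hi-C
  background modeling but does not claim numerical parity with any
  external implementation; the distance-weight calibration is a
  documented in-package choice.
- One-sided translocation breakpoints localize more coarsely than
  reciprocal ones (single-derivative evidence).
- Exact breakpoint coordinates are bounded by restriction-fragment
  resolution; sub-fragment localization is not attempted.
- Fine-mapping is single-causal-variant per region; multi-causal
  methods are out of scope.
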