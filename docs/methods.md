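# Methods

This note documents the models and procedures implemented in `apadiff`,
the parameters that matter, the numerical choices, and what the synthetic
studies used by the tests do and do not demonstrate.

## Coordinates and strand handling

All coordinates are 0-based half-open (BED-native); 1-based coordinates
appear only in labelled report columns. Every comparison between genomic
features — read-to-site counting, site-to-gene assignment, annotation
rescue — requires strand agreement. A site's *cleavage point* is the
strand-aware 3'-most base of its interval. Annotated cleavage-site BED
records are collapsed to that single base, since a cleavage site is a
position, not an interval. Minus-strand sequence queries return the
reverse complement, so all sequence logic operates in mRNA sense.

## Site discovery

Candidate sites are maximal runs of per-base coverage (computed from full
aligned read spans, the same semantics as bedtools genomecov) with depth
>= `min_depth` (default 1), separated by read strand. The library
orientation switch (`strandness` forward/reverse, default forward) maps
read orientation to transcript strand, since 3'Seq kits differ. Features
from all replicates are pooled and merged transitively whenever two
same-strand features overlap or their gap is <= `md`. `md` (default
25 bp) absorbs cleavage wobble and should be raised for protocols with
poorer positional resolution; discovery deliberately keeps everything
above zero coverage because the downstream denoising filters carry the
noise burden and per-stage attrition is reported.

## Internal-priming filter

Misprimed reads sit immediately upstream (5') of a genomic adenine
stretch, so the scan extends from the site's cleavage point 3'-ward by
`mpd` (default 20 bp, the minimum that fills one window) and takes the
maximum A fraction over 20 bp sliding windows. Sites are flagged when
that fraction strictly exceeds 0.65 — a window at exactly 13/20 is kept.
The conventional rule in the field is 15/20 (75%); 65% is the more
conservative choice and both the threshold and window are configurable.
Sites within 50 bp of an annotated cleavage site on the same strand are
retained regardless (annotation rescue), and every verdict (fraction,
flag, rescue, annotation distance) is recorded for attrition reporting.
The scan truncates silently at chromosome ends.

## APA matrices and denoising

Sites map to the gene whose body they overlap (same strand; nearest-TES
wins among overlapping bodies), or to a gene whose transcriptional end
site lies <= 16 kb upstream (strand-aware) provided the site overlaps no
other gene's body on either strand; ties between two extension zones are
left unassigned rather than guessed. The 16 kb bound corresponds to the
longest known human 3'UTR.

Counting is overlap-based (a read counts once for every site its aligned
span overlaps, strand-matched) — i.e. featureCounts-style interval
overlap semantics. Three filters follow, with deliberately different
quantifiers:

* **pOverA** — a site passes if *at least one* group has a fraction >= `p`
  (0.6) of replicates with count > `A` (5) and a group maximum >= `M` (10).
  "Fraction >= p" is non-strict (the boundary case passes); the choice is
  documented here because it is not forced by the rule's wording.
* **proportion** — a site fails only if its share of the gene's reads is
  < `mp` (0.05) in *both* conditions, so a condition-specific site survives.
* **expression** — a gene is dropped if its retained-site total is < `me`
  (10) in *either* condition.

These defaults are deliberately conservative desk-scale values; all are
configurable and logged, and each removal is attributed to exactly one
stage via site flags so the attrition table sums exactly. Retained
counts are column-normalized within the gene; zero columns are left zero
with a warning, and genes with fewer than two retained sites are excluded
(no APA is expressible) with the reason recorded.

## Consensus NMF

The gene's normalized proportion matrix V (m sites x n replicates) is
factorized as V ~ W H, W (m x k), H (k x n), k = 2, minimizing
||V − WH||²_F by hierarchical alternating least squares (HALS) — block
coordinate descent with closed-form non-negative updates, which makes the
objective provably non-increasing. W is initialized uniformly at random
scaled to sqrt(mean(V)/k); H starts at zero and is filled by the first
descent pass, which has a useful consequence: the whole run is exactly
equivariant under replicate permutations of V. Convergence is declared
at relative objective change < 1e-6 or 500 iterations — small enough
matrices that this is effectively exact. All-zero V is an error (such
genes are filtered upstream).

Replicate j joins the cluster with the largest H coefficient in column j.
Because a single run depends on initialization, `ni` = 100 runs are
executed with consecutive seeds derived from the base seed (per-gene
offsets come from the sorted gene order, so whole-run outputs are
byte-reproducible). The consensus matrix stores, in its upper triangle,
the fraction of runs in which replicates i and j share a cluster; the
diagonal is 1 and the lower triangle 0 by storage convention — only
genuine unordered pairs are ever treated as data.

The **stability score** is the mean pairwise agreement with the design:
co-clustering frequency for same-condition pairs, one minus it for
cross-condition pairs (1 = perfect, 0.5 = chance). This pairwise
convention is this package's own; other consensus-clustering stability
definitions exist, so absolute values should not be compared across tools.

## Beta modeling and the LRT

Pair frequencies are clamped into [1e-4, 1 − 1e-4] (frequencies of
exactly 0/1 are routine under strong consensus) and fit by the method of
moments with population moments and a variance floor of 1e-6:
α = x̄[x̄(1−x̄)/s² − 1], β = α(1−x̄)/x̄, falling back to Beta(1,1) if the
bracket is non-positive. Separate fits to intra-group, inter-group and
pooled frequencies give log-likelihoods L1, L2, L0 (computed via
log-gamma), and LRT = −2(L0 − (L1 + L2)) is clamped at zero — moment fits
are not nested MLEs, so the "alternative" can fit worse than the null —
and referred to the upper tail of χ²(2 df). Genes with fewer than two
intra- or inter-group pairs are untestable and excluded from the
Benjamini–Hochberg FDR adjustment.

**Calibration caveat (measured, important).** The χ²(2) reference is
anti-conservative at realistic replicate counts. With 3+3 replicates
there are only 6 intra and 9 inter pairs; even for *iid* beta samples of
those sizes the moment-fit LRT exceeds the χ²(2) 95th percentile about
9% of the time (measured across several beta shapes), and consensus pair
frequencies are additionally dependent (pairs share replicates and runs),
raising the null exceedance to roughly 19% on simulated null genes —
while the zero-clamp simultaneously creates a point mass at p = 1 (about
a third of null genes). The dedicated acceptance test asserts the
nominal binomial interval around 0.05 and fails; it is kept failing
rather than loosened, as an honest record. Practically this means the
q-value alone over-calls; combining it with the direction gate
(|score| > δ) restores specificity on synthetic studies (the end-to-end
tests call exactly the programmed genes), and users should treat
significance-plus-direction, not significance alone, as the call.

## Projection score

Retained sites are ordered proximal → distal by strand-aware distance
from the gene's 3' end. The reference vector places each site at its
genomic distance from the most proximal cleavage point, normalized so
w_proximal = 0 and w_distal = 1; a scalar projection (u·w)/||w|| of the
group-mean proportion vectors onto w is compared between conditions and
the difference rescaled by its maximum attainable value, which reduces to
score = (u_treated − u_control)·w ∈ [−1, 1]. Negative scores are 3'UTR
shortening, positive lengthening, |score| <= δ (default 0.05) is
NoChange. The distance weighting distinguishes a distal→proximal switch
from a distal→intermediate switch of equal mass — a single-axis
projection cannot — and for two-site genes the score reduces exactly to
the change in distal usage. The score is antisymmetric under swapping
condition labels and bounded by construction.

## Synthetic studies

The generator emulates a clean two-condition 3'Seq experiment: a uniform
random genome; strand-alternating genes on two chromosomes, each with 2-5
cleavage sites spaced 200-2000 bp at/downstream of the annotated gene 3'
end (so the TES-extension rule is exercised); a configurable fraction
(default 0.5) of true sites in the annotated BED; reads of fixed length
60, ungapped, MAPQ 60, ending within 5 bp of their site's cleavage point.
Baseline usage is distal-dominant (distal site 0.6 plus a Dirichlet
remainder); affected genes move a fixed mass (default 0.4) from the most
distal to the most proximal site in the treated condition. Replicate
usage jitters around the condition truth via a symmetric-scale Dirichlet
(concentration 200, i.e. proportion s.d. ~0.03), and per-replicate gene
depth is Poisson around 1000 reads. Internal priming is emulated by one
planted 20 bp A-stretch decoy per gene attracting 20% of its reads; the
50 bp immediately 3' of every *true* cleavage point is resampled A-poor
so no true site trips the filter by chance.

What passing on these fixtures does **not** show: robustness to sequencing
error, soft-clipping or multimappers; cleavage-site microheterogeneity
beyond ±5 bp; overlapping or nested genes; library-size imbalance between
replicates; or real internal-priming sequence context (partial A-stretches,
A-rich UTRs). The default study sizes (50 genes end-to-end, 500 null genes
for calibration, ni = 100) were chosen as the smallest that give stable
percentages; all are parameters of `SimSpec` and the acceptance script.

## Known limitations

* Only k = 2 (two-condition) designs; no covariates.
* Gene-level inference only; no per-site differential statistics.
* The χ²(2) p-values are anti-conservative (see above); ranks and the
  significance-plus-direction call are the reliable outputs.
* No cross-sample normalization is needed or performed: all modeling is
  on within-gene proportions.
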