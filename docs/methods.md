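# Methods

## Profile estimation

All features derive from two plug-in estimates over the alphabet
A = {A, C, G, T}: the marginal p̂⁰(X) (base counts over the window,
ambiguous letters excluded from numerator and denominator) and the lagged
joint p̂ᵏ(X,Y) (counts of ordered pairs at separation k, a pair dropped
if either member is ambiguous, divided by the number of surviving pairs).
Pairing is linear, so a window of length L yields at most L − k pairs at
lag k; both estimates are proper distributions by construction.

Per-window design: p̂⁰ is estimated from the window being profiled, not
from the parent sequence it was drawn from, so a profile is a
self-contained function of its window and models are portable to windows
of unknown origin.

Definitions, with the convention 0·log(·) = 0:

* AMIₖ = Σ p̂ᵏ(X,Y) log₂[p̂ᵏ(X,Y)/(p̂⁰(X)p̂⁰(Y))] — one value per lag.
  Because p̂ᵏ and p̂⁰⊗p̂⁰ are both proper distributions this is a genuine
  KL divergence and is nonnegative even though the joint's own marginals
  differ slightly from p̂⁰ (they are computed over L − k positions, not L).
* eAMIₖ(X,Y) = p̂ᵏ(X,Y) — 16 values per lag, summing to 1.
* eaAMIₖ(X,Y) = the corresponding summand of AMIₖ — 16 values per lag,
  summing to AMIₖ.

The logarithm base defaults to 2 (bits) and is configurable; changing it
rescales features uniformly per component and cannot alter SVM or
centroid decisions. Component ordering is frozen (lag-major; X outer, Y
inner; base order A,C,G,T) so serialized models remain valid across runs.

A known property of plug-in mutual information is its positive
finite-sample bias, ≈ (|A|−1)²/(2N ln 2) bits at N pairs for an i.i.d.
null. The bias is essentially lag-independent at fixed window length, so
it shifts AMI profiles uniformly and washes out of within-window
comparisons and of classifiers trained and tested at one window length;
it is why short-window AMI values sit well above their asymptotic values.

Default lag depths: K = 16 for AMI and K = 6 for the expanded profiles.
The period-3 structure repeats with period three, so K = 16 spans five
full periods for the averaged profile, while for the 16-per-lag expanded
profiles K = 6 (96 features) already includes two full periods and keeps
the feature count well below typical training-set sizes; returns diminish
quickly beyond small lags for the expanded profiles.

## Parent construction

GTF rows with feature type `CDS` are taken as-is (no ORF re-calling; the
phase column is ignored). Coding parent: CDS segments are grouped by
`transcript_id`, ordered 5′→3′ (coordinate order, then whole-transcript
reverse complement on the minus strand — equivalent to per-segment
reverse complement in reverse coordinate order), concatenated per
transcript, deduplicated across byte-identical transcript sequences
(isoforms sharing their CDS would otherwise be over-weighted), and joined
in annotation order. Both grouping and deduplication are switchable
(`per_transcript`, `dedupe`), since raw row-order concatenation is an
equally defensible reading; the frame-preserving grouped order is the
default because it keeps the period-3 signal intact across exon
junctions. Noncoding parent: the strand-agnostic union of CDS intervals
is complemented per contig, and each maximal noncoding interval
contributes its forward sequence immediately followed by its reverse
complement, in coordinate order — noncoding context of genes on both
strands is thereby represented. A `max_seqs` option restricts analysis to
the first N assembly records (useful for large genomes); the default is
unrestricted.

Coordinates are 1-based inclusive (GTF convention) everywhere inside the
package; the BED-like interval audit table is converted to 0-based
half-open at write time.

## Sampling and splitting

Windows are drawn by partitioning a parent into ⌊L/length⌋ consecutive
disjoint windows and sampling uniformly without replacement — non-overlap
is guaranteed structurally and the attainable count is exact, where
rejection sampling could stall near capacity. When a parent cannot supply
the requested count (default 2000 per class) the class shrinks to
capacity. Window start offsets are recorded so every sample is traceable
to parent coordinates. Windows containing ambiguous letters are kept
(profile estimation drops invalid pairs). Cross-validation uses
stratified 5-fold splits (shuffled, seeded) so per-fold class balance is
preserved.

## Classifiers

* **Linear SVM**: soft-margin, linear kernel (scikit-learn SVC), C = 1 by
  default. Features are standardized with training-fold statistics
  because profile components span different scales across lags and
  margin-based training is scale-sensitive. The fitted decision rule is
  collapsed to an explicit weight vector and bias, and the orientation is
  calibrated after training — if the mean decision value of coding
  training windows is not positive, weights and bias are flipped — so the
  convention *positive score ⇒ coding* holds regardless of solver
  internals.
* **Centroid**: per-class arithmetic means of raw (unstandardized)
  profiles, matching a plain Euclidean-distance reading; the score is
  d(x, noncoding centroid) − d(x, coding centroid).

Prediction uses the strict rule coding ⇔ score > threshold (default 0);
a score exactly at the threshold is called noncoding.

## Evaluation

ROC curves sweep the threshold over every distinct observed score: tied
scores move as a block and the curve is completed by a sentinel below the
minimum score, so it always spans (0,0)–(1,1). The trapezoidal area under
this curve equals the Mann-Whitney estimator
P(score_coding > score_noncoding) + ½·P(tie), which the test suite
verifies against an exhaustive pair-count oracle. Cross-validation pools
the test-fold scores of all folds into one score set and reports a single
ROC/AUC and a single sensitivity/specificity per condition — a single
operating characteristic over the full score range, rather than an
average of per-fold metrics (per-fold averaging was the plausible
alternative; pooling was chosen because each condition should yield one
score distribution and one curve). Cross-species evaluation trains on all
of one species' dataset and scores all of another's, with no fold
structure.

## Synthetic genomes

The generator produces the statistical contrast the classifiers exploit,
and nothing more:

* **Coding model** — i.i.d. codons from a 61-entry sense-codon table
  (stop codons carry zero weight; no start/stop placement, no
  amino-acid-level correlation). Codon-usage bias alone induces the
  period-3 dependence: the lag-k pair distribution of an i.i.d.-codon
  sequence is a three-phase mixture, and at lags divisible by three both
  positions share a codon phase. The default table prefers up to two
  G/C-ending synonymous codons per amino-acid class at an 8:1 ratio.
  Both choices follow from a closed-form analysis of the asymptotic AMI
  profile of the i.i.d.-codon model: concentrating preference on the
  third codon position maximizes the between-phase composition contrast
  that creates the lag-3 peaks, while preference rules tied to the first
  two positions mostly feed within-codon dependence at lags 1–2; and at
  4:1 the lag-3 peak only just clears the lag-2 value (ratio ≈ 1.03),
  which would make the characteristic peaks-at-multiples-of-three
  structure degenerate at realistic sample sizes, whereas 8:1 gives a
  clear margin (ratio ≈ 1.6) while remaining within the codon-bias range
  of strongly biased genomes. The preference ratio is the
  `bias_strength` dial (1 = unbiased).
* **Noncoding model** — an order-1 Markov chain
  P = (1 − a)·𝟙π + a·I with stationary composition
  π = (A .30, C .17, G .13, T .40) and persistence a = 0.2 (the mixture
  form keeps π exactly stationary while giving same-base runs a mild
  excess), plus poly-T runs inserted at rate 0.002/base with geometric
  mean length 8 — emulating the antisense trace of poly-A tails, a
  strong noncoding indicator. These constants are arbitrary but frozen.
* **Annotated genomes** — genes (random strands, lengths rounded to whole
  codons) interleaved with noncoding stretches on one or more contigs,
  emitted as FASTA + GTF together with the embedded ground-truth parents.
  Ground truth follows exactly the conventions of the extractor, so
  round-trip extraction is byte-exact; overlapping genes are never
  generated, which is what makes the byte-exact invariant possible.

What passing tests on these synthetics do **not** show: real genomes have
amino-acid-level correlations, intron/exon architecture, splice signals,
isochores and repeat content that the generator deliberately omits.
Synthetic results validate the machinery and the qualitative mechanism
(codon bias ⇒ period-3 ⇒ separability; composition ⇒ expanded-profile
advantage), not absolute performance on any real genome.

## Numerical choices and degenerate inputs

0·log 0 := 0 throughout; joint cells that are zero contribute zero eaAMI
components, and marginally absent bases cannot appear in any occupied
joint cell. Sequences with no unambiguous base, lags outside [1, L−1],
and lags with zero valid pairs raise typed errors (`no-valid-bases`,
`invalid-lag`, `no-valid-pairs`). Constant features are left centered but
unscaled during standardization. Model JSON serialization stores floats
at full precision, so reloaded models score bit-identically.

## Problem sizes

The shipped benchmark uses synthetic parents of 520 kb per class (220 kb
for the second species), 500 windows per class at 1000 bp and for the
50/200/800 bp length sweep, 1000 per class for the null calibration at
200 bp, and 150 per class at 3000 bp for the centroid analysis — sizes
chosen so that every protocol stage (capacity-limited sampling included)
is exercised at sample sizes where the expected effects are far outside
sampling noise, while the complete benchmark runs in well under a minute
on one CPU.

## Known limitations

* The SVM solver and C are not tuned; results on well-separated data are
  insensitive to C, but short-window performance could likely be improved
  by calibration.
* AUC confidence intervals are not computed.
* GTF only (no GFF3 dialect support); CDS phase is ignored.
* No overlapping-gene mode in the byte-exact round-trip guarantee.
* Amino-acid-alphabet profiles are not implemented.
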