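# Methods

This note documents the models and procedures implemented in `indeltax`,
the parameters that matter, the synthetic-data conditions the tests run
under, and the numerical choices made where the design was genuinely
open.

## Variant normalization

All classification operates on a canonical variant representation:
shared trailing then leading bases are trimmed from REF/ALT, and pure
insertions/deletions are shifted maximally 5' (left-aligned), rotating
the motif as they move.  Records whose trimmed REF and ALT are both
non-empty are *complex* InDels (simultaneous insertion and deletion);
records with equal REF/ALT length are substitutions/MNVs and are routed
to the SNV counter at VCF reading, never into the InDel pipeline.
Internally all coordinates are 0-based half-open; `pos0` is the anchor
base immediately 5' of the event.

Each normalized InDel carries flanking sequence: at least 10 bp 5' and
50 bp 3', with the 3' window growing as `max(50, 9·|motif| + 1)` so
that repeat-copy bins up to their caps never saturate against a
truncated window.  The 50 bp floor is a configurable default; it
comfortably exceeds the longest homopolymer tract any scheme
distinguishes (9+).

## Segmentation

For an InDel with motif *m* and 3' reference context *c*, every prefix
*P* of *m* is scored by the number of gap-free tandem copies of *P*
reading from the event anchor: whole copies inside *m*, continuing into
*c* only when *P* tiles *m* exactly (a non-empty remainder interrupts
the tandem run, so context copies then do not count; partial trailing
copies never count).  The segmentation is the shortest prefix attaining
the maximal copy count — ties go to the shorter unit, which also
guarantees the chosen unit is primitive.  Copies straddling the
motif/context boundary are not counted: allowing them would make the
within-event and in-context copy numbers non-integral and the unit
non-reconstructive (`motif = unit × copies_in_indel + remainder` must
hold exactly).

Two consequences used throughout:

* for a 1 bp deletion, total copies equal the reference homopolymer
  run length (the deleted base is the 5'-most of its run after left
  alignment); for a 1 bp insertion, total copies equal the run length
  plus one, because the inserted copy itself counts;
* after left alignment a deletion can have no 5'-side junction
  homology (a suffix match of length ≥ 1 would permit a further left
  shift), so microhomology *M* reduces to the longest proper prefix of
  the motif matched by the immediate 3' context.  Both flanks are
  still checked, matching the general definition.

## Channel schemes

Three schemes are provided, each a total, non-overlapping
classification of normalized InDels.

**Six divisions** order the routing: complex > microhomology > repeat.
A deletion in a repeat context (total tandem copies ≥ 2) is a slippage
deletion even if its junction shows homology; microhomology requires a
non-repeat deletion of length ≥ 2 with *M* ≥ 1.

**full476** (476 channels) crosses:

| division | bins | count |
|---|---|---|
| 1 bp insertions | motif C/T × run 0–8, 9+; runs ≤ 4 sub-split by 5'×3' flanking base pairs (3 × 3 each) | 100 |
| 1 bp deletions | motif C/T × run 1–8, 9+; runs ≤ 4 flank-split | 82 |
| ≥2 bp insertions | repeat: unit-length {1, 2, 3, 4, 5+} with unit content (C/T for 1 bp units; 8 reverse-complement dinucleotide classes for 2 bp) × total copies {2–8, 9+}; non-repeat: length {2–9, 10+} | 113 |
| ≥2 bp deletions | as insertions | 113 |
| microhomology deletions | L {2–11, 12+} × M {1..min(L−1, 8), 9+} | 63 |
| complex | total replaced length {2–5, 6+} | 5 |

1 bp InDels are reported on the strand where the motif is a pyrimidine;
reverse-complementing swaps and complements the two flanking features.
Flank sub-channels exist only at short runs because in longer runs the
run itself is the 3' context and the 5' base adds little signal.

**ind89** (89 channels, six divisions) is a strict coarsening shipped
as a canonical merge map: flank pairs collapse to the single most
informative flanking base (the 3' base at run 0 insertions, the 5'
base at run 1), runs 2–4 lose their flank splits, unit lengths collapse
to {1, 2, 3+} without content classes, copies to {2, 3, 4+}, non-repeat
lengths to {2–5, 6+}, microhomology to L {2, 3, 4, 5+} × M {1, 2, 3,
4+}, and complex to a single channel.  The per-length run bins up to
9 (9 meaning ≥ 9) retain the long-homopolymer resolution that the
legacy scheme aggregates away; longer tracts are not subdivided because
short-read InDel calling becomes unreliable there.

**cosmic83** is the standard PCAWG/COSMIC ID-83 classification
(SigProfiler-style channel ids): 1 bp C/T × run bins terminating at 6+
(deletions) / 5+ (insertions), ≥2 bp repeat InDels binned by whole-
motif length {2, 3, 4, 5+} × whole-motif repeat counts, and an 11-bin
microhomology block.  It has no complex division; to keep the function
total, complex InDels are routed by their larger component (the
deletion on ties).

Because the published full-476 and 89-channel definition tables are
supplementary assets not available to this implementation, the channel
tables here are a **reconstruction** that honours every documented
property of the taxonomy (cardinalities 476/89/83, six divisions,
pyrimidine collapsing, flank context at short runs, per-length long-run
bins, unit-length × copy binning from segmentation, L×M microhomology
bins, data-driven consolidation).  The shipped TSV assets under
`indeltax/data` are generated from the scheme builders, versioned
`reconstructed-1.0`, and tested for bit-identity with the code.

`consolidate()` additionally implements the generic data-driven path:
channels with no cohort signal are dropped and channels below a signal
fraction merge into their canonical parent aggregate; at threshold 0 on
a fully populated cohort it is the identity, and merging everything
reproduces the 89-channel scheme.

## Profile statistics

**Bootstrap background envelope.**  Control catalogs are aggregated
into a background density; `n_boot` (default 100) multinomial
replicates are drawn at each control's own burden (cycling through the
controls) and their cosines to the background define the envelope.  A
query profile is *distinct* when its cosine falls below mean − 3 sd.
Replicates resample at per-control burdens rather than the pooled
burden so the envelope reflects sampling noise at realistic depth.
The multinomial cosine null is left-skewed, so the 3 sd rule sits near,
not exactly at, the Gaussian 0.13% point; calibration tests bound the
null call rate at 1%.

**Background subtraction.**  `max(0, edited_counts −
background_density × background_burden)`, renormalized; the background
is scaled by burden, not proportion.  A zero background burden returns
the edited profile unchanged; a subtraction that annihilates every
channel is an error (the edit produced no signature).

**Exposure refitting** is non-negative least squares per sample, with
an optional sparsity threshold that zeroes small exposures and refits
the remainder.  Rank-deficient signature matrices produce a warning
(NNLS still returns a minimiser; it may be non-unique).  The tiered
common/rare signature search of dedicated refitting tools is out of
scope.

**Excess-variation test.**  The sample's NNLS reconstruction defines a
multinomial null at the observed burden; `n_sim` simulated profiles
(default 10,000) are each refit and the fitting error — the L1
residual normalized by burden (the L1/L2 choice was open; L1 is the
default and is flagged here) — yields an empirical p value, the
fraction of simulated errors at least as large as observed.  The
cohort wrapper applies Benjamini–Hochberg and flags adjusted p < 0.05.
Calibration tests use 200 null samples × 2,000 simulations at burden
700 — enough for p-value resolution of 5 × 10⁻⁴ while keeping the
suite inside a CPU-minute budget.

**Hypermutator detection.**  Samples under 100 InDels are removed;
profiles are clustered (complete linkage, cosine distance; dendrogram
cut maximising mean silhouette width) and per cluster a one- versus
two-component Gaussian mixture on burden is selected by BIC.
Hypermutators are the union of global IQR outliers (burden > Q3 +
1.5 IQR) and samples with > 50% posterior in the higher-mean component.
Clusters smaller than 3 skip the mixture; cohorts smaller than 10 fall
back to the IQR rule alone.

**Strand asymmetry.**  1 bp InDels are pyrimidine-aligned: an event
whose reference motif is a purine has its pyrimidine context on the
reverse strand, so the annotated replication-strand label is flipped
for it.  Channel groups are (operation × pyrimidine base × run bin
{0–4, 5–7, 8+}) — the middle bin isolates the polymerase-footprint
tract lengths.  The expected leading/lagging split per group counts
matching maximal homopolymer loci (both strands) inside the annotated
regions; this locus enumeration is the package's resolution of an
under-specified step and is deliberately simple.  Significance is a
binomial test (χ² optional) against the expected split,
BH-corrected across groups.  Odds ratios use a Haldane 0.5 correction
on observed counts only, which preserves exact label-swap reciprocity.

**De novo factorization harness.**  Bootstrap NMF replicates per
candidate rank; pooled replicate signatures are re-clustered and scored
by mean silhouette width (cosine distance; rank 1 uses mean cosine to
the centroid).  The selected rank is the largest with stability ≥ 0.9 —
the rank just before the silhouette collapses.  This harness exists to
property-test channel discriminability (two signatures differing only
inside long-homopolymer sub-bins are separable at 89 channels but not
under the legacy aggregation); it is not a production extractor.

## PRRDetect

Seven features: grouped exposures of MMRd-associated SBS 6/15/26/44/97,
Pol-dys SBS 10a/10d, mixed SBS 14/20, MMRd InD 7/19, Pol-dys
InD 14/15, mixed InD 16a/16b/20/21, and the total InDel/SNV ratio.  In
proportional mode (the default) the six signature features are divided
by the sample's total SBS / InD exposure.  Features are log2(x + pc)
transformed (pc = 1 for raw counts, 10⁻⁶ for proportions — the
pseudocount was an open choice and is stored in the model), then
z-scored with training-set moments.

Training performs stratified 70:30 partitions (default 10); within each
training split a grid over the elastic-net mixing α ∈ {0, 0.1, …, 1}
and penalty λ (log-spaced 10⁻⁴…10¹; the grid itself was unstated and
is a package default) is searched by repeated stratified k-fold
cross-validated multinomial log loss.  λ maps onto the scikit-learn
parameterization as C = 1/(n·λ), so λ → ∞ drives all slopes to zero.
Coefficient means ± sd across partitions form the stability report;
the final model is refit on the full cohort with the same protocol.
Classes with fewer members than folds reduce the fold count with a
warning; cross-validation folds are stratified, as the positive
classes are small.

Prediction is a softmax over the stored coefficients.  The call is
PRR-proficient iff P(Neg) > 0.5 (strictly); otherwise the
highest-probability positive class.  Evaluation collapses the three
positive classes, scores by 1 − P(Neg), and reports ROC and
precision–recall curves with trapezoidal AUC, plus the per-class
confusion matrix of categorical calls.

## Synthetic data

The generator produces every input the pipelines need, deterministic
under a seed.

*References and planted InDels.*  Each requested event gets its own
planted site whose channel is known by construction: guard bases
prevent run extension and left-shift beyond the locus; repeat units are
restricted to strings whose first base does not recur inside the unit,
making the planted unit provably the segmentation optimum; homology at
microhomology sites is pinned by an explicit breaker base.  Truth
channel ids are derived from the construction parameters, never from
the classifier, so plant → VCF → read → normalize → classify is a
genuine end-to-end check.  The VCF emitter deliberately writes
denormalized encodings (random right-shifts within repeats, shared
trailing padding).  Planted cores are separated by ≥ 10 bp spacers.
Equal-length replacements cannot be planted: they are MNVs and the VCF
reader excludes them by definition.

*Catalogs* are multinomial draws from signature-mixture densities at
each sample's exposure burden.

*Classifier cohorts* emulate a curated PRRd training set: class mix
defaulting to 214 MMRd / 36 Pol-dys / 41 mixed / 280 negative out of
571 samples; MMRd samples are InDel-driven (mean InDel/SNV ratio 0.5 at
a mean SNV burden of 5 × 10⁴), Pol-dys substitution-driven (ratio 0.02
at 2 × 10⁵), mixed intermediate, negatives background-only (ratio 0.08
at 5 × 10³).  Exposure fractions are Dirichlet draws around the class
mixture (concentration 150), burdens lognormal (σ = 0.35).  These
defaults produce strongly separated classes (≥ 2 sd in transformed
feature space), which is what the recovery tests assume; they do not
model borderline phenotypes, subclonality, inter-signature bleed-through
from imperfect refitting, or label noise, so classifier results on this
cohort demonstrate correctness of the training/decision machinery, not
clinical performance.

*Strand annotation* tiles contigs with alternating leading/lagging
blocks.

What the synthetic data does **not** emulate, and what passing tests
therefore do not show: sequencing and alignment error, caller-specific
artifacts, real genomic repeat-length distributions and GC structure,
overlapping/phased variants, and real signature profiles.  The channel
truth sites are deliberately unambiguous, whereas real loci can mix
repeat and homology structure; the classifier remains total on such
loci, and the routing precedence above decides them.

## Problem sizes and tolerances

Test and acceptance runs use: 10⁵ fuzzed InDels for partition checks,
10⁴ for the segmentation oracle, ≥ 10³ planted events covering all 89
channels, 5 seeds × 40 samples for the discriminability experiment,
200 null samples × 2,000 simulations for excess-variation calibration,
and 400/250-sample train/held-out cohorts with a reduced grid
(α ∈ {0, 0.5, 1}, four λ values, 3 partitions, 5-fold CV) for the
classifier — sizes chosen so each property is measured with comfortable
statistical margin on a single CPU.  Numerical tolerances: profile
normalization 10⁻⁹; exact-recovery refits 10⁻⁶ relative; NNLS and NMF
use library defaults (NMF max_iter 3,000, tol 10⁻⁵).

## Known limitations

* The channel tables are a reconstruction (see above); exact
  channel-for-channel agreement with the published supplementary
  tables is not claimed, and catalogs produced here should not be
  mixed with externally produced 89-channel catalogs without checking
  the definitions.
* The expected-ratio locus enumeration in the strand-asymmetry test
  counts maximal homopolymer runs only; insertions "at run 0" reuse
  the length-1 locus count as their opportunity proxy.
* `extract_denovo` is a stability harness, not a replacement for
  dedicated signature extractors; its rank selection threshold (0.9)
  was chosen for clear separation on well-conditioned inputs.
* Hypermutator mixture fits operate on raw burdens; heavy-tailed
  burden distributions within a cluster can favour the two-component
  model without a biologically distinct subpopulation (the IQR rule is
  the backstop).
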