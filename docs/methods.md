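# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `endotraits`, in the order the pipeline runs them.

## Plate scoring

A Biolog SF-P2-style plate gives one isolate a raw OD590 reading per
carbon resource plus a single water-control well. Standardized growth is
`od[i, r] − water[i]`; negative values are retained in every mean (the
subtraction is the only normalization — truncating at zero would bias
means upward). Binary use is `sg ≥ 0.005`: the threshold is the
photometric accuracy of common plate readers, and the boundary value
counts as growth so that the dichotomy is exhaustive. The "common"
resource set is those used by at least half of all isolates (ties at
exactly 50% included); restricting the per-isolate mean to this set
damps the influence of rarely-used, zero-heavy resources. Growth
efficiency (mean over only the isolate's own used resources) is undefined
at niche width 0 and reported as NaN rather than an error, since
zero-width isolates are legitimate data.

## Mixture classification

Per-isolate mean standardized growth is modeled as a two-component
univariate Gaussian mixture with unequal variances (empirically the slow
mode is much tighter than the fast one). Fitting is EM with `n_starts`
initializations: the first splits the sorted sample at its median, the
rest seed component means from random data pairs. Convergence is declared
when the log-likelihood increment falls below `tol · n` — the increment,
unlike the log-likelihood itself, is invariant under affine data
transforms, which makes the fitted cutoff affinely equivariant to
numerical precision. Component standard deviations are floored at 10⁻⁴
of the data sd; a start that ends on the floor (the classic unbounded-
likelihood collapse) is discarded, and the best surviving start by
log-likelihood wins. Components are relabeled so μ₁ < μ₂.

The classification cutoff is the equal-posterior point
w₁φ(x; μ₁, σ₁) = w₂φ(x; μ₂, σ₂) in (μ₁, μ₂), located by a dense
sign-change scan plus Brent's method (tolerance 1e-10). With unequal
variances this equation is quadratic and can lack a root between the
means (e.g. a tiny, tight component under a broad one); that case raises
an error recommending a manual cutoff rather than guessing. The
equal-posterior definition is the Bayes decision boundary and reduces to
the midpoint in the symmetric case; the density-minimum alternative gives
nearly identical values for well-separated components. Values at or above
the cutoff are "fast" (the slow class is defined by strict inequality).
A separation diagnostic (|μ₂−μ₁| relative to the pooled sd) flags fits
where the dichotomy is not meaningful (< 2 pooled sd).

## Phylogenetic covariance and Blomberg's K

Trees are used as rooted, with branch lengths as given (unitless);
missing lengths are an error unless a constant is explicitly supplied,
because silently defaulting would corrupt the covariance. C[i, j] is the
root-to-MRCA shared path length; the diagonal is the root-to-tip
distance. Polytomy resolution inserts zero-length edges only, so C and
all patristic distances are unchanged; subtree extraction sums through
suppressed unary nodes, preserving patristic distances.

K is computed from the closed-form GLS expression (see README). The
"more conserved than Brownian motion" criterion is operationalized
exactly as K > 1: the BM expectation is the denominator of K, so no
separate simulation test is needed for that count. BM simulation (joint
Gaussian via independent per-branch increments, which handles singular C
exactly) is provided for calibration — mean K over BM replicates sits in
[0.9, 1.1] on a 50-tip tree — and for building synthetic traits.

Degenerate covariance matrices (duplicate rows from zero-length terminal
branches) trigger a pseudo-inverse fallback with a logged warning.
Constant traits are an error in direct calls and a recorded-but-skipped
row in scans. A 2-tip tree with equal terminal branches returns K = 1
identically, as does any star phylogeny.

## Random-tips permutation test

The RT null shuffles trait values across tips, destroying phylogenetic
structure while keeping the trait distribution. The p-value uses the
include-observed convention p = (1 + #{K_perm ≥ K_obs})/(n_perm + 1), so
p is never 0 and 999 permutations give granularity 1/1000; ties count as
exceedances (conservative). The default 999 permutations give a one-
tailed test read at α = 0.05. An exhaustive mode enumerates all n!
relabelings for n ≤ 8 and is tested against independent enumeration.
K evaluations are vectorized against a precomputed C⁻¹, which is what
makes 999 permutations × 95 resources × several taxonomic levels run in
seconds.

Scans resolve polytomies once per level (all traits at a level must share
one topology) with seeds derived from the scan seed via `SeedSequence`
spawning. Groups with fewer than `min_tips = 5` usable tips are skipped:
below that, C⁻¹-based GLS and permutation granularity are uninformative,
matching the n ≤ 5 exclusion used for the Fisher tables.

## Group statistics

The default t-test is Welch (the two assemblages have very different
dispersions); the pooled "Student" variant is always computed alongside
because field reports conventionally name Student's test, and the two can
be compared in the output. Fligner–Killeen (rank-based normal scores of
|x − group median|, χ² reference with k − 1 df) tests niche-width
variance without normality assumptions. Per-taxon composition tests are
row-vs-pooled-remainder 2×2 Fisher exact tests, two-sided by the
"sum of probabilities ≤ observed" rule, with the conditional-MLE odds
ratio; rows with ≤ 5 isolates are flagged NA and excluded from the Holm
adjustment, which spans only tested rows. Richness per leaf counts
distinct OTUs per leaf × method; cells with no isolates count 0 by
default (the sampling design guarantees both methods were attempted per
leaf), with an exclusion flag available.

## Synthetic-data generator

The generator's defaults are the study conditions the package is built
for: 12 leaves × 2 isolation methods × 10 isolates = 240 isolates on 95
resources; slow growers N(0.04, 0.03²) OD590 with niche width
N(46, 25²), fast growers N(0.29, 0.14²) with width N(82, 12²);
maceration recovers fast growers with probability 0.85 (sectioning with
the complement).

Structure: a pure-birth (Yule) tree conditioned on the isolate count
(waiting time Exp(k·λ) at k lineages, tips extended by a final
Exp(n·λ), so expected height is Σ_{k=2..n} 1/k). Nested "classes",
"orders" and "OTUs" are the clades crossing fixed depth fractions of
tree height (0.25, 0.40, 0.75 — chosen once to give roughly 3–6 classes,
~10 orders and ~60 OTUs at 240 tips, the granularity typical of such
collections). Each class draws a majority assemblage; isolates follow it
with probability `clade_assemblage_fidelity` (default 0.9). A
deterministic guard flips whole-class labels until each assemblage covers
at least 20% of isolates — a Yule tree's largest clade often dominates,
and a near-single-assemblage community would make the mixture stage
meaningless. Isolation methods fill fixed-size halves by weighted
sampling without replacement (Efraimidis–Spirakis keys) with fast:slow
odds p : 1−p, so p = 0.5 is exactly an exchangeable split with no
method × assemblage association.

Per-well model: water N(0.05, 0.01²) truncated at 0 (an arbitrary but
realistic blank level; only differences matter); unused wells add
N(0, 0.002²) noise, so binarizing at 0.005 misclassifies ~1% of unused
wells — intentional realism, configurable to 0; used wells add the
isolate's growth signal scaled by `n_resources / niche_width` plus
N(0, 0.02²) noise. The scaling realizes the drawn per-isolate value as
its mean standardized growth *across the plate* — an unscaled per-well
value would be diluted by the unused-well fraction, and the recovered
mixture means would sit below the generating parameters by a
width-dependent factor. Niche widths are drawn independently of mean
growth within assemblage (a documented simplification; real data may
correlate them), rounded and clipped to [0, n_resources]. A width
distribution whose mean exceeds the resource count by more than 3 sd is
rejected as infeasible.

What the generator does *not* emulate: resource identity effects (all
resources are exchangeable, so the "common" set is usually all 95 —
unlike real plates where rarely-used substrates cut it to ~62),
correlated wells within isolate beyond the shared growth level,
sequence-level error, or richness differences between isolation methods.
Passing end-to-end tests therefore demonstrates correct recovery of
clade-structured bimodal growth under the stated noise, not robustness to
those unmodeled features.

## Pipeline and reproducibility

All randomness flows from explicit integer seeds (mixture and signal
stages separately); permutation and polytomy seeds are derived via
`SeedSequence` spawning, so re-running a config reproduces every output
byte-for-byte. The manifest records the package version, full config,
SHA-256 of each input, and summary counts. Tip-label matching between
tree and trait table is exact string equality; unmatched tips are dropped
with a logged count, and isolates present on the plate but absent from
the metadata are an error listing the mismatches.

## Problem sizes used in validation

The calibration suite uses a 50-tip tree × 500 BM replicates for the
K ≈ 1 check, 1000 replicates × 199 permutations on 16 tips for the
type-I error of the RT test, 50 study-scale replicates (93 slow + 147
fast values) for mixture recovery, and 20 default-spec communities for
end-to-end recovery — sizes chosen so the whole suite runs in about a
minute on one CPU while leaving Monte-Carlo error well inside the
asserted bands.

## Known limitations

- K assumes a fully resolved tree with meaningful branch lengths; with
  many zero-length branches the pseudo-inverse fallback changes the GLS
  geometry and K values should be interpreted cautiously.
- The mixture model is restricted to two Gaussian components by design;
  collections with more growth modes need a different classifier.
- The RT test is one-tailed for conservation (K larger than null); trait
  overdispersion is not tested.
- Branch-length units are taken as given; K is invariant to uniform
  rescaling but not to unit mixtures across subtrees.
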