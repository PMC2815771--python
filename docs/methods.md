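# Methods

## Motif model and PWM generation

A motif of width `w` is a position weight matrix (PWM): one probability
vector over {A,C,G,T} per column.  Information content is the total
relative entropy to a background vector in bits, `Σ_i Σ_b W_ib
log2(W_ib/π_b)` with `0·log 0 = 0`; the background defaults to uniform
and is configurable everywhere the IC is used.

`generate_wm` draws each column from a symmetric Dirichlet and tunes the
concentration parameter α until the total IC hits the target.  To make
that tuning well posed, the Dirichlet draws are computed as the gamma
inverse CDF of a fixed seeded uniform matrix, so IC(α) is a continuous
deterministic curve that decreases from `2w` bits (α→0, point-mass
columns) to 0 (α→∞, uniform columns); α is bisected on a log scale
until the IC is within the tolerance (default 0.1 bits, 0.25 in dataset
configs).  Targets within one tolerance of 0 or `2w` short-circuit to
the exact uniform / point-mass limits.  The benchmark's "high-IC" motif
is generated at 24 bits and the degenerate regimes at 20 and 14 bits of
a 26-bit maximum for width 13.

## PWM comparison

Two PWMs are compared by the minimum, over all column offsets that keep
at least half of the shorter width aligned and over both orientations
(forward and reverse complement), of the mean per-aligned-column
Euclidean distance.  The metric is symmetric and zero for identical or
reverse-complementary matrices.  The default match threshold, 0.3139,
is the 5% quantile of this score over 20,000 pairs of independent
random 13-column PWMs (symmetric Dirichlet(1) columns, seed 20260101),
i.e. a 5% false-match rate on unrelated motifs; it is recomputable with
`calibrate_match_threshold`.  PWMs estimated from ten true sites of a
14–24-bit motif score ≈0.09–0.24 against the source motif, so the
threshold separates the two populations comfortably.  Predicted motif
models are estimated from sites with a per-base pseudocount of 0.25
(keeps columns strictly positive for distance computations).

## Evolution model

Each branch carries a proximity `q ∈ (0,1]`, the probability that a
base is copied unchanged; otherwise it is redrawn from the equilibrium
distribution — the background vector for background positions
(Jukes–Cantor when uniform, F81 otherwise), or the PWM column for
positions inside the embedded site.  The kernel is `P(a→b) = q δ(a,b) +
(1−q) π_b`, which composes exactly: `T(q1)T(q2) = T(q1·q2)`.  Because of
this composition, evolving per edge through internal nodes is
distributionally identical to evolving each leaf directly at its path
proximity; the implementation recurses per edge, consuming RNG draws in
deterministic pre-order so results are seed-reproducible for any tree
shape.  Distance-annotated Newick trees are converted through the F81
relation `q = exp(−βt)`, `β = 1/(1 − Σπ_b²)` (4/3 for uniform π).

Motif loss is modelled as replacement of the site window by fresh
i.i.d. background at the affected leaf (orthologous direction) or by
generating the whole ancestor as background so the reference gene and
all its orthologs lack the site (coregulation direction).  There are no
indels, rate heterogeneity, or site-turnover dynamics: all sequences in
a dataset have identical length.

## Dataset assembly

Ancestors are 500 bp i.i.d. background with one sampled site
overwriting a uniformly placed window (overwriting, not inserting,
keeps lengths equal).  The coregulation space evolves ten independent
ancestors over a single 0.80-proximity branch and keeps only the
reference leaf; `dropout_k` randomly chosen genes carry no site.  The
combined space evolves each ancestor down the full tree (star or
internal-node topologies; the canonical unequal star is
REF:0.80, 0.90, 0.85, 0.75 plus a distant 0.20 ortholog); the
orthologous space is the combined space with a single gene.  Internal
coordinates are 0-based half-open; GFF3 output is 1-based inclusive
with feature type `TF_binding_site`; all embedded sites are on the +
strand and strand is ignored during matching.  Each of the ten genes
uses an independent random background.  Datasets regenerate
bit-identically from (config, seed); the PWM seed is derived from the
dataset seed.

## Evaluation

A predicted site is a true positive when its overlap with its
best-overlapping truth site on the same (species, gene) is at least
half that truth site's length (real-valued comparison; a width-13 site
needs ≥6.5 bp, i.e. ≥7 bp, of overlap).  Ties on overlap go to the
leftmost truth start, and one prediction validates at most that one
truth site; a truth site counts as found if any prediction half-covers
it.  PPV = TP/(TP+FP), Sens = TP/(TP+FN); spPPV/spSens recompute both
after restricting predictions and truths to the reference species.  A
measure with a zero denominator is reported as undefined (`None`) and
excluded from means rather than coerced to 0 or 100, which would bias
small tests.

Recovery of a run is 1 when its predicted PWM matches the "correct"
model (the PWM built from the embedded sites) under the comparison
above, or, failing that, when both spPPV and spSens exceed 50% or
either exceeds 80% (strict inequalities).  Per test, D1 (or R1 for
repeated runs on one input) counts runs with any output, RR is the
percentage of outputs with recovery 1, quality means are taken over the
correct outputs only, and the F-value is the harmonic mean of the mean
spPPV and mean spSens, with F-differences reported against a designated
baseline test.

## Baseline finder

The built-in finder is a collapsed Gibbs site sampler with a
product-multinomial motif model (pseudocount 0.25) against a 0th-order
background estimated from the input; orthologs are treated as
independent sequences, so it represents the class of finders that use
no evolutionary model.  It is not a re-implementation of any published
tool.  Modes: one site per sequence, or zero-or-one with a
per-sequence site prior of 0.9 (most benchmark configurations embed a
site in every sequence; dropout configurations remove at most two of
ten).  Defaults: 120 sweeps, 8 restarts, best state by total
log-likelihood ratio.  The reported score is the mean per-site log2
likelihood ratio in bits; with `significance_threshold` set, runs
scoring below it return no output.  `NULL_SCORE_THRESHOLD = 14.5` bits
was calibrated above the 90th percentile of best scores reached on 50
motif-free 10×500 bp datasets (null scores 13.4–14.8 bits; planted
24-bit motifs score ≈20–22 bits).

## What the simulations do and do not show

The generator reproduces the benchmark's synthetic study conditions:
equal-length, alignment-free, substitution-only promoters with exactly
one site per non-lost sequence and independent backgrounds.  Real
promoters add indels (and hence alignment uncertainty — the major
bottleneck for alignment-dependent phylogenetic finders), composition
bias, multiple and overlapping sites, and correlated backgrounds; none
of these is modelled, so passing results here certify the machinery and
the relative difficulty of the configured conditions, not performance
on real genomes.  Headline comparisons of external tools depend on
those tools' binaries and parameter tuning and are out of scope; their
outputs can be scored through the predictions TSV or the MEME text
adapter.

## Problem sizes and numerics

Statistical tests in the suite use 10,000-position or
10,000-replicate simulations with 3-standard-error or chi-square
(p > 0.01) acceptance at fixed seeds; end-to-end finder checks use 20
datasets per IC level at the package's own choice of desk scale, with
grid examples at 3–5 replicates (the full-scale convention is 100
datasets per synthetic test and 10 repeated runs for fixed-input
tests).  Degenerate cases are pinned by tests: zero-IC and maximum-IC
PWM targets, single-leaf trees, background length equal to motif width,
empty prediction sets, and zero-denominator measures.  Gamma-ppf
underflow at extreme Dirichlet concentrations falls back to the exact
point-mass limit.  Newick round-trips preserve proximities to 1e-9
(12 significant digits on write).
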