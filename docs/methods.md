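# Methods

This note documents the models implemented in `asrbench`, the conventions
chosen where several were defensible, and what the simulations do and do not
establish about real data.

## Tree simulation

Trees are ultrametric, rooted and strictly binary. Given *n* sampled tips,
birth rate λ, death rate μ (λ > μ ≥ 0) and sampling fraction ρ ∈ (0, 1],
the *n* − 2 non-root divergence ages are i.i.d. draws from the conditional
age kernel of the sampled birth–death process. With ages measured backwards
from the tips and constants a = λ − μ, c = ρλ, d = λ(1 − ρ) − μ, the kernel
density on (0, h) is

    g(t) ∝ a² ρ e^{−at} / (c + d e^{−at})²,

whose antiderivative is closed-form, so sampling uses exact inverse-CDF
inversion (the test suite cross-checks the empirical age distribution
against a quadrature-integrated CDF by a Kolmogorov–Smirnov test). Sorted
ages are attached by splitting a uniformly chosen active lineage, the
uniform ranked-topology construction. This conditioned construction yields
exactly *n* tips without rejection, which matters at ρ = 0.01 where forward
simulation would discard almost every replicate.

The root is placed at the requested height and all branch lengths are
rescaled so the root-to-tip distance equals the height exactly: height is
treated as a controlled design variable, not an emergent property of
(λ, μ). Defaults follow the study design: λ = 6, μ = 3, heights
{0.8, 1.0, 1.2, 2.0}, sampling fractions {0.01, 0.25, 0.99}, taxon counts
{16, 32, 64}. Internal nodes are labeled N1 (root) … N(n−1) in preorder so
true and reconstructed ancestors correspond by label.

## Sequence evolution

Substitutions follow the WAG replacement model (bundled published
exchangeabilities and frequencies, integrity-checked in the tests) with
discrete-gamma rate variation: K equal-probability bins of Gamma(α, α),
each represented by its conditional mean, so category rates average exactly
1. Defaults α = 1.8, K = 4. The generator Q is normalized to one expected
substitution per unit branch length for a rate-1 site at stationarity.

The root sequence (default 408 residues) is drawn i.i.d. from the
stationary frequencies with i.i.d. category assignments. Evolution along
each branch is an exact Gillespie simulation; substitution events use
thinning against the uniform bound (max category rate × max leave rate), so
each step is O(1) while remaining an exact sample of the CTMC (verified
against matrix exponentials in the tests).

Indel conventions (insertion and deletion rates are equal by default, 0.01
or 0.05, in units of the average substitution rate):

- insertions occur at the L + 1 inter-residue slots, including both ends,
  at `insertion_rate` per slot; inserted residues are stationary draws with
  fresh gamma categories;
- deletions occur at `deletion_rate` per residue, independent of the
  site's gamma category; the length is drawn first, the start residue
  uniformly, and deletions overrunning the end are truncated;
- lengths are truncated-Zipf, P(L = k) ∝ k^(−1.7), 1 ≤ k ≤ 20.

These end-handling and fresh-category rules are this package's documented
choices; equal-rate simulations drift slightly long because insertions act
on L + 1 slots while deletions act on L sites with end truncation (the
tests assert the direction and a 5% bound on a seeded batch). A replicate in
which any lineage's sequence shrinks to length zero is rejected and re-run
with a fresh sub-stream, with the rejection count recorded.

Homology is tracked by column objects in a doubly-linked global column
list, so the true alignment of all nodes — tips and ancestors — is an exact
byproduct of the event history, not a post-hoc estimate. Columns left with
no surviving residue in any recorded node (insertions erased within a
single branch) are dropped.

## Ancestral reconstruction

Reconstruction is marginal maximum likelihood on the true tree with the
true model and branch lengths; nothing is estimated. Per column, inside
(pruning) and outside recursions run per gamma category with per-column
scaling; node posteriors are mixed across categories by the per-column
category posterior. Gaps and ambiguity codes (X, B, Z, J, ?, *) are missing
data in the amino-acid model. The root prior is the stationary
distribution; reversibility makes the likelihood invariant to root
placement (tested via the pulley principle at 1e-8).

Presence/absence is reconstructed with a symmetric two-state model over the
same tree, with flip rate per unit branch length equal to insertion rate +
deletion rate from the scenario (default 0.1); only '-' counts as absence.
A column is called present at a node iff its presence posterior is ≥ the
cutoff (0.50 by default, inclusive); present columns report the argmax
residue, exact ties broken alphabetically. The two-state model is a
documented stand-in for the richer indel models of production ASR software;
its rate is configurable and the cutoff semantics are the tested contract.

## Accuracy and alignment quality

Reconstructed and true ancestors are aligned by a deterministic global
affine-gap Needleman–Wunsch–Gotoh aligner (BLOSUM62, gap open 11, extend 1,
gap of length k costs 11 + (k − 1); fixed traceback preference
match > delete > insert). The error decomposition over alignment columns —
insertion, deletion and substitution errors plus accuracy summing exactly
to 1 — is the package's accuracy measure. Using an internal deterministic
aligner rather than an external pairwise tool makes accuracies reproducible
to the bit; absolute values shift slightly with aligner and parameters, so
conclusions should rest on comparisons and bounds, not third-decimal
values.

MSA quality against the true alignment: SP/Developer (reference residue
pairs recovered), Modeler (test pairs that are correct; 0/0 defined as 0,
the underalignment pathology), Total Column (reference columns reproduced
as residue-index sets), and the Cline shift score with ε = 0.2, symmetrized
by summing both directions and normalizing by the total pair count, range
[−ε, 1]. Residues aligned in one alignment but unaligned in the other
contribute 0.

## Benchmark statistics

- Seeds: master seed → SeedSequence([master, crc32(scenario id)]) →
  spawned child streams per (tree replicate, sequence replicate). Identical
  config + seed reproduces every table byte for byte.
- Mann–Whitney–Wilcoxon comparisons are two-sided on node-level accuracies;
  for combined samples of ≤ 16 the p-value is the exact permutation
  enumeration, otherwise the asymptotic approximation with tie correction.
  All-tied samples give p = 1. Benjamini–Hochberg is applied jointly across
  all scenario × pair tests (the conservative family choice); a win
  requires adjusted p strictly below α = 0.01 and the higher median.
- Depth profiles are equal-width binned means with counts and standard
  errors; LOESS is optional presentation smoothing only.
- Quality–accuracy correlations (Pearson r, r², Spearman ρ) are computed
  over scenario means per aligner and pooled; zero-variance inputs are
  flagged undefined instead of propagating NaN.
- Failed external aligner invocations yield rows marked `failed` with
  missing metrics; downstream statistics exclude them explicitly.

The builtin progressive aligner (UPGMA guide tree on k-mer cosine
distances, profile–profile affine NW merges sharing the pairwise DP core)
exists so the complete pipeline runs and is testable without external
tools; it is deliberately simple and is not a competitor to production
aligners.

## What the simulations do and do not show

The generator realizes the study conditions: ultrametric trees, i.i.d.
sites, stationary root, equal insertion/deletion rates, no rate variation
across lineages, no selection, no domain structure or conserved motifs.
Passing tests therefore demonstrate correctness of the machinery and the
direction/magnitude of effects *under this model*, not performance on real
proteins, where indels cluster, composition drifts and alignment errors are
correlated with structure. Tool-specific rankings of external aligners
depend on tool versions and are out of scope.

## Problem sizes and numerical choices

Default test and acceptance runs use scaled-down replication chosen as the
smallest sizes at which the stochastic assertions are stable: 10 tree
replicates × 1 sequence set at 16 taxa for the headline accuracy figure
(150 node-level observations) and for the monotonicity checks in height
{0.8, 2.0} and sampling fraction {0.99, 0.01}; the full 10 × 10 × 72-
scenario grid is available through `default_grid()`. Oracle comparisons use
exhaustive enumeration (quartet marginals at 1e-10, short-string alignment
scores), quadrature (gamma category rates at 1e-6) and closed-form
normalizers (truncated Zipf). Likelihood scaling is per column and per
category; posteriors are normalized per node and column (1e-9 test bound).
Degenerate inputs — empty sequences, all-gap columns, tied statistics,
zero-variance correlations — have defined, tested behavior rather than
exceptions wherever a sensible value exists.
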