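# Methods

## Model

`riddle` treats a weighted, undirected functional gene network as the
substrate on which gene-set association is measured. Nodes are opaque gene
identifiers; an edge weight is a positive, dimensionless evidence strength.
The association between a query set *q* and a pathway set *p* is scored by
three families of statistics computed on the network universe (the number
of "known genes" *N* is always the number of network genes, and set sizes
are counted after restriction to the network):

1. **Overlap.** The hypergeometric upper tail
   `P(x ≥ k) = Σ_{x=k}^{min(n,m)} C(m,x)·C(N−m,n−x)/C(N,n)`
   for an observed overlap of *k* genes between sets of in-network sizes
   *n* and *m*. Implemented through the survival function of
   `scipy.stats.hypergeom`, which works in log space, so tails far below
   double-precision underflow of the naive sum remain accurate.

2. **Local extension.** Candidate genes outside a set are scored by the
   sum of their edge weights into the set. The top `LEn = min(⌊αn⌋, β)`
   candidates are added (α = 0.8, β = 100 by default — the values at which
   the procedure performs best on split-set benchmarks; the floor is
   clamped to 1 so a tiny set can always extend by one gene). When the
   score at the cutoff boundary is tied with excluded candidates, all tied
   genes are admitted and the result is flagged as breached, so membership
   never depends on an arbitrary tie order; within a tie block the reported
   order is lexicographic, which affects reporting only. The overlap test
   is then rerun on the extended set. Only one side is extended per call;
   the combiner layer calls it in both directions.

3. **Reflective diffusion.** A random walk with restart: with the
   symmetric degree-normalized weight matrix `Ŵ = D^{−1/2} W D^{−1/2}` and
   uniform unit seed mass `Y` (1/|seed| per in-network seed gene, so
   profiles are comparable across seed sizes), the propagation
   `F ← (1−r)·Ŵ·F + r·Y` is iterated to its fixed point. For restart
   `r > 0` the update is a contraction, so the fixed point is unique and
   equals the solution of `(I − (1−r)Ŵ)F = rY`; a direct sparse solve is
   provided as an independent solver for cross-checking. Defaults:
   `r = 0.5`, tolerance `1e−9` (max-norm on successive iterates),
   `max_iter = 1000`; row normalization is available as an option.
   Genes in components disjoint from the seed score exactly 0.

   Recovery of the terminal set from the ranked scores is summarized by
   ROC AUC — computed as the Mann–Whitney statistic with midrank tie
   handling, so it equals the trapezoidal ROC area and the
   pair-ordering fraction — and by average precision
   `AP = (1/k)·Σᵢ i/rankᵢ` over the *k* terminal genes sorted by rank.
   Seed genes that are not terminal candidates are removed from the
   ranking; genes shared between seed and terminal stay in and take the
   top ranks they earn. This convention makes overlapping-subset tests
   behave sensibly (a shared gene is genuine evidence, not a candidate to
   be discarded) and is pinned by tests. A size-normalized AP (AP/k) is
   exposed as a diagnostic property but is not a combiner feature.

## Why a trained combiner

AUC and AP are proximity summaries, not calibrated probabilities, and each
carries a systematic bias: under random seed sets, AUC rises with the mean
centrality (weighted degree) of the terminal set, while AP rises strongly
with terminal-set size (in the limit where the terminal set is the whole
universe, AP = 1 regardless of the ranking). Both confounds are reproduced
on the synthetic world by the test suite and the acceptance script as
rank-correlation sign checks. Rather than correcting each statistic, the
package feeds the raw statistics *and* the confounding covariates to a
radial-basis-kernel SVM: 13 features per pair — natural-log p-values of
the hypergeometric and the forward/reverse extension tests (p floored at
1e−300 to avoid −∞), forward/reverse AUC and AP, in-network query,
pathway and overlap sizes, query and pathway mean centrality, and the
fraction of query genes covered by the network.

Training pools labelled pairs, splits each class into modeling (25%),
cross-validation (25%) and final-validation (50%) subsets, z-scores the
features on the modeling split (the scaling is stored in the model so
scoring is exactly reproducible), and fits `sklearn.svm.SVC` with
`w1 = 1`, `w0 = 0.3` (negatives are down-weighted because they outnumber
positives by an order of magnitude), `C = 1e9`, termination `e = 0.01`,
`γ = 0.07`. The association score (RAS) is the signed decision value, not
a probability estimate — ranks and the empirical FDR are the calibrated
quantities, and the decision value preserves resolution in the far tails
where Platt scaling saturates.

The empirical FDR at a score *s* is `N̄(s) / (N̄(s) + P̄(s))`, with
`P̄, N̄` the fractions of final-validation positive and negative scores at
or above *s* — each distribution normalized to unit area, i.e. class
priors are deliberately ignored. Finite samples make the raw ratio locally
non-monotone, so a decreasing isotonic regression over the observed score
grid is applied; queries between grid points take the value at the
smallest observed score above them, scores above all observations take 0.

Library ranking sorts by descending RAS with ties broken by pathway id,
assigns ranks 1..P and reciprocal ranks, and attaches the FDR from the
model's stored validation distributions. Diffusion profiles are cached per
seed set, so ranking P pathways costs P + 1 diffusions, not 2P.

## Synthetic world

The generator plants a partition: `n_modules` modules of `module_size`
genes each, wired internally with probability `p_in` and to everything
else with `p_out`, plus `n_background` genes attached at `p_out`; weights
are log-normal (μ = 0, σ = 0.5, median 1). Defaults — 30 modules × 25
genes, 500 background genes, `p_in = 0.25`, `p_out = 0.01` — keep the full
train-and-benchmark cycle in the tens of seconds on one CPU while leaving
modules recoverable but not trivially separable (a module gene's expected
within-module degree is ~6 edges against ~12 background edges). All
generators are pure functions of (parameters, seed).

Three subset regimes emulate the benchmark designs: (a) *overlap* — two
independent draws of ⌈n/2⌉ distinct genes from a module, overlap between
the draws allowed (expected overlap n/4); (b) *disjoint* — a random
partition into halves differing by at most one gene; (c) *timesplit* — an
asymmetric 70/30 disjoint split standing in for annotation-time splits,
with the small side as the query (the hardest case, kept as a distinct
tag). A centrality-matched randomizer bins network genes into 10
equal-width centrality bins (equal-width, not quantile, so bin membership
tracks absolute centrality) and replaces each template member with a
uniform draw from its bin, deduplicating by redraw and falling back to the
nearest non-empty bin.

The training corpus follows the recipe: positives are the matched overlap
and disjoint pairs of every module; negatives are ten mismatched known
subsets per query plus random gene sets of varying size (5–50) paired
with a real module set. The benchmark scores every query against the
pooled known subsets by RAS and by the component baselines
(hypergeometric p, reverse-direction extension p, reverse AUC, reverse
AP). Candidate ranks use midranks and a query counts as matched only when
its own module's subset is the *unique* top candidate — this is what
forces the hypergeometric baseline to exactly zero matches in the disjoint
regime, where every candidate ties at p = 1.

## What the synthetic world does and does not show

The planted-partition world has homogeneous module sizes, no overlap or
hierarchy between modules, no hub genes beyond what the degree
distribution of a Bernoulli graph produces, and no study bias (real
networks concentrate edges on well-studied genes). Passing benchmarks on
it therefore demonstrates that the pipeline's mechanics are correct — that
diffusion and extension recover planted structure, that the combiner
learns to exploit them, and that the overlap test fails exactly where it
must — not that the trained model transfers to a real functional network;
on real data the combiner should be retrained on subset pairs drawn from
real annotation databases. The confound reproductions are sign-level
checks by design: the magnitude of the AUC–centrality slope depends on the
degree distribution, which the synthetic world does not attempt to match.

## Numerical choices and edge cases

- Duplicate edges keep the maximum weight (order-independent); self-loops
  are dropped and counted in the log. Non-positive-weight lines in an edge
  list are rejected with a log message rather than aborting the parse.
- Isolated genes score 0 in diffusion and rank last by midrank; a seed
  with no in-network gene is an error, non-convergence returns the profile
  with a warning flag rather than failing.
- The absolute diffusion score of a gene is *not* monotone in the weight
  of an edge leading to it: under degree normalization the weight also
  inflates the gene's normalizing degree. The invariant that holds, and
  that the property test pins, is relative — strengthening the only path
  edge raises the gene's score relative to the intermediate node.
- AUC is undefined (error) when the terminal set covers all or none of
  the ranking; AP is an error only when no terminal gene is present.
- `⌊αn⌋` uses floor with a clamp at 1; zero-gene extension reproduces the
  plain hypergeometric p exactly.
- Feature standardization guards zero-variance features by leaving them
  unscaled. Model files are versioned; loading a mismatched version is
  refused.

## Problem sizes

Default test and acceptance runs use the 1,250-gene default world (30
modules), a 120-trial confound survey, a ~690-pair training corpus, and
30-module benchmarks per regime — sizes chosen so the whole cycle
completes in well under a minute while every qualitative effect the
package claims is statistically unambiguous at those sizes.
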