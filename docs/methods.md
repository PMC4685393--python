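# Methods

This note documents the statistical model behind each stage, the
parameters that matter, the synthetic benchmark the tests run on, and
the numerical and design choices made where the published procedure left
the design open.

## Gene-level association test

For a gene with SNP P-values `p_1..p_m` (SNPs mapped when they fall in
the gene body extended by a flank, default 20,000 bp, 1-based closed
intervals; BED input is converted on read; only autosomes are analysed),
the statistic is

    T = Σ_j Q(p_j),   Q = upper-tail quantile of χ² with 1 df.

Under the null with independent SNPs, `T ~ χ²(m)`; LD makes the SNP
tests dependent, so the null is simulated: draw `z ~ MVN(0, Σ)` with `Σ`
the SNP-by-SNP Pearson correlation of reference dosages, and use
`Σ_j z_j²` as a null draw.  The empirical P-value is
`(#{draws ≥ T} + 1)/(n + 1)`, which can never be zero and has floor
`1/(n+1)`.

Numerical choices:

* SNP P-values are clamped at `1e-16` before the quantile transform so a
  printed zero cannot produce an infinite statistic.
* Monomorphic SNPs are dropped (their correlation is undefined); an
  all-missing SNP is an error naming the SNP.
* Sample correlation matrices from finite panels are often indefinite:
  eigenvalues are clipped at `1e-10` and the matrix rescaled to unit
  diagonal before Cholesky factorisation.
* The number of draws escalates `10³ → 10⁴` when the estimate falls
  below 0.1 and `→ 10⁶` below 0.005; the cap is configurable because
  very small gene P-values (e.g. 10⁻⁷) need up to 10⁷ draws to resolve.
* Per-gene RNG streams are derived from the master seed and the gene id
  (CRC-32 into a `SeedSequence` spawn key), so results do not depend on
  evaluation order.

The test's calibration is verified on simulated AR(1) LD blocks
(rejection rate at 0.05, uniformity), its independence limit against the
closed-form χ²(m) survival function, and its single-SNP limit against
the SNP P-value itself.

## Node-weighted interactome

Interactions are canonicalized to unordered pairs, duplicate pairs
merged by publication-set union (support counts unique publication
identifiers, not file rows, because unions of source databases duplicate
rows), self-loops dropped, and edges kept when supported by at least 2
publications.  Isolated nodes are then dropped; an empty result is a
hard error.  Nodes with a gene P-value `p` receive the weight
`z = Φ⁻¹(1 − p)`.

MHC handling: genes whose unextended body overlaps the classical MHC
interval (chr6:28,477,797–33,448,354 on GRCh37 by default, configurable)
and whose `p < 0.05` are flagged sigMHC.  They keep no `z`, are never
search seeds and cannot be absorbed during growth — the MHC's gene
density and long-range LD would otherwise pull every module into it —
but they remain in the graph and re-enter the final candidate set at the
merge step.  Nodes with no gene P-value at all are removed.

## Dense module search

Module score for `k` genes: `Z_m = Σ z_i / √k`.  Growth from a seed
admits, at each step, the candidate within distance `d` of the module
that maximises the new score, accepted only if
`Z_{m+1} > Z_m · (1 + r)`; defaults `r = 0.1`, `d = 1`.  Ties break to
the lexicographically smallest gene id, so the search is deterministic.
With `d = 2` a two-hop candidate is absorbed together with its
highest-`z` bridging neighbor (scored as a two-node addition); absorbing
it alone would disconnect the module, and modules are connected by
contract.  One growth per eligible seed; modules with identical gene
sets collapse to the first seed in sorted order.

The greedy result is a connected subgraph containing the seed, hence
bounded by the exhaustive maximum over such subgraphs; the test suite
enforces this bound against a brute-force oracle on small graphs and
exact equality on designed fixtures where the optimum is reachable
greedily.

## Two-stage module evaluation

**Stage 1 (empirical score null).**  Module scores are median-centered
and a normal `N(mu, sigma)` is fitted to the central bulk: empirical
quantiles over the central band (default 25th–75th percentile) are
regressed on standard normal quantiles; the intercept estimates `mu`,
the slope `sigma`.  This quantile (central) matching ignores a minority
of genuinely enriched modules in the right tail; a truncated-normal MLE
on the same band is available as a fallback.  Each module's
`p_norm = 1 − Φ((score − median − mu)/sigma)` must be < 0.05.

**Stage 2 (degree-matched topology null).**  All network nodes are
split into four groups at the quartiles of the degree distribution
(ties to the lower group).  For a module of size `k`, each of 10,000
resamples replaces every module gene with a random distinct weighted
gene from its degree group (without replacement within a resample — a
random module cannot contain duplicates) and scores the set;
`p_topo = (#{random ≥ observed} + 1)/(n_perm + 1)` must be < 0.05.
Random sets are not required to be connected, matching the "pick one
gene from the corresponding group" construction.  Unweighted sigMHC
nodes are excluded from the sampling pools because they carry no `z`.

Modules passing both tests are merged: the union of their genes with
induced edges, plus an extended subnetwork that re-admits the sigMHC
genes (possibly as singletons).

**What the two stages do and do not control.**  Stage 2 is calibrated
against its own null (verified: uniform `p_topo` for degree-matched
random modules) and controls the bias of the search toward
well-connected hubs.  It does not control optimization bias: a module
produced by greedy score maximisation will beat almost any random
degree-matched set, so stage 2 rarely removes a stage-1 survivor when
node weights are independent of degree.  Stage 1 is a relative test
within one run's score distribution.  On small dense networks (a few
hundred nodes, scale-free) almost every seed's module converges onto the
same globally best genes; the score distribution is then left-skewed
with its bulk near the maximum, median-centering absorbs a genuinely
planted signal into the bulk, and a short null right tail can still
leak past the 0.05 normal cut.  Consequently, end-to-end power and
family-wise type-I behaviour at the 500-node benchmark scale are
erratic in both directions — the acceptance suite measures this
honestly rather than masking it — whereas on networks of several
thousand nodes modules stay local and the cascade behaves as published.
This is a property of the published two-stage design, not of a
particular implementation, and is the package's main known limitation.

## Connectivity test

The observed statistic is the number of network edges with both ends in
the candidate gene set.  The null permutes node labels only within
exact-degree classes — topology, degree sequence and per-label degree
are all preserved — so null connectivity is entirely a function of the
members' degrees.  Since only the members' images matter, each
permutation draws, per degree class, as many distinct nodes as the class
contributes members and counts induced edges; this is the exact marginal
of a full label permutation.  Empirical P with the `(+1)/(+1)`
correction, floor `1/(n_perm+1)` (9.999 × 10⁻⁵ at 10,000 permutations).
A caveat verified in testing: the count statistic is a small integer, so
the permutation P is mildly conservative where ties straddle the
rejection cutoff; calibration checks are therefore run in a regime
(dense graph, 20-gene sets) where the count spreads over many values.

## Enrichment

One-sided over-representation P per term is the hypergeometric upper
tail of the overlap (identical to the one-sided Fisher exact test),
Benjamini–Hochberg adjusted, reported below adjusted P 0.25.  The
default background is the set of weighted genes in the analysis network
— the universe actually tested — and is configurable.  An EASE-style
variant (overlap deflated by one) is available but off by default.

## Synthetic benchmark

The generator's defaults define the benchmark study: a 500-node
preferential-attachment network with 3 edges per new node (average
degree ≈ 6, matching the ~7 of a publication-filtered human
interactome), per-edge publication counts uniform on 2–8 with 15% of
edges set to a single publication to exercise the filter, a planted
connected 8-gene module with P-values uniform on (0, 10⁻³), 20 mock-MHC
genes disjoint from the planted module, and uniform background
P-values.  SNP blocks have AR(1) dosage correlation `rho^|i−j|`
(Gaussian fractional dosages) and a continuous phenotype loading on the
first SNP; fixture files carry one SNP per gene at the gene midpoint.
Erdős–Rényi topology is available for calibration tests that need
degree-homogeneous graphs.

What the generator does not emulate: realistic human LD maps and
recombination structure, allele-frequency spectra, genome-wide SNP
density, case/control sampling, or any correlation between gene
significance and network degree.  Passing tests therefore demonstrate
algorithmic and statistical correctness of each stage and of the chain
on data satisfying the stated assumptions — not performance on a real
GWAS, where study-bias correlations between degree and significance
make stage 2 materially more stringent.

All problem sizes in the test and acceptance suites (500–2,000 genes,
10³–10⁴ permutations, 20–40 replicate runs) were chosen as the smallest
scales at which the binomial/KS tolerances asserted are meaningful.

## Reproducibility

Every random draw descends from one integer master seed through named
`SeedSequence` sub-streams (per stage, per gene, per module), so adding
permutations to one stage never shifts another stage's draws, parallel
and serial evaluation orders agree, and fixed seeds give byte-identical
outputs.  Each pipeline run writes its resolved configuration next to
its outputs.
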