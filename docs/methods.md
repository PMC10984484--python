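# Methods

This note documents the statistical machinery of `covnet`: the models and
procedures, their assumptions, the tunable parameters, the numerical
choices, and what the synthetic-cohort results do and do not establish
about real imaging data.

## Covariance network estimation

A group's network is the Pearson correlation of regional SUVR across the
animals of that group. Inputs are assumed complete (no missing regions),
strictly positive, and already reduced to 27 bilaterally averaged regions;
hemisphere averaging and atlas extraction are upstream of this package.
Groups need n ≥ 3 animals (Pearson r is degenerate below that), and in
practice the per-group n of 9–12 animals means every edge estimate carries
a standard error of roughly 1/√(n−3) ≈ 0.3–0.4 — the dominant noise source
in everything downstream. Z-scoring regions (sample SD, n−1 denominator)
is applied for interpretability; Pearson correlation is affine-invariant,
so the network is identical with or without it (tested to 1e-12). The
diagonal is fixed at 0 rather than 1: self-correlations carry no
information and would distort strength sums.

### Edge significance: the random-shift null

Each of the `n_null_permutations` (default 10,000) null iterates permutes
every region's column independently across animals and recomputes the full
27 × 27 correlation matrix. This destroys inter-regional covariance while
preserving every regional marginal. Positive and negative empirical
correlations are handled separately: an edge with r > 0 is referred to the
positive half of its null distribution, an edge with r < 0 to the negative
half, with an add-one estimator:

    p = (1 + #{same-sign nulls with |r_null| ≥ |r_emp|}) / (1 + #{same-sign nulls})

Conditioning the denominator on the same-sign null count is what makes the
estimator calibrated: each sign tail is a conditional one-sided test, so
the overall type-I error at nominal 0.05 is 0.05 (measured 0.046–0.053 on
null cohorts), an edge with r = 0 gets p = 1, and p can never reach 0. An
unconditional same-sign count over all n_perm + 1 iterates would double
the false-positive rate (each tail firing at 5%). The smallest attainable
p is ≈ 2/n_perm, so 10,000 permutations resolve p-values comfortably below
the 0.01 threshold tier.

Thresholding keeps the signed weight of edges with p < level and zeroes
the rest; levels below 0.01 are not offered (they fragment these small
networks). Each thresholded network carries a `fragmented` flag from a
connected-components check. Level sets are nested by construction
(p < 0.01 ⊆ p < 0.05).

## Signed network measures

Degree counts nonzero edges; positive/negative strengths are separate sums
with the negative strength reported as a magnitude (matching how "negative
strength" is conventionally plotted as a positive quantity). The signed
clustering coefficient normalizes weights by the network-wide max |w| and
computes, per node, total signed triangle weight over total open-triple
weight:

    C_i = Σ_{j≠i} Σ_{k≠i,j} ŵ_ij ŵ_jk ŵ_ki / Σ_{j≠i} Σ_{k≠i,j} |ŵ_ij ŵ_ki|

so triangles whose edge-sign product is negative count against clustering;
C_i ∈ [−1, 1] and is 0 for nodes without open triples. The implementation
is pinned by an independently coded brute-force triple enumeration (1e-12
agreement on random signed networks) rather than by a runtime dependency
on the reference MATLAB toolbox. Hubs are the top ⌈27 × 0.25⌉ = 7 regions
by degree or cumulative absolute strength; ties break by region index
order so hub sets are deterministic. Path-based measures (efficiency,
betweenness) are deliberately absent — their meaning on covariance
networks is unclear.

## Community detection

### Signed modularity and Louvain

Modularity maximization runs on *unthresholded* networks (they retain the
most information). The quality function is the asymmetric signed variant:
positive within-community weight is rewarded under a configuration-model
expectation normalized by v⁺, negative weight penalized with the softer
1/(v⁺+v⁻) normalization — the standard recommendation for
correlation-derived networks, where negative edges should discourage but
not dominate. The optimizer is a generalized Louvain on the combined
modularity matrix B (γ baked in): greedy node moves (with a spare empty
community so nodes can always split off) alternate with community-level
moves on the aggregated matrix until neither improves Q, inside
`n_restarts` (default 10) shuffled-order restarts, each polished by 6
rounds of iterated local search (perturb 30% of nodes, re-optimize, keep
if better). On random signed networks of ≤ 8 nodes this matches exhaustive
search over all set partitions in 250/250 instances; without the ILS
rounds it missed ~2%. Ties between equal-Q partitions go to the
first-found; diagonal B terms are included (they are
partition-independent, so the argmax is unaffected).

### Multiresolution consensus clustering

MRCC summarizes community structure across resolution scales:

1. **γ range.** A positive pair (i, j) stays attractive while
   γ < w⁺_ij v⁺ / (s⁺_i s⁺_j). The informative range runs from γ = 1e-3 to
   the 0.95 quantile of these per-pair limits; beyond it essentially no
   pair is attractive and finer γ adds no informative partitions. (With
   the asymmetric signed quality function a literal all-singletons
   partition need not exist at any finite γ, so the classical
   "first all-singletons γ" endpoint is not well defined; the quantile cap
   replaces it.)
2. **Ensemble.** `n_mrcc_partitions` (default 10,000) single-pass Louvain
   partitions at γ values drawn uniformly over the range (a deterministic
   grid is available). Uniform-in-γ sampling weights each scale by its
   γ-measure; concentrating samples where partitions *change* (event
   refinement) was evaluated and rejected — partition events crowd the
   fine-scale end, which dilutes coarse-scale evidence in the
   co-assignment matrix and destroys recovery of planted coarse structure.
3. **Co-assignment and null.** C_ij = fraction of ensemble partitions with
   c_i = c_j. Under the permutation model, the null co-assignment of any
   pair is the mean over the ensemble of Bernoulli(p0_m) draws, with
   p0_m = Σ_k n_k(n_k−1)/(n(n−1)) from partition m's community sizes; the
   (1−α) quantile of that null (α = 0.05 default, 1000 Monte-Carlo draws)
   is the significance threshold.
4. **Consensus and hierarchy.** The consensus partition is one global
   consensus-clustering pass: Louvain on C − threshold. Within each
   consensus community the procedure recurses with a local null
   (ensemble labels restricted to the subset) to expose finer, locally
   persistent scales; those splits form the coarse-to-fine hierarchy but
   do not redefine the consensus. This separation is deliberate: at n ≈ 12
   animals, sampling noise in the correlations creates sub-block structure
   that is *consistent across γ* and therefore statistically significant
   at fine scales, so a consensus defined as the leaves of the recursion
   shatters genuine modules; the globally supported scale is the right
   summary, and matches the coarse (few-community) consensus partitions
   such networks are reported to have.

Partition similarity uses AMI with the permutation-model chance correction
and arithmetic-mean normalizer (1 iff identical up to relabeling);
co-classification matrices report per-pair agreement across any set of
partitions.

## Between-group statistics

Edge-weight distributions (351 values per network) and nodal-metric
distributions (per threshold level, tested separately) are compared with
the asymptotic two-sample KS test. Edgewise differences use the only
statistic available for a group-level construct — Δr per edge — with a
group-label permutation null: pooled animals are randomly reassigned to
two pseudo-groups of the original sizes and both networks recomputed each
of the `n_comparison_permutations` (default 10,000) iterates; p-values are
two-sided with the add-one correction and invariant to swapping the two
groups (the pooling order is canonicalized). FDR control is
Benjamini–Hochberg at q = 0.05 over the 351 edges; BH assumes
positive-regression dependence, which correlated edges only approximately
satisfy — acknowledged, not modeled.

## Module-mean SUVR ANOVA

Module means are extracted for every animal of every group against a
*single* reference partition (by default the 4-month male wild-type
group's consensus), so the same regions are averaged everywhere. The
model is a three-factor ANOVA (age, sex, genotype) with all three two-way
interactions and no three-way term, fitted by OLS with Type II sums of
squares — order-invariant for main effects and equal to the classical
marginal SS when the design is balanced; Type III is available via
`ss_type=3` for the mildly unbalanced published group sizes. Tukey–Kramer
post hoc comparisons use the studentized range with the unequal-n standard
error and the full-model residual mean square and degrees of freedom as
the error term (not a one-way re-fit), which makes the adjusted p-values
conservative relative to same-error-term pairwise t-tests.

## Synthetic cohorts

The generator draws each animal's 27 SUVR values from a multivariate
normal with an equicorrelated-block correlation matrix: `rho_within` for
same-module pairs, `rho_between` otherwise, induced by a shared global
factor plus per-module factors plus independent noise — which guarantees
positive semidefiniteness for 0 ≤ rho_between ≤ rho_within < 1 and gives
every downstream stage an analytic truth (`implied_correlation`). Values
are clipped below at 0.01 to keep SUVR positive; at the default mean 1.0
and noise SD 0.1 the clip probability is ~1e-23, so the clip exists purely
as a guard and never distorts the distribution in practice.

Default study conditions mirror the published design: 12 groups
(2 genotypes × 2 sexes × 3 ages) with n = 12, 11, 9 / 12, 11, 10 /
11, 10, 9 / 12, 12, 10; baseline SUVR 1.0; noise SD 0.1. Wild-type cells
carry a coarse 3-module planted structure, 5XFAD cells a finer 5-module
structure (emulating the less coherent covariance organisation of the
disease groups); rho_within = 0.6, rho_between = 0.2 produce edge-weight
distributions with the broad positive bulk real covariance matrices show.
Module 1 carries an age effect (+0.05 at 4 and 12 months relative to
6 months, i.e. half a noise SD) plus a +0.03 extra shift in 12-month
females, planting the age main effect and age × sex interaction the
module-level ANOVA is designed to detect. Effect sizes are free parameters
of the simulation, not claims about 5XFAD biology.

What the generator does **not** emulate: partial-volume effects, scanner
noise structure, registration error, non-Gaussian SUVR tails, hub
topology beyond block structure, or any hierarchical community structure.
Passing tests therefore establish that the *pipeline* is correct and
calibrated under its own model assumptions — not that the biological
findings would replicate; analyses of the real deposited cohort are out of
scope here.

## Verification scale and numerical choices

Simulation studies in the test suite and acceptance script use sizes
chosen to pin each property with comfortable Monte-Carlo margins while
keeping a full run in tens of seconds: permutation-test calibration at
2,000 permutations × 20 replicate tables (±0.005 on a 0.05 rate);
planted-structure recovery over 20 simulated groups with 500-partition
ensembles (recovery is data-limited, not ensemble-limited — 500 and
10,000 partitions give the same consensus on 27-node networks); optimizer
oracles over 50–250 random instances; power studies over 50–200
replicates. At n = 12 animals per group, roughly one simulated group in
ten contains a region whose sample correlations genuinely favor the wrong
module (or two modules whose factors correlate by chance), which bounds
any estimator's planted-recovery rate near 0.9 — an intrinsic property of
inter-subject correlation at this sample size, worth remembering when
interpreting real 27-region, 10-animal networks.

Other numerical conventions: move gains below 1e-12 are treated as ties
(no move); permutation matrices are generated by argsort of uniform draws
for vectorization; all stochastic stages consume a single seeded
`numpy` generator hierarchy (`SeedSequence.spawn`), making every pipeline
run bit-identical for a fixed seed; matrices are written with 17
significant digits so text round trips are exact to < 1e-12.
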