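# Methods

This note documents the models, numerical choices, and design decisions
behind `fconn`, and what the synthetic validation does and does not show.

## Network construction

Edge weights are zero-lag Pearson correlations between voxel-averaged ROI
time series. Negative correlations are clamped to zero at load time and
counted, never silently dropped: the pipeline's metrics (geometric-mean
clustering, `1/w` path lengths, modularity on nonnegative weights) are
defined for nonnegative weights, and in dense task-fMRI correlation
matrices the negative tail is a small minority of pairs. No global-signal
regression is applied anywhere.

Proportional thresholding keeps the `floor(d · N(N−1)/2)` highest-weight
edges for a target density `d`. Ties at the cut weight are broken by
lexicographic node-pair order so results are bit-reproducible; kept weights
are never altered, so thresholded graphs are exactly nested across an
increasing density schedule.

**Nodal elimination** is computed once on a reference condition and applied
identically everywhere, so that between-condition comparisons always use
the same node set: the across-subject *mean* reference matrix (an aggregate
decision — a single removal set shared by all subjects implies the decision
cannot be per-subject) is thresholded to 50% density, and nodes with fewer
than `0.05 · (N−1)` surviving links are dropped. Both the 50% target and
the 5% floor are parameters, not constants. A surrogate control
(`random_network_control`) repeats the elimination on random networks with
the same number of nonzero entries and compares the degree-distribution
coefficient of variation of full vs downsized graphs; the elimination is
considered shape-preserving when that statistic changes by less than 20%.

**Group averaging** uses a quorum rule: an edge enters the group network
when at least a fraction `min_presence` of subjects shows it, with weight
equal to the across-subject mean. The function default is the full
intersection (`min_presence = 1`), the strictest consensus. The pipeline
default is 0.7 (10 of 14 subjects): on the synthetic cohort, whose
between-subject edge agreement is governed purely by sampling noise, the
full intersection collapses group densities to ~0.30, whereas the 0.7
quorum maps per-subject densities of 77–86% onto group densities of
roughly 0.64–0.90 — the regime in which group networks are meant to be
analyzed. Real cohorts, with anatomically stable connectivity, reach
comparable group densities under stricter quorums; `min_presence` is the
single knob that absorbs this difference.

## Graph metrics

- Degree `k_i` counts positive-weight incident edges; strength `s_i` sums
  them. Both are min–max normalized to [0, 1] per network; a constant
  vector maps to all ones with a warning (the degenerate case).
- Local clustering uses the Onnela geometric-mean form on weights scaled by
  the network maximum, so `c_i ∈ [0, 1]`, with `c_i = 0` for nodes with
  fewer than two neighbours. Global `C` is the unweighted mean over nodes.
- Global efficiency uses edge lengths `1/w` and Dijkstra shortest paths;
  disconnected pairs contribute zero. For correlation networks path-based
  metrics conflate direct and indirect coupling, so every metric report
  carries a standing caveat note.
- Null ensembles preserve the degree sequence exactly (Maslov–Sneppen pair
  rewiring, ≥ 10 accepted swaps per edge, attempt cap 10× that) and the
  weight multiset exactly. Weights are reassigned by residual-strength rank
  matching in 10 batches: remaining edges are scored by the product of
  their endpoints' residual target strengths and matched rank-for-rank
  against the sorted remaining weights. This keeps per-node strengths
  within ~5% mean relative error on hub-bearing graphs while costing
  `O(E log E)` instead of the `O(E²)` of fully sequential assignment.
  Complete graphs admit no rewiring; the ensemble then degrades to
  weight-shuffled nulls with a warning.
- Normalized metrics divide the observed value by the null-ensemble mean;
  `σ = C_norm · E_norm`. A graph normalized against itself has `σ = 1`
  exactly. By default the null ensemble is spent at the minimum density of
  a schedule — the density at which all comparative analysis runs — and the
  remaining densities carry raw values: on ~90%-dense graphs edge swaps are
  almost always rejected, so rewiring mixes poorly there while costing the
  bulk of the runtime, and the normalized values add little beyond the
  minimum-density ones. `normalize="all"` restores per-density ensembles.

## Community detection

Modularity is the weighted Newman form `Q = Σ_m [W_m/W − (S_m/2W)²]`.
Refinement sweeps nodes in seeded random order (reshuffled every sweep);
each node moves to the neighbouring module — or opens a fresh singleton
module, which is necessary to escape merges that the all-singleton start
would otherwise lock in — with the largest positive gain, computed
incrementally as

    ΔQ(i: a → b) = [w_i(b) − w_i(a\i)]/W − s_i (S_b − S_a + s_i) / (2W²).

The sweep loop terminates when a full pass makes no move, so `Q` never
decreases. Moves need a gain above 1e−12 to guard against floating-point
oscillation.

The stochastic refinement is chained: `M⁰` (singletons) seeds run 1, whose
output seeds run 2, and so on for 100 runs, each canonicalized so node #1
is in module 1 and module ids appear in order of first appearance. The
consensus affiliation is the node-wise modal module id across the chain,
ties resolved toward the earliest iteration. A co-classification-matrix
consensus (refine the mean co-assignment matrix) is available as an
alternative mode; on strongly modular graphs the two agree.

Partition similarity is NMI with arithmetic-mean normalization,
`2I/(H₁+H₂)`, natural logarithms (the base cancels). Conventions: two
identical partitions give exactly 1 (including two single-module ones);
if exactly one partition has zero entropy the similarity is 0. Note the
field often calls this quantity a partition *distance* even though larger
values mean more similar partitions.

## Hubs and roles

Hub rule: value ≥ mean + 1 sample SD (N−1 denominator), applied to degree
or strength; invariant under positive affine transforms. Banding uses
min–max-normalized values with lower-inclusive edges at 0.9 / 0.7 / 0.4;
the ≥ 0.7 band is what "top 30%" refers to. The participation coefficient
is strength-weighted by default (`κ_im` sums edge weights into module m);
an edge-count mode is provided for sensitivity checks, since verbal
definitions of "share of inter- vs intramodular edges" admit both readings.
Connector hubs have `pc_i ≥ 0.9 (1 − 1/m)`; provincial hubs are hubs below
that; non-hubs are unclassified.

## Permutation statistics

The paired test computes per-node paired t statistics on condition
differences and builds the null by flipping the sign of each subject's
entire difference vector jointly — joint flips preserve the spatial
correlation structure that the max-statistic correction relies on.
Corrected `p_i = (1 + #{perm: max_j |t_j| ≥ |t_i|}) / (n_perm + 1)`
(add-one, so p is never 0), two-sided. When `2^n_subjects ≤ n_perm` the
full sign-pattern set is enumerated instead and p values are exact
(including the identity pattern, so again p > 0). Zero-variance nodes get
t = 0 with a warning. An unpaired variant over per-node time-series
summaries (mean and SD, Welch t, label permutation) serves as a
between-group consistency check.

Monte-Carlo calibration (500 null replicates of 14 subjects × 150 nodes at
1000 permutations) puts the empirical family-wise error at nominal 0.05
inside [0.03, 0.07].

## Synthetic cohort

Each node's signal is a linear combination of module latent signals plus
independent noise, all unit variance: node i in module m loads
`√ρ_w` on its module's latent; module latents share a common component so
between-module correlations equal `ρ_b`; hub nodes additionally load on
every other module (cross-loading, default 0.3), with their loading row
rescaled so their baseline signal variance matches an ordinary node's —
hubs gain breadth, not raw variance. Task conditions multiply hub loading
rows by a gain ≥ 1, raising all hub-incident edge weights. Weak nodes have
their loadings attenuated. Latents follow an AR(1) process (coefficient
0.3) for fMRI-like smoothness; this leaves zero-lag cross-correlations
unchanged, so the population correlation matrix is available in closed
form (`L K Lᵀ` off-diagonal) and is nonnegative by construction. Sample
correlation matrices converge to it (mean absolute deviation ≤ 0.02 at
T = 5000 is checked in the tests).

The default study cohort (`study_cohort_spec`) has 212 ROIs, 14 subjects,
150 time points, 5 planted modules, two hubs per module, three conditions
(rest, gain 1; syllable, gain 1.15; speech, gain 1.25), and 62 weakly
coupled regions (attenuation 0.02). `ρ_w = 0.6`; `ρ_b = 0.18`, chosen so
that (a) the retained core's raw densities land near the ~90% typical of
task-fMRI correlation matrices, (b) every subject's reduced network
supports the 77–86% density schedule, and (c) the elimination stage
discards exactly the 62 weak regions. On this cohort the full pipeline
reproduces the expected qualitative pattern: 212 → 150 nodes, 5 recovered
modules in every condition, the 10 planted hubs in the top strength band
and classified as connectors, and the T_max contrast flagging exactly the
hub regions for speech vs rest.

**What the synthetic validation does not show.** The generator has
homogeneous within-block correlations, a single planted partition shared
by all conditions, iid sampling noise across subjects, no hemodynamic
forward model, no physiological confounds and no spatial autocorrelation.
Consequently: between-condition partition NMI is 1 by construction (real
conditions reorganize modules); inter-subject edge agreement is lower than
in real cohorts (absorbed by `min_presence`); and the rest network's
small-world index on this cohort sits just below 1 (its modularity costs
more efficiency against matched nulls than its homogeneous clustering
earns), whereas the gained task conditions sit at or above 1. Passing the
recovery benchmarks demonstrates that the pipeline's inference machinery
is correct and calibrated, not that any particular empirical brain result
holds.

## Problem sizes

Default desk-scale settings: 100-graph null ensembles at the minimum
density, 100 consensus iterations, 10,000 permutations, ≤ 212 nodes and
≤ 14 subjects. The full analysis (all numbered drivers, or the acceptance
script) completes in well under a minute on one CPU; the test suite,
including the brute-force oracle comparisons and the 500-replicate FWE
calibration, runs in seconds.
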