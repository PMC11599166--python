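# Methods

## The model

A structural covariance network treats each parcellated brain region as a
node and the between-subject Pearson correlation of a morphometric measure
(here regional gray-matter volume, mm³) as the edge weight. The method
rests on two assumptions: that covariance of regional anatomy across a
cohort reflects shared developmental, maturational or disease processes,
and that a single group-level network is a meaningful summary — individual
subjects do not have networks of their own in this framework, which is why
all inference is by permutation of group labels.

### Covariate adjustment

Regional volumes are residualized on an intercept plus age (years), sex
(coded 0/1 by sorted level name) and total intracranial volume (mm³) by
ordinary least squares, independently per region. The fit is done **once on
the pooled cohort**, not per group and not inside permutation loops:
covariates are group-agnostic nuisance terms, and refitting per relabeling
would break the exchangeability that justifies the permutation null. A
covariate column that is constant is absorbed by the intercept rather than
treated as a singularity; genuinely collinear covariates are an error.

### Thresholding

Correlation matrices are binarized two ways:

* `threshold_absolute(net, t=0.1)` — `a_ij = 1` iff `r_ij > t`. Simple, but
  two groups binarized at one cutoff generally differ in edge count, which
  confounds metric comparison.
* `threshold_density(net, D)` — keep exactly
  `E = round(D · N(N−1)/2)` edges with the largest correlations
  (round half away from zero; ties broken lexicographically on `(i, j)` so
  runs are platform-stable and edge sets nest as `D` grows). Only strictly
  positive correlations are eligible; asking for a density that positive
  entries cannot supply is an error rather than a silent shortfall.

All analyses use density thresholding on a grid, default 0.33–0.50 in
steps of 0.01 (18 points, generated by integer stepping anchored at the
lower bound to avoid float drift). 0.33 is the typical minimum density at
which 90-region gray-matter SCNs are fully connected
(`min_connected_density` verifies this per dataset); densities above 0.50
are conventionally regarded as biologically implausible.

### Graph metrics

For a binary network with adjacency `A`:

* `C_p` — mean local clustering `c_i = 2·t_i / (k_i(k_i−1))`, `c_i = 0`
  when `k_i < 2`.
* `L_p` — **harmonic-mean** characteristic path length: the number of
  ordered pairs divided by `Σ 1/d_ij`, with `1/d = 0` for disconnected
  pairs. This keeps `L_p` finite under fragmentation and makes
  `E_glob · L_p = 1` an exact identity, which the tests exploit.
* `E_glob`, `E_loc` — global efficiency and the node-average efficiency of
  each neighbor-induced subgraph (0 for degree < 2).
* transitivity — `3·triangles / connected triples = trace(A³) / Σ k(k−1)`;
  a whole-graph segregation measure distinct from `C_p` (they coincide on
  vertex-transitive graphs, not in general).
* modularity — best `Q` over 10 seeded restarts of Louvain agglomeration.
  Any Q-maximizing heuristic would do; Louvain is deterministic under a
  fixed seed, which the reproducibility contract requires.
* assortativity — Pearson correlation of end-node degrees over edges
  (NaN for degree-regular or empty graphs, propagated as "untestable"
  rather than silently zeroed).
* betweenness — shortest-path betweenness normalized by `(N−1)(N−2)/2`.

Metrics are computed by dense numpy kernels (`_fast.py`): matrix-power
triangle counts and boolean-matmul BFS level sets. At N ≤ ~100 nodes these
beat per-call graph objects by orders of magnitude, which is what makes
permutation inference (thousands of full pipeline re-evaluations)
practical on one CPU. The kernels are pinned against exhaustive
brute-force oracles and networkx in the test suite; betweenness and
Louvain modularity are delegated to networkx directly.

### Small-world normalization

`γ = C_p/C_rand`, `λ = L_p/L_rand`, `σ = γ/λ`, where `C_rand`/`L_rand` are
means over m = 20 degree-preserving null networks, generated by attempted
double-edge swaps (10·E attempts per network, swaps rejected if they would
create self-loops or duplicate edges). Each density point is normalized by
its own ensemble. A graph too rigid to swap (e.g. complete) yields m
identical copies plus a warning instead of an error, so saturated grid
points degrade gracefully to `γ = λ = σ = 1`.

### Permutation inference

For each test, subjects are randomly reassigned to two pseudo-groups of
the original sizes (default 1,000 relabelings) and the entire construction
— correlation, density thresholding, metric — is recomputed per labeling.
Relabelings are generated by shuffling the group-label *vector* over the
subjects in a canonical order, which makes inference exactly invariant to
swapping the two group names (the stream of relabelings is identical; only
the pseudo-group roles exchange, negating each null difference).

Two-tailed p-values use the add-one rule
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`, so `p ≥ 1/(1+n_perm) > 0`.
FDR control is Benjamini–Hochberg step-up at q = 0.05 within families:

* one family per global metric across the grid densities;
* one family across metrics for the AUC summaries (trapezoidal area over
  the exact grid points, no interpolation);
* one family per nodal metric across the N nodes, computed both at the
  minimum density and on per-node AUCs (both conventions are in use in the
  SCN literature, so both are reported).

Small-world curves (γ/λ/σ) are reported descriptively but excluded from
the permutation families: each permuted labeling would need its own null
ensembles, inflating cost by a factor of m for a quantity whose group
difference is already expressed through `C_p` and `L_p`.

### Hubs and robustness

Hubs: nodes whose betweenness-AUC exceeds the across-node mean by more
than 2 sample SDs (ddof = 1; N = 90 is a finite sample). Zero variance
across nodes yields an empty hub set with a warning.

Robustness: nodes are removed one at a time — targeted attack removes the
currently highest-degree node, recomputing degrees after every removal
with ties broken by lowest index; random attack averages over seeded
uniformly random orders (default 100) — and the size of the largest
connected component relative to the original N is recorded after each
step. The area under the (fraction removed, relative size) curve
summarizes each run as a scalar. Note that degree-targeting is only
guaranteed to be more damaging than random failure *on average over
heterogeneous-degree graphs*; on degree-regular graphs (rings, lattices)
the adaptive rule with index tie-break conveys no advantage and can be
strictly gentler than random removal.

## The synthetic cohort generator

`synthetic.GeneratorSpec` draws two groups of positive regional volumes
whose correlation follows an explicit factor model: a global factor gives
every region pair the between-module floor `ρ_between`, one factor per
module raises within-module pairs to `ρ_within` (plus a group-1 boost `δ`),
and planted hub nodes load evenly on *all* module factors, making them
uniformly correlated bridges at `hub_rho`. Building the target from
factors keeps it positive semi-definite by construction and exposes the
feasibility bound `hub_rho ≤ ρ_b + sqrt((1−ρ_b)(ρ_w−ρ_b)/m)` — a node
cannot be strongly correlated with many mutually weakly-correlated nodes,
so an infeasible spec is rejected with that bound in the message.

Volumes are `8000 + 800·latent + covariate terms` mm³ (means 10 SDs above
zero, so positivity holds without truncation — truncation would distort
the planted correlations). Covariates: age ~ U(30, 60) years with loading
−15 mm³/yr; sex ~ Bernoulli(0.5) with a 300 mm³ offset; TIV ~
N(1.45×10⁶, 1.2×10⁵) mm³ with loading 0.002. Group sizes default to 38
vs 50 and 90 regions in four modules (23/23/22/22).

What the generator does **not** emulate: spatially smooth atrophy,
heavy-tailed or heteroskedastic volume noise, site/scanner effects,
covariate–group confounding, or realistic per-ROI mean profiles. Passing
tests therefore demonstrate the statistical machinery (calibration, power
against planted effects, hub recovery) under a clean Gaussian
block-covariance world, not robustness to real-data pathologies.

### Reference scenarios

* **null** — `δ = 0`: the two groups share one generative model; used for
  type-I calibration. The pipeline's per-density rejection rate at
  α = 0.05 is ~5% and AUC p-values are ~uniform.
* **transitivity-shift** — `ρ_within = 0.25, ρ_between = 0.05, δ = 0.25`.
  The shift must act at the thresholding boundary: with a saturated
  baseline (e.g. `ρ_within = 0.45`) every within-module edge survives
  density thresholding in *both* groups and the binary topology never
  changes, so no power is available at any `δ`. With a moderate baseline,
  group 2 loses part of its within-module edges to sampling noise while
  the boosted group 1 retains them, raising group-1 transitivity across
  the grid. At these settings the transitivity-AUC permutation test
  rejects at FDR < 0.05 in well over 80% of runs at n_perm = 200.
* **hub-swap** — three modules of 30, `ρ_within = 0.60,
  ρ_between = 0.05`, one planted bridge per module per group (nodes
  4/34/64 vs 14/44/74, 0-based) at `hub_rho = 0.46`. Within-module pairs
  then nearly exhaust the edge budget at D = 0.33, so inter-module
  shortest paths must route through the planted bridges, giving them
  unambiguous top betweenness. The mean+2SD rule recovers exactly the
  planted sets in ≈95% of runs; the residual failures are *emergent
  bridges* — non-hub nodes that, at n = 38/50 subjects, luck into several
  strong cross-module sample correlations. That failure mode is a property
  of small-sample SCNs, not of the detector. `ρ_between` below ~0.05 is
  avoided because whole between-module blocks can swing negative through
  module-factor sampling noise, occasionally leaving too few positive
  correlations to reach the top of the density grid.

## Numerical and design choices

* Edge counts use round-half-away-from-zero at the grid precision
  (`D = 0.33, N = 90 → E = 1322`), and stored densities are recomputed
  from the realized edge count so `D = E/[N(N−1)/2]` holds exactly.
* All stage seeds fan out deterministically from one master seed
  (`SeedSequence.spawn`); a saved run configuration re-runs to a
  byte-identical report. Reports contain no timestamps for this reason.
* Missing values are a hard error; nothing is imputed.
* Degenerate inputs: empty graphs are an error for global metrics;
  degree-regular graphs yield NaN assortativity; zero-variance ROIs are an
  error naming the ROI; `min_connected_density` returns `None` when no
  grid density connects the network.
* Demographics: Pearson chi-square without Yates continuity correction
  (the correction would not reproduce the standard hand formula on 2×2
  tables); Shapiro–Wilk at α = 0.05 per group gates the t-test vs
  Mann–Whitney choice, with Levene deciding pooled vs Welch variance.

## Simulation sizes

Calibration and power checks in the test suite run at reduced but stated
scales chosen to estimate the relevant rates with useful precision:
type-I calibration uses 500 replicate cohorts × 200 permutations on a
three-density subgrid {0.33, 0.41, 0.49} with transitivity as the probe
statistic (under exchangeability, permutation p-values share their null
distribution across statistics, so one statistic suffices to check
calibration); power uses 50 replicates × 200 permutations on the full
grid; hub recovery uses a documented panel of 20 generator seeds.
`scripts/acceptance.py` reports each quantity together with the problem
size used.

## Known limitations

* Binary, undirected networks only — no weighted or directed variants.
* No rich-club, participation coefficient, or cluster-based correction.
* Louvain restarts explore a limited part of the `Q` landscape; reported
  modularity is a lower bound on the optimum (as with any heuristic).
* Nodal permutation tests with betweenness across the full grid are the
  slowest path (networkx betweenness per density per relabeling); at the
  default n_perm = 1000 expect minutes, not seconds.
* The add-one p-value floor (1/(1+n_perm)) bounds attainable significance;
  FDR-corrected discovery at small n_perm requires the observed statistic
  to be extreme.
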