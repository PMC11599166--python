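# scnkit

Group-level **structural covariance network (SCN)** analysis for regional
brain morphometry.

An SCN is a graph built over a brain parcellation (here the 90
cortical/subcortical AAL regions) in which the edge weight between regions
*i* and *j* is the Pearson correlation `r_ij` of their gray-matter volumes
across the subjects of one group, after adjusting the volumes for age, sex
and total intracranial volume. Because each *group* — not each subject —
contributes a single network, group comparison needs label-permutation
inference rather than per-subject statistics. `scnkit` implements that full
workflow for two-group morphometry studies (e.g., a patient cohort against
controls):

1. **Cohort I/O** — read/validate a subjects × ROI volume table, residualize
   volumes on covariates by pooled OLS, and compute Table-1-style
   demographics (Pearson chi-square for categorical variables, t or
   rank-sum for continuous ones).
2. **Network construction** — per-group correlation matrices, binarized
   either at a fixed cutoff (`r_ij > 0.1`) or, for between-group
   comparability, at matched network densities
   `D = E / [N(N−1)/2]` over a grid (default 0.33–0.50, step 0.01).
3. **Graph metrics** — clustering coefficient `C_p`, harmonic-mean
   characteristic path length `L_p` (so that `E_glob·L_p = 1` even under
   fragmentation), global/local efficiency, transitivity, modularity `Q`,
   assortativity; nodal degree, betweenness and clustering; small-world
   parameters `γ = C_p/C_rand`, `λ = L_p/L_rand`, `σ = γ/λ` against
   ensembles of degree-preserving rewired null networks (default m = 20).
4. **Group inference** — permutation tests (default 1,000 relabelings) per
   density and on trapezoidal AUCs across the density grid, with
   Benjamini–Hochberg FDR within each metric family.
5. **Hubs & robustness** — hubs as nodes whose betweenness AUC exceeds the
   network mean by more than 2 SDs; robustness curves under adaptive
   degree-targeted and random node-removal attacks.
6. **Synthetic cohorts** — a generator of two-group, 90-region cohorts with
   block (community) covariance, covariate confounds and plantable group
   effects, so the whole pipeline is testable without any imaging data.

## Worked example

```python
from scnkit import (DensityGrid, correlation_network, generate,
                    metric_curves, permutation_test_global, residualize,
                    threshold_density)
from scnkit.synthetic import scenario

# a synthetic 38-vs-50 cohort with a planted transitivity excess in group 1
cohort = generate(scenario("transitivity-shift", seed=42))
residuals = residualize(cohort)           # pooled OLS on age + sex + TIV

net = correlation_network(residuals, "patient")
bn = threshold_density(net, 0.33)
print(bn.n_edges)                         # 1322 = round(0.33 * 90*89/2)

results = permutation_test_global(
    residuals, grid=DensityGrid(),
    metrics=("transitivity", "clustering", "path_length"),
    n_perm=200, seed=7,
)
auc = {r.metric: r for r in results if r.scope == "global-auc"}
r = auc["transitivity"]
print(f"{r.observed:+.4f} p={r.p_value:.4f} fdr={r.fdr_significant}")
```

Output:

```
1322
+0.0214 p=0.0050 fdr=True
```

1322 is the exact edge count the density formula prescribes at D = 0.33 for
90 nodes. The observed transitivity AUC of group 1 exceeds group 2 by
0.0214 and no more extreme difference occurs in the 200 relabelings
(p = 1/201 ≈ 0.005), surviving FDR across the three AUC tests — the planted
segregation effect is detected.

The same analysis is available from the shell:

```bash
scn simulate --scenario transitivity-shift --seed 42 --out cohort.csv
scn run --input cohort.csv --seed 7 --nperm 1000 --out results/
scn report results/report.json
```

`scn run` writes `report.json` plus tidy tables (`curves.tsv`,
`permutations.tsv`, `robustness.tsv`) and re-runs byte-identically from the
same master seed.

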