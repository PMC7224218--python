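# nicheshift

Quantify realized-niche change between a species' native and invaded ranges,
test niche conservatism, and evaluate how niche shifts undermine the
transferability of ensemble suitability models — all runnable end-to-end on
synthetic data with known, controllable niche dynamics.

## What it does

| Stage | Module | Summary |
|---|---|---|
| Synthetic data | `nicheshift.synthetic` | Two-range environmental backgrounds (controllable analogous/non-analogous split) and occurrence samples drawn from a Gaussian suitability kernel with controllable centroid shift, unfilling, and expansion |
| Environmental space | `nicheshift.envspace` | PCA calibrated on the pooled backgrounds, a 100×100 grid bounded by background scores, Gaussian-KDE occurrence/background densities, and availability masks I₇₅/I₁₀₀ |
| Niche change | `nicheshift.coue` | Stability / unfilling / expansion in analogous climate, centroid shift, five-class niche topology, Schoener's D |
| Conservatism tests | `nicheshift.conservatism` | Permutation niche-equivalency test (pooled-occurrence reassignment) and niche-similarity tests (random centroid placement, N↔P and N→P), one-tailed "greater" rule at α = 0.05 |
| Hypervolumes | `nicheshift.hypervolume` | Gaussian-KDE hypervolumes (Silverman bandwidths, rejection-sampled random points) compared by Jaccard, centroid/minimum distance, intersection volume and unique fractions at H₇₅/H₁₀₀ |
| Suitability models | `nicheshift.enm` | Spatial thinning, \|r\| ≤ 0.7 correlation filtering, pseudo-absence sampling, prevalence-0.5 weighting, nested 70/30 splits × repeats, pluggable learners (logistic GLM, spline GAM, random forest, boosted trees, CART, ANN), AUC/TSS evaluation, TSS-weighted ensembles, reciprocal projection, clamping detection |
| Orchestration | `nicheshift.workbench` | Config-driven pipeline, CSV/JSON/ESRI-ASCII artifacts, seeded reproducibility |

## CLI

A study is described by one YAML file (see `StudyConfig`); every stage writes
its artifacts into the configured output directory:

```bash
nicheshift all -c study.yaml --seed 1 -o out/
nicheshift niche -c study.yaml          # just the gridded-niche stage
```

Minimal config:

```yaml
seed: 1
outdir: out
grid_resolution: 100
synthetic:
  background: {n_points: 2000, k: 2, spread: 1.5, resolution: 0.5}
  truth:
    centroid_native: [0.0, 0.0]
    centroid_shift: [1.0, 0.0]
    niche_sd: 0.6
    unfilling_frac: 0.2
    expansion_frac: 0.2
    n_native: 500
    n_invaded: 500
tests: {n_reps: 999}
enm: {learners: [glm, gam, rf, brt], n_pseudo: 1000, n_repeats: 10}
```

Outputs include `coue_metrics.csv` (stability/unfilling/expansion at I₇₅ and
I₁₀₀ plus D and test p-values), `hypervolume_metrics.csv`,
`enm_evaluation.csv` (ensemble and member AUC/TSS on E_eval/E_inv/E_nat),
density and mask grids, suitability rasters, and a seeded run log. Real data
can be supplied instead of the synthetic scenario via the `inputs:` section
(occurrence and background CSVs).

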