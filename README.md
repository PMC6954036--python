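# mpmlife

Comparative senescence and life-history analysis for plant matrix population
models (MPMs), aimed at population ecologists asking whether clonal plants
escape ageing. Starting from the standard decomposition of a projection
matrix,

    A = U + F + C,

with **U** survival/growth/shrinkage, **F** sexual recruitment and **C**
clonal (ramet) recruitment, the package derives age-based life tables from
stage-based models, computes senescence metrics, and runs the full
comparative workflow from raw model collections to phylogenetically-corrected
ordination and inference.

The two metrics at the core:

- **Keyfitz's life-table entropy**
  `H = [−∫ log(l_x) l_x dx] / [∫ l_x dx]` — the shape of the survivorship
  curve. `H = 1` for constant mortality (Type II), `H < 1` when mortality
  rises with age (senescence, Type I), `H > 1` when it declines (escape from
  senescence, Type III).
- **Demetrius's entropy** `S = −Σ p_x log p_x` with
  `p_x ∝ λ^{−x} l_x m_x` — the spread of reproduction over the lifespan,
  from `S = 0` (strict semelparity) up to `log k` for reproduction spread
  evenly over `k` ages.

The full pipeline: structural validation (non-negative, irreducible,
primitive) → eleven study-selection criteria → reproduction-mode
classification (strictly sexual / clonal-but-unquantified / sexual-and-
clonal) → age-from-stage trajectories `l_x, m_x, c_x` with seed-bank left
truncation and quasi-stationary (QSD₉₀) right truncation → eight
life-history traits (generation time `T`, mean life expectancy `η_e`, mature
life expectancy `L_{α−ω}`, SSD-weighted survival σ, sexual reproduction φ,
growth γ, shrinkage ρ, iteroparity `S`) → log transform, outlier masking and
standardization → chained-equation imputation with predictive mean matching
→ phylogenetically-corrected PCA under a Brownian-motion tree covariance
with Kaiser axis retention → OLS of `H` on the retained axis scores,
clonality-covariate models, per-mode one-sample t-tests of `H` against 1,
and Tukey HSD contrasts.

Because no curated MPM compilation ships with the package, a first-class
synthetic-data module generates collections with known ground truth: Leslie
models built from Type I/II/III mortality regimes, calibrated by
Euler–Lotka to a target growth rate, pooled into realistic stage classes,
with optional seed banks and clonal reproduction, plus Yule phylogenies and
Brownian-motion traits.

## Worked example

```python
import mpmlife as ml

scenario = ml.reference_scenario(seed=1)          # 124 / 35 / 22 species by mode
collection, tree, truth = ml.make_collection(scenario)
result = ml.run_pipeline(collection, tree, ml.PipelineConfig(seed=1))

print("retained:", len(result.filter_report.retained),
      "eligible:", len(result.trait_vectors))
print("variance explained (PC1, PC2): %.2f%% %.2f%%" % tuple(result.pca.pct_var[:2]))
print(result.group_tests.round(3).to_string(index=False))
```

prints

```
retained: 181 eligible: 127
variance explained (PC1, PC2): 46.64% 26.73%
                  mode  n  mean    SE  df       t   P
           only_sexual 93 0.782 0.034  92  -6.382 0.0
only_sexual_but_clonal 19 0.590 0.007  18 -60.352 0.0
     sexual_and_clonal 15 0.646 0.048  14  -7.397 0.0
```

Reading this: of 184 generated records, the selection criteria retain 181
(the three planted inadmissible species are excluded); 127 pass the QSD₉₀
eligibility rule. Each reproduction-mode group's mean Keyfitz entropy sits
below 1 — every group senesces on average, with the clonal groups lowest —
and the one-sample t-tests against the negligible-senescence threshold
`H = 1` are all strongly significant, matching the increasing-hazard ground
truth planted for most species in this scenario.

The same run from a shell:

```sh
mpmlife simulate --seed 1 --out-dir sim/
mpmlife run-all --collection sim/collection.json --tree sim/tree.nwk \
        --seed 1 --out-dir out/
```

writes `filter_report.csv`, `traits.csv`, `pca_loadings.csv`,
`pca_scores.csv`, `regression.csv`, `group_tests.csv` and `tukey.csv`.

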