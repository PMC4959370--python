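# progmod

Prognostic gene-module discovery from tumor expression profiles.

Breast-cancer survival is highly heterogeneous, and single-gene markers
(ER, HER2, proliferation genes) capture only part of that variation.
`progmod` implements a pipeline that mines a training cohort — an
expression matrix plus time-to-event clinical data — for *paired* gene
sets whose expression ratio predicts outcome:

1. **Quartile survival screen.** For each gene g, patients are split into
   the bottom and top expression quartiles and compared with a log-rank
   test and Cox hazard ratio. A gene is called over-expressed in poor
   survival when HR > 1, BH-adjusted p < 0.001 and the quartile medians
   are ≥ 2-fold apart; under-expressed in poor survival is the mirror
   call with HR < 1.
2. **Clique clustering.** Within each directional gene list, genes are
   connected when Pearson r > 0.4 across samples, and the largest cliques
   are extracted iteratively (two major clusters per direction, each with
   more than 15 genes).
3. **Bi-clique pairing.** Each (high, low) cluster pair is reduced to the
   maximal bi-clique of its bipartite anticorrelation graph (r ≤ −0.4),
   giving a *prognostic module*: gene sets H and L with every h∈H, l∈L
   pair anticorrelated.
4. **Scoring and validation.** A sample's module score is
   median(expr<sub>H</sub>) / median(expr<sub>L</sub>) (the difference of
   medians on log-scale data). Scores are dichotomized at the cohort
   median (or cut into quartiles), and the strata are compared with
   Kaplan–Meier curves, a log-rank test and a hazard ratio on held-out
   cohorts.

Two companion analyses are included: nonparametric association of module
scores with clinical covariates (subtype, TNBC, ER, grade, TP53), and a
Welch-*t* / BH-FDR differential-expression screen between TNBC and
non-TNBC tumors with module-overlap reporting.

Because the statistical structure the pipeline assumes is easy to state —
co-expressed blocks, high/low anticorrelation, hazard linked to block
activity, right censoring — the package ships a synthetic-cohort
generator (`progmod.simulate`) that plants that structure with known
ground truth, so every stage is testable end to end without any external
download.

It is aimed at computational biologists analysing microarray- or
RNA-seq-derived cohorts with survival follow-up (METABRIC-like training
sets, GEO-style validation sets).

## Worked example

```python
from progmod import (SimConfig, simulate, screen_all, ScreenConfig,
                     build_modules, validate_module)

# training cohort: 2000 genes, n=400, one planted 20-gene high-risk and
# one 20-gene low-risk block (within r≈0.7, cross r≈−0.5), 50% censoring
train_expr, train_clin, truth = simulate(SimConfig(seed=0))

high, low, stats = screen_all(train_expr, train_clin,
                              ScreenConfig(scale_hint="log"))
print(f"screen: {len(high)} genes over-expressed, "
      f"{len(low)} under-expressed in poor survival")

mods = build_modules(train_expr, high, low)
for m in mods:
    print(f"{m.label}: {len(m.high_genes)} high / {len(m.low_genes)} low genes")

test_expr, test_clin, _ = simulate(SimConfig(seed=1000))   # independent cohort
rep = validate_module(mods[0], test_expr, test_clin, mode="difference")
print(f"held-out validation: log-rank p = {rep.logrank_p:.2e}, "
      f"HR(high vs low) = {rep.hazard_ratio:.2f}")
```

prints

```
screen: 20 genes over-expressed, 20 under-expressed in poor survival
module 1: 20 high / 20 low genes
held-out validation: log-rank p = 9.09e-25, HR(high vs low) = 4.99
```

The screen recovered exactly the 40 planted genes; clustering and
bi-clique pairing assembled them into a single module; and on an
independently simulated cohort the module's median-dichotomized score
separates survival decisively (patients in the high-score stratum carry
about five times the event hazard of the low stratum).

The same chain is available as a scikit-learn estimator
(`PrognosticModuleDiscovery().fit(X, y).transform(X2)` with X as
samples × genes and y as a time/event structure) and as a CLI:

```bash
progmod simulate --out-dir sim/ --seed 0
progmod screen --expr sim/expression.tsv --clinical sim/clinical.tsv \
               --scale log --out stats.tsv
progmod build-modules --expr sim/expression.tsv --stats stats.tsv --out mods.gmt
progmod score --expr sim/expression.tsv --modules mods.gmt \
              --mode difference --out scores.tsv
progmod validate --expr sim/expression.tsv --clinical sim/clinical.tsv \
                 --modules mods.gmt --mode difference --out report.json
```

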