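# coexland

Cross-dataset gene co-expression landscapes for tumor transcriptomics.

Large compilations of tumor expression profiles make gene-gene
correlation a powerful handle on core transcriptional programs — cell
cycle, stroma/EMT, immune response, steroid response — but networks
built from pooled multi-study data are easily contaminated by
single-study batch effects, and a flat network at a permissive
threshold is unreadable. `coexland` implements a pipeline that deals
with both problems and carries the resulting modules through to
biological testing:

- **Robust edges.** For a cohort of D studies, each gene pair gets D
  Pearson correlations, each computed with one study left out; the edge
  weight is the *minimum* `r_min(g1, g2) = min_d r^(-d)(g1, g2)`, and
  only positive minima count. A correlation driven by one study
  collapses in the run excluding it and never enters the network.
- **Significance floor.** Independent per-gene permutation of the
  pooled matrix gives the null distribution of the maximum absolute
  pairwise correlation; at reference scale (3,824 genes × 1,608
  samples) this floor is ≈ 0.14.
- **Modules and landscape.** Networks threshold edges at r > c and
  iteratively prune genes with fewer than k = 5 neighbors (the
  k-core); modules are the connected components. Each gene gets
  landscape coordinates: x/y from a weighted spring-embedded layout,
  z = the highest cutoff in {0.3, …, 0.7} at which it is still in a
  network.
- **Module statistics.** Mean pairwise correlation against random
  same-size gene sets; NACC (fraction of gene pairs connected at a
  cutoff) within and between modules, with subsampling tests for
  subgroup-specific interconnection (e.g. TP53-mutant vs wildtype) and
  expression-quartile stratification; rank-based per-sample activity
  scores in (0, 1]; cross-cancer conserved cores; above/below-mean
  dichotomization for survival tooling.
- **Screen testing.** Module-level analysis of siRNA knockdown screens:
  mean Ki-67 intensity of a module's genes against 10,000 resampled
  same-size gene groups, one-sided toward reduced proliferation.
- **Synthetic cohorts.** A Gaussian factor-model generator plants
  modules, covariate-dependent couplings, batch artifacts and screen
  effects with closed-form expectations, so the whole pipeline is
  testable end to end without any data download.

See `docs/methods.md` for definitions, conventions and caveats.

## Worked example

```python
from coexland import (
    SyntheticCohortConfig, generate_cohort, loo_min_correlation,
    NetworkConfig, build_network, extract_modules, landscape_z, nacc,
    activity_scores, generate_screen, module_knockdown_test,
)

cohort, truth = generate_cohort(SyntheticCohortConfig(seed=0))
corr = loo_min_correlation(cohort)
net = build_network(corr, NetworkConfig(cutoff=0.6, min_neighbors=5))
modules = extract_modules(net, min_size=6)
m1 = modules[0]
z = landscape_z(corr)
scores = activity_scores(modules, cohort.datasets[0])
screen = generate_screen(n_genes=500,
                         effect_modules=[(sorted(m1.gene_ids), -2.0)],
                         noise_sd=1.0, seed=1)
res = module_knockdown_test(screen, m1, n_samples=10000, seed=2)
```

This prints, via the obvious f-strings:

```
cohort: 500 genes, 600 samples, 4 datasets
network at r>0.6: 152 genes, 1516 edges, 8 modules
largest module: M1 (30 genes), NACC@0.6 = 0.982
genes at z=0.7: 75; z=0 (outside landscape): 348
M1 activity scores in D1: mean 0.469, range [0.047, 0.964]
knockdown test M1: centered mean -1.91, one-sided p = 0.0001
```

Reading the numbers: the benchmark generator plants eight correlated
blocks among 500 genes; thresholding the leave-one-out minimum
correlations at 0.6 and pruning to the 5-core retains exactly the 152
planted module genes in eight components. The largest module is nearly
a clique at its source cutoff (NACC 0.982). 75 genes still hold
together at r > 0.7 (landscape peaks), while background genes sit at
z = 0. Rank-mean activity scores spread over (0, 1] per sample, and a
screen in which the module's knockdown lowers Ki-67 intensity by two
noise SDs is called at the resolution limit of a 10,000-draw null
(p = 1/10001 ≈ 1e-4).

The same workflow is available from the shell:

```bash
coexland simulate --out-dir sim/ --seed 5
coexland correlate --matrix sim/D1.tsv --matrix sim/D2.tsv \
    --matrix sim/D3.tsv --matrix sim/D4.tsv --floor 0.14 --out edges.tsv
coexland network --edges edges.tsv --cutoff 0.6 --modules-out modules.gmt
coexland landscape --edges edges.tsv --out coords.tsv
coexland score --matrix sim/D1.tsv --modules modules.gmt --out scores.tsv
```

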