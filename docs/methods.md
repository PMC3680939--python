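# Methods

This note documents the statistical procedures implemented in
`coexland`, the choices made where the design was genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## Leave-one-out minimum correlation

Given a cohort of D independent expression studies sharing a gene list,
every gene pair receives D Pearson correlations, the d-th computed on
the pooled samples of all studies except study d. The stored edge
weight is the minimum of the D values, and pairs whose minimum is not
strictly positive are marked absent (stored as NaN, never as 0 — a
filtered pair and a zero weight are different statements).

The minimum is the cohort's batch defense: a correlation induced by a
single study's artifacts (array batch, cohort composition, processing)
collapses toward 0 in the run that excludes that study, so it cannot
survive any positive cutoff. The correlations are computed on pooled
samples of the retained studies, not averaged per-study correlations;
per-study averaging would weight small studies equally with large ones
and has no leave-one-out interpretation.

Degenerate inputs: a gene constant within some leave-one-out pool has
undefined correlations there; all its pairs are marked absent and a
warning is logged. Computed correlations are clipped to [-1, 1] to
guard against floating-point overshoot. Fewer than two datasets is an
error; each pool must contain at least `min_samples` samples (default
30, below which Pearson estimates are too noisy to threshold).

## Permutation significance floor

The null for "how large can a correlation be by chance" permutes each
gene's values independently across all pooled samples, which destroys
every gene-gene correlation while preserving each gene's marginal
distribution. Per repetition the maximum *absolute* pairwise
correlation is recorded; the magnitude is the two-sided statistic (a
negative correlation of equal size is equally significant under this
null, and all tests in the pipeline are two-sided unless stated).

Two summary statistics are exposed: `threshold`, the overall maximum
across repetitions (the conservative floor), and `median_max`, the
median per-repetition maximum (the typical single-matrix extreme). The
per-repetition maxima are retained so users can take any quantile. At
the reference dimensions of 3,824 genes by 1,608 samples, the
single-matrix maximum centers near 0.13; correlations above ~0.14 can
be treated as significant at this scale. `scripts/acceptance.py`
recomputes this number from scratch.

## Network construction, modules, landscape

Edges connect pairs with stored weight strictly greater than the
cutoff; a tie at exactly the cutoff is excluded ("above" is strict).
Nodes with fewer than k neighbors (default k = 5) are then pruned.
The default prune mode is iterative: removing a low-degree node can
drop a neighbor below k, so removal repeats until stable, yielding the
k-core — the unique maximal subgraph of minimum degree >= k. A
`single_pass` mode (one removal sweep judged on the unpruned graph,
then dropping isolated leftovers) is provided for comparison, but it
leaves nodes that violate the stated degree property and is not the
default.

Modules are the connected components of the pruned network with at
least `min_size` genes (default 6, the smallest possible 5-core),
ordered by decreasing size with deterministic tie-breaking. At high
cutoffs the pruned network fragments into its tightly co-expressed
blocks, so components are the natural mechanization of visually
distinct modules; a community-detection alternative can be plugged in
but is not validated here.

Landscape coordinates: x/y come from a spring-embedded (Fruchterman-
Reingold) layout of the base-cutoff network, with correlations as edge
weights and coordinates rescaled to a unit bounding box centered on the
origin; the layout is deterministic given a seed. Each gene's height z
is the highest cutoff on the grid {0.3, 0.4, 0.5, 0.6, 0.7} at which
the gene is still in a pruned network (0 if in none). Because the
k-core is monotone under edge addition, membership at a cutoff implies
membership at all smaller cutoffs, so the maximum is well defined.
Surface interpolation of (x, y, z) is left to external plotting tools.

## Module statistics

**Co-expression.** A module's co-expression in a dataset is the mean
Pearson correlation over all its gene pairs, compared with the same
statistic for random same-size gene sets (default 1,000) drawn
uniformly from the dataset's gene universe.

**NACC.** For a gene set at a cutoff: the number of pairs with
correlation above the cutoff divided by all m(m-1)/2 possible pairs.
For two disjoint sets the `union` mode treats them as one module
(within- plus between-set pairs), while `cross_only` counts only A-B
pairs over |A|·|B| — a sharper measure of interconnection. Both are
exposed; profiles over a cutoff grid are non-increasing by construction
and this invariant is asserted on every call.

**Subgroup test.** To ask whether two modules are more interconnected
in a small sample subgroup (e.g. TP53-mutant tumors) than expected, the
observed NACC profile on the subgroup's samples is compared to
`n_resample` (default 10,000) same-size subsets of the reference group
(e.g. wildtype), recomputing correlations each time; the one-sided p
uses the add-one estimator. Null mean and SD per cutoff are reported
for plotting. *Caveat:* subsampling a finite reference group
under-disperses the null — the subsets share samples, so their spread
carries a finite-population factor of roughly (1 - n/N). When the
subgroup is a third the size of the reference, the nominal 5% level
inflates to roughly 12%; at n/N around 5% the test is calibrated to
within the Monte-Carlo error. p-values for comparably sized groups
should be read as approximate. A label-permutation variant would fix
this but is not the default because the subsampling design is the one
being modeled.

**Quartile stratification.** Samples are split into four near-equal
groups (sizes differ by at most one) by ascending expression of a
stratifier gene, ties broken by stable input order, and a NACC profile
is computed per quartile plus an all-samples reference. At least 8
samples per quartile are required.

**Activity scores.** The rank-mean score of a module in a sample is the
mean within-sample rank of the module's genes (average ranks on ties)
divided by the total gene count, giving values in (0, 1]. The score is
exactly invariant to any strictly increasing per-sample transform of
expression — the property that makes it comparable across samples and
platforms — and to module gene ordering. This definition is fixed and
covered by invariance tests rather than claimed identical to any
particular prior formulation. An `expression_sum` mode (plain
per-sample sum of module genes) is provided for core-module marker
scoring. Modules with fewer than half their genes present in a dataset
raise; partial presence scores the present subset with a warning.
Spearman correlation links scores to individual genes; above/below-mean
dichotomization (strictly above; all-equal scores are all "below") is
exported for external survival tooling, which is out of scope here.

**Conservation.** A module's conserved core across two correlation
matrices is the largest connected component of the graph of
module-internal pairs exceeding the cutoff in *both* matrices; with no
conserved edge the core is empty.

## Knockdown screen testing

One log-intensity per targeted gene; replicate rows are collapsed by
median at read time. A module's mean intensity is compared with
`n_samples` (default 10,000) random gene groups of the same size drawn
without replacement from the screened library; flagged non-specific
controls are excluded from the sampling universe by default since they
are not library genes. The default alternative is one-sided toward
reduced intensity (proliferation inhibition); `greater` and `two-sided`
are available. `centered_mean` subtracts the empirical null mean, the
centering used when plotting observed means against null densities. The
control set can be run through the identical machinery.

## Synthetic cohorts

A Gaussian factor model generates benchmark data with closed-form
targets for every moment the pipeline estimates. A gene in a module
with within-module correlation rho is
`sqrt(rho) * f_m(sample) + sqrt(1 - rho) * noise`, with standard-normal
factors and noise, so within-module gene pairs correlate at rho and
genes of modules coupled at factor correlation tau correlate at
`tau * sqrt(rho_i * rho_j)`. Couplings may switch value on a per-sample
covariate (modeling mutation-status-dependent interconnection); the
factor correlation matrix is Cholesky-checked before sampling and
infeasible structures fail fast. The per-sample factor value is the
planted activity level that rank-mean scores should recover. An
artifact module shares a factor only inside one designated study (the
planted batch effect for leave-one-out tests) and additive per-
(dataset, gene) mean shifts are available; multiplicative batch effects
are not modeled.

Defaults: 4 datasets x 150 samples, 500 genes, eight modules of sizes
30, 25, 22, 20, 18, 15, 12, 10 with rho 0.65, 0.68, 0.70, 0.72, 0.75,
0.78, 0.80, 0.85 — larger, looser programs alongside small tight ones,
sized so the suite runs in seconds while every pipeline stage has
signal to find. The covariate (default name `tp53_status`) marks ~30%
of samples as the alternative state.

The generator emulates block-correlation structure, batch artifacts,
and covariate-dependent coupling; it does **not** emulate platform
probe effects, realistic (non-Gaussian) intensity marginals, missing
values, or survival times. Tests passing on these cohorts demonstrate
the estimators' correctness and calibration under the factor model,
not robustness to every property of clinical microarray data.

The knockdown-screen generator plants mean shifts on disjoint gene
sets over i.i.d. Gaussian noise with flagged controls — the structure,
not the marginal distribution, of a real arrayed screen.

## Numerical conventions

- Standard deviations use the n-1 denominator; the variance filter is
  strictly "above" the cutoff.
- Pooled-gene centering is the default ("per_gene_global"); per-dataset
  centering is available. Pearson correlations within a pool are
  location-invariant, so centering choice affects only the pooled SD
  filter and exported values.
- Resampling p-values use `(1 + #{null >= obs}) / (1 + n)` and are
  never 0.
- Absent correlation entries are NaN throughout; comparisons treat NaN
  as "never qualifies".
- All stochastic procedures take explicit seeds and are reproducible;
  module ordering, quartile assignment and component tie-breaks are
  deterministic.

## Problem sizes in the test suite

Unit tests run on fixtures of tens of genes; calibration checks use 500
null simulations with 500 resamples each; recovery checks use 20 seeded
benchmark cohorts; the permutation-floor check runs five repetitions at
the full 3,824 x 1,608 reference scale. The whole suite completes in
about a minute on one CPU.

## Known limitations

- Module extraction by connected components cannot split a component
  containing two merged programs at a given cutoff; raising the cutoff
  is the intended mechanism, community detection the unvalidated hook.
- The subsampling subgroup test is approximate for subgroup-to-
  reference ratios that are not small (see above).
- Spearman-based alternatives to the Pearson network are accepted by
  the config surface but unvalidated.
- The landscape layout is a force-directed embedding: distances are
  suggestive, not metric; only the z-values carry a defined meaning.
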