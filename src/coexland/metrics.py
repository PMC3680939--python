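"""Module-level statistics.

Co-expression with random-gene-set nulls, the NACC interconnectivity
statistic and its resampling tests, rank-based single-sample activity
scores, gene-to-module correlation, cross-dataset module conservation
and score dichotomization.

NACC (network average clustering coefficient, as used for gene sets
here) is the fraction of gene pairs in a set whose correlation exceeds a
cutoff, relative to all possible pairs in the set. Between two disjoint
sets it can be taken over the union (both within- and between-set pairs)
or over cross pairs only, which isolates the interconnection signal.

All resampling p-values use the add-one estimator
``p = (1 + #{null >= observed}) / (1 + n_draws)`` so that p is never 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset, standardize_rows
from .loocorr import CorrelationMatrix
from .network import GeneModule

log = logging.getLogger(__name__)

CombineMode = Literal["union", "cross_only"]
ScoringMode = Literal["rank_mean", "expression_sum"]


# ---------------------------------------------------------------------------
# module co-expression vs random gene sets
# ---------------------------------------------------------------------------

@dataclass
class CoexpressionSummary:
    module_id: str
    mean_pairwise_r: float
    null_mean_r: np.ndarray
    empirical_p: float
    n_genes_used: int


def _mean_pairwise_r(z: np.ndarray) -> float:
    """Mean off-diagonal correlation of row-standardized data ``z``."""
    m = z.shape[0]
    corr = z @ z.T
    return float((corr.sum() - np.trace(corr)) / (m * (m - 1)))


def module_coexpression(
    module: GeneModule | Iterable[str],
    ds: ExpressionDataset,
    n_random: int = 1000,
    seed: int | None = None,
    module_id: str | None = None,
) -> CoexpressionSummary:
    """Average pairwise Pearson correlation of a module in one dataset,
    compared with random gene sets of the same size.

    The null draws ``n_random`` uniform same-size gene sets from the
    dataset's gene universe and records their mean pairwise correlation.
    """
    genes = sorted(module.gene_ids) if isinstance(module, GeneModule) else sorted(module)
    mid = module_id or (module.module_id if isinstance(module, GeneModule) else "module")
    present = [g for g in genes if g in ds.values.index]
    missing = sorted(set(genes) - set(present))
    if len(present) < 2:
        raise ValueError(
            f"module {mid!r}: fewer than 2 genes present in {ds.dataset_id!r} "
            f"(missing: {missing[:10]})"
        )
    if missing:
        log.warning("module %s: %d genes absent from %s", mid, len(missing), ds.dataset_id)

    z_all = standardize_rows(ds.values.to_numpy())
    gene_pos = {g: i for i, g in enumerate(ds.values.index)}
    idx = [gene_pos[g] for g in present]
    observed = _mean_pairwise_r(z_all[idx])

    rng = np.random.default_rng(seed)
    m = len(present)
    null = np.empty(n_random)
    for i in range(n_random):
        draw = rng.choice(z_all.shape[0], size=m, replace=False)
        null[i] = _mean_pairwise_r(z_all[draw])
    p = (1 + int((null >= observed).sum())) / (1 + n_random) if n_random else np.nan
    return CoexpressionSummary(mid, observed, null, p, m)


# ---------------------------------------------------------------------------
# NACC
# ---------------------------------------------------------------------------

def _pair_weights(
    corr_sub: np.ndarray, n_a: int, combine_mode: CombineMode
) -> np.ndarray:
    """Flatten the relevant pair weights of a (A then B)-ordered submatrix."""
    if combine_mode == "union":
        iu, ju = np.triu_indices(corr_sub.shape[0], k=1)
        return corr_sub[iu, ju]
    return corr_sub[:n_a, n_a:].ravel()


def nacc(genes: Iterable[str], corr: CorrelationMatrix, cutoff: float) -> float:
    """Fraction of gene pairs connected at ``cutoff``: qualifying pairs
    over m(m-1)/2. Absent (NaN) pairs never qualify."""
    genes = sorted(set(genes))
    if len(genes) < 2:
        raise ValueError("NACC needs at least 2 genes")
    missing = [g for g in genes if g not in corr]
    if missing:
        raise KeyError(f"genes absent from correlation matrix: {missing[:10]}")
    sub = corr.submatrix(genes)
    iu, ju = np.triu_indices(len(genes), k=1)
    w = sub[iu, ju]
    return float((np.nan_to_num(w, nan=-np.inf) > cutoff).mean())


@dataclass
class NACCProfile:
    """NACC across an ascending cutoff grid, optionally with a resampled null.

    ``nacc`` is non-increasing in the cutoff by construction (fewer pairs
    qualify at a higher threshold); this is asserted on creation.
    """

    cutoffs: np.ndarray
    nacc: np.ndarray
    combine_mode: CombineMode = "union"
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    p_values: np.ndarray | None = None
    n_resample: int = 0

    def __post_init__(self) -> None:
        self.cutoffs = np.asarray(self.cutoffs, dtype=float)
        self.nacc = np.asarray(self.nacc, dtype=float)
        if np.any(np.diff(self.cutoffs) <= 0):
            raise ValueError("cutoff grid must be strictly ascending")
        if np.any(np.diff(self.nacc) > 1e-12):
            raise AssertionError("NACC must be non-increasing in the cutoff")

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"cutoff": self.cutoffs, "nacc": self.nacc})
        if self.null_mean is not None:
            out["null_mean"] = self.null_mean
            out["null_sd"] = self.null_sd
            out["p"] = self.p_values
        return out


def _nacc_values(
    corr_sub: np.ndarray, n_a: int, cutoffs: np.ndarray, combine_mode: CombineMode
) -> np.ndarray:
    w = np.nan_to_num(_pair_weights(corr_sub, n_a, combine_mode), nan=-np.inf)
    return np.array([(w > c).mean() for c in cutoffs])


def _split_sets(genes_a, genes_b, combine_mode: CombineMode):
    a = sorted(set(genes_a))
    if genes_b is None:
        if combine_mode == "cross_only":
            raise ValueError("cross_only mode needs two gene sets")
        return a, []
    b = sorted(set(genes_b))
    overlap = set(a) & set(b)
    if overlap and combine_mode == "cross_only":
        raise ValueError(f"gene sets overlap in cross_only mode: {sorted(overlap)[:10]}")
    if combine_mode == "union":
        b = sorted(set(b) - set(a))
    return a, b


def nacc_profile(
    genes_a: Iterable[str],
    genes_b: Iterable[str] | None,
    corr: CorrelationMatrix,
    cutoffs: Sequence[float],
    combine_mode: CombineMode = "union",
) -> NACCProfile:
    """NACC over a cutoff grid for one gene set or a pair of sets.

    ``union`` treats A ∪ B as a single module; ``cross_only`` counts only
    A-B pairs over |A|*|B| possible pairs.
    """
    a, b = _split_sets(genes_a, genes_b, combine_mode)
    genes = a + b
    missing = [g for g in genes if g not in corr]
    if missing:
        raise KeyError(f"genes absent from correlation matrix: {missing[:10]}")
    sub = corr.submatrix(genes)
    cutoffs = np.asarray(sorted(cutoffs), dtype=float)
    vals = _nacc_values(sub, len(a), cutoffs, combine_mode)
    return NACCProfile(cutoffs=cutoffs, nacc=vals, combine_mode=combine_mode)


def subgroup_nacc_test(
    genes_a: Iterable[str],
    genes_b: Iterable[str] | None,
    values: pd.DataFrame,
    small_samples: Sequence[str],
    large_samples: Sequence[str],
    cutoffs: Sequence[float],
    n_resample: int = 10000,
    seed: int | None = None,
    combine_mode: CombineMode = "union",
) -> NACCProfile:
    """Is module interconnectivity in a small sample group higher than
    expected from same-size subsets of a large reference group?

    The observed NACC profile is computed from Pearson correlations over
    the small group's samples (e.g. TP53-mutant tumors). The null draws
    ``n_resample`` subsets of the large group (e.g. wildtype tumors) of
    the same size, recomputing correlations and NACC each time. One-sided
    p per cutoff with the add-one estimator; null mean and SD per cutoff
    are reported for plotting.
    """
    small = list(small_samples)
    large = list(large_samples)
    if not small or not large:
        raise ValueError("both sample groups must be non-empty")
    if len(small) > len(large):
        raise ValueError(
            f"small group ({len(small)}) exceeds reference group ({len(large)})"
        )
    a, b = _split_sets(genes_a, genes_b, combine_mode)
    genes = a + b
    missing = [g for g in genes if g not in values.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:10]}")
    cutoffs = np.asarray(sorted(cutoffs), dtype=float)

    sub = values.loc[genes]
    z_small = standardize_rows(sub[small].to_numpy())
    observed = _nacc_values(z_small @ z_small.T, len(a), cutoffs, combine_mode)

    x_large = sub[large].to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)
    null = np.empty((n_resample, len(cutoffs)))
    for i in range(n_resample):
        cols = rng.choice(x_large.shape[1], size=len(small), replace=False)
        z = standardize_rows(x_large[:, cols])
        null[i] = _nacc_values(z @ z.T, len(a), cutoffs, combine_mode)
    exceed = (null >= observed - 1e-12).sum(axis=0)
    p = (1 + exceed) / (1 + n_resample)
    return NACCProfile(
        cutoffs=cutoffs,
        nacc=observed,
        combine_mode=combine_mode,
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0, ddof=1),
        p_values=p,
        n_resample=n_resample,
    )


def quartile_nacc(
    genes_a: Iterable[str],
    genes_b: Iterable[str] | None,
    ds: ExpressionDataset,
    stratifier_gene: str,
    cutoffs: Sequence[float],
    combine_mode: CombineMode = "union",
) -> dict[str, NACCProfile]:
    """NACC profiles within sample quartiles of a stratifier gene.

    Samples are split into four near-equal groups (sizes differ by at
    most one) by ascending stratifier expression, ties broken by stable
    input order. Returns profiles keyed 'Q1' (lowest) .. 'Q4' plus an
    'all'-samples reference.
    """
    if stratifier_gene not in ds.values.index:
        raise KeyError(f"stratifier gene {stratifier_gene!r} not in dataset")
    n = ds.n_samples
    if n < 32:
        raise ValueError(f"need >= 8 samples per quartile, have {n} total")
    expr = ds.values.loc[stratifier_gene].to_numpy()
    order = np.argsort(expr, kind="stable")
    samples = np.asarray(ds.sample_ids)
    groups = np.array_split(samples[order], 4)

    def _profile(cols) -> NACCProfile:
        a, b = _split_sets(genes_a, genes_b, combine_mode)
        genes = a + b
        z = standardize_rows(ds.values.loc[genes, list(cols)].to_numpy())
        vals = _nacc_values(
            z @ z.T, len(a), np.asarray(sorted(cutoffs), dtype=float), combine_mode
        )
        return NACCProfile(
            cutoffs=np.asarray(sorted(cutoffs), dtype=float),
            nacc=vals,
            combine_mode=combine_mode,
        )

    out = {f"Q{i + 1}": _profile(g) for i, g in enumerate(groups)}
    out["all"] = _profile(samples)
    return out


# ---------------------------------------------------------------------------
# activity scores
# ---------------------------------------------------------------------------

@dataclass
class ModuleActivityScores:
    """Module x sample score matrix.

    ``rank_mean`` scores are the mean within-sample rank of the module's
    genes divided by the number of genes, hence in (0, 1] and invariant
    to any strictly increasing per-sample transform of expression.
    ``expression_sum`` scores are plain per-sample sums of module genes.
    """

    scores: pd.DataFrame
    scoring_mode: ScoringMode

    def sample_scores(self, module_id: str) -> pd.Series:
        return self.scores.loc[module_id]


def activity_scores(
    modules: Sequence[GeneModule],
    ds: ExpressionDataset,
    mode: ScoringMode = "rank_mean",
) -> ModuleActivityScores:
    """Per-sample activity score of each module in one dataset.

    Modules with fewer than half their genes present raise; partially
    present modules are scored on the present subset with a warning.
    """
    if mode not in ("rank_mean", "expression_sum"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    x = ds.values.to_numpy()
    gene_pos = {g: i for i, g in enumerate(ds.values.index)}
    n_genes = x.shape[0]
    if mode == "rank_mean":
        ranks = stats.rankdata(x, axis=0, method="average")
    rows = {}
    for mod in modules:
        present = [g for g in sorted(mod.gene_ids) if g in gene_pos]
        frac = len(present) / len(mod.gene_ids)
        if frac < 0.5:
            raise ValueError(
                f"module {mod.module_id!r}: only {len(present)}/{len(mod.gene_ids)} "
                f"genes present in {ds.dataset_id!r}"
            )
        if frac < 1.0:
            warnings.warn(
                f"module {mod.module_id}: scoring on {len(present)}/"
                f"{len(mod.gene_ids)} present genes",
                stacklevel=2,
            )
        idx = [gene_pos[g] for g in present]
        if mode == "rank_mean":
            rows[mod.module_id] = ranks[idx].mean(axis=0) / n_genes
        else:
            rows[mod.module_id] = x[idx].sum(axis=0)
    scores = pd.DataFrame.from_dict(rows, orient="index", columns=ds.sample_ids)
    scores.index.name = "module"
    return ModuleActivityScores(scores=scores, scoring_mode=mode)


def gene_module_correlation(
    scores: ModuleActivityScores, module_id: str, gene: str, ds: ExpressionDataset
) -> float:
    """Spearman rank correlation between a module's activity scores and
    one gene's expression across samples."""
    if gene not in ds.values.index:
        raise KeyError(f"gene {gene!r} not in dataset")
    s = scores.sample_scores(module_id).reindex(ds.sample_ids).to_numpy()
    g = ds.values.loc[gene].to_numpy()
    if np.ptp(g) == 0 or np.ptp(s) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, _ = stats.spearmanr(s, g)
    return float(rho)


def dichotomize_scores(scores: ModuleActivityScores, module_id: str) -> pd.Series:
    """Per-sample above/below-mean labels for one module's scores.

    A sample is 'above' only if its score is strictly greater than the
    module mean (all-equal scores are all 'below'). The labels are meant
    for export to external survival tooling.
    """
    s = scores.sample_scores(module_id)
    if len(s) < 2:
        raise ValueError("dichotomization needs at least 2 samples")
    return (s > s.mean()).map({True: "above", False: "below"}).rename(module_id)


# ---------------------------------------------------------------------------
# cross-dataset conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservedCore:
    """Genes of a module whose mutual correlations replicate elsewhere.

    ``conserved_edges`` are module-internal pairs above the cutoff in
    BOTH correlation matrices; ``core_genes`` is the largest connected
    component of the conserved-edge graph (empty when there are no
    conserved edges).
    """

    source_module: str
    conserved_edges: pd.DataFrame
    core_genes: frozenset[str]


def module_conservation(
    module: GeneModule,
    corr_source: CorrelationMatrix,
    corr_other: CorrelationMatrix,
    cutoff: float,
) -> ConservedCore:
    """Conserved core of a module across two correlation matrices."""
    genes = sorted(module.gene_ids)
    present = [g for g in genes if g in corr_source and g in corr_other]
    lost = len(genes) - len(present)
    if lost:
        log.warning(
            "module %s: %d genes absent from one of the matrices", module.module_id, lost
        )
    sub_s = corr_source.submatrix(present)
    sub_o = corr_other.submatrix(present)
    iu, ju = np.triu_indices(len(present), k=1)
    w_s = np.nan_to_num(sub_s[iu, ju], nan=-np.inf)
    w_o = np.nan_to_num(sub_o[iu, ju], nan=-np.inf)
    keep = (w_s > cutoff) & (w_o > cutoff)
    arr = np.asarray(present)
    edges = pd.DataFrame(
        {
            "gene_a": arr[iu[keep]],
            "gene_b": arr[ju[keep]],
            "weight_source": sub_s[iu, ju][keep],
            "weight_other": sub_o[iu, ju][keep],
        }
    )
    if len(edges):
        g = nx.Graph()
        g.add_edges_from(zip(edges["gene_a"], edges["gene_b"]))
        core = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
    else:
        core = set()
    return ConservedCore(
        source_module=module.module_id,
        conserved_edges=edges,
        core_genes=frozenset(core),
    )
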