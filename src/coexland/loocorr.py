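"""Leave-one-out minimum Pearson correlations and the permutation null.

The batch defense at the heart of the pipeline: with D datasets, every
gene pair gets D Pearson correlations, each computed on the samples of
the D-1 retained datasets pooled together. Only the minimum of these is
kept, and only if it is positive. A correlation driven by a single
study therefore collapses to ~0 in the run that excludes that study and
never makes it into the network.

The significance floor for edges comes from a permutation null: each
gene's values are permuted independently across all pooled samples,
destroying every gene-gene correlation while preserving marginals, and
the maximum pairwise correlation of the permuted matrix is recorded per
repetition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Cohort, standardize_rows

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Symmetric gene x gene matrix of edge weights.

    ``values`` holds NaN for absent pairs (filtered by the positivity or
    minimum rule), never zero: a zero weight and a filtered pair are
    different things. The diagonal is not meaningful and is stored NaN.
    """

    gene_ids: list[str]
    values: np.ndarray
    n_datasets: int = 1

    def __post_init__(self) -> None:
        m = len(self.gene_ids)
        if self.values.shape != (m, m):
            raise ValueError("correlation matrix shape does not match gene ids")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def weight(self, gene_a: str, gene_b: str) -> float:
        """Stored weight for a pair; NaN when the pair is absent."""
        return float(self.values[self._index[gene_a], self._index[gene_b]])

    def submatrix(self, genes) -> np.ndarray:
        idx = [self._index[g] for g in genes]
        return self.values[np.ix_(idx, idx)]

    def edge_list(self, floor: float = 0.0) -> pd.DataFrame:
        """Upper-triangle pairs with weight strictly above ``floor``."""
        iu, ju = np.triu_indices(len(self.gene_ids), k=1)
        w = self.values[iu, ju]
        keep = np.isfinite(w) & (w > floor)
        genes = np.asarray(self.gene_ids)
        return pd.DataFrame(
            {"gene_a": genes[iu[keep]], "gene_b": genes[ju[keep]], "weight": w[keep]}
        )

    @classmethod
    def from_dataset(cls, values: pd.DataFrame) -> "CorrelationMatrix":
        """Plain all-sample Pearson correlations of a genes x samples frame.

        No positivity filtering: negative correlations are kept (they
        simply never qualify at a positive cutoff). Constant genes get
        NaN rows.
        """
        z = standardize_rows(values.to_numpy())
        corr = z @ z.T
        np.clip(corr, -1.0, 1.0, out=corr)
        np.fill_diagonal(corr, np.nan)
        return cls(values.index.tolist(), corr, n_datasets=1)

    @classmethod
    def from_edge_list(
        cls, edges: pd.DataFrame, gene_ids: list[str] | None = None
    ) -> "CorrelationMatrix":
        """Rebuild a (sparse-in-NaN) matrix from a gene_a/gene_b/weight frame."""
        if gene_ids is None:
            gene_ids = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
        idx = {g: i for i, g in enumerate(gene_ids)}
        m = len(gene_ids)
        vals = np.full((m, m), np.nan)
        ia = edges["gene_a"].map(idx).to_numpy()
        ib = edges["gene_b"].map(idx).to_numpy()
        w = edges["weight"].to_numpy(dtype=float)
        vals[ia, ib] = w
        vals[ib, ia] = w
        return cls(gene_ids, vals, n_datasets=0)


@dataclass
class PermutationNull:
    """Result of the permutation significance procedure.

    ``threshold`` is the overall maximum random correlation across all
    repetitions (the conservative floor); the per-repetition maxima are
    kept so a quantile can be used instead.
    """

    n_perm: int
    seed: int | None
    per_perm_max: np.ndarray

    def __post_init__(self) -> None:
        if len(self.per_perm_max) != self.n_perm:
            raise ValueError("per_perm_max length must equal n_perm")

    @property
    def threshold(self) -> float:
        return float(np.max(self.per_perm_max))

    @property
    def median_max(self) -> float:
        """Median of the per-repetition maxima (the single-matrix statistic)."""
        return float(np.median(self.per_perm_max))

    def quantile(self, q: float) -> float:
        return float(np.quantile(self.per_perm_max, q))


def max_offdiag_correlation(x: np.ndarray) -> float:
    """Maximum absolute pairwise Pearson correlation between rows of ``x``.

    The magnitude is the two-sided statistic: a negative correlation of
    the same size is equally significant under the permutation null.
    """
    z = standardize_rows(np.asarray(x, dtype=np.float64))
    corr = z @ z.T
    np.fill_diagonal(corr, 0.0)
    return float(np.nanmax(np.abs(corr)))


def loo_min_correlation(cohort: Cohort, min_samples: int = 30) -> CorrelationMatrix:
    """Leave-one-out minimum Pearson correlation for every gene pair.

    For each of the D datasets, correlations are computed on the pooled
    samples of the other D-1 datasets; the elementwise minimum over the D
    runs is stored. Pairs whose minimum is <= 0 are marked absent (NaN),
    as are pairs involving a gene that is constant in some pool.
    """
    if cohort.n_datasets < 2:
        raise ValueError("leave-one-out correlation needs at least 2 datasets")
    m = cohort.n_genes
    min_corr = np.full((m, m), np.inf)
    had_nan = np.zeros(m, dtype=bool)
    for ds_id in cohort.dataset_ids:
        pool = cohort.pooled_values(exclude=ds_id)
        if pool.shape[1] < min_samples:
            raise ValueError(
                f"pool excluding {ds_id!r} has {pool.shape[1]} samples "
                f"(< min_samples={min_samples})"
            )
        z = standardize_rows(pool.to_numpy())
        constant = ~np.isfinite(z).all(axis=1)
        if constant.any():
            log.warning(
                "%d genes constant in pool excluding %s; their pairs are dropped",
                int(constant.sum()), ds_id,
            )
            had_nan |= constant
            z = np.nan_to_num(z)
        corr = z @ z.T
        np.clip(corr, -1.0, 1.0, out=corr)
        np.minimum(min_corr, corr, out=min_corr)
    min_corr[min_corr <= 0] = np.nan
    min_corr[had_nan, :] = np.nan
    min_corr[:, had_nan] = np.nan
    np.fill_diagonal(min_corr, np.nan)
    return CorrelationMatrix(cohort.gene_ids, min_corr, n_datasets=cohort.n_datasets)


def permutation_threshold(
    cohort: Cohort | pd.DataFrame, n_perm: int = 1000, seed: int | None = None
) -> PermutationNull:
    """Permutation null for the maximum pairwise correlation.

    Each repetition independently permutes every gene's values across all
    pooled samples and records the maximum absolute pairwise Pearson
    correlation of the permuted matrix (two-sided, matching the use of
    the threshold as a significance floor). Reproducible given ``seed``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    values = cohort.pooled_values() if isinstance(cohort, Cohort) else cohort
    x = values.to_numpy(dtype=np.float64)
    rng = np.random.default_rng(seed)
    maxima = np.empty(n_perm)
    for i in range(n_perm):
        maxima[i] = max_offdiag_correlation(rng.permuted(x, axis=1))
    return PermutationNull(n_perm=n_perm, seed=seed, per_perm_max=maxima)
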