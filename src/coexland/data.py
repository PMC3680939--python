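"""Core in-memory containers for multi-study expression cohorts.

Expression values live in pandas DataFrames oriented genes x samples.
A :class:`Cohort` holds several studies with an identical gene index so
that leave-one-out operations can pool samples across the remaining
studies without realignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: annotation columns the pipeline knows about; extra columns are carried
#: through untouched.
KNOWN_ANNOTATIONS = (
    "subtype",
    "er_status",
    "tp53_status",
    "tp53_expression",
    "node_status",
    "tumor_size",
    "grade",
)


@dataclass
class ExpressionDataset:
    """One study's genes x samples expression matrix plus sample annotations.

    Parameters
    ----------
    dataset_id
        Identifier of the study (e.g. a GEO series accession).
    values
        Normalized expression, genes as rows, samples as columns. Gene and
        sample identifiers must be unique and no value may be missing.
    annotations
        Optional per-sample table indexed by sample id; reindexed to the
        sample order of ``values`` on construction.
    """

    dataset_id: str
    values: pd.DataFrame
    annotations: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene ids in {self.dataset_id!r}: {dup}")
        if not self.values.columns.is_unique:
            raise ValueError(f"duplicate sample ids in {self.dataset_id!r}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)][:5].tolist()
            raise ValueError(
                f"missing values in {self.dataset_id!r} (first genes: {bad}); "
                "complete matrices are required"
            )
        if self.annotations is not None:
            missing = self.values.columns.difference(self.annotations.index)
            if len(missing):
                raise ValueError(
                    f"annotations for {self.dataset_id!r} lack samples: "
                    f"{missing[:5].tolist()}"
                )
            self.annotations = self.annotations.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionDataset":
        return ExpressionDataset(
            self.dataset_id, self.values.loc[list(genes)], self.annotations
        )

    def subset_samples(self, samples) -> "ExpressionDataset":
        samples = list(samples)
        ann = self.annotations.loc[samples] if self.annotations is not None else None
        return ExpressionDataset(self.dataset_id, self.values[samples], ann)


@dataclass
class Cohort:
    """Ordered collection of datasets sharing one gene index.

    All member datasets must have byte-identical gene id ordering; this is
    what makes pooled and leave-one-out views cheap column concatenations.
    """

    datasets: list[ExpressionDataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("cohort needs at least one dataset")
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate dataset ids: {ids}")
        ref = self.datasets[0].values.index
        for d in self.datasets[1:]:
            if not ref.equals(d.values.index):
                raise ValueError(
                    f"dataset {d.dataset_id!r} gene ordering differs from "
                    f"{self.datasets[0].dataset_id!r}; use align_datasets first"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.datasets[0].gene_ids

    @property
    def n_genes(self) -> int:
        return len(self.datasets[0].values.index)

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)

    @property
    def n_samples(self) -> int:
        return sum(d.n_samples for d in self.datasets)

    @property
    def dataset_ids(self) -> list[str]:
        return [d.dataset_id for d in self.datasets]

    def pooled_values(self, exclude: str | None = None) -> pd.DataFrame:
        """Concatenate sample columns across datasets.

        Sample ids are prefixed ``<dataset_id>:`` to stay unique. With
        ``exclude`` set, that dataset is left out (the leave-one-out pool).
        """
        parts = []
        for d in self.datasets:
            if d.dataset_id == exclude:
                continue
            v = d.values.copy()
            v.columns = [f"{d.dataset_id}:{s}" for s in v.columns]
            parts.append(v)
        if not parts:
            raise ValueError("no datasets left after exclusion")
        return pd.concat(parts, axis=1)

    def pooled_annotations(self) -> pd.DataFrame:
        """Concatenate annotations with prefixed sample ids; adds a
        ``dataset`` column."""
        parts = []
        for d in self.datasets:
            ann = (
                d.annotations.copy()
                if d.annotations is not None
                else pd.DataFrame(index=d.values.columns)
            )
            ann.index = [f"{d.dataset_id}:{s}" for s in ann.index]
            ann["dataset"] = d.dataset_id
            parts.append(ann)
        return pd.concat(parts, axis=0)

    def subset_genes(self, genes) -> "Cohort":
        return Cohort([d.subset_genes(genes) for d in self.datasets])


def pooled_sd(cohort: Cohort, ddof: int = 1) -> pd.Series:
    """Per-gene standard deviation over all samples pooled across datasets."""
    pooled = cohort.pooled_values()
    return pooled.std(axis=1, ddof=ddof)


def standardize_rows(x: np.ndarray) -> np.ndarray:
    """Center and scale rows to unit norm; constant rows become NaN rows."""
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean(axis=1, keepdims=True)
    norm = np.sqrt((x * x).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = x / norm
    out[np.broadcast_to(norm == 0, out.shape)] = np.nan
    return out
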