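"""Probe-to-gene collapsing, centering, variance filtering and alignment.

The pipeline consumes already-normalized probe-level matrices. Probes that
cross-hybridize or that map to more than one gene are discarded; the
remaining probes for a gene are averaged. Non-varying genes are removed
with a pooled-standard-deviation filter before any correlation is
computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import pandas as pd

from .data import Cohort, ExpressionDataset

log = logging.getLogger(__name__)

CenterMode = Literal["per_gene_global", "per_gene_within_dataset", "none"]


@dataclass
class ProbeGeneMap:
    """Probe id -> (gene ids, cross-hybridization flag).

    Every probe must map to at least one gene. Probes flagged as
    cross-hybridizing, or mapping to more than one gene, are removed
    during collapsing.
    """

    mapping: Mapping[str, tuple[frozenset[str], bool]]

    def __post_init__(self) -> None:
        for probe, (genes, _) in self.mapping.items():
            if not genes:
                raise ValueError(f"probe {probe!r} maps to no gene")

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def __getitem__(self, probe: str) -> tuple[frozenset[str], bool]:
        return self.mapping[probe]

    @classmethod
    def from_records(cls, records) -> "ProbeGeneMap":
        """Build from iterable of (probe_id, gene_ids, crosshyb) where
        gene_ids is an iterable of gene ids."""
        return cls(
            {p: (frozenset(g), bool(x)) for p, g, x in records}
        )


@dataclass
class PreprocessConfig:
    """Knobs for the preprocessing stage.

    sd_cutoff
        Genes are kept only if their pooled-sample standard deviation is
        strictly greater than this value (default 1.0 on log-scale
        expression).
    center_mode
        ``per_gene_global`` subtracts each gene's mean over all pooled
        samples, ``per_gene_within_dataset`` centers inside each study,
        ``none`` leaves values untouched.
    """

    sd_cutoff: float = 1.0
    center_mode: CenterMode = "per_gene_global"

    def __post_init__(self) -> None:
        if self.sd_cutoff < 0:
            raise ValueError("sd_cutoff must be >= 0")
        if self.center_mode not in ("per_gene_global", "per_gene_within_dataset", "none"):
            raise ValueError(f"unknown center_mode {self.center_mode!r}")


def merge_probes_to_genes(
    probes: pd.DataFrame,
    probe_map: ProbeGeneMap,
    dataset_id: str = "dataset",
    annotations: pd.DataFrame | None = None,
) -> ExpressionDataset:
    """Collapse a probes x samples matrix to genes x samples.

    Probes flagged as cross-hybridizing or mapping to more than one gene
    are dropped; each gene row is the arithmetic mean of its surviving
    probes. Raises if a probe is absent from the map or if no probe
    survives.
    """
    unmapped = [p for p in probes.index if p not in probe_map]
    if unmapped:
        raise KeyError(f"probes missing from probe map: {unmapped[:5]}")

    keep_probe: list[str] = []
    keep_gene: list[str] = []
    for probe in probes.index:
        genes, crosshyb = probe_map[probe]
        if crosshyb or len(genes) != 1:
            continue
        keep_probe.append(probe)
        (gene,) = genes
        keep_gene.append(gene)

    if not keep_probe:
        raise ValueError("all probes were discarded (cross-hybridizing or multi-gene)")

    surviving = probes.loc[keep_probe]
    merged = surviving.groupby(pd.Index(keep_gene, name="gene"), sort=True).mean()
    n_dropped = probes.shape[0] - len(keep_probe)
    log.info(
        "merged %d probes into %d genes (%d probes discarded)",
        len(keep_probe), merged.shape[0], n_dropped,
    )
    return ExpressionDataset(dataset_id, merged, annotations)


def mean_center(
    data: ExpressionDataset | Cohort, cfg: PreprocessConfig | None = None
) -> ExpressionDataset | Cohort:
    """Center each gene row according to ``cfg.center_mode``.

    For a cohort, ``per_gene_global`` subtracts the gene mean computed
    over all samples pooled across datasets, so downstream pooled
    statistics see mean-zero genes; ``per_gene_within_dataset`` centers
    each study on its own. For a single dataset the two modes coincide.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.center_mode == "none":
        return data
    if isinstance(data, ExpressionDataset):
        centered = data.values.sub(data.values.mean(axis=1), axis=0)
        return ExpressionDataset(data.dataset_id, centered, data.annotations)

    if cfg.center_mode == "per_gene_within_dataset":
        return Cohort([mean_center(d, cfg) for d in data.datasets])

    # pooled gene means; weights are per-dataset sample counts
    total = sum(d.values.sum(axis=1) for d in data.datasets)
    gene_mean = total / data.n_samples
    out = [
        ExpressionDataset(d.dataset_id, d.values.sub(gene_mean, axis=0), d.annotations)
        for d in data.datasets
    ]
    return Cohort(out)


def variance_filter(cohort: Cohort, cfg: PreprocessConfig | None = None) -> Cohort:
    """Keep genes whose pooled-sample SD is strictly above ``cfg.sd_cutoff``.

    The SD uses the n-1 denominator and is computed over all samples of
    all datasets pooled together. Gene order is preserved. Raises if no
    gene passes, reporting the observed SD range.
    """
    cfg = cfg or PreprocessConfig()
    sd = cohort.pooled_values().std(axis=1, ddof=1)
    keep = sd.index[sd > cfg.sd_cutoff]
    if len(keep) == 0:
        raise ValueError(
            f"no gene has pooled SD > {cfg.sd_cutoff}; observed SD range "
            f"[{sd.min():.4g}, {sd.max():.4g}]"
        )
    log.info("variance filter kept %d/%d genes", len(keep), cohort.n_genes)
    return cohort.subset_genes(keep)


def align_datasets(datasets: list[ExpressionDataset]) -> Cohort:
    """Restrict all datasets to their common genes, identically ordered.

    Gene order follows the first dataset. Logs per-dataset counts of
    dropped genes; raises if the intersection is empty.
    """
    if len(datasets) < 2:
        raise ValueError("alignment needs at least two datasets")
    common = datasets[0].values.index
    for d in datasets[1:]:
        common = common[common.isin(d.values.index)]
    if len(common) == 0:
        raise ValueError("gene intersection across datasets is empty")
    for d in datasets:
        dropped = d.values.shape[0] - len(common)
        if dropped:
            log.info("align: dropped %d genes from %s", dropped, d.dataset_id)
    return Cohort([d.subset_genes(common) for d in datasets])
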