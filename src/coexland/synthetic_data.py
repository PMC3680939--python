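"""Synthetic multi-dataset cohorts with planted co-expression structure.

A Gaussian factor model generates everything the pipeline estimates,
with closed-form targets: a gene in a module with within-module
correlation ``rho`` is

    value = sqrt(rho) * module_factor(sample) + sqrt(1 - rho) * noise

so the expected correlation of two module genes is ``rho``, and two
genes of modules coupled at factor correlation ``tau`` correlate at
``tau * sqrt(rho_i * rho_j)``. Couplings can depend on a per-sample
covariate (e.g. TP53 status), emulating subgroup-specific module
interconnection. A per-dataset artifact module shares a factor only
inside one study — the planted input for leave-one-out batch-defense
tests — and additive per-(dataset, gene) batch shifts are available.

The default configuration is the benchmark scenario used throughout the
test suite: 4 datasets x 150 samples, 500 genes, 8 modules of sizes
10-30 with rho between 0.65 and 0.85 (larger modules get the lower
correlations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Cohort, ExpressionDataset
from .screen import ScreenData

#: benchmark module layout: (size, within-module correlation)
DEFAULT_MODULES: tuple[tuple[int, float], ...] = (
    (30, 0.65),
    (25, 0.68),
    (22, 0.70),
    (20, 0.72),
    (18, 0.75),
    (15, 0.78),
    (12, 0.80),
    (10, 0.85),
)


@dataclass(frozen=True)
class ModuleSpec:
    size: int
    rho: float

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class CrossCoupling:
    """Factor correlation ``tau`` between two modules.

    ``tau_alt``, when set, replaces ``tau_base`` for samples whose
    covariate label is the alternative state (e.g. TP53-mutant).
    """

    module_i: int
    module_j: int
    tau_base: float
    tau_alt: float | None = None

    def __post_init__(self) -> None:
        if self.module_i == self.module_j:
            raise ValueError("coupling needs two distinct modules")
        for tau in (self.tau_base, self.tau_alt):
            if tau is not None and not 0 <= tau < 1:
                raise ValueError("tau must lie in [0, 1)")


@dataclass(frozen=True)
class ArtifactModule:
    """Genes sharing a factor only inside one dataset (a batch artifact)."""

    size: int
    rho: float
    dataset_index: int = 0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_datasets: int = 4
    samples_per_dataset: int = 150
    n_genes: int = 500
    modules: tuple[tuple[int, float], ...] = DEFAULT_MODULES
    cross_couplings: tuple[CrossCoupling, ...] = ()
    batch_shift_sd: float = 0.0
    artifact_module: ArtifactModule | None = None
    score_amplitude: bool = False
    covariate_name: str = "tp53_status"
    covariate_fraction: float = 0.3
    seed: int = 0

    def module_specs(self) -> list[ModuleSpec]:
        return [ModuleSpec(int(s), float(r)) for s, r in self.modules]

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")
        specs = self.module_specs()
        planted = sum(m.size for m in specs)
        if self.artifact_module is not None:
            planted += self.artifact_module.size
            if not 0 <= self.artifact_module.dataset_index < self.n_datasets:
                raise ValueError("artifact dataset index out of range")
        if planted > self.n_genes:
            raise ValueError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if not 0 <= self.covariate_fraction <= 1:
            raise ValueError("covariate_fraction must lie in [0, 1]")
        for c in self.cross_couplings:
            if not (0 <= c.module_i < len(specs) and 0 <= c.module_j < len(specs)):
                raise ValueError("coupling references unknown module index")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a generated cohort."""

    module_genes: dict[str, list[str]]
    artifact_genes: list[str]
    artifact_dataset: str | None
    factors: pd.DataFrame  # modules x pooled samples (dataset-prefixed ids)
    amplitudes: pd.DataFrame | None
    covariates: pd.Series  # pooled sample id -> covariate label
    config: SyntheticCohortConfig

    def gene_labels(self) -> pd.Series:
        """Per-gene module assignment ('' for background genes)."""
        labels = {}
        for mid, genes in self.module_genes.items():
            for g in genes:
                labels[g] = mid
        for g in self.artifact_genes:
            labels[g] = "artifact"
        return pd.Series(labels, name="module")

    def to_json(self) -> str:
        payload = {
            "module_genes": self.module_genes,
            "artifact_genes": self.artifact_genes,
            "artifact_dataset": self.artifact_dataset,
            "covariates": self.covariates.to_dict(),
            "seed": self.config.seed,
        }
        return json.dumps(payload, indent=1)


def _factor_cholesky(cfg: SyntheticCohortConfig, alt: bool) -> np.ndarray:
    n_mod = len(cfg.modules)
    sigma = np.eye(n_mod)
    for c in cfg.cross_couplings:
        tau = c.tau_alt if (alt and c.tau_alt is not None) else c.tau_base
        sigma[c.module_i, c.module_j] = tau
        sigma[c.module_j, c.module_i] = tau
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "cross-coupling correlation matrix is not positive definite"
        ) from err


def generate_cohort(
    cfg: SyntheticCohortConfig | None = None,
) -> tuple[Cohort, SyntheticTruth]:
    """Generate a multi-dataset cohort and its ground truth.

    Fully reproducible from ``cfg.seed``. Module genes occupy the first
    gene ids in module order, artifact genes follow, and the remaining
    genes are independent standard-normal background.
    """
    cfg = cfg or SyntheticCohortConfig()
    specs = cfg.module_specs()
    rng = np.random.default_rng(cfg.seed)

    width = max(4, len(str(cfg.n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(cfg.n_genes)]
    module_genes: dict[str, list[str]] = {}
    pos = 0
    for i, spec in enumerate(specs):
        module_genes[f"M{i + 1}"] = genes[pos : pos + spec.size]
        pos += spec.size
    artifact_genes: list[str] = []
    if cfg.artifact_module is not None:
        artifact_genes = genes[pos : pos + cfg.artifact_module.size]
        pos += cfg.artifact_module.size

    chol_base = _factor_cholesky(cfg, alt=False)
    chol_alt = _factor_cholesky(cfg, alt=True)
    n_mod = len(specs)

    datasets: list[ExpressionDataset] = []
    factor_cols: list[pd.DataFrame] = []
    covariate_parts: list[pd.Series] = []
    artifact_ds_id: str | None = None

    for d in range(cfg.n_datasets):
        ds_id = f"D{d + 1}"
        n = cfg.samples_per_dataset
        samples = [f"s{j + 1:03d}" for j in range(n)]
        is_alt = rng.random(n) < cfg.covariate_fraction
        raw = rng.standard_normal((n_mod, n))
        factors = np.empty_like(raw)
        if is_alt.any():
            factors[:, is_alt] = chol_alt @ raw[:, is_alt]
        if (~is_alt).any():
            factors[:, ~is_alt] = chol_base @ raw[:, ~is_alt]

        x = rng.standard_normal((cfg.n_genes, n))  # background noise for all genes
        row = 0
        for i, spec in enumerate(specs):
            x[row : row + spec.size] = (
                np.sqrt(spec.rho) * factors[i]
                + np.sqrt(1 - spec.rho) * x[row : row + spec.size]
            )
            row += spec.size
        if cfg.artifact_module is not None:
            size, rho_a = cfg.artifact_module.size, cfg.artifact_module.rho
            if d == cfg.artifact_module.dataset_index:
                artifact_ds_id = ds_id
                f_art = rng.standard_normal(n)
                x[row : row + size] = (
                    np.sqrt(rho_a) * f_art + np.sqrt(1 - rho_a) * x[row : row + size]
                )
            row += size
        if cfg.batch_shift_sd > 0:
            x += rng.normal(0.0, cfg.batch_shift_sd, size=(cfg.n_genes, 1))

        values = pd.DataFrame(x, index=genes, columns=samples)
        labels = np.where(is_alt, "mut", "wt")
        annotations = pd.DataFrame({cfg.covariate_name: labels}, index=samples)
        datasets.append(ExpressionDataset(ds_id, values, annotations))

        prefixed = [f"{ds_id}:{s}" for s in samples]
        factor_cols.append(
            pd.DataFrame(factors, index=list(module_genes), columns=prefixed)
        )
        covariate_parts.append(
            pd.Series(labels, index=prefixed, name=cfg.covariate_name)
        )

    factors_all = pd.concat(factor_cols, axis=1)
    truth = SyntheticTruth(
        module_genes=module_genes,
        artifact_genes=artifact_genes,
        artifact_dataset=artifact_ds_id,
        factors=factors_all,
        amplitudes=factors_all if cfg.score_amplitude else None,
        covariates=pd.concat(covariate_parts),
        config=cfg,
    )
    return Cohort(datasets), truth


def generate_screen(
    n_genes: int = 5000,
    effect_modules: Sequence[tuple[Sequence[str], float]] = (),
    noise_sd: float = 1.0,
    n_controls: int = 5,
    control_shift: float = 0.0,
    baseline: float = 10.0,
    seed: int | None = None,
) -> ScreenData:
    """Synthetic knockdown screen: one intensity per gene.

    Intensity = ``baseline + shift(gene) + Normal(0, noise_sd)``. Genes
    named ``g0001..`` match the cohort generator's naming so planted
    cohort modules can be tested directly; controls are named ``ctrl*``
    and shifted by ``control_shift``.
    """
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_genes)))
    genes = [f"g{i + 1:0{width}d}" for i in range(n_genes)]
    gene_set = set(genes)
    shifts = pd.Series(0.0, index=genes)
    seen: set[str] = set()
    for module_genes, shift in effect_modules:
        module_genes = list(module_genes)
        unknown = [g for g in module_genes if g not in gene_set]
        if unknown:
            raise ValueError(f"effect genes outside the screen: {unknown[:5]}")
        if seen & set(module_genes):
            raise ValueError("effect gene sets must be disjoint")
        seen |= set(module_genes)
        shifts.loc[module_genes] = shift

    intensities = baseline + shifts + rng.normal(0.0, noise_sd, size=n_genes)
    controls = [f"ctrl{i + 1}" for i in range(n_controls)]
    ctrl_vals = baseline + control_shift + rng.normal(0.0, noise_sd, size=n_controls)
    all_vals = pd.concat(
        [intensities, pd.Series(ctrl_vals, index=controls)]
    ).rename("intensity")
    return ScreenData(all_vals, frozenset(controls))
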