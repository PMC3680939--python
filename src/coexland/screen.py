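"""Module-level testing of arrayed siRNA knockdown screens.

The screen readout is one log-transformed Ki-67 staining intensity per
targeted gene (lower intensity = reduced proliferation after knockdown).
A module's mean intensity is compared to a resampled null of same-size
gene groups drawn from the screened library; the default alternative is
one-sided toward reduced intensity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .network import GeneModule

log = logging.getLogger(__name__)

Alternative = Literal["less", "greater", "two-sided"]


@dataclass
class ScreenData:
    """One intensity per gene plus the set of non-specific control ids.

    ``intensities`` is indexed by gene id; replicate rows for a gene are
    collapsed by median via :meth:`from_frame`.
    """

    intensities: pd.Series
    control_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.intensities.index.is_unique:
            raise ValueError("gene ids must be unique (collapse replicates first)")
        if not np.isfinite(self.intensities.to_numpy()).all():
            raise ValueError("intensities must be finite")
        self.intensities = self.intensities.rename_axis("gene_id").rename("intensity")
        self.control_ids = frozenset(self.control_ids)
        unknown = self.control_ids - set(self.intensities.index)
        if unknown:
            raise ValueError(f"control ids not in screen: {sorted(unknown)[:5]}")

    @property
    def library_genes(self) -> pd.Index:
        """Screened genes excluding controls."""
        return self.intensities.index.difference(self.control_ids, sort=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ScreenData":
        """Build from a frame with columns gene_id, intensity, is_control.

        Multiple rows per gene (replicate siRNAs) are collapsed by
        median; a gene is a control if any of its rows is flagged.
        """
        grouped = df.groupby("gene_id", sort=True)
        intensities = grouped["intensity"].median()
        flags = grouped["is_control"].max().astype(bool)
        return cls(intensities, frozenset(flags.index[flags]))


@dataclass
class ScreenResult:
    """Outcome of a module-level resampling test."""

    module_id: str
    observed_mean: float
    centered_mean: float
    null_means: np.ndarray
    p_one_sided: float
    alternative: Alternative
    n_genes_used: int


def module_knockdown_test(
    screen: ScreenData,
    module: GeneModule | Iterable[str],
    n_samples: int = 10000,
    seed: int | None = None,
    exclude_controls: bool = True,
    alternative: Alternative = "less",
) -> ScreenResult:
    """Compare a module's mean intensity to same-size random gene groups.

    Null groups are drawn uniformly without replacement from the screened
    genes (library genes only when ``exclude_controls``). The default
    one-sided p asks whether knockdown of the module reduced intensity;
    ``centered_mean`` is the observed mean minus the null mean, matching
    the centering used for plotting.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if isinstance(module, GeneModule):
        genes, mid = sorted(module.gene_ids), module.module_id
    else:
        genes, mid = sorted(set(module)), "module"
    present = [g for g in genes if g in screen.intensities.index]
    if not present:
        raise ValueError(f"no genes of module {mid!r} were screened")
    missing = sorted(set(genes) - set(present))
    if missing:
        log.warning(
            "module %s: %d/%d genes not screened: %s",
            mid, len(missing), len(genes), missing[:10],
        )

    universe = screen.library_genes if exclude_controls else screen.intensities.index
    vals = screen.intensities.loc[universe].to_numpy(dtype=np.float64)
    m = len(present)
    if m > len(vals):
        raise ValueError("module larger than the sampling universe")
    observed = float(screen.intensities.loc[present].mean())

    rng = np.random.default_rng(seed)
    draws = np.empty((n_samples, m), dtype=np.intp)
    for i in range(n_samples):
        draws[i] = rng.choice(len(vals), size=m, replace=False)
    null = vals[draws].mean(axis=1)

    n_low = int((null <= observed).sum())
    n_high = int((null >= observed).sum())
    if alternative == "less":
        p = (1 + n_low) / (1 + n_samples)
    elif alternative == "greater":
        p = (1 + n_high) / (1 + n_samples)
    else:
        p = min(1.0, 2 * (1 + min(n_low, n_high)) / (1 + n_samples))
    return ScreenResult(
        module_id=mid,
        observed_mean=observed,
        centered_mean=observed - float(null.mean()),
        null_means=null,
        p_one_sided=p,
        alternative=alternative,
        n_genes_used=m,
    )


def control_group_test(
    screen: ScreenData,
    n_samples: int = 10000,
    seed: int | None = None,
    alternative: Alternative = "less",
) -> ScreenResult:
    """Run the module test on the screen's non-specific controls.

    The controls are treated as a module and compared to the full-library
    null; a positive ``centered_mean`` indicates the bulk of the library
    reduced proliferation more than the controls did.
    """
    if not screen.control_ids:
        raise ValueError("screen has no flagged controls")
    result = module_knockdown_test(
        screen,
        sorted(screen.control_ids),
        n_samples=n_samples,
        seed=seed,
        exclude_controls=True,
        alternative=alternative,
    )
    result.module_id = "controls"
    return result
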