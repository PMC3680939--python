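"""Thresholded, degree-pruned co-expression networks and landscape coordinates.

A network at cutoff ``c`` connects gene pairs whose stored (minimum
leave-one-out) correlation is strictly above ``c``; nodes with fewer
than ``k`` neighbors are then pruned. Iterative pruning yields the
k-core, the maximal subgraph with minimum degree >= k. Modules are the
connected components of the pruned graph. Each gene's landscape height
(z) is the highest cutoff on a grid at which it is still in a network;
x/y come from a weighted spring-embedded layout of the base network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .loocorr import CorrelationMatrix

#: cutoff grid used for landscape heights
DEFAULT_GRID: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.7)

PruneMode = Literal["iterative_kcore", "single_pass"]


@dataclass
class NetworkConfig:
    cutoff: float = 0.6
    min_neighbors: int = 5
    prune_mode: PruneMode = "iterative_kcore"

    def __post_init__(self) -> None:
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must lie in (0, 1)")
        if self.min_neighbors < 0:
            raise ValueError("min_neighbors must be >= 0")
        if self.prune_mode not in ("iterative_kcore", "single_pass"):
            raise ValueError(f"unknown prune_mode {self.prune_mode!r}")


@dataclass
class CoexpressionNetwork:
    """Undirected weighted graph of genes surviving threshold + pruning."""

    graph: nx.Graph
    cutoff: float
    prune_mode: PruneMode

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (min(a, b), max(a, b), d["weight"])
            for a, b, d in self.graph.edges(data=True)
        ]
        rows.sort()
        return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


@dataclass
class GeneModule:
    """A named set of co-expressed genes extracted from one network."""

    module_id: str
    gene_ids: frozenset[str]
    label: str = ""
    source_cutoff: float | None = None

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("module must contain at least one gene")
        self.gene_ids = frozenset(self.gene_ids)

    def __len__(self) -> int:
        return len(self.gene_ids)


def _thresholded_graph(corr: CorrelationMatrix, cutoff: float) -> nx.Graph:
    g = nx.Graph()
    iu, ju = np.triu_indices(len(corr.gene_ids), k=1)
    w = corr.values[iu, ju]
    keep = np.isfinite(w) & (w > cutoff)
    genes = np.asarray(corr.gene_ids)
    g.add_weighted_edges_from(
        zip(genes[iu[keep]], genes[ju[keep]], w[keep].astype(float))
    )
    return g


def build_network(corr: CorrelationMatrix, cfg: NetworkConfig) -> CoexpressionNetwork:
    """Threshold at ``cfg.cutoff`` (strict >) and prune low-degree genes.

    ``iterative_kcore`` repeatedly removes nodes of degree < k until
    stable (the k-core); ``single_pass`` removes them once, judged on the
    unpruned thresholded graph, then drops any node left isolated. An
    empty network is a valid result.
    """
    g = _thresholded_graph(corr, cfg.cutoff)
    k = cfg.min_neighbors
    if cfg.prune_mode == "iterative_kcore":
        g = nx.k_core(g, k) if g.number_of_nodes() else g
    else:
        low = [n for n, deg in g.degree if deg < k]
        g.remove_nodes_from(low)
        g.remove_nodes_from([n for n, deg in g.degree if deg == 0])
    return CoexpressionNetwork(graph=g, cutoff=cfg.cutoff, prune_mode=cfg.prune_mode)


def extract_modules(
    net: CoexpressionNetwork, min_size: int = 6
) -> list[GeneModule]:
    """Connected components with >= ``min_size`` genes, largest first.

    The default minimum of 6 is the smallest possible 5-core. Ordering is
    deterministic: by decreasing size, ties broken by sorted gene ids.
    """
    comps = [
        tuple(sorted(c))
        for c in nx.connected_components(net.graph)
        if len(c) >= min_size
    ]
    comps.sort(key=lambda c: (-len(c), c))
    return [
        GeneModule(module_id=f"M{i + 1}", gene_ids=frozenset(c),
                   source_cutoff=net.cutoff)
        for i, c in enumerate(comps)
    ]


def landscape_z(
    corr: CorrelationMatrix,
    grid: Sequence[float] = DEFAULT_GRID,
    cfg: NetworkConfig | None = None,
) -> pd.Series:
    """Highest grid cutoff at which each gene is in a pruned network.

    Genes absent from every network get the sentinel 0. The k-core is
    monotone under edge addition, so membership at a cutoff implies
    membership at every smaller cutoff and the maximum is well defined.
    """
    grid = sorted(grid)
    cfg = cfg or NetworkConfig()
    z = pd.Series(0.0, index=pd.Index(corr.gene_ids, name="gene"), name="z")
    for cutoff in grid:
        net = build_network(
            corr,
            NetworkConfig(cutoff=cutoff, min_neighbors=cfg.min_neighbors,
                          prune_mode=cfg.prune_mode),
        )
        if net.graph.number_of_nodes():
            z.loc[list(net.graph.nodes)] = cutoff
    return z


def layout_xy(net: CoexpressionNetwork, seed: int | None = None) -> pd.DataFrame:
    """Spring-embedded layout using correlations as edge weights.

    Coordinates are rescaled to a unit bounding box centered on the
    origin; deterministic given ``seed``.
    """
    if net.graph.number_of_nodes() == 0:
        raise ValueError("cannot lay out an empty network")
    pos = nx.spring_layout(net.graph, weight="weight", seed=seed)
    coords = pd.DataFrame(pos).T
    coords.columns = ["x", "y"]
    coords.index.name = "gene"
    span = coords.max() - coords.min()
    center = (coords.max() + coords.min()) / 2
    scale = max(float(span.max()), 0.0)
    coords = coords - center
    if scale > 0:
        coords = coords / scale
    return coords.sort_index()


def landscape_coordinates(
    corr: CorrelationMatrix,
    grid: Sequence[float] = DEFAULT_GRID,
    cfg: NetworkConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Full (x, y, z) landscape table for the base-cutoff network.

    x/y come from the layout of the network at the smallest grid cutoff;
    z is the highest grid cutoff of network membership. Only genes in the
    base network appear.
    """
    grid = sorted(grid)
    cfg = cfg or NetworkConfig()
    base = build_network(
        corr,
        NetworkConfig(cutoff=grid[0], min_neighbors=cfg.min_neighbors,
                      prune_mode=cfg.prune_mode),
    )
    coords = layout_xy(base, seed=seed)
    z = landscape_z(corr, grid, cfg)
    coords["z"] = z.reindex(coords.index)
    return coords
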