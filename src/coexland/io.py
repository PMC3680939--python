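"""Plain-text readers and writers for the formats the pipeline exchanges.

Expression matrices are TSV with a gene/probe id first column and sample
ids in the header. Probe maps are TSV (probe_id, gene_ids
semicolon-separated, crosshyb 0/1). Modules travel as GMT lines
(module_id, label, genes...). Screens are TSV (gene_id, intensity,
is_control 0/1).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .data import ExpressionDataset
from .network import GeneModule
from .preprocess import ProbeGeneMap
from .screen import ScreenData


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_expression_tsv(values: pd.DataFrame, path: str | os.PathLike) -> None:
    values.to_csv(path, sep="\t", index_label="gene")


def read_annotations_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})


def read_dataset(
    matrix_path: str | os.PathLike,
    annotations_path: str | os.PathLike | None = None,
    dataset_id: str | None = None,
) -> ExpressionDataset:
    values = read_expression_tsv(matrix_path)
    ann = read_annotations_tsv(annotations_path) if annotations_path else None
    if dataset_id is None:
        dataset_id = Path(matrix_path).stem
    return ExpressionDataset(dataset_id, values, ann)


def read_probe_map(path: str | os.PathLike) -> ProbeGeneMap:
    df = pd.read_csv(
        path, sep="\t", dtype={"probe_id": str, "gene_ids": str, "crosshyb": int}
    )
    records = (
        (row.probe_id, row.gene_ids.split(";"), bool(row.crosshyb))
        for row in df.itertuples()
    )
    return ProbeGeneMap.from_records(records)


def write_probe_map(probe_map: ProbeGeneMap, path: str | os.PathLike) -> None:
    rows = [
        {"probe_id": p, "gene_ids": ";".join(sorted(g)), "crosshyb": int(x)}
        for p, (g, x) in probe_map.mapping.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_list(edges: pd.DataFrame, path: str | os.PathLike) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", dtype={"gene_a": str, "gene_b": str, "weight": float}
    )


def write_gmt(modules: Sequence[GeneModule], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for mod in modules:
            genes = "\t".join(sorted(mod.gene_ids))
            fh.write(f"{mod.module_id}\t{mod.label}\t{genes}\n")


def read_gmt(path: str | os.PathLike) -> list[GeneModule]:
    modules = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            modules.append(
                GeneModule(
                    module_id=parts[0], label=parts[1], gene_ids=frozenset(parts[2:])
                )
            )
    return modules


def write_coordinates(coords: pd.DataFrame, path: str | os.PathLike) -> None:
    coords.to_csv(path, sep="\t", index_label="gene")


def read_screen_tsv(path: str | os.PathLike) -> ScreenData:
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_id": str, "intensity": float, "is_control": int}
    )
    return ScreenData.from_frame(df)


def write_screen_tsv(screen: ScreenData, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        {
            "gene_id": screen.intensities.index,
            "intensity": screen.intensities.to_numpy(),
            "is_control": [
                int(g in screen.control_ids) for g in screen.intensities.index
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
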