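"""Tab-separated readers and writers for the pipeline's file formats.

All files are UTF-8 TSV with a header row; gene identifiers are opaque
strings.  Formats:

* expression: genes x samples, first column ``gene_id``, plus a sample
  metadata sidecar with columns ``sample_id``, ``nutrient``,
  ``growth_rate``;
* network: two columns ``tf``, ``target``;
* partition: ``gene_id``, ``sector`` and the evidence counts;
* compendium: mutants x genes plus a ``mutant``/``modifier_class``
  metadata sidecar;
* gene sets: one identifier per line (no header).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import (
    ExpressionDataset,
    ModifierCompendium,
    RegulatoryNetwork,
    SectorPartition,
)


def read_expression(expr_path, meta_path) -> ExpressionDataset:
    raw = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="sample_id")
    return ExpressionDataset(raw=raw, samples=meta)


def write_expression(dataset: ExpressionDataset, expr_path, meta_path) -> None:
    dataset.raw.rename_axis("gene_id").to_csv(expr_path, sep="\t")
    dataset.samples.rename_axis("sample_id").to_csv(meta_path, sep="\t")


def read_network(path) -> RegulatoryNetwork:
    edges = pd.read_csv(path, sep="\t", dtype=str)
    if not {"tf", "target"}.issubset(edges.columns):
        raise ValueError("network TSV needs 'tf' and 'target' columns")
    return RegulatoryNetwork(edges=edges[["tf", "target"]])


def write_network(network: RegulatoryNetwork, path) -> None:
    network.edges.to_csv(path, sep="\t", index=False)


def read_partition(path) -> SectorPartition:
    table = pd.read_csv(path, sep="\t", index_col="gene_id")
    return SectorPartition(table=table)


def write_partition(partition: SectorPartition, path) -> None:
    partition.table.rename_axis("gene_id").to_csv(path, sep="\t")


def read_compendium(profiles_path, classes_path) -> ModifierCompendium:
    profiles = pd.read_csv(profiles_path, sep="\t", index_col="mutant")
    classes = pd.read_csv(classes_path, sep="\t", index_col="mutant")["modifier_class"]
    return ModifierCompendium(profiles=profiles, modifier_class=classes)


def write_compendium(compendium: ModifierCompendium, profiles_path, classes_path) -> None:
    compendium.profiles.rename_axis("mutant").to_csv(profiles_path, sep="\t")
    compendium.modifier_class.rename("modifier_class").rename_axis("mutant").to_csv(
        classes_path, sep="\t"
    )


def read_score_track(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    return df.iloc[:, 0]


def write_score_track(track: pd.Series, path, name: str = "value") -> None:
    track.rename(name).rename_axis("gene_id").to_csv(path, sep="\t")


def read_gene_set(path) -> set[str]:
    return {
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }


def write_gene_set(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n", encoding="utf-8")


def read_matrix(path, index_col: str | int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
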