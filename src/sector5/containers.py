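"""Shared in-memory containers for the five-sector analysis pipeline.

The pipeline operates on a gene x sample expression table with
(nutrient, growth-rate) sample metadata, a directed TF->target network,
and a chromatin-modifier mutant x gene compendium.  Containers are thin
dataclasses around pandas objects so every stage can be inspected and
serialized as TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Canonical order of the five resource-allocation sectors.
SECTORS = ("repressed", "negative", "invariant", "positive", "activated")

#: The three growth-response classes used within a single nutrient.
GROWTH_CLASSES = ("negative", "invariant", "positive")


class InvalidDesignError(ValueError):
    """A simulation or analysis design that cannot be realised."""


class DegenerateDataError(ValueError):
    """Input data degenerate for the requested operation (e.g. all-zero sample)."""


class InsufficientGenesError(ValueError):
    """Fewer rankable genes than the classification quotas require."""


class IncompleteEvidenceError(ValueError):
    """A gene is missing per-pair or per-nutrient calls required for aggregation."""


@dataclass
class ExpressionDataset:
    """Gene x sample expression on the raw positive scale.

    Parameters
    ----------
    raw : DataFrame
        Nonnegative signal, genes in rows, samples in columns.
    samples : DataFrame
        Indexed by sample id with columns ``nutrient`` and ``growth_rate``.
        Growth rates are strictly increasing within each nutrient.
    """

    raw: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("nutrient", "growth_rate") if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata lacks columns {missing}")
        if not self.raw.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.raw.columns]

    @property
    def nutrients(self) -> list[str]:
        return list(dict.fromkeys(self.samples["nutrient"]))

    def samples_for(self, nutrient: str) -> pd.DataFrame:
        """Sample metadata for one nutrient, ordered by growth rate."""
        sub = self.samples[self.samples["nutrient"] == nutrient]
        return sub.sort_values("growth_rate")


@dataclass
class NutrientSVD:
    """Rank-2 decomposition of one nutrient's fractional-expression profile.

    ``v1`` is the (flat-like) baseline direction, ``v2`` the growth
    direction; ``a`` and ``b`` are the per-gene loadings onto them.  Sign
    convention: ``sum(v1) > 0`` and ``corr(v2, growth_rate) > 0``.
    """

    nutrient: str
    growth_rates: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    a: pd.Series
    b: pd.Series
    var_explained: np.ndarray

    @property
    def var_explained_1(self) -> float:
        return float(self.var_explained[0])

    @property
    def var_explained_2(self) -> float:
        return float(self.var_explained[1]) if len(self.var_explained) > 1 else 0.0


@dataclass
class SectorPartition:
    """Per-gene five-sector labels plus the evidence counts behind them."""

    table: pd.DataFrame  # columns: sector, n_nonspecific_pairs, n_invariant_nutrients, n_pos, n_neg

    @property
    def labels(self) -> pd.Series:
        return self.table["sector"]

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def sector_counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(SECTORS, fill_value=0)

    def members(self, sector: str) -> pd.Index:
        return self.table.index[self.table["sector"] == sector]

    @property
    def nonspecific_mask(self) -> pd.Series:
        return self.labels.isin(("negative", "invariant", "positive"))


@dataclass
class RegulatoryNetwork:
    """Directed TF -> target network.

    Duplicate edges in the input are dropped (their count is recorded in
    ``n_duplicates_dropped``).
    """

    edges: pd.DataFrame  # columns: tf, target
    tfs: list[str] = field(default_factory=list)
    n_duplicates_dropped: int = 0

    def __post_init__(self) -> None:
        n0 = len(self.edges)
        self.edges = self.edges.drop_duplicates(subset=["tf", "target"]).reset_index(drop=True)
        self.n_duplicates_dropped += n0 - len(self.edges)
        edge_tfs = set(self.edges["tf"])
        if not edge_tfs.issubset(self.tfs):
            self.tfs = sorted(set(self.tfs) | edge_tfs)

    def regulators_of(self) -> dict[str, list[str]]:
        """Map target -> list of regulating TFs."""
        return {t: list(g) for t, g in self.edges.groupby("target")["tf"].agg(list).items()}

    def in_degree(self, genes: pd.Index) -> pd.Series:
        """Number of regulators for each gene; genes absent from the network count 0."""
        counts = self.edges["target"].value_counts()
        return counts.reindex(genes, fill_value=0).astype(int)


@dataclass
class ModifierCompendium:
    """Chromatin-modifier mutant x gene log2-ratio matrix."""

    profiles: pd.DataFrame  # mutants in rows, genes in columns
    modifier_class: pd.Series  # mutant -> class label
    normalized: bool = False

    def __post_init__(self) -> None:
        self.modifier_class = self.modifier_class.reindex(self.profiles.index)
        if self.modifier_class.isna().any():
            bad = list(self.modifier_class.index[self.modifier_class.isna()])
            raise InvalidDesignError(f"mutants without a modifier class: {bad}")


@dataclass
class NullSummary:
    """Observed statistic against a randomization null."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_randomizations: int
    seed: int | None = None
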