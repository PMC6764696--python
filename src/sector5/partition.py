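"""Genome-wide five-sector partition from expression data.

The partition rests on a rank-2 picture of fractional expression within
each nutrient: a baseline component (flat across growth rates, loading
``a_i``) and a growth component (monotone in growth rate, loading
``b_i``).  A gene whose baseline loading is conserved between nutrients
is *nonspecific*; within nonspecific genes the sign and size of the
growth loading separates *negative*, *invariant* and *positive* genes.
Specific genes split into *repressed* and *activated* by the same growth
votes.  Aggregation over all nutrient pairs and nutrients gives the
final five-sector label per gene.

Pipeline::

    raw signal -> fractional_expression -> nutrient_svd (per nutrient)
      -> pairwise_specificity (per nutrient pair, on a loadings)
      -> growth_response_class (per nutrient, on b loadings)
      -> aggregate_partition

:class:`FiveSectorPartitioner` wires the steps into a scikit-learn style
estimator.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import (
    DegenerateDataError,
    IncompleteEvidenceError,
    NutrientSVD,
    SectorPartition,
)

__all__ = [
    "fractional_expression",
    "nutrient_svd",
    "pairwise_specificity",
    "growth_response_class",
    "per_nutrient_allgene_class",
    "aggregate_partition",
    "FiveSectorPartitioner",
]


def fractional_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """Fractional expression f_i = log10(1e6 * g_i / sum_j g_j) per sample.

    The scale is parts-per-million on log10: per sample,
    ``sum_i 10**f_i == 1e6`` exactly.  Zero signals map to ``-inf``; the
    affected genes should be dropped from downstream SVDs.

    Raises
    ------
    DegenerateDataError
        If a sample sums to zero.
    ValueError
        If any signal is negative.
    """
    g = raw.to_numpy(dtype=float)
    if (g < 0).any():
        raise ValueError("raw signal must be nonnegative")
    totals = g.sum(axis=0)
    if (totals <= 0).any():
        bad = list(raw.columns[totals <= 0])
        raise DegenerateDataError(f"all-zero samples: {bad}")
    with np.errstate(divide="ignore"):
        f = np.log10(1e6 * g / totals)
    return pd.DataFrame(f, index=raw.index, columns=raw.columns)


def nutrient_svd(
    frac: pd.DataFrame, growth_rates: np.ndarray, nutrient: str = ""
) -> NutrientSVD:
    """Top-two singular directions of one nutrient's fractional matrix.

    ``frac`` holds genes in rows and that nutrient's samples (ordered by
    increasing growth rate) in columns; it must be finite.  The SVD is
    computed on the uncentred matrix so the first component captures the
    baseline level.  Sign convention: ``sum(v1) > 0`` and ``v2``
    positively correlated with growth rate.
    """
    rates = np.asarray(growth_rates, dtype=float)
    if frac.shape[1] < 2:
        raise DegenerateDataError("need at least 2 samples per nutrient for SVD")
    if frac.shape[1] != rates.size:
        raise ValueError("growth_rates length must match the number of samples")
    m = frac.to_numpy(dtype=float)
    if not np.isfinite(m).all():
        raise ValueError(
            "non-finite fractional values; drop flagged (zero-signal) genes first"
        )
    _, s, vt = np.linalg.svd(m, full_matrices=False)
    v1, v2 = vt[0].copy(), vt[1].copy()
    if v1.sum() < 0:
        v1 = -v1
    centred = rates - rates.mean()
    if float(v2 @ centred) < 0:
        v2 = -v2
    a = pd.Series(m @ v1, index=frac.index, name="a")
    b = pd.Series(m @ v2, index=frac.index, name="b")
    total = float((s**2).sum())
    var_explained = s**2 / total if total > 0 else np.zeros_like(s)
    return NutrientSVD(
        nutrient=nutrient,
        growth_rates=rates,
        v1=v1,
        v2=v2,
        a=a,
        b=b,
        var_explained=var_explained,
    )


def pairwise_specificity(
    a_low: pd.Series,
    a_high: pd.Series,
    k_sd: float = 3.0,
    sd_mode: str = "signed",
) -> pd.Series:
    """Classify genes as nonspecific / specific between two nutrients.

    The difference of baseline loadings ``d_i = a_i(B) - a_i(A)`` is
    compared against ``k_sd`` standard deviations of the differences
    across all genes: within the band the gene's baseline is conserved
    (nonspecific), outside it the gene is specific (up or down with the
    sign of ``d_i``).

    ``sd_mode`` selects the spread estimate: ``"signed"`` (default) uses
    the SD of the signed differences, ``"abs"`` the SD of their absolute
    values.
    """
    common = a_low.index.intersection(a_high.index)
    d = (a_high.loc[common] - a_low.loc[common]).astype(float)
    spread = d.abs() if sd_mode == "abs" else d
    s = float(spread.std(ddof=0))
    if s == 0:
        warnings.warn("zero variance of loading differences; all genes nonspecific")
        return pd.Series("nonspecific", index=common)
    out = pd.Series("nonspecific", index=common)
    mask = d.abs() > k_sd * s
    out[mask & (d > 0)] = "specific_up"
    out[mask & (d < 0)] = "specific_down"
    return out


def growth_response_class(
    b: pd.Series, n_invariant: int = 2500
) -> pd.Series:
    """Per-gene growth-response class from second-component loadings.

    The ``n_invariant`` genes with smallest ``|b_i|`` are invariant; the
    rest are positive or negative by the sign of ``b_i``.  Ties in
    ``|b_i|`` are broken by gene id (lexicographic) for determinism.
    A gene with ``b_i == 0`` left outside the invariant quota is flagged
    degenerate and assigned positive.
    """
    if len(b) < n_invariant:
        warnings.warn(
            f"fewer genes ({len(b)}) than n_invariant ({n_invariant}); all invariant"
        )
        return pd.Series("invariant", index=b.index)
    absb = b.abs().to_numpy()
    order = np.lexsort((b.index.to_numpy(), absb))
    out = pd.Series("", index=b.index, dtype=object)
    inv_idx = b.index[order[:n_invariant]]
    out[inv_idx] = "invariant"
    rest = b.index[order[n_invariant:]]
    signs = np.sign(b.loc[rest].to_numpy())
    if (signs == 0).any():
        warnings.warn("zero loadings outside the invariant quota; assigned positive")
    out[rest] = np.where(signs < 0, "negative", "positive")
    return out


def per_nutrient_allgene_class(
    svds: dict[str, NutrientSVD], n_invariant: int = 2500
) -> pd.DataFrame:
    """Growth-response class of every gene in every nutrient.

    Applies :func:`growth_response_class` per nutrient ignoring the
    specific/nonspecific split (used for TF-class and coherence
    analyses).  Genes absent from a nutrient get NaN.
    """
    cols = {}
    for nutrient, svd in svds.items():
        cols[nutrient] = growth_response_class(svd.b, n_invariant=n_invariant)
    return pd.DataFrame(cols)


def aggregate_partition(
    pair_calls: pd.DataFrame,
    nutrient_classes: pd.DataFrame,
    b_total: pd.Series,
    nonspecific_min: int = 9,
    invariant_min: int = 4,
) -> SectorPartition:
    """Aggregate per-pair and per-nutrient calls into five sectors.

    Parameters
    ----------
    pair_calls : DataFrame
        genes x nutrient-pairs, entries in {nonspecific, specific_up,
        specific_down}.
    nutrient_classes : DataFrame
        genes x nutrients, entries in {negative, invariant, positive}.
    b_total : Series
        Sum of second-component loadings over nutrients; breaks exact
        positive/negative vote ties by its sign.
    nonspecific_min, invariant_min : int
        A gene is nonspecific when conserved in at least
        ``nonspecific_min`` of the pairs, and invariant when additionally
        invariant in at least ``invariant_min`` nutrients.

    Raises
    ------
    IncompleteEvidenceError
        If any gene has missing calls.
    """
    if pair_calls.isna().any().any() or nutrient_classes.isna().any().any():
        bad = set(pair_calls.index[pair_calls.isna().any(axis=1)]) | set(
            nutrient_classes.index[nutrient_classes.isna().any(axis=1)]
        )
        raise IncompleteEvidenceError(
            f"{len(bad)} genes have missing pairwise or nutrient calls"
        )
    genes = pair_calls.index
    nutrient_classes = nutrient_classes.loc[genes]
    b_total = b_total.loc[genes]
    ns_count = (pair_calls == "nonspecific").sum(axis=1)
    n_inv = (nutrient_classes == "invariant").sum(axis=1)
    n_pos = (nutrient_classes == "positive").sum(axis=1)
    n_neg = (nutrient_classes == "negative").sum(axis=1)

    nonspecific = ns_count >= nonspecific_min
    invariant = nonspecific & (n_inv >= invariant_min)
    # vote ties (n_pos == n_neg) fall back to the sign of the summed b loading
    positive_vote = (n_pos > n_neg) | ((n_pos == n_neg) & (b_total > 0))

    sector = pd.Series("", index=genes, dtype=object)
    sector[invariant] = "invariant"
    sector[nonspecific & ~invariant & positive_vote] = "positive"
    sector[nonspecific & ~invariant & ~positive_vote] = "negative"
    sector[~nonspecific & positive_vote] = "activated"
    sector[~nonspecific & ~positive_vote] = "repressed"

    table = pd.DataFrame(
        {
            "sector": sector,
            "n_nonspecific_pairs": ns_count,
            "n_invariant_nutrients": n_inv,
            "n_pos": n_pos,
            "n_neg": n_neg,
        }
    )
    return SectorPartition(table)


class FiveSectorPartitioner(BaseEstimator):
    """Five-sector genome partition from a raw expression matrix.

    scikit-learn style estimator: ``fit(X, sample_meta)`` with ``X`` the
    gene x sample raw signal DataFrame and ``sample_meta`` indexed by
    sample id with ``nutrient`` and ``growth_rate`` columns.

    Parameters
    ----------
    n_invariant : int
        Per-nutrient invariant quota (genes with smallest ``|b_i|``).
    k_sd : float
        Width of the baseline-conservation band in SDs of the loading
        differences.
    nonspecific_min : int
        Minimum number of nonspecific pairwise calls for a nonspecific gene.
    invariant_min : int
        Minimum number of invariant nutrients for an invariant gene.
    sd_mode : {"signed", "abs"}
        Spread estimate used by the pairwise specificity test.
    on_incomplete : {"drop", "error"}
        Genes with a zero signal somewhere lack calls for the affected
        nutrient; drop them from the partition or raise.

    Attributes
    ----------
    labels_ : Series gene -> sector
    partition_ : SectorPartition
    svd_ : dict nutrient -> NutrientSVD
    nutrient_classes_ : DataFrame genes x nutrients (all-gene classes)
    pair_calls_ : DataFrame genes x pairs
    dropped_genes_ : list of genes excluded for zero signal
    """

    def __init__(
        self,
        n_invariant: int = 2500,
        k_sd: float = 3.0,
        nonspecific_min: int = 9,
        invariant_min: int = 4,
        sd_mode: str = "signed",
        on_incomplete: str = "drop",
    ):
        self.n_invariant = n_invariant
        self.k_sd = k_sd
        self.nonspecific_min = nonspecific_min
        self.invariant_min = invariant_min
        self.sd_mode = sd_mode
        self.on_incomplete = on_incomplete

    def fit(self, X: pd.DataFrame, sample_meta: pd.DataFrame):
        frac = fractional_expression(X)
        flagged = ~np.isfinite(frac).all(axis=1)
        if flagged.any():
            if self.on_incomplete == "error":
                raise IncompleteEvidenceError(
                    f"{int(flagged.sum())} genes with zero signal"
                )
            frac = frac.loc[~flagged]
        self.dropped_genes_ = list(X.index[flagged])

        meta = sample_meta.loc[frac.columns]
        nutrients = list(dict.fromkeys(meta["nutrient"]))
        self.svd_: dict[str, NutrientSVD] = {}
        for nutrient in nutrients:
            sub = meta[meta["nutrient"] == nutrient].sort_values("growth_rate")
            self.svd_[nutrient] = nutrient_svd(
                frac[sub.index], sub["growth_rate"].to_numpy(), nutrient
            )

        pair_cols = {}
        for na, nb in itertools.combinations(nutrients, 2):
            pair_cols[f"{na}|{nb}"] = pairwise_specificity(
                self.svd_[na].a, self.svd_[nb].a, k_sd=self.k_sd, sd_mode=self.sd_mode
            )
        self.pair_calls_ = pd.DataFrame(pair_cols)

        self.nutrient_classes_ = per_nutrient_allgene_class(
            self.svd_, n_invariant=self.n_invariant
        )
        b_total = sum(svd.b for svd in self.svd_.values())
        self.partition_ = aggregate_partition(
            self.pair_calls_,
            self.nutrient_classes_,
            b_total,
            nonspecific_min=self.nonspecific_min,
            invariant_min=self.invariant_min,
        )
        self.labels_ = self.partition_.labels
        return self

    def run_summary(self) -> dict:
        """JSON-serializable summary of thresholds and outcome counts."""
        counts = self.partition_.sector_counts()
        return {
            "n_invariant": self.n_invariant,
            "k_sd": self.k_sd,
            "nonspecific_min": self.nonspecific_min,
            "invariant_min": self.invariant_min,
            "sd_mode": self.sd_mode,
            "n_genes": int(len(self.labels_)),
            "n_dropped": len(self.dropped_genes_),
            "sector_counts": {k: int(v) for k, v in counts.items()},
            "var_explained_top2": {
                n: float(s.var_explained_1 + s.var_explained_2)
                for n, s in self.svd_.items()
            },
        }
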