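"""Five-sector classification of promoter-activity (PA) data.

Works on fractional promoter activity (fPA): each promoter's share of the
summed activity of all promoters in a condition.  For every ordered pair
of conditions (low -> high growth rate) promoters are ranked by how far
their fPA ratio departs from 1; fixed quotas pick the invariant core and
the specifically activated/repressed extremes, the remainder splits into
moderately positive/negative.  A gene's *typical class* is its modal
label over all transitions.

The ranking distance is |log ratio| by default (symmetric in up/down
changes); ``distance="linear"`` uses |ratio - 1| instead.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import DegenerateDataError, InsufficientGenesError

__all__ = [
    "fractional_pa",
    "classify_transition",
    "typical_class",
    "class_scaling",
    "ScalingFit",
    "PromoterActivitySectors",
]

PA_LABELS = ("repressed", "negative", "invariant", "positive", "activated", "low_activity")
# deterministic label precedence used as a last-resort tie-break
_LABEL_ORDER = {lab: i for i, lab in enumerate(PA_LABELS[:5])}


def fractional_pa(pa: pd.DataFrame) -> pd.DataFrame:
    """Per-condition fractional activities: PA_i / sum_j PA_j.

    Raises
    ------
    DegenerateDataError
        If a condition's activities sum to zero.
    """
    vals = pa.to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("promoter activity must be nonnegative")
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        bad = list(pa.columns[totals <= 0])
        raise DegenerateDataError(f"all-zero conditions: {bad}")
    return pd.DataFrame(vals / totals, index=pa.index, columns=pa.columns)


def classify_transition(
    fpa_low: pd.Series,
    fpa_high: pd.Series,
    n_invariant: int = 350,
    n_specific: int = 50,
    activity_floor: float = 1e-4,
    distance: str = "log",
) -> pd.DataFrame:
    """Five-sector calls for one low->high growth transition.

    Genes with both fractions at or below ``activity_floor`` are labelled
    ``low_activity`` and excluded from the ranking.  Among the rankable
    genes the ``n_invariant`` with ratio closest to 1 are invariant;
    among the rest, the ``n_specific`` with largest distance and ratio
    above (below) 1 are activated (repressed); the remainder is positive
    or negative by the side of 1 its ratio falls on.

    A gene with zero fPA in the low condition but above-floor activity in
    the high one gets ratio +inf and ranks first among activated.

    Returns a DataFrame indexed by gene with columns ``label``, ``ratio``
    and ``distance``.
    """
    genes = fpa_low.index
    if not genes.equals(fpa_high.index):
        raise ValueError("fraction vectors must cover the same genes in the same order")
    lo = fpa_low.to_numpy(dtype=float)
    hi = fpa_high.to_numpy(dtype=float)

    floor_mask = (lo <= activity_floor) & (hi <= activity_floor)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lo > 0, hi / lo, np.inf)
        if distance == "log":
            dist = np.abs(np.log(ratio))
        elif distance == "linear":
            dist = np.abs(ratio - 1.0)
        else:
            raise ValueError("distance must be 'log' or 'linear'")
    dist = np.where(np.isnan(dist), np.inf, dist)

    rankable = genes[~floor_mask]
    need = n_invariant + 2 * n_specific
    if len(rankable) < need:
        raise InsufficientGenesError(
            f"{len(rankable)} rankable genes < n_invariant + 2*n_specific = {need}"
        )

    label = pd.Series("", index=genes, dtype=object)
    label[floor_mask] = "low_activity"

    sub = pd.DataFrame(
        {"ratio": ratio[~floor_mask], "distance": dist[~floor_mask]}, index=rankable
    )
    # invariant: closest to ratio 1, ties broken by gene id
    order = np.lexsort((sub.index.to_numpy(), sub["distance"].to_numpy()))
    inv_genes = sub.index[order[:n_invariant]]
    label[inv_genes] = "invariant"
    rest = sub.drop(index=inv_genes)

    up = rest[rest["ratio"] > 1]
    down = rest[rest["ratio"] < 1]
    flat = rest[rest["ratio"] == 1]
    if len(flat):
        warnings.warn(
            f"{len(flat)} genes with ratio exactly 1 outside the invariant quota; "
            "assigned positive (degenerate transition)"
        )

    def _top(frame: pd.DataFrame, k: int) -> pd.Index:
        o = np.lexsort((frame.index.to_numpy(), -frame["distance"].to_numpy()))
        return frame.index[o[:k]]

    act = _top(up, n_specific)
    rep = _top(down, n_specific)
    label[act] = "activated"
    label[rep] = "repressed"
    label[up.index.difference(act)] = "positive"
    label[down.index.difference(rep)] = "negative"
    label[flat.index] = "positive"

    return pd.DataFrame(
        {"label": label, "ratio": ratio, "distance": np.where(floor_mask, np.nan, dist)},
        index=genes,
    )


def typical_class(calls: pd.DataFrame) -> pd.Series:
    """Modal label per gene over all transitions.

    ``calls`` is a long DataFrame with columns ``gene_id``, ``label`` and
    (optionally) ``rate_low``/``rate_high``.  ``low_activity`` calls do
    not vote unless a gene is low_activity in every transition.  Modal
    ties are broken by the label assigned in the highest-growth
    transition (by ``(rate_high, rate_low)``), falling back to a fixed
    label precedence when rates are absent.
    """
    required = {"gene_id", "label"}
    if not required.issubset(calls.columns):
        raise ValueError(f"calls must have columns {sorted(required)}")
    has_rates = {"rate_low", "rate_high"}.issubset(calls.columns)
    out = {}
    for gene, sub in calls.groupby("gene_id", sort=True):
        votes = sub[sub["label"] != "low_activity"]
        if votes.empty:
            out[gene] = "low_activity"
            continue
        counts = votes["label"].value_counts()
        top = counts[counts == counts.iloc[0]].index
        if len(top) == 1:
            out[gene] = top[0]
            continue
        if has_rates:
            tied = votes[votes["label"].isin(top)]
            tied = tied.sort_values(["rate_high", "rate_low"])
            out[gene] = tied["label"].iloc[-1]
        else:
            out[gene] = max(top, key=lambda lab: _LABEL_ORDER.get(lab, -1))
    return pd.Series(out, name="typical_class")


@dataclass
class ScalingFit:
    """Least-squares through-origin scaling of fPA between two conditions."""

    slope: float
    r2: float
    n: int
    null_ratio: float | None = None  # growth-rate ratio null


def class_scaling(
    fpa_low: pd.Series,
    fpa_high: pd.Series,
    members: pd.Index,
    null_ratio: float | None = None,
) -> ScalingFit:
    """Single proportional scaling of a gene subset between conditions.

    Fits ``fpa_high = slope * fpa_low`` through the origin over
    ``members`` and reports the uncentred R^2.  ``null_ratio`` (typically
    the ratio of growth rates between the two conditions) is carried
    along as the reference expectation.
    """
    members = pd.Index(members)
    x = fpa_low.loc[members].to_numpy(dtype=float)
    y = fpa_high.loc[members].to_numpy(dtype=float)
    sxx = float(x @ x)
    if len(x) < 1 or sxx == 0:
        raise DegenerateDataError("members have all-zero fractions")
    slope = float(x @ y) / sxx
    ss_res = float(((y - slope * x) ** 2).sum())
    ss_tot = float(y @ y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ScalingFit(slope=slope, r2=r2, n=len(x), null_ratio=null_ratio)


class PromoterActivitySectors(BaseEstimator):
    """PA-based five-sector classification over all growth transitions.

    ``fit(pa, condition_meta)`` takes a gene x condition PA table and
    condition metadata with a ``growth_rate`` column.  All ordered
    condition pairs with increasing growth rate are classified (set
    ``pairs="consecutive"`` to restrict to adjacent rates).

    Attributes
    ----------
    fractional_ : DataFrame of fPA values
    transition_calls_ : long DataFrame (gene_id, cond_low, cond_high,
        rate_low, rate_high, label, ratio, distance)
    typical_class_ : Series gene -> modal label
    """

    def __init__(
        self,
        n_invariant: int = 350,
        n_specific: int = 50,
        activity_floor: float = 1e-4,
        distance: str = "log",
        pairs: str = "all",
    ):
        self.n_invariant = n_invariant
        self.n_specific = n_specific
        self.activity_floor = activity_floor
        self.distance = distance
        self.pairs = pairs

    def fit(self, pa: pd.DataFrame, condition_meta: pd.DataFrame):
        if "growth_rate" not in condition_meta.columns:
            raise ValueError("condition metadata needs a growth_rate column")
        meta = condition_meta.loc[pa.columns].sort_values("growth_rate")
        conds = list(meta.index)
        if len(conds) < 2:
            raise ValueError("need at least 2 conditions")
        self.fractional_ = fractional_pa(pa)
        if self.pairs == "consecutive":
            pair_list = list(zip(conds[:-1], conds[1:]))
        else:
            pair_list = list(itertools.combinations(conds, 2))
        frames = []
        for lo, hi in pair_list:
            calls = classify_transition(
                self.fractional_[lo],
                self.fractional_[hi],
                n_invariant=self.n_invariant,
                n_specific=self.n_specific,
                activity_floor=self.activity_floor,
                distance=self.distance,
            )
            calls = calls.rename_axis("gene_id").reset_index()
            calls["cond_low"] = lo
            calls["cond_high"] = hi
            calls["rate_low"] = float(meta.loc[lo, "growth_rate"])
            calls["rate_high"] = float(meta.loc[hi, "growth_rate"])
            frames.append(calls)
        self.transition_calls_ = pd.concat(frames, ignore_index=True)
        self.typical_class_ = typical_class(self.transition_calls_)
        return self
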