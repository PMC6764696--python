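"""Randomization nulls and shared statistics.

Most downstream questions ("is the mean in-degree of the positive sector
unusual?") are answered against a null obtained by randomly reassigning
genes to sectors while preserving sector sizes.  The engine here permutes
the value vector, which is equivalent to permuting the labels, and
summarizes each class by its mean (or a caller-supplied statistic).

Conventions
-----------
* 10000 randomizations by default.
* Null moments use the population standard deviation (ddof=0).
* A null with zero spread yields z = 0 when the observed value equals the
  null mean and a signed-infinity sentinel otherwise, so downstream
  thresholding is always total (never NaN).
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import NullSummary

__all__ = [
    "sector_randomization_null",
    "sector_randomization_null_exact",
    "permutation_effect_density",
    "hypergeom_enrichment",
    "holm_bonferroni",
    "ks_two_sample",
    "zscore_from_null",
]


def zscore_from_null(observed: float, null_mean: float, null_sd: float) -> float:
    """z-score with total behaviour at degenerate (zero-spread) nulls."""
    if null_sd > 0:
        return (observed - null_mean) / null_sd
    if math.isclose(observed, null_mean, rel_tol=1e-12, abs_tol=1e-12):
        return 0.0
    return math.inf if observed > null_mean else -math.inf


def _align(gene_values: pd.Series | Mapping[str, float], labels: pd.Series):
    values = pd.Series(gene_values)
    common = labels.index.intersection(values.index)
    labels = labels.loc[common]
    values = values.loc[common].astype(float)
    return values, labels


def _class_layout(labels: pd.Series):
    """Order genes so classes are contiguous; return (order, names, starts, sizes)."""
    codes, names = pd.factorize(labels, sort=True)
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes, minlength=len(names))
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return order, list(names), starts, sizes


def _null_sample(
    values: np.ndarray,
    starts: np.ndarray,
    sizes: np.ndarray,
    statistic: str | Callable,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, n_classes) matrix of per-class statistics under label shuffling."""
    n_classes = len(sizes)
    out = np.empty((n, n_classes))
    if statistic == "mean":
        for i in range(n):
            perm = rng.permutation(values)
            out[i] = np.add.reduceat(perm, starts) / np.maximum(sizes, 1)
    else:
        for i in range(n):
            perm = rng.permutation(values)
            for j, (s, k) in enumerate(zip(starts, sizes)):
                out[i, j] = statistic(perm[s : s + k]) if k else np.nan
    return out


def _observed(values, starts, sizes, statistic):
    if statistic == "mean":
        return np.add.reduceat(values, starts) / np.maximum(sizes, 1)
    return np.array(
        [statistic(values[s : s + k]) if k else np.nan for s, k in zip(starts, sizes)]
    )


def sector_randomization_null(
    gene_values: pd.Series | Mapping[str, float],
    labels: pd.Series,
    statistic: str | Callable = "mean",
    n: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, NullSummary]:
    """Per-class statistic against a size-preserving label-randomization null.

    Parameters
    ----------
    gene_values : mapping gene -> value
    labels : Series gene -> class label (e.g. the sector partition labels)
    statistic : "mean" or a callable applied to each class's value vector
    n : number of randomizations
    seed : RNG seed (ignored when ``rng`` is passed)

    Returns
    -------
    dict label -> NullSummary.  Empty classes are skipped.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values, labels = _align(gene_values, labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    order, names, starts, sizes = _class_layout(labels)
    vals = values.to_numpy()[order]
    obs = _observed(vals, starts, sizes, statistic)
    null = _null_sample(values.to_numpy(), starts, sizes, statistic, n, rng)
    out: dict[str, NullSummary] = {}
    for j, name in enumerate(names):
        if sizes[j] == 0:
            continue
        mu = float(null[:, j].mean())
        sd = float(null[:, j].std(ddof=0))
        out[name] = NullSummary(
            observed=float(obs[j]),
            null_mean=mu,
            null_sd=sd,
            z=zscore_from_null(float(obs[j]), mu, sd),
            n_randomizations=n,
            seed=seed,
        )
    return out


def sector_randomization_null_exact(
    gene_values: pd.Series | Mapping[str, float],
    labels: pd.Series,
    statistic: str | Callable = "mean",
) -> dict[str, NullSummary]:
    """Exact version of :func:`sector_randomization_null`.

    Enumerates every permutation of the value vector (all label
    assignments appear with equal multiplicity), so it is only feasible
    for small instances (<= 9 or so genes).
    """
    values, labels = _align(gene_values, labels)
    order, names, starts, sizes = _class_layout(labels)
    vals = values.to_numpy()[order]
    obs = _observed(vals, starts, sizes, statistic)
    rows = []
    for perm in itertools.permutations(values.to_numpy()):
        rows.append(_observed(np.asarray(perm), starts, sizes, statistic))
    null = np.asarray(rows)
    out: dict[str, NullSummary] = {}
    for j, name in enumerate(names):
        if sizes[j] == 0:
            continue
        mu = float(null[:, j].mean())
        sd = float(null[:, j].std(ddof=0))
        out[name] = NullSummary(
            observed=float(obs[j]),
            null_mean=mu,
            null_sd=sd,
            z=zscore_from_null(float(obs[j]), mu, sd),
            n_randomizations=len(rows),
        )
    return out


def permutation_effect_density(
    gene_values: pd.Series | Mapping[str, float],
    labels: pd.Series,
    n: int = 10000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Full null sample of per-class means under label shuffling.

    Same engine as :func:`sector_randomization_null` but returning the
    raw null sample per class, suitable for kernel-density display and
    for empirical-quantile significance bands.
    """
    values, labels = _align(gene_values, labels)
    if rng is None:
        rng = np.random.default_rng(seed)
    order, names, starts, sizes = _class_layout(labels)
    null = _null_sample(values.to_numpy(), starts, sizes, "mean", n, rng)
    return {name: null[:, j] for j, name in enumerate(names) if sizes[j] > 0}


def hypergeom_enrichment(
    overlap: int, group_size: int, category_size: int, population: int
) -> float:
    """Upper-tail hypergeometric p-value, P[X >= overlap].

    ``X`` counts category members in a random group of ``group_size``
    drawn without replacement from ``population`` genes of which
    ``category_size`` belong to the category.
    """
    if not (0 <= overlap <= min(group_size, category_size) <= population):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, group={group_size}, "
            f"category={category_size}, population={population}"
        )
    if max(group_size, category_size) > population:
        raise ValueError("group or category larger than population")
    return float(stats.hypergeom.sf(overlap - 1, population, category_size, group_size))


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (capped at 1, monotone)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "asymp",
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p by default)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("KS test requires nonempty samples")
    res = stats.ks_2samp(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
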