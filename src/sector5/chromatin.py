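"""Epigenetic analyses over the five-sector partition.

Covers the general-transcription-factor (GTF) fraction, per-sector
summaries of continuous score tracks and binary promoter features,
chromatin-modifier effect strength and signed-effect classification
(activator / dual / repressor), removal of the slow-growth expression
signature by orthogonal projection, and stress-response-set overlaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .containers import (
    DegenerateDataError,
    ModifierCompendium,
    NullSummary,
    RegulatoryNetwork,
    SectorPartition,
)
from .nulls import (
    holm_bonferroni,
    hypergeom_enrichment,
    permutation_effect_density,
    sector_randomization_null,
    zscore_from_null,
)

__all__ = [
    "GTF_SET",
    "gtf_fraction",
    "sector_score_summary",
    "binary_feature_enrichment",
    "normalize_compendium",
    "cre_strength",
    "modifier_signed_effects",
    "slow_growth_signature",
    "remove_slow_growth",
    "SlowGrowthCorrector",
    "esr_overlap",
]

#: Broad-acting general transcription factors of budding yeast.
GTF_SET = frozenset({"Rap1", "Abf1", "Reb1", "Cbf1", "Mcm1"})

NONSPECIFIC_SECTORS = ("negative", "invariant", "positive")


def gtf_fraction(
    network: RegulatoryNetwork,
    partition: SectorPartition,
    gtf_set: frozenset[str] | set[str] = GTF_SET,
    n: int = 10000,
    seed: int | None = None,
) -> tuple[pd.Series, dict[str, NullSummary]]:
    """Mean fraction of GTFs among each gene's regulators, per sector.

    Genes with no regulators are excluded.  Returns the per-gene
    fractions and per-sector randomization summaries.
    """
    if not gtf_set:
        raise ValueError("gtf_set must be nonempty")
    regs = network.regulators_of()
    frac = {
        g: len(set(tfs) & set(gtf_set)) / len(tfs)
        for g, tfs in regs.items()
        if len(tfs) > 0 and g in partition.genes
    }
    series = pd.Series(frac, name="gtf_fraction")
    summaries = sector_randomization_null(
        series, partition.labels.loc[series.index], n=n, seed=seed
    )
    return series, summaries


def sector_score_summary(
    track: pd.Series,
    partition: SectorPartition,
    n: int = 10000,
    seed: int | None = None,
) -> dict[str, NullSummary]:
    """Per-sector mean of a continuous gene score with randomization z.

    Genes missing from the track are excluded pairwise (the gene
    universe is the track/partition intersection).
    """
    track = track.dropna()
    common = track.index.intersection(partition.genes)
    return sector_randomization_null(
        track.loc[common], partition.labels.loc[common], n=n, seed=seed
    )


def binary_feature_enrichment(
    track: pd.Series,
    partition: SectorPartition,
    n: int = 10000,
    seed: int | None = None,
) -> dict[str, NullSummary]:
    """Per-sector enrichment of a 0/1 promoter feature.

    The statistic is the within-sector feature fraction (the mean of the
    indicator), tested against size-preserving label randomization.
    """
    vals = set(track.dropna().unique())
    if not vals.issubset({0, 1, True, False}):
        raise ValueError("binary track must take values in {0, 1}")
    return sector_score_summary(track.astype(float), partition, n=n, seed=seed)


def normalize_compendium(compendium: ModifierCompendium) -> ModifierCompendium:
    """Scale each mutant profile to unit variance (mean untouched).

    Zero-variance profiles are dropped with a warning.  Idempotent.
    """
    profiles = compendium.profiles
    sds = profiles.std(axis=1, ddof=0)
    keep = sds > 0
    if (~keep).any():
        warnings.warn(f"dropping zero-variance profiles: {list(profiles.index[~keep])}")
    scaled = profiles.loc[keep].div(sds[keep], axis=0)
    return ModifierCompendium(
        profiles=scaled,
        modifier_class=compendium.modifier_class.loc[keep],
        normalized=True,
    )


def cre_strength(
    compendium: ModifierCompendium,
    partition: SectorPartition,
    n: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Chromatin-regulator effect strength on specific vs nonspecific genes.

    Per modifier, the mean absolute normalized log2 ratio over each gene
    group, with a z-score from gene-label randomization.  A modifier is
    "stronger in specific genes" when the specific-group z exceeds 2.
    """
    if not compendium.normalized:
        compendium = normalize_compendium(compendium)
    labels = partition.labels
    common = compendium.profiles.columns.intersection(labels.index)
    if len(common) == 0:
        raise DegenerateDataError("no genes shared between compendium and partition")
    group = pd.Series(
        np.where(
            labels.loc[common].isin(("repressed", "activated")), "specific", "nonspecific"
        ),
        index=common,
    )
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(compendium.profiles))]
    rows = []
    for (mutant, profile), sd in zip(compendium.profiles.iterrows(), seeds):
        strength = profile.loc[common].abs()
        summ = sector_randomization_null(strength, group, n=n, seed=sd)
        for grp, s in summ.items():
            rows.append(
                {
                    "mutant": mutant,
                    "modifier_class": compendium.modifier_class.loc[mutant],
                    "group": grp,
                    "mean_abs_effect": s.observed,
                    "z": s.z,
                    "stronger": s.z > 2,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class ModifierEffectResult:
    """Signed per-sector effects and classification for one compendium."""

    effects: pd.DataFrame  # mutant x (sector mean, z, sig_pos, sig_neg columns)
    classification: pd.Series  # mutant -> activator / dual / repressor / unclassified
    null_samples: dict[str, dict[str, np.ndarray]]  # mutant -> sector -> null sample


def _classify_modifier(sig_pos: dict[str, bool], sig_neg: dict[str, bool]) -> str:
    """Activator / dual / repressor call from per-sector significance flags.

    * dual: positive genes significantly down AND invariant or negative
      genes significantly up;
    * activator: invariant or positive genes significantly down, no
      sector significantly up;
    * repressor: negative genes significantly up, no sector
      significantly down.
    """
    any_pos = any(sig_pos.values())
    any_neg = any(sig_neg.values())
    if sig_neg.get("positive") and (sig_pos.get("invariant") or sig_pos.get("negative")):
        return "dual"
    if (sig_neg.get("invariant") or sig_neg.get("positive")) and not any_pos:
        return "activator"
    if sig_pos.get("negative") and not any_neg:
        return "repressor"
    return "unclassified"


def modifier_signed_effects(
    compendium: ModifierCompendium,
    partition: SectorPartition,
    n: int = 10000,
    seed: int | None = None,
    band: str = "sd",
    center: str = "both",
) -> ModifierEffectResult:
    """Signed mean effect of each modifier on the nonspecific sectors.

    For each modifier the mean normalized log2 ratio over the negative,
    invariant and positive sectors is compared to a label-permutation
    null of per-sector means.  Significance: outside a +-2 null-SD band
    (``band="quantile"`` uses the matching central-95.4% empirical
    quantile width instead).  ``center`` selects the band's reference
    point(s):

    * ``"both"`` (default): significant only when outside the band
      around the zero-effect point *and* around the null's mean -- the
      sector departs from zero and is not explained by a global profile
      shift;
    * ``"zero"``: the zero-effect point only (absolute reference for
      centred log-ratio data);
    * ``"null"``: the null's own mean only; note the three sector
      deviations from it are constrained to balance, so a one-sided
      (pure activator or pure repressor) pattern cannot reach
      significance under this reading.

    The per-sector significance pattern classifies the modifier as
    activator, dual activator/repressor, or repressor.
    """
    if band not in ("sd", "quantile"):
        raise ValueError("band must be 'sd' or 'quantile'")
    if center not in ("both", "zero", "null"):
        raise ValueError("center must be 'both', 'zero' or 'null'")
    if not compendium.normalized:
        compendium = normalize_compendium(compendium)
    labels = partition.labels
    nonspec = labels[labels.isin(NONSPECIFIC_SECTORS)]
    common = compendium.profiles.columns.intersection(nonspec.index)
    if len(common) == 0:
        raise DegenerateDataError("no nonspecific genes shared with the compendium")
    labs = nonspec.loc[common]

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(compendium.profiles))]
    rows = []
    classification = {}
    null_store: dict[str, dict[str, np.ndarray]] = {}
    lo_q, hi_q = 0.0228, 0.9772  # central 95.4%, the +-2 SD mass
    for (mutant, profile), sd_seed in zip(compendium.profiles.iterrows(), seeds):
        values = profile.loc[common]
        nulls = permutation_effect_density(values, labs, n=n, seed=sd_seed)
        null_store[mutant] = nulls
        sig_pos: dict[str, bool] = {}
        sig_neg: dict[str, bool] = {}
        for sector in NONSPECIFIC_SECTORS:
            obs = float(values[labs == sector].mean())
            sample = nulls[sector]
            mu, sd = float(sample.mean()), float(sample.std(ddof=0))
            refs = {"zero": (0.0,), "null": (mu,), "both": (0.0, mu)}[center]
            if band == "sd":
                lo_w, hi_w = -2 * sd, 2 * sd
            else:
                lo_w = float(np.quantile(sample, lo_q)) - mu
                hi_w = float(np.quantile(sample, hi_q)) - mu
            sig_pos[sector] = all(obs > r + hi_w for r in refs)
            sig_neg[sector] = all(obs < r + lo_w for r in refs)
            rows.append(
                {
                    "mutant": mutant,
                    "modifier_class": compendium.modifier_class.loc[mutant],
                    "sector": sector,
                    "mean_effect": obs,
                    "null_mean": mu,
                    "null_sd": sd,
                    "z": zscore_from_null(obs, mu, sd),
                    "sig_positive": sig_pos[sector],
                    "sig_negative": sig_neg[sector],
                }
            )
        classification[mutant] = _classify_modifier(sig_pos, sig_neg)
    return ModifierEffectResult(
        effects=pd.DataFrame(rows),
        classification=pd.Series(classification, name="call"),
        null_samples=null_store,
    )


def slow_growth_signature(reference: pd.DataFrame) -> pd.Series:
    """Slow-growth signature from a reference gene x condition matrix.

    The rank-1 SVD approximation of the matrix is formed and the column
    of that approximation with the largest Euclidean norm is returned,
    normalized to unit norm.
    """
    if reference.shape[1] < 2:
        raise DegenerateDataError("reference matrix needs at least 2 columns")
    m = reference.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(m, full_matrices=False)
    if s[0] == 0:
        raise DegenerateDataError("reference matrix is identically zero")
    approx = s[0] * np.outer(u[:, 0], vt[0])
    norms = np.linalg.norm(approx, axis=0)
    j = int(np.argmax(norms))
    col = approx[:, j]
    return pd.Series(col / np.linalg.norm(col), index=reference.index, name="signature")


def remove_slow_growth(
    compendium: ModifierCompendium, signature: pd.Series
) -> ModifierCompendium:
    """Project the slow-growth signature out of every mutant profile.

    Gram-Schmidt style: each profile ``p`` becomes ``p - (p . s) s`` over
    the gene intersection, leaving profiles exactly orthogonal to the
    unit-norm signature.  Idempotent.
    """
    common = compendium.profiles.columns.intersection(signature.index)
    if len(common) == 0:
        raise DegenerateDataError("no genes shared between compendium and signature")
    s = signature.loc[common].to_numpy(dtype=float)
    norm = np.linalg.norm(s)
    if norm == 0:
        raise DegenerateDataError("signature is identically zero")
    s = s / norm
    p = compendium.profiles[common].to_numpy(dtype=float)
    corrected = p - np.outer(p @ s, s)
    return replace(
        compendium,
        profiles=pd.DataFrame(corrected, index=compendium.profiles.index, columns=common),
        normalized=False,
    )


class SlowGrowthCorrector:
    """Transformer wrapper around signature derivation and removal.

    ``fit(reference)`` derives the unit-norm slow-growth signature;
    ``transform(compendium)`` returns a compendium orthogonal to it.
    """

    def fit(self, reference: pd.DataFrame):
        self.signature_ = slow_growth_signature(reference)
        return self

    def transform(self, compendium: ModifierCompendium) -> ModifierCompendium:
        return remove_slow_growth(compendium, self.signature_)

    def fit_transform(self, reference: pd.DataFrame, compendium: ModifierCompendium):
        return self.fit(reference).transform(compendium)


def esr_overlap(
    esr_induced: set[str],
    esr_repressed: set[str],
    partition: SectorPartition,
) -> pd.DataFrame:
    """Overlap of the stress-induced/repressed gene sets with each sector.

    Hypergeometric upper-tail p-values (within the partition universe)
    with a Holm correction over all sector x set tests.  Empty sets give
    zero overlaps and p = 1.
    """
    universe = set(partition.genes)
    population = len(universe)
    sets = {
        "esr_induced": esr_induced & universe,
        "esr_repressed": esr_repressed & universe,
    }
    rows = []
    for set_name, members in sets.items():
        for sector in partition.labels.unique():
            sector_genes = set(partition.members(sector))
            overlap = len(sector_genes & members)
            p = (
                hypergeom_enrichment(overlap, len(sector_genes), len(members), population)
                if members
                else 1.0
            )
            rows.append(
                {
                    "set": set_name,
                    "sector": sector,
                    "overlap": overlap,
                    "sector_size": len(sector_genes),
                    "set_size": len(members),
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_bonferroni(table["p"].to_numpy())
    return table
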