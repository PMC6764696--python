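"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* a gene x sample expression matrix whose per-nutrient profiles are a
  rank-2 combination of a flat baseline and a monotone growth direction,
  with baseline shifts planted on specific genes;
* a directed TF -> target network in which designated coherent targets
  are wired to TFs sharing their growth-response class, and regulator
  counts differ by sector;
* a chromatin-modifier compendium with activator / dual / repressor
  effect patterns, optionally contaminated by a slow-growth signature;
* a promoter-activity table, per-gene score/feature tracks and a
  reference matrix for deriving the slow-growth signature.

A single global seed drives a fixed per-generator seed stream, so
partial runs are reproducible: the network produced for a config does
not change when the compendium is regenerated.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    SECTORS,
    ExpressionDataset,
    InvalidDesignError,
    ModifierCompendium,
    RegulatoryNetwork,
)

__all__ = [
    "SimulationConfig",
    "TruthLabels",
    "SyntheticTracks",
    "generate_expression",
    "generate_network",
    "generate_compendium",
    "generate_pa",
    "generate_score_tracks",
    "generate_reference_matrix",
]

# Brauer-style chemostat design: six limiting nutrients, six dilution rates.
DEFAULT_NUTRIENTS = ("glucose", "ammonium", "phosphate", "sulfate", "leucine", "uracil")
DEFAULT_RATES = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

# Genome-scale sector proportions follow the published genome-wide counts
# (repressed, negative, invariant, positive, activated) = (70, 2503, 1749, 1914, 20).
DEFAULT_PROPORTIONS = (70 / 6256, 2503 / 6256, 1749 / 6256, 1914 / 6256, 20 / 6256)

# Mean number of regulators per sector (specific genes most regulated,
# invariant least).
DEFAULT_REGULATORS_MEAN = {
    "repressed": 5.06,
    "activated": 5.06,
    "negative": 3.27,
    "invariant": 2.56,
    "positive": 3.33,
}

DEFAULT_MODIFIER_CLASSES = {
    # general activators: HAT/SAGA/TAF/methyltransferase-like
    "gcn5": "activator", "esa1": "activator", "taf1": "activator",
    "taf12": "activator", "spt20": "activator", "sgf29": "activator",
    "set1": "activator", "set2": "activator", "hat1": "activator",
    "elp3": "activator",
    # dual remodelers: repress negative genes, activate positive ones
    "snf2": "dual", "swi3": "dual", "swr1": "dual", "ino80": "dual",
    "isw1": "dual", "isw2": "dual", "htz1": "dual", "arp8": "dual",
    "chd1": "dual", "nhp10": "dual",
    # broad repressors / silencing
    "sir2": "repressor", "sir3": "repressor", "sir4": "repressor",
    "hda1": "repressor", "rpd3": "repressor", "set3": "repressor",
    "hos2": "repressor", "tup1": "repressor", "cyc8": "repressor",
    "spt10": "repressor",
}

MODIFIER_EFFECT_CLASSES = ("activator", "dual", "repressor")

_STREAMS = {
    "expression": 0,
    "network": 1,
    "compendium": 2,
    "pa": 3,
    "tracks": 4,
    "reference": 5,
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs.

    ``sector_proportions`` follows the (repressed, negative, invariant,
    positive, activated) order.  ``baseline_shift_sd`` is the baseline
    displacement (log10 fractional units) planted on specific genes
    between nutrients; ``growth_slope_scale`` the |b| loading of
    positive/negative genes; ``noise_sd`` additive Gaussian noise on the
    fractional-log scale.
    """

    n_genes: int = 2000
    n_tfs: int = 120
    nutrients: tuple[str, ...] = DEFAULT_NUTRIENTS
    rates_per_nutrient: int = 6
    growth_rates: dict[str, tuple[float, ...]] | None = None
    sector_proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    baseline_shift_sd: float = 1.0
    growth_slope_scale: float = 0.5
    noise_sd: float = 0.02
    coherent_fraction: float = 0.3
    regulators_mean: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGULATORS_MEAN)
    )
    modifier_classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MODIFIER_CLASSES)
    )
    specificity_mode: str = "block"  # "block": 9/15 pairs; "full": all 15
    n_marginal: int = 0  # specific genes planted specific in exactly 7 pairs
    cre_specific_boost: float = 4.0
    seed: int = 0

    def resolved_rates(self) -> dict[str, np.ndarray]:
        if self.growth_rates is not None:
            return {n: np.asarray(r, dtype=float) for n, r in self.growth_rates.items()}
        rates = np.asarray(DEFAULT_RATES[: self.rates_per_nutrient], dtype=float)
        if len(rates) < self.rates_per_nutrient:
            rates = np.linspace(0.05, 0.05 * self.rates_per_nutrient, self.rates_per_nutrient)
        return {n: rates for n in self.nutrients}

    def validate(self) -> None:
        if self.rates_per_nutrient < 2:
            raise InvalidDesignError("rates_per_nutrient must be >= 2 (SVD needs >= 2 samples)")
        if self.n_genes < 1:
            raise InvalidDesignError("n_genes must be positive")
        props = np.asarray(self.sector_proportions, dtype=float)
        if props.size != 5 or (props < 0).any() or abs(props.sum() - 1.0) > 1e-8:
            raise InvalidDesignError("sector_proportions must be a 5-simplex")
        if self.noise_sd < 0:
            raise InvalidDesignError("noise_sd must be >= 0")
        for n, r in self.resolved_rates().items():
            if len(r) != self.rates_per_nutrient or (np.diff(r) <= 0).any():
                raise InvalidDesignError(
                    f"growth rates for {n} must be strictly increasing with "
                    f"{self.rates_per_nutrient} values"
                )
        bad = set(self.modifier_classes.values()) - set(MODIFIER_EFFECT_CLASSES)
        if bad:
            raise InvalidDesignError(f"unknown modifier classes: {sorted(bad)}")
        if self.specificity_mode not in ("block", "full"):
            raise InvalidDesignError("specificity_mode must be 'block' or 'full'")

    def sector_counts(self) -> dict[str, int]:
        """Planted sector sizes (largest-remainder apportionment)."""
        props = np.asarray(self.sector_proportions, dtype=float)
        raw = props * self.n_genes
        counts = np.floor(raw).astype(int)
        rem = self.n_genes - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        return {s: int(c) for s, c in zip(SECTORS, counts)}

    @property
    def n_invariant_planted(self) -> int:
        """Per-nutrient invariant quota implied by the planted proportions."""
        return self.sector_counts()["invariant"]

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )


@dataclass
class TruthLabels:
    """Planted ground truth for a generated dataset."""

    sector: pd.Series  # gene -> one of the five sectors
    per_nutrient_class: pd.DataFrame  # genes x nutrients in {negative, invariant, positive}
    is_coherent_target: pd.Series  # filled by generate_network
    regulating_tfs: dict[str, list[str]] = field(default_factory=dict)
    tf_genes: list[str] = field(default_factory=list)
    marginal_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.sector.index


@dataclass
class SyntheticTracks:
    """Per-gene score/feature tracks plus stress-response gene sets."""

    continuous: dict[str, pd.Series]
    binary: dict[str, pd.Series]
    esr_induced: set[str]
    esr_repressed: set[str]


def _gene_ids(n: int, prefix: str = "g") -> pd.Index:
    width = max(4, len(str(n)))
    return pd.Index([f"{prefix}{i:0{width}d}" for i in range(n)], name="gene_id")


def _sector_assignment(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    counts = config.sector_counts()
    labels = np.repeat(list(counts.keys()), list(counts.values()))
    rng.shuffle(labels)
    return pd.Series(labels, index=_gene_ids(config.n_genes), name="sector")


def _specific_offsets(
    config: SimulationConfig,
    sector: pd.Series,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[str]]:
    """Planted baseline offsets (genes x nutrients) for specific genes.

    ``block`` mode (default) displaces each specific gene's baseline by
    +-baseline_shift_sd in a small subset of nutrients (size 2 of 6),
    making it specific in 8 of the 15 nutrient pairs -- past the
    nonspecific cutoff with margin.  The subsets are assigned cyclically
    over all possible subsets so every nutrient pair sees the same
    number of displaced genes: the adaptive 3-SD threshold is then
    deterministic and sits below the displacement for specific
    fractions up to ~20%.  ``full`` mode uses six graded offset levels
    so every pair differs; it is only feasible when specific genes are
    rare (the adaptive threshold scales with the planted spread).
    ``n_marginal`` genes get a graded pattern calibrated to be specific
    in exactly 7 pairs, the minimal evidence the aggregation rule
    accepts.
    """
    n_nut = len(config.nutrients)
    genes = sector.index
    spec_mask = sector.isin(("repressed", "activated")).to_numpy()
    spec_idx = np.flatnonzero(spec_mask)
    offsets = np.zeros((len(genes), n_nut))
    L = config.baseline_shift_sd
    if len(spec_idx) == 0 or L == 0:
        return offsets, []

    n_marginal = min(config.n_marginal, len(spec_idx))
    marginal_idx = spec_idx[:n_marginal]
    regular_idx = spec_idx[n_marginal:]

    if config.specificity_mode == "block":
        k = max(1, n_nut // 3)
        subsets = list(itertools.combinations(range(n_nut), k))
        subsets = [subsets[j] for j in rng.permutation(len(subsets))]
        n_pairs = n_nut * (n_nut - 1) // 2
        crossing = k * (n_nut - k) / n_pairs
        p_spec = len(spec_idx) / len(genes)
        if 3.0 * np.sqrt(crossing * p_spec) >= 0.95:
            warnings.warn(
                "planted specific fraction too large for the adaptive 3-SD "
                "test; specific genes may not be recoverable"
            )
        for j, i in enumerate(regular_idx):
            sign = rng.choice((-1.0, 1.0))
            offsets[i, list(subsets[j % len(subsets)])] = sign * L
    else:
        for i in regular_idx:
            sign = rng.choice((-1.0, 1.0))
            levels = rng.permutation(np.arange(1, n_nut + 1, dtype=float))
            offsets[i] = sign * L * levels

    marginal_genes: list[str] = []
    if n_marginal:
        if n_nut != 6:
            raise InvalidDesignError("marginal specificity requires 6 nutrients")
        # per-pair SD of baseline differences from the regular offsets
        pairs = [(i, j) for i in range(n_nut) for j in range(i + 1, n_nut)]
        sds = np.array(
            [float(np.std(offsets[:, j] - offsets[:, i])) for i, j in pairs]
        )
        if (sds <= 0).any():
            raise InvalidDesignError(
                "marginal genes need regular specific genes to set the 3-SD scale"
            )
        t = 1.1 * sds.max()
        if 2 * t > 3 * sds.min():
            raise InvalidDesignError(
                "per-pair thresholds too heterogeneous for marginal calibration"
            )
        pattern = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 6.0])
        for i in marginal_idx:
            offsets[i] = t * rng.permutation(pattern)
            marginal_genes.append(genes[i])
        # verify: each marginal gene specific (|d| > 3 SD) in exactly 7 pairs
        sds2 = np.array(
            [float(np.std(offsets[:, j] - offsets[:, i])) for i, j in pairs]
        )
        for i in marginal_idx:
            d = np.array([abs(offsets[i, j] - offsets[i, k]) for k, j in pairs])
            n_specific_pairs = int((d > 3 * sds2).sum())
            if n_specific_pairs != 7:
                raise InvalidDesignError(
                    f"marginal calibration failed ({n_specific_pairs} specific pairs)"
                )
    return offsets, marginal_genes


def _balance_block(F: np.ndarray, max_iter: int = 200, tol: float = 1e-13) -> np.ndarray:
    """Make one nutrient's fractional-log block exactly rank-2 and budget-true.

    Fractional expression carries a hard constraint the raw planted
    structure cannot satisfy on its own: the per-sample budget
    ``sum_i 10**F_i = 1e6``.  A positive mixture of exponentials with
    heterogeneous growth slopes is strictly convex in the growth
    coordinate, so its total always varies across growth rates, and the
    normalization correction would leak a small third component into the
    profile matrix.  Alternating projections between the budget manifold
    (per-column renormalization) and the set of rank-2 matrices converge
    to a nearby matrix satisfying both exactly, so the noise-free
    planted data stays exactly rank 2 *after* fractional normalization.
    The planted loadings shift by a common, sector-preserving amount.
    """
    for _ in range(max_iter):
        totals = (10.0**F).sum(axis=0)
        F = F - np.log10(totals / 1e6)[None, :]
        u_, s_, vt_ = np.linalg.svd(F, full_matrices=False)
        F2 = (u_[:, :2] * s_[:2]) @ vt_[:2]
        gap = np.abs(F2 - F).max()
        F = F2
        if gap < tol:
            break
    return F


def generate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionDataset, TruthLabels]:
    """Gene x sample raw expression with planted five-sector structure.

    Within each nutrient every gene's fractional-log profile across
    growth rates is ``a_i * v1 + b_i * v2`` plus Gaussian noise, with
    ``v1`` a flat-like unit-norm baseline and ``v2`` a centred, linearly
    increasing unit-norm growth direction.  Invariant genes have
    ``b_i = 0``; positive/activated ``+growth_slope_scale``;
    negative/repressed ``-growth_slope_scale`` (all up to the common
    budget-balancing shift of :func:`_balance_block`).  Specific genes
    get planted baseline offsets between nutrients (see
    :func:`_specific_offsets`).  The matrix is returned on the raw
    positive scale (arbitrary per-sample scaling) so the fractional
    normalization step is exercised downstream.
    """
    config.validate()
    rng = config.rng("expression")
    sector = _sector_assignment(config, rng)
    genes = sector.index
    n = len(genes)

    # baseline fractional levels: lognormal share of the ppm budget
    w = rng.uniform(-0.8, 0.8, size=n)
    frac = 10.0**w
    frac /= frac.sum()
    base = np.log10(1e6 * frac)

    slope_sign = sector.map(
        {"repressed": -1.0, "negative": -1.0, "invariant": 0.0, "positive": 1.0, "activated": 1.0}
    ).to_numpy()
    b = slope_sign * config.growth_slope_scale

    offsets, marginal_genes = _specific_offsets(config, sector, rng)

    rates = config.resolved_rates()
    cols, col_meta = [], []
    blocks = []
    for k, nutrient in enumerate(config.nutrients):
        r = rates[nutrient]
        m = len(r)
        u = r - r.mean()
        norm = np.linalg.norm(u)
        u = u / norm if norm > 0 else np.full(m, 0.0)
        F = base[:, None] + offsets[:, k][:, None] + b[:, None] * u[None, :]
        F = _balance_block(F)
        F = F + rng.normal(0.0, config.noise_sd, size=(n, m))
        blocks.append(F)
        for j, rate in enumerate(r):
            cols.append(f"{nutrient}_{j}")
            col_meta.append((nutrient, float(rate)))
    F_all = np.concatenate(blocks, axis=1)
    scale = rng.uniform(0.5, 2.0, size=F_all.shape[1])
    raw = scale[None, :] * 10.0 ** (F_all - 3.0)

    samples = pd.DataFrame(col_meta, index=pd.Index(cols, name="sample_id"),
                           columns=["nutrient", "growth_rate"])
    dataset = ExpressionDataset(
        raw=pd.DataFrame(raw, index=genes, columns=samples.index), samples=samples
    )

    class_map = {
        "repressed": "negative",
        "negative": "negative",
        "invariant": "invariant",
        "positive": "positive",
        "activated": "positive",
    }
    per_nutrient = pd.DataFrame(
        {nut: sector.map(class_map) for nut in config.nutrients}, index=genes
    )
    truth = TruthLabels(
        sector=sector,
        per_nutrient_class=per_nutrient,
        is_coherent_target=pd.Series(False, index=genes, name="is_coherent_target"),
        marginal_genes=marginal_genes,
    )
    return dataset, truth


# Target composition of the TF pool over sectors; mostly nonspecific,
# with enough TFs of every growth class to wire coherent targets.
_TF_COMPOSITION = {
    "negative": 0.30,
    "invariant": 0.25,
    "positive": 0.30,
    "repressed": 0.075,
    "activated": 0.075,
}


def generate_network(config: SimulationConfig, truth: TruthLabels) -> RegulatoryNetwork:
    """Directed TF -> target edge list with planted in-degree and coherence.

    Specific genes receive more regulators on average than nonspecific
    ones and invariant genes the fewest.  A target designated coherent
    (probability ``coherent_fraction``; only genes with a nonzero growth
    response are eligible, since an invariant target has no growth
    profile for a TF to echo) is wired exclusively to TFs sharing its
    growth-response class, so its expression correlates positively with
    its regulators across growth rates.
    """
    config.validate()
    if config.n_tfs == 0 and config.coherent_fraction > 0:
        raise InvalidDesignError("coherent_fraction > 0 requires n_tfs > 0")
    rng = config.rng("network")
    genes = truth.genes
    sector = truth.sector

    # pick TF genes with a sector composition dominated by nonspecific classes
    pools = {
        s: rng.permutation(np.asarray(genes[sector == s])) for s in SECTORS
    }
    tf_genes: list[str] = []
    leftovers: list[str] = []
    for s in SECTORS:
        want = int(round(_TF_COMPOSITION[s] * config.n_tfs))
        take = min(want, len(pools[s]))
        tf_genes.extend(pools[s][:take])
        leftovers.extend(pools[s][take:])
    if len(tf_genes) > config.n_tfs:
        tf_genes = tf_genes[: config.n_tfs]
    elif len(tf_genes) < config.n_tfs:
        extra = rng.permutation(np.asarray(leftovers))[: config.n_tfs - len(tf_genes)]
        tf_genes.extend(extra)
    tf_genes = sorted(tf_genes)

    tf_class = truth.per_nutrient_class.loc[tf_genes].iloc[:, 0]
    class_pools = {
        c: np.asarray(tf_class.index[tf_class == c]) for c in ("negative", "invariant", "positive")
    }
    all_tfs = np.asarray(tf_genes)

    edges_tf: list[str] = []
    edges_target: list[str] = []
    coherent = truth.is_coherent_target.copy()
    regulating: dict[str, list[str]] = {}
    means = config.regulators_mean
    gene_class = truth.per_nutrient_class.iloc[:, 0]
    for gene in genes:
        s = sector.loc[gene]
        k = 1 + rng.poisson(max(means.get(s, 3.0) - 1.0, 0.0))
        is_coh = (
            gene_class.loc[gene] != "invariant"
            and rng.random() < config.coherent_fraction
            and config.n_tfs > 0
        )
        pool = class_pools[gene_class.loc[gene]] if is_coh else all_tfs
        pool = pool[pool != gene]
        if len(pool) == 0:
            continue
        k = min(k, len(pool))
        regs = rng.choice(pool, size=k, replace=False)
        coherent.loc[gene] = bool(is_coh)
        regulating[gene] = list(regs)
        edges_tf.extend(regs)
        edges_target.extend([gene] * k)

    truth.is_coherent_target = coherent
    truth.regulating_tfs = regulating
    truth.tf_genes = list(tf_genes)
    edges = pd.DataFrame({"tf": edges_tf, "target": edges_target})
    return RegulatoryNetwork(edges=edges, tfs=list(tf_genes))


def generate_compendium(
    config: SimulationConfig,
    truth: TruthLabels,
    slow_growth: pd.Series | None = None,
    lam: float = 0.0,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
) -> ModifierCompendium:
    """Mutant x gene log2-ratio matrix with planted modifier classes.

    Sector-dependent effect means per planted class:

    * activator  -- mutation decreases expression of invariant and
      positive genes (mean ``-effect_size`` there);
    * dual       -- increases negative genes, decreases positive genes;
    * repressor  -- increases negative genes.

    Specific genes carry no class signal but a ``cre_specific_boost``-fold
    noise magnitude, mirroring the stronger chromatin-regulator effect on
    specific genes.  ``lam`` adds a slow-growth contamination
    ``lam * slow_growth`` to every profile.
    """
    config.validate()
    rng = config.rng("compendium")
    genes = truth.genes
    sector = truth.sector
    mean_by_class = {
        "activator": {"invariant": -effect_size, "positive": -effect_size},
        "dual": {"negative": effect_size, "positive": -effect_size},
        "repressor": {"negative": effect_size},
    }
    spec_mask = sector.isin(("repressed", "activated")).to_numpy()
    sd = np.where(spec_mask, config.cre_specific_boost * noise_sd, noise_sd)
    if lam != 0.0:
        if slow_growth is None:
            raise InvalidDesignError("lam != 0 requires a slow_growth signature")
        sig = slow_growth.reindex(genes).fillna(0.0).to_numpy()
    rows = {}
    for mutant, cls in config.modifier_classes.items():
        if cls not in mean_by_class:
            raise InvalidDesignError(f"unknown modifier class {cls!r} for {mutant}")
        mu = sector.map(lambda s: mean_by_class[cls].get(s, 0.0)).to_numpy()
        profile = mu + rng.normal(0.0, 1.0, size=len(genes)) * sd
        if lam != 0.0:
            profile = profile + lam * sig
        rows[mutant] = profile
    profiles = pd.DataFrame.from_dict(rows, orient="index", columns=genes)
    profiles.index.name = "mutant"
    classes = pd.Series(config.modifier_classes, name="modifier_class")
    return ModifierCompendium(profiles=profiles, modifier_class=classes)


PA_CLASS_EXPONENT = {
    "invariant": 0.0,
    "positive": 0.35,
    "negative": -0.35,
    "activated": 1.2,
    "repressed": -1.2,
}
_PA_EXPONENT_JITTER = {
    "invariant": 0.02,
    "positive": 0.06,
    "negative": -0.06,
    "activated": 0.15,
    "repressed": -0.15,
}
# fraction of the activity budget each class occupies at the lowest rate
_PA_CLASS_SHARE = {
    "invariant": 0.25,
    "positive": 0.18,
    "negative": 0.20,
    "activated": 0.025,
    "repressed": 0.10,
}


def generate_pa(
    config: SimulationConfig,
    class_counts: dict[str, int] | None = None,
    n_low_activity: int = 20,
    n_conditions: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Promoter-activity table emulating a ~900-promoter reporter library.

    The fractional activity of each planted gene scales exactly as
    ``share_i * (rate / rate_min) ** gamma_i`` with a class-dependent
    exponent (invariant ~0, positive/negative moderate,
    activated/repressed extreme).  Fractional activities carry a hard
    budget (they sum to 1 per condition), which a fixed set of scaling
    genes cannot satisfy on its own; a single *ballast* promoter absorbs
    the budget residual, so the planted genes' fractional ratios are
    exact and the class ordering survives every pairwise transition.
    ``n_low_activity`` extra promoters sit below the activity floor
    everywhere.  The ballast promoter is labelled ``ballast`` and has no
    planted class.

    Returns (PA table genes x conditions, condition metadata with
    growth_rate, planted class Series).
    """
    config.validate()
    rng = config.rng("pa")
    if class_counts is None:
        class_counts = {
            "repressed": 50,
            "negative": 225,
            "invariant": 350,
            "positive": 225,
            "activated": 50,
        }
    labels = np.repeat(list(class_counts.keys()), list(class_counts.values()))
    labels = np.concatenate([labels, ["low_activity"] * n_low_activity, ["ballast"]])
    order = rng.permutation(len(labels) - 1)  # ballast stays last
    labels = np.concatenate([labels[:-1][order], labels[-1:]])
    genes = _gene_ids(len(labels), prefix="p")
    classes = pd.Series(labels, index=genes, name="pa_class")

    rates = np.linspace(0.10, 0.55, n_conditions)
    conds = pd.Index([f"c{j:02d}" for j in range(n_conditions)], name="condition")
    meta = pd.DataFrame({"growth_rate": rates}, index=conds)

    frac = np.zeros((len(genes), n_conditions))
    rho = rates / rates[0]
    for cls, share in _PA_CLASS_SHARE.items():
        mask = labels == cls
        k = int(mask.sum())
        if k == 0:
            continue
        w = 10.0 ** rng.uniform(-0.3, 0.3, size=k)
        w = share * w / w.sum()
        gamma = PA_CLASS_EXPONENT[cls] + rng.normal(
            0.0, abs(_PA_EXPONENT_JITTER[cls]), size=k
        )
        frac[mask] = w[:, None] * rho[None, :] ** gamma[:, None]
    low = labels == "low_activity"
    frac[low] = 10.0 ** rng.uniform(-8.5, -7.5, size=int(low.sum()))[:, None]
    residual = 1.0 - frac.sum(axis=0)
    if (residual <= 0).any():
        raise InvalidDesignError("planted PA shares exceed the activity budget")
    frac[-1] = residual  # ballast promoter
    totals = rng.uniform(50.0, 200.0, size=n_conditions)
    pa = pd.DataFrame(frac * totals, index=genes, columns=conds)
    return pa, meta, classes


def generate_score_tracks(config: SimulationConfig, truth: TruthLabels) -> SyntheticTracks:
    """Per-gene score/feature tracks with sector-dependent structure.

    Continuous tracks (fragility, cis/trans variability, expression,
    noise) are unit-noise Gaussians with planted sector shifts; binary
    tracks (TATA, TFIID, shNFR) are Bernoulli with sector-dependent
    frequencies; the two stress-response sets are drawn mostly from the
    negative/repressed (induced) and positive (repressed) sectors.
    """
    config.validate()
    rng = config.rng("tracks")
    genes = truth.genes
    s = truth.sector
    n = len(genes)
    pos = (s == "positive").to_numpy()
    inv = (s == "invariant").to_numpy()
    neg = (s == "negative").to_numpy()
    spec = s.isin(("repressed", "activated")).to_numpy()

    def noisy(shift: np.ndarray) -> pd.Series:
        return pd.Series(shift + rng.normal(0.0, 1.0, size=n), index=genes)

    continuous = {
        "fragility": noisy(1.2 * pos),
        "trans_var": noisy(0.8 * pos),
        "cis_var": noisy(0.5 * (neg | spec)),
        "expression": noisy(1.0 * pos + 0.5 * inv),
        "noise": noisy(-0.8 * pos - 0.4 * inv),
    }

    def bern(p_hi: float, p_lo: float, mask: np.ndarray) -> pd.Series:
        p = np.where(mask, p_hi, p_lo)
        return pd.Series((rng.random(n) < p).astype(int), index=genes)

    binary = {
        "tata": bern(0.45, 0.10, neg | spec),
        "tfiid": bern(0.70, 0.30, inv | pos),
        "shnfr": bern(0.60, 0.20, pos),
    }

    neg_genes = np.asarray(genes[neg])
    rep_genes = np.asarray(genes[(s == "repressed").to_numpy()])
    pos_genes = np.asarray(genes[pos])
    esr_induced = set(rng.choice(neg_genes, size=max(1, len(neg_genes) // 10), replace=False))
    if len(rep_genes):
        esr_induced |= set(
            rng.choice(rep_genes, size=max(1, len(rep_genes) // 7), replace=False)
        )
    esr_repressed = set(
        rng.choice(pos_genes, size=max(1, len(pos_genes) // 4), replace=False)
    )
    return SyntheticTracks(
        continuous=continuous,
        binary=binary,
        esr_induced=esr_induced,
        esr_repressed=esr_repressed,
    )


def generate_reference_matrix(
    config: SimulationConfig,
    n_conditions: int = 8,
    strength: float = 25.0,
    noise_sd: float = 0.2,
) -> tuple[pd.DataFrame, pd.Series]:
    """Reference gene x condition matrix dominated by one expression mode.

    The matrix is a rank-1 signal (the planted slow-growth signature
    outer a per-condition weight vector) plus Gaussian noise.  Returns
    (matrix, planted unit-norm signature).
    """
    config.validate()
    rng = config.rng("reference")
    genes = _gene_ids(config.n_genes)
    s = rng.normal(0.0, 1.0, size=config.n_genes)
    s /= np.linalg.norm(s)
    w = rng.uniform(0.6, 1.6, size=n_conditions)
    mat = strength * np.outer(s, w) + rng.normal(0.0, noise_sd, size=(config.n_genes, n_conditions))
    cols = pd.Index([f"r{j:02d}" for j in range(n_conditions)], name="condition")
    return pd.DataFrame(mat, index=genes, columns=cols), pd.Series(s, index=genes, name="signature")
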