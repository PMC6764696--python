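"""TF-network analyses over the five-sector partition.

Regulatory coherence is the mean Pearson correlation, across growth
rates within one nutrient, between a target gene's fractional-expression
profile and the profiles of the TFs regulating it.  Significance comes
from a permutation null that scrambles every gene's profile across the
growth-rate positions (breaking growth alignment while preserving each
gene's value distribution); a one-sided z > 2 flags significant
coherence.  Additional analyses: regulators-per-sector with
randomization nulls, TF self-classification, per-target TF-class
fractions, TF-sector enrichment among coherent genes, and the
vertex-sort network hierarchy.
"""

from __future__ import annotations

import math
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .containers import NullSummary, RegulatoryNetwork, SectorPartition
from .nulls import ks_two_sample, sector_randomization_null, zscore_from_null

__all__ = [
    "regulators_per_sector",
    "classify_tfs",
    "tf_class_fractions",
    "regulatory_coherence",
    "coherence_null",
    "coherence_table",
    "tf_sector_enrichment",
    "network_hierarchy",
]


def _nutrient_profiles(
    frac: pd.DataFrame, samples: pd.DataFrame, nutrient: str
) -> pd.DataFrame:
    """Fractional profiles (genes x growth rates) for one nutrient."""
    sub = samples[samples["nutrient"] == nutrient].sort_values("growth_rate")
    if len(sub) < 2:
        raise ValueError(f"nutrient {nutrient!r} has fewer than 2 growth-rate points")
    return frac[sub.index]


def _standardize_rows(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows scaled to zero mean / unit Euclidean norm; flags constant rows.

    After this transform the dot product of two rows is their Pearson r.
    """
    centred = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    constant = norms < 1e-12
    safe = np.where(constant, 1.0, norms)
    return centred / safe[:, None], constant


def regulators_per_sector(
    network: RegulatoryNetwork,
    partition: SectorPartition,
    n: int = 10000,
    seed: int | None = None,
) -> tuple[dict[str, NullSummary], pd.DataFrame]:
    """Mean number of regulators per sector against a randomization null.

    Genes absent from the network count in-degree 0.  Also returns the
    KS comparisons the sectors invite: specific vs nonspecific,
    invariant vs nonspecific-non-invariant, and positive vs negative
    in-degree distributions.
    """
    indeg = network.in_degree(partition.genes).astype(float)
    labels = partition.labels
    summaries = sector_randomization_null(indeg, labels, n=n, seed=seed)

    groups = {
        "specific": indeg[labels.isin(("repressed", "activated"))],
        "nonspecific": indeg[labels.isin(("negative", "invariant", "positive"))],
        "invariant": indeg[labels == "invariant"],
        "nonspecific_not_invariant": indeg[labels.isin(("negative", "positive"))],
        "positive": indeg[labels == "positive"],
        "negative": indeg[labels == "negative"],
    }
    comparisons = [
        ("specific", "nonspecific"),
        ("invariant", "nonspecific_not_invariant"),
        ("positive", "negative"),
    ]
    rows = []
    for ga, gb in comparisons:
        xa, xb = groups[ga], groups[gb]
        if len(xa) == 0 or len(xb) == 0:
            warnings.warn(f"empty group in KS comparison {ga} vs {gb}; skipped")
            continue
        d, p = ks_two_sample(xa, xb)
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "mean_a": float(xa.mean()),
                "mean_b": float(xb.mean()),
                "ks_D": d,
                "ks_p": p,
            }
        )
    return summaries, pd.DataFrame(rows)


def classify_tfs(
    network: RegulatoryNetwork,
    nutrient_classes: pd.DataFrame,
    partition: SectorPartition,
) -> tuple[pd.DataFrame, dict]:
    """Apply the sector rules to the TF genes themselves.

    Returns a per-TF table (sector, number of invariant nutrients,
    majority growth behaviour) and a census: how many TFs have
    expression, how many are nonspecific, the fraction invariant in more
    than half the nutrients, and the all-condition invariants.
    """
    rows = []
    excluded = []
    n_nut = nutrient_classes.shape[1]
    for tf in network.tfs:
        if tf not in nutrient_classes.index or tf not in partition.genes:
            excluded.append(tf)
            continue
        classes = nutrient_classes.loc[tf]
        n_inv = int((classes == "invariant").sum())
        n_pos = int((classes == "positive").sum())
        n_neg = int((classes == "negative").sum())
        if n_pos > max(n_neg, n_inv):
            majority = "mostly_positive"
        elif n_neg > max(n_pos, n_inv):
            majority = "mostly_negative"
        else:
            majority = "mostly_invariant"
        rows.append(
            {
                "tf": tf,
                "sector": partition.labels.loc[tf],
                "n_invariant_nutrients": n_inv,
                "n_positive_nutrients": n_pos,
                "n_negative_nutrients": n_neg,
                "majority": majority,
                "invariant_all_conditions": n_inv == n_nut,
            }
        )
    table = pd.DataFrame(rows).set_index("tf") if rows else pd.DataFrame()
    nonspecific = (
        table["sector"].isin(("negative", "invariant", "positive"))
        if len(table)
        else pd.Series(dtype=bool)
    )
    census = {
        "n_tfs": len(network.tfs),
        "n_with_expression": len(table),
        "n_excluded": len(excluded),
        "excluded": excluded,
        "n_nonspecific": int(nonspecific.sum()),
        "frac_invariant_majority": float(
            (table["n_invariant_nutrients"] > n_nut / 2).mean()
        )
        if len(table)
        else float("nan"),
        "invariant_all_conditions": list(table.index[table["invariant_all_conditions"]])
        if len(table)
        else [],
    }
    return table, census


def tf_class_fractions(
    network: RegulatoryNetwork,
    nutrient_classes: pd.DataFrame,
    nutrient: str,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Fractions of negative/invariant/positive regulators per target.

    For each target with at least one classified regulator in the given
    nutrient, returns (TF_neg, TF_inv, TF_pos) fractions (summing to 1),
    their means aggregated by the target's own class, and two-sided KS
    comparisons of each fraction's distribution between one target class
    and all other classes.
    """
    cls = nutrient_classes[nutrient].dropna()
    regs = network.regulators_of()
    rows = []
    for target, tfs in regs.items():
        classified = [cls.loc[t] for t in tfs if t in cls.index]
        if not classified or target not in cls.index:
            continue
        k = len(classified)
        rows.append(
            {
                "target": target,
                "target_class": cls.loc[target],
                "TF_neg": classified.count("negative") / k,
                "TF_inv": classified.count("invariant") / k,
                "TF_pos": classified.count("positive") / k,
                "n_regulators": k,
            }
        )
    per_target = pd.DataFrame(rows).set_index("target") if rows else pd.DataFrame()
    if per_target.empty:
        return per_target, pd.DataFrame(), pd.DataFrame()
    means = per_target.groupby("target_class")[["TF_neg", "TF_inv", "TF_pos"]].mean()

    ks_rows = []
    for frac_col in ("TF_neg", "TF_inv", "TF_pos"):
        for tclass in means.index:
            in_class = per_target.loc[per_target["target_class"] == tclass, frac_col]
            out_class = per_target.loc[per_target["target_class"] != tclass, frac_col]
            if len(in_class) == 0 or len(out_class) == 0:
                continue
            d, p = ks_two_sample(in_class, out_class)
            ks_rows.append(
                {"fraction": frac_col, "target_class": tclass, "ks_D": d, "ks_p": p}
            )
    return per_target, means, pd.DataFrame(ks_rows)


def regulatory_coherence(
    frac: pd.DataFrame,
    samples: pd.DataFrame,
    network: RegulatoryNetwork,
    nutrient: str,
) -> pd.DataFrame:
    """Mean Pearson correlation between each target and its TFs.

    Computed on fractional profiles across growth rates within one
    nutrient.  Constant profiles yield undefined correlations: constant
    TFs are excluded from the mean, and a target with a constant profile
    (or no usable TF) gets NaN coherence.

    Returns a DataFrame indexed by target with columns ``n_tfs`` (usable
    regulators) and ``coherence``.
    """
    profiles = _nutrient_profiles(frac, samples, nutrient)
    z, constant = _standardize_rows(profiles.to_numpy(dtype=float))
    gene_pos = {g: i for i, g in enumerate(profiles.index)}

    edges = network.edges
    usable = edges[edges["tf"].isin(gene_pos) & edges["target"].isin(gene_pos)]
    ti = usable["target"].map(gene_pos).to_numpy()
    fi = usable["tf"].map(gene_pos).to_numpy()
    r = np.einsum("ij,ij->i", z[ti], z[fi])
    ok = ~(constant[ti] | constant[fi])

    out = {}
    frame = pd.DataFrame({"target": usable["target"].to_numpy(), "r": r, "ok": ok})
    for target, sub in frame.groupby("target"):
        good = sub.loc[sub["ok"], "r"]
        out[target] = {
            "n_tfs": int(len(good)),
            "coherence": float(good.mean()) if len(good) else float("nan"),
        }
    return pd.DataFrame.from_dict(out, orient="index").rename_axis("target")


def coherence_null(
    frac: pd.DataFrame,
    samples: pd.DataFrame,
    network: RegulatoryNetwork,
    nutrient: str,
    n: int = 1000,
    seed: int | None = None,
    mode: str = "within",
) -> pd.DataFrame:
    """Coherence significance against a profile-randomization null.

    Each of the ``n`` iterations independently permutes every gene's
    profile across the nutrient's growth-rate positions
    (``mode="within"``; ``mode="swap"`` instead swaps whole profiles
    between genes) and recomputes every target's coherence.  The z score
    is one-sided: ``significant`` means z > 2.

    Returns a DataFrame indexed by target with columns ``nutrient``,
    ``n_tfs``, ``coherence``, ``z``, ``significant``.
    """
    if mode not in ("within", "swap"):
        raise ValueError("mode must be 'within' or 'swap'")
    profiles = _nutrient_profiles(frac, samples, nutrient)
    z_rows, constant = _standardize_rows(profiles.to_numpy(dtype=float))
    gene_pos = {g: i for i, g in enumerate(profiles.index)}

    edges = network.edges
    usable = edges[edges["tf"].isin(gene_pos) & edges["target"].isin(gene_pos)]
    ti = usable["target"].map(gene_pos).to_numpy()
    fi = usable["tf"].map(gene_pos).to_numpy()
    edge_ok = ~(constant[ti] | constant[fi])

    targets, t_inv = np.unique(usable["target"].to_numpy(), return_inverse=True)
    n_targets = len(targets)
    counts = np.bincount(t_inv, weights=edge_ok.astype(float), minlength=n_targets)

    def mean_r(zmat: np.ndarray) -> np.ndarray:
        r = np.einsum("ij,ij->i", zmat[ti], zmat[fi])
        sums = np.bincount(t_inv, weights=np.where(edge_ok, r, 0.0), minlength=n_targets)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / counts, np.nan)

    observed = mean_r(z_rows)
    rng = np.random.default_rng(seed)
    null = np.empty((n, n_targets))
    for it in range(n):
        if mode == "within":
            perm = rng.permuted(z_rows, axis=1)
        else:
            perm = z_rows[rng.permutation(z_rows.shape[0])]
        null[it] = mean_r(perm)

    null_mean = np.nanmean(null, axis=0)
    null_sd = np.nanstd(null, axis=0, ddof=0)
    zscores = np.array(
        [
            zscore_from_null(o, m, s) if not math.isnan(o) else math.nan
            for o, m, s in zip(observed, null_mean, null_sd)
        ]
    )
    out = pd.DataFrame(
        {
            "nutrient": nutrient,
            "n_tfs": counts.astype(int),
            "coherence": observed,
            "z": zscores,
            "significant": zscores > 2,
        },
        index=pd.Index(targets, name="target"),
    )
    out.loc[out["coherence"].isna(), "significant"] = False
    return out


def coherence_table(
    frac: pd.DataFrame,
    samples: pd.DataFrame,
    network: RegulatoryNetwork,
    nutrients: list[str] | None = None,
    n: int = 1000,
    seed: int | None = None,
    mode: str = "within",
) -> pd.DataFrame:
    """Long coherence table over several nutrients (one row per
    target x nutrient), using an independent seed stream per nutrient."""
    if nutrients is None:
        nutrients = list(dict.fromkeys(samples["nutrient"]))
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(nutrients))]
    frames = []
    for nutrient, sd in zip(nutrients, seeds):
        frames.append(
            coherence_null(frac, samples, network, nutrient, n=n, seed=sd, mode=mode)
            .reset_index()
        )
    return pd.concat(frames, ignore_index=True)


def coherent_gene_set(coherence: pd.DataFrame) -> set[str]:
    """Genes significantly coherent in at least one nutrient condition."""
    sig = coherence[coherence["significant"]]
    return set(sig["target"]) if "target" in sig.columns else set(sig.index)


def tf_sector_enrichment(
    coherent_genes: set[str],
    network: RegulatoryNetwork,
    partition: SectorPartition,
    n: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-TF, per-sector enrichment among significantly coherent genes.

    For each TF the observed proportion of its coherent targets falling
    in each sector is compared to a null in which the partition labels
    are permuted (sector sizes preserved).  Positive z = the TF acts on
    coherent genes of that sector more than chance; a TF with no
    coherent targets gets a row of 0 sentinels.
    """
    from .containers import SECTORS

    labels = partition.labels
    coherent = sorted(coherent_genes & set(labels.index))
    pos = {g: i for i, g in enumerate(coherent)}
    sector_codes = pd.Categorical(labels, categories=list(SECTORS)).codes
    coh_label_pos = labels.index.get_indexer(coherent)

    edges = network.edges
    sub = edges[edges["target"].isin(pos)]
    tfs = sorted(set(network.tfs))
    n_tf, n_sec = len(tfs), len(SECTORS)
    if sub.empty:
        return pd.DataFrame(
            np.zeros((n_tf, n_sec)), index=pd.Index(tfs, name="tf"),
            columns=list(SECTORS),
        )
    tf_index = {t: i for i, t in enumerate(tfs)}
    e_tf = sub["tf"].map(tf_index).to_numpy(dtype=int)
    e_tgt = sub["target"].map(pos).to_numpy(dtype=int)

    def props(code_vec: np.ndarray) -> np.ndarray:
        flat = e_tf * n_sec + code_vec[e_tgt]
        counts = np.bincount(flat, minlength=n_tf * n_sec).reshape(n_tf, n_sec)
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, counts / totals, 0.0)

    codes_all = np.asarray(sector_codes)
    obs = props(codes_all[coh_label_pos])
    rng = np.random.default_rng(seed)
    mean = np.zeros((n_tf, n_sec))
    m2 = np.zeros((n_tf, n_sec))
    for it in range(n):
        shuffled = rng.permutation(codes_all)
        p = props(shuffled[coh_label_pos])
        delta = p - mean
        mean += delta / (it + 1)
        m2 += delta * (p - mean)
    sd = np.sqrt(m2 / n)
    z = np.empty_like(obs)
    for i in range(n_tf):
        for j in range(n_sec):
            z[i, j] = zscore_from_null(obs[i, j], mean[i, j], sd[i, j])
    # TFs with no coherent targets: all-zero proportions -> 0 sentinels
    totals = np.bincount(e_tf, minlength=n_tf)
    z[totals == 0] = 0.0
    return pd.DataFrame(z, index=pd.Index(tfs, name="tf"), columns=list(SECTORS))


def network_hierarchy(network: RegulatoryNetwork | pd.DataFrame) -> pd.Series:
    """Vertex-sort hierarchy levels of a directed network.

    Condenses strongly connected components, then iteratively strips
    sink components: the first stripped layer is level 0 (bottom), the
    last remaining layer the top.  Nodes of one component share a level.
    """
    edges = network.edges if isinstance(network, RegulatoryNetwork) else network
    g = nx.DiGraph()
    g.add_edges_from(edges[["tf", "target"]].itertuples(index=False, name=None))
    if isinstance(network, RegulatoryNetwork):
        g.add_nodes_from(network.tfs)
    if g.number_of_nodes() == 0:
        return pd.Series(dtype=int)
    cond = nx.condensation(g)
    level = {}
    current = 0
    while cond.number_of_nodes():
        sinks = [v for v in cond.nodes if cond.out_degree(v) == 0]
        for v in sinks:
            level[v] = current
        cond.remove_nodes_from(sinks)
        current += 1
    out = {}
    cond_full = nx.condensation(g)
    for comp, members in cond_full.nodes(data="members"):
        for node in members:
            out[node] = level[comp]
    return pd.Series(out, name="level").sort_index()
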