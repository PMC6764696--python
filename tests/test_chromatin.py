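"""Chromatin-modifier analyses and slow-growth-signature removal."""

import numpy as np
import pandas as pd
import pytest

import sector5 as s5
from conftest import make_partition


def power_iteration_signature(m: np.ndarray, n_iter: int = 2000):
    """Independent rank-1 oracle: dominant left singular vector by power iteration."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=m.shape[1])
    for _ in range(n_iter):
        u = m @ v
        u /= np.linalg.norm(u)
        v = m.T @ u
        v /= np.linalg.norm(v)
    sigma = float(u @ m @ v)
    approx = sigma * np.outer(u, v)
    j = int(np.argmax(np.linalg.norm(approx, axis=0)))
    col = approx[:, j]
    return col / np.linalg.norm(col)


class TestGTFFraction:
    def test_explicit_fractions(self):
        edges = [("Rap1", "g1"), ("X", "g1"), ("Y", "g1"), ("Z", "g1"),
                 ("Rap1", "g2"), ("Abf1", "g2")]
        net = s5.RegulatoryNetwork(edges=pd.DataFrame(edges, columns=["tf", "target"]))
        part = make_partition({"g1": "positive", "g2": "negative", "g3": "invariant"})
        frac, summ = s5.gtf_fraction(net, part, n=50, seed=0)
        assert frac["g1"] == pytest.approx(0.25)
        assert frac["g2"] == pytest.approx(1.0)
        assert "g3" not in frac.index  # no regulators -> excluded

    def test_empty_gtf_set_raises(self, network, fitted):
        with pytest.raises(ValueError):
            s5.gtf_fraction(network, fitted.partition_, gtf_set=set())


class TestSectorScoreSummary:
    def test_constant_track_zero_sentinel(self, fitted):
        track = pd.Series(1.5, index=fitted.labels_.index)
        summ = s5.sector_score_summary(track, fitted.partition_, n=100, seed=0)
        assert all(v.z == 0.0 for v in summ.values())

    def test_indicator_track_enriched_in_its_sector(self, fitted):
        track = (fitted.labels_ == "positive").astype(float)
        summ = s5.sector_score_summary(track, fitted.partition_, n=500, seed=1)
        assert summ["positive"].z > 2
        assert summ["negative"].z < 0

    def test_label_shuffle_calibration(self, fitted):
        rng = np.random.default_rng(2)
        labels = fitted.labels_
        n_inside = 0
        reps = 40
        for _ in range(reps):
            track = pd.Series(rng.normal(0, 1, len(labels)), index=labels.index)
            summ = s5.sector_score_summary(track, fitted.partition_, n=300,
                                           seed=int(rng.integers(2**31)))
            n_inside += sum(abs(v.z) < 2 for v in summ.values())
        assert n_inside / (reps * 5) >= 0.90

    def test_planted_fragility_signal(self, config, dataset_truth, fitted):
        _, truth = dataset_truth
        tracks = s5.generate_score_tracks(config, truth)
        summ = s5.sector_score_summary(tracks.continuous["fragility"],
                                       fitted.partition_, n=500, seed=3)
        assert summ["positive"].z > 2


class TestBinaryFeatureEnrichment:
    def test_feature_everywhere_zero_sentinel(self, fitted):
        track = pd.Series(1, index=fitted.labels_.index)
        summ = s5.binary_feature_enrichment(track, fitted.partition_, n=100, seed=0)
        assert all(v.z == 0.0 for v in summ.values())

    def test_feature_equals_sector_membership(self, fitted):
        track = (fitted.labels_ == "negative").astype(int)
        summ = s5.binary_feature_enrichment(track, fitted.partition_, n=500, seed=1)
        zs = {k: v.z for k, v in summ.items()}
        assert zs["negative"] == max(zs.values())
        assert zs["positive"] < 0

    def test_empty_feature_zero_sentinel(self, fitted):
        track = pd.Series(0, index=fitted.labels_.index)
        summ = s5.binary_feature_enrichment(track, fitted.partition_, n=100, seed=0)
        assert all(v.z == 0.0 for v in summ.values())

    def test_nonbinary_track_rejected(self, fitted):
        track = pd.Series(0.5, index=fitted.labels_.index)
        with pytest.raises(ValueError):
            s5.binary_feature_enrichment(track, fitted.partition_, n=10)


class TestNormalizeCompendium:
    @staticmethod
    def _comp(values, classes=None):
        profiles = pd.DataFrame(values, dtype=float)
        classes = classes or {m: "activator" for m in profiles.index}
        return s5.ModifierCompendium(
            profiles=profiles, modifier_class=pd.Series(classes)
        )

    def test_sd_two_halved(self):
        comp = self._comp({0: {"m": 2.0}, 1: {"m": -2.0}, 2: {"m": 2.0}, 3: {"m": -2.0}})
        norm = s5.normalize_compendium(comp)
        assert norm.profiles.loc["m"].std(ddof=0) == pytest.approx(1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        comp = self._comp(pd.DataFrame(rng.normal(0, 3, (2, 20)), index=["a", "b"]),
                          classes={"a": "dual", "b": "repressor"})
        once = s5.normalize_compendium(comp)
        twice = s5.normalize_compendium(once)
        assert np.allclose(once.profiles, twice.profiles)

    def test_zero_variance_profile_dropped(self):
        comp = self._comp({0: {"m": 1.0, "flat": 1.0}, 1: {"m": -1.0, "flat": 1.0}},
                          classes={"m": "dual", "flat": "dual"})
        with pytest.warns(UserWarning):
            norm = s5.normalize_compendium(comp)
        assert "flat" not in norm.profiles.index


class TestCREStrength:
    def test_twofold_magnitude_alone_is_detected(self, config, dataset_truth, fitted):
        """2x noise magnitude on specific genes, no class effects -> z > 2."""
        import dataclasses

        _, truth = dataset_truth
        cfg = dataclasses.replace(config, cre_specific_boost=2.0)
        comp = s5.generate_compendium(cfg, truth, effect_size=0.0)
        cre = s5.cre_strength(s5.normalize_compendium(comp), fitted.partition_,
                              n=300, seed=4)
        spec = cre[cre["group"] == "specific"]
        assert spec["stronger"].mean() >= 0.8

    def test_planted_boost_with_class_effects(self):
        """At the default study conditions the specific group is stronger
        for most modifiers despite the planted sector effects."""
        cfg = s5.SimulationConfig(n_genes=2000, n_tfs=0, coherent_fraction=0.0,
                                  seed=19)
        _, truth = s5.generate_expression(cfg)
        comp = s5.generate_compendium(cfg, truth)
        part = make_partition(truth.sector.to_dict())
        cre = s5.cre_strength(s5.normalize_compendium(comp), part, n=300, seed=5)
        spec = cre[cre["group"] == "specific"]
        assert spec["stronger"].mean() >= 0.8

    def test_sign_flip_invariance(self, fitted):
        rng = np.random.default_rng(5)
        genes = fitted.labels_.index
        vals = rng.normal(0, 1, len(genes))
        comp = s5.ModifierCompendium(
            profiles=pd.DataFrame([vals], index=["m"], columns=genes),
            modifier_class=pd.Series({"m": "dual"}),
        )
        comp_flip = s5.ModifierCompendium(
            profiles=-comp.profiles, modifier_class=comp.modifier_class.copy()
        )
        a = s5.cre_strength(comp, fitted.partition_, n=100, seed=6)
        b = s5.cre_strength(comp_flip, fitted.partition_, n=100, seed=6)
        assert np.allclose(a["mean_abs_effect"], b["mean_abs_effect"])


class TestModifierSignedEffects:
    def test_planted_classes_recovered(self, config, dataset_truth, fitted):
        _, truth = dataset_truth
        comp = s5.generate_compendium(config, truth)
        res = s5.modifier_signed_effects(
            s5.normalize_compendium(comp), fitted.partition_, n=400, seed=7
        )
        agree = (res.classification == comp.modifier_class).mean()
        assert agree >= 0.95

    def test_pure_noise_mostly_unclassified(self, fitted):
        rng = np.random.default_rng(8)
        genes = fitted.labels_.index
        n_mod = 60
        profiles = pd.DataFrame(
            rng.normal(0, 1, (n_mod, len(genes))),
            index=[f"m{i:02d}" for i in range(n_mod)], columns=genes,
        )
        comp = s5.ModifierCompendium(
            profiles=profiles,
            modifier_class=pd.Series("dual", index=profiles.index),
        )
        res = s5.modifier_signed_effects(
            s5.normalize_compendium(comp), fitted.partition_, n=400, seed=9
        )
        # chance-level call rate for the 3-sector band pattern is ~6-7%
        assert (res.classification != "unclassified").mean() <= 0.15

    def test_quantile_band_option(self, config, dataset_truth, fitted):
        _, truth = dataset_truth
        comp = s5.generate_compendium(config, truth)
        res = s5.modifier_signed_effects(
            s5.normalize_compendium(comp), fitted.partition_, n=400, seed=10,
            band="quantile",
        )
        assert (res.classification == comp.modifier_class).mean() >= 0.9

    def test_null_centred_band_cannot_see_one_sided_patterns(self, config,
                                                             dataset_truth, fitted):
        """With the band centred on the permutation null's mean, sector
        deviations must balance, so planted activators read as dual."""
        _, truth = dataset_truth
        comp = s5.generate_compendium(config, truth)
        res = s5.modifier_signed_effects(
            s5.normalize_compendium(comp), fitted.partition_, n=400, seed=11,
            center="null",
        )
        activators = comp.modifier_class[comp.modifier_class == "activator"].index
        assert (res.classification.loc[activators] == "dual").all()


class TestSlowGrowthSignature:
    def test_rank_one_input_exact(self):
        u = np.array([1.0, -2.0, 0.5, 3.0])
        w = np.array([0.5, 2.0, 1.0])
        ref = pd.DataFrame(np.outer(u, w), index=list("abcd"))
        sig = s5.slow_growth_signature(ref)
        expect = u / np.linalg.norm(u)
        assert np.allclose(np.abs(sig), np.abs(expect))
        # returned signature carries the sign of the largest-norm column
        assert np.allclose(sig, expect)

    def test_zero_column_does_not_change_signature(self):
        rng = np.random.default_rng(12)
        ref = pd.DataFrame(rng.normal(0, 1, (20, 5)))
        ref2 = ref.copy()
        ref2[5] = 0.0
        s1 = s5.slow_growth_signature(ref)
        s2 = s5.slow_growth_signature(ref2)
        assert np.allclose(s1, s2)

    def test_matches_power_iteration_oracle(self):
        rng = np.random.default_rng(13)
        m = rng.normal(0, 1, (20, 5))
        ref = pd.DataFrame(m)
        sig = s5.slow_growth_signature(ref).to_numpy()
        oracle = power_iteration_signature(m)
        assert np.allclose(sig, oracle, atol=1e-8)

    def test_all_zero_raises(self):
        with pytest.raises(s5.DegenerateDataError):
            s5.slow_growth_signature(pd.DataFrame(np.zeros((4, 3))))


class TestRemoveSlowGrowth:
    @staticmethod
    def _comp_from(profiles: pd.DataFrame):
        return s5.ModifierCompendium(
            profiles=profiles,
            modifier_class=pd.Series("dual", index=profiles.index),
        )

    def test_pure_signature_removed_to_zero(self):
        s = pd.Series([0.6, 0.8], index=["a", "b"])
        comp = self._comp_from(pd.DataFrame([3 * s], index=["m"]))
        out = s5.remove_slow_growth(comp, s)
        assert np.allclose(out.profiles.to_numpy(), 0.0, atol=1e-12)

    def test_orthogonal_profile_unchanged(self):
        s = pd.Series([1.0, 0.0], index=["a", "b"])
        comp = self._comp_from(pd.DataFrame([[0.0, 5.0]], index=["m"],
                                            columns=["a", "b"]))
        out = s5.remove_slow_growth(comp, s)
        assert np.allclose(out.profiles.to_numpy(), [[0.0, 5.0]])

    def test_orthogonality_and_idempotence(self):
        rng = np.random.default_rng(14)
        genes = [f"g{i:02d}" for i in range(50)]
        s = pd.Series(rng.normal(0, 1, 50), index=genes)
        s /= np.linalg.norm(s)
        profiles = pd.DataFrame(rng.normal(0, 1, (5, 50)),
                                index=[f"m{i}" for i in range(5)], columns=genes)
        comp = self._comp_from(profiles)
        once = s5.remove_slow_growth(comp, s)
        resid = once.profiles.to_numpy() @ s.to_numpy()
        assert np.abs(resid).max() < 1e-10
        twice = s5.remove_slow_growth(once, s)
        assert np.allclose(once.profiles, twice.profiles)

    def test_contamination_removal_restores_classification(self, config,
                                                           dataset_truth, fitted):
        _, truth = dataset_truth
        ref, sig_true = s5.generate_reference_matrix(config)
        lam = 600.0  # per-gene contamination ~ lam/sqrt(n_genes): swamps the effects
        contaminated = s5.generate_compendium(config, truth,
                                              slow_growth=sig_true, lam=lam)
        sig_est = s5.slow_growth_signature(ref)
        res_dirty = s5.modifier_signed_effects(
            s5.normalize_compendium(contaminated), fitted.partition_, n=300, seed=15
        )
        acc_dirty = (res_dirty.classification == contaminated.modifier_class).mean()
        cleaned = s5.remove_slow_growth(contaminated, sig_est)
        res_clean = s5.modifier_signed_effects(
            s5.normalize_compendium(cleaned), fitted.partition_, n=300, seed=15
        )
        acc_clean = (res_clean.classification == contaminated.modifier_class).mean()
        assert acc_dirty < 0.7  # contamination genuinely corrupts the calls
        assert acc_clean >= 0.95

    def test_corrector_transformer_api(self, config, dataset_truth):
        _, truth = dataset_truth
        ref, sig_true = s5.generate_reference_matrix(config)
        comp = s5.generate_compendium(config, truth, slow_growth=sig_true, lam=5.0)
        corr = s5.SlowGrowthCorrector().fit(ref)
        out = corr.transform(comp)
        resid = out.profiles.to_numpy() @ corr.signature_.loc[out.profiles.columns].to_numpy()
        assert np.abs(resid).max() < 1e-10


class TestESROverlap:
    def test_full_sector_overlap_minimal_p(self, fitted):
        negatives = set(fitted.partition_.members("negative"))
        table = s5.esr_overlap(negatives, set(), fitted.partition_)
        row = table[(table["set"] == "esr_induced") & (table["sector"] == "negative")]
        assert row["overlap"].iloc[0] == len(negatives)
        assert row["p"].iloc[0] < 1e-10

    def test_disjoint_sets_zero_overlap(self, fitted):
        table = s5.esr_overlap({"nonexistent"}, set(), fitted.partition_)
        assert (table["overlap"] == 0).all()
        empty = table[table["set"] == "esr_repressed"]
        assert (empty["p"] == 1.0).all()

    def test_toy_counts_match_hand_enumeration(self):
        part = make_partition(
            {f"g{i}": ("negative" if i < 4 else "positive") for i in range(10)}
        )
        induced = {"g0", "g1", "g5"}
        table = s5.esr_overlap(induced, set(), part)
        neg = table[(table["set"] == "esr_induced") & (table["sector"] == "negative")]
        pos = table[(table["set"] == "esr_induced") & (table["sector"] == "positive")]
        assert neg["overlap"].iloc[0] == 2
        assert pos["overlap"].iloc[0] == 1
        # P[X >= 2], X ~ Hypergeom(N=10, K=3, n=4) = (C(3,2)C(7,2)+C(3,3)C(7,1)) / C(10,4)
        import math

        expect = (math.comb(3, 2) * math.comb(7, 2) + math.comb(3, 3) * math.comb(7, 1)) / math.comb(10, 4)
        assert neg["p"].iloc[0] == pytest.approx(expect)
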