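import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmech import (
    au_quartile_efficacy,
    ks_one_sided,
    paired_pairing_ttest,
    pairing_class_efficacy,
    region_efficacy,
    site_type_efficacy,
)


def ecdf_sup_oracle(a, b):
    """Brute-force sup over all pooled breakpoints of F_a - F_b."""
    pooled = np.concatenate([a, b])
    best = 0.0
    for x in pooled:
        fa = np.mean(np.asarray(a) <= x)
        fb = np.mean(np.asarray(b) <= x)
        best = max(best, fa - fb)
    return best


class TestKsOneSided:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0]
        d, p = ks_one_sided(a, a)
        assert d == 0.0 and p == 1.0

    def test_pure_negative_shift_highly_significant(self, rng):
        b = rng.normal(size=100)
        a = b - 10.0
        _, p = ks_one_sided(a, b)
        assert p < 1e-6

    def test_wrong_direction_shift_not_significant(self, rng):
        b = rng.normal(size=100)
        a = b + 10.0
        d, p = ks_one_sided(a, b)
        assert d == 0.0 and p == 1.0

    def test_statistic_matches_ecdf_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(2, 50))
            n = int(rng.integers(2, 50))
            a = rng.normal(size=m)
            b = rng.normal(loc=rng.normal(), size=n)
            d, p = ks_one_sided(a, b)
            assert d == pytest.approx(ecdf_sup_oracle(a, b), abs=1e-12)
            assert 0 < p <= 1
            # asymptotic formula
            assert p == pytest.approx(
                min(1.0, np.exp(-2 * d * d * m * n / (m + n))), rel=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_one_sided([], [1.0])


def _tables(n_feature=15, n_background=30, feature_shift=-0.9, rng=None):
    """Correlation + site tables: feature genes carry one 3'UTR 8mer site."""
    rng = rng or np.random.default_rng(7)
    rows, sites = [], []
    for i in range(n_feature + n_background):
        gene = f"G{i:03d}"
        has_site = i < n_feature
        r_m = feature_shift + 0.05 * rng.normal() if has_site else 0.1 * rng.normal()
        rows.append({"mirna": "miR-1", "gene": gene, "r_mrna": r_m,
                     "p_mrna": 0.5, "r_protein": 0.1 * rng.normal(),
                     "p_protein": 0.5, "r_ratio": 0.1 * rng.normal(),
                     "p_ratio": 0.5, "n": 9})
        if has_site:
            sites.append({"mirna": "miR-1", "gene": gene, "region": "3UTR",
                          "start": 50, "end": 58, "site_type": "8mer",
                          "au_score": rng.uniform(), "pairing3p_score": 0.0,
                          "utr3_len": 300})
    return pd.DataFrame(rows), pd.DataFrame(sites)


class TestSiteTypeEfficacy:
    def test_planted_decay_signal_detected_on_mrna_layer_only(self):
        corr_df, sites = _tables()
        out_m = site_type_efficacy(corr_df, sites, "mrna")
        out_r = site_type_efficacy(corr_df, sites, "ratio")
        p_m = out_m.loc[out_m.level == "8mer", "p"].item()
        p_r = out_r.loc[out_r.level == "8mer", "p"].item()
        assert p_m < 0.001
        assert p_r > 0.05

    def test_absent_type_flagged_not_scored(self):
        corr_df, sites = _tables()
        out = site_type_efficacy(corr_df, sites, "mrna")
        row = out[out.level == "6mer"].iloc[0]
        assert row.flag == "set_below_min_size" and np.isnan(row.p)

    def test_shuffled_labels_mostly_uniform(self):
        rng = np.random.default_rng(11)
        corr_df, sites = _tables(rng=np.random.default_rng(5),
                                 feature_shift=0.0)
        n_small = 0
        for _ in range(100):
            shuffled = corr_df.copy()
            shuffled["r_mrna"] = rng.permutation(shuffled["r_mrna"].to_numpy())
            out = site_type_efficacy(shuffled, sites, "mrna")
            p = out.loc[out.level == "8mer", "p"].item()
            n_small += p < 0.05
        assert n_small <= 10

    def test_min_size_does_not_perturb_other_sets(self):
        corr_df, sites = _tables()
        full = site_type_efficacy(corr_df, sites, "mrna")
        # removing 6mer/7mer rows (already absent) leaves 8mer p unchanged
        only8 = site_type_efficacy(corr_df, sites[sites.site_type == "8mer"],
                                   "mrna")
        assert (full.loc[full.level == "8mer", "p"].item()
                == only8.loc[only8.level == "8mer", "p"].item())


class TestRegionEfficacy:
    def test_8mer_region_restriction(self):
        corr_df, sites = _tables()
        out = region_efficacy(corr_df, sites, "mrna")
        assert out.loc[out.level == "3UTR", "p"].item() < 0.001
        assert out.loc[out.level == "ORF", "flag"].item() == "set_below_min_size"


class TestAuQuartileEfficacy:
    def test_quartile_size_floor(self):
        corr_df, sites = _tables(n_feature=10, n_background=5)
        cmp_ = au_quartile_efficacy(corr_df, sites, "mrna")
        assert cmp_.n_a == 2 and cmp_.n_b == 2  # floor(10/4)

    def test_high_au_recovery(self):
        rng = np.random.default_rng(3)
        corr_df, sites = _tables(n_feature=40, n_background=0, rng=rng)
        # strengthen correlation for high-AU sites, weaken for low-AU
        merged = sites.merge(corr_df, on=["mirna", "gene"])
        for row in merged.itertuples():
            val = -0.95 if row.au_score > 0.5 else -0.1
            corr_df.loc[corr_df.gene == row.gene, "r_mrna"] = val + 0.02 * rng.normal()
        sites["au_score"] = sites["au_score"].round(3)
        cmp_ = au_quartile_efficacy(corr_df, sites, "mrna")
        assert cmp_.p < 0.05

    def test_too_few_single_site_genes_rejected(self):
        corr_df, sites = _tables(n_feature=5, n_background=5)
        with pytest.raises(ValueError, match="single-8mer"):
            au_quartile_efficacy(corr_df, sites, "mrna")

    def test_multi_site_genes_excluded(self):
        corr_df, sites = _tables(n_feature=12, n_background=0)
        dup = sites.iloc[[0]].assign(start=100, end=108)
        sites2 = pd.concat([sites, dup], ignore_index=True)
        cmp_full = au_quartile_efficacy(corr_df, sites2, "mrna")
        assert cmp_full.n_a == (12 - 1) // 4


class TestPairingClassEfficacy:
    def test_strict_thresholds_and_empty_class_error(self):
        corr_df, sites = _tables()
        sites["pairing3p_score"] = 2.0  # all between 1 and 4: both classes empty
        with pytest.raises(ValueError, match="empty 3'-pairing class"):
            pairing_class_efficacy(corr_df, sites, "mrna")

    def test_boundary_scores_in_neither_class(self):
        corr_df, sites = _tables(n_feature=4, n_background=0)
        sites["pairing3p_score"] = [4.0, 1.0, 5.0, 0.0]
        out = pairing_class_efficacy(corr_df, sites, "mrna")
        assert (out["n_a"] == 1).all() or out.iloc[0].n_a == 1  # only score 5 good

    def test_planted_good_pairing_decay_boost(self):
        rng = np.random.default_rng(9)
        corr_df, sites = _tables(n_feature=30, n_background=0, rng=rng)
        sites["pairing3p_score"] = [5.0] * 15 + [0.0] * 15
        good = sites.head(15)["gene"]
        corr_df.loc[corr_df.gene.isin(good), "r_mrna"] = \
            -0.95 + 0.02 * rng.normal(size=15)
        corr_df.loc[~corr_df.gene.isin(good), "r_mrna"] = \
            -0.1 + 0.05 * rng.normal(size=15)
        out = pairing_class_efficacy(corr_df, sites, "mrna")
        p_good = out.loc[out.level == "good_more_negative", "p"].item()
        p_poor = out.loc[out.level == "poor_more_negative", "p"].item()
        assert p_good < 0.01 and p_poor > 0.5


class TestPairedPairingTtest:
    def _tables_with_combos(self, diff, rng, n_combo=10):
        rows, sites = [], []
        for c in range(n_combo):
            mirna = f"miR-{c}"
            for i in range(6):
                gene = f"G{c}_{i}"
                decay = i < 3
                rows.append({"mirna": mirna, "gene": gene,
                             "r_mrna": -0.9 if decay else 0.0, "p_mrna": 0.5,
                             "r_protein": 0.0, "p_protein": 0.5,
                             "r_ratio": 0.0 if decay else -0.9, "p_ratio": 0.5,
                             "n": 9})
                base = 2.0 + (diff[c] if decay else 0.0)
                sites.append({"mirna": mirna, "gene": gene, "region": "3UTR",
                              "start": 50, "end": 58, "site_type": "8mer",
                              "au_score": 0.5,
                              "pairing3p_score": base + 0.1 * rng.normal(),
                              "utr3_len": 300})
        return pd.DataFrame(rows), pd.DataFrame(sites)

    def test_no_difference_gives_null_result(self):
        rng = np.random.default_rng(1)
        corr_df, sites = self._tables_with_combos(np.zeros(10), rng)
        t, p, n = paired_pairing_ttest(corr_df, sites)
        assert n == 10 and abs(t) < 2.5 and p > 0.01

    def test_exactly_equal_means_give_t_zero(self):
        rng = np.random.default_rng(1)
        corr_df, sites = self._tables_with_combos(np.zeros(4), rng, n_combo=4)
        sites["pairing3p_score"] = 2.0
        t, p, n = paired_pairing_ttest(corr_df, sites)
        assert t == 0.0 and p == 1.0

    def test_constant_positive_difference_degenerate(self):
        rng = np.random.default_rng(1)
        corr_df, sites = self._tables_with_combos(np.zeros(4), rng, n_combo=4)
        sites["pairing3p_score"] = np.where(
            sites.index % 6 < 3, 3.0, 2.0)  # decay genes exactly +1
        t, p, n = paired_pairing_ttest(corr_df, sites)
        assert p == 0.0 and np.isinf(t)

    def test_matches_textbook_paired_oracle(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.5, 0.3, size=12)
        corr_df, sites = self._tables_with_combos(diffs, rng, n_combo=12)
        t, p, n = paired_pairing_ttest(corr_df, sites)
        # reconstruct per-combo means independently
        merged = sites.merge(corr_df, on=["mirna", "gene"])
        d = []
        for mirna, grp in merged.groupby("mirna"):
            d.append(grp.loc[grp.r_mrna < -0.8, "pairing3p_score"].mean()
                     - grp.loc[grp.r_ratio < -0.8, "pairing3p_score"].mean())
        d = np.asarray(d)
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), len(d) - 1)
        assert t == pytest.approx(t_oracle, abs=1e-10)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_too_few_combinations_rejected(self):
        rng = np.random.default_rng(1)
        corr_df, sites = self._tables_with_combos(np.zeros(1), rng, n_combo=1)
        with pytest.raises(ValueError, match="paired combinations"):
            paired_pairing_ttest(corr_df, sites)
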