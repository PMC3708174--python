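"""Site-feature efficacy statistics.

Feature-defined gene sets (per miRNA) are compared on their correlation
distributions with a one-sided two-sample Kolmogorov-Smirnov test: the
alternative is that the feature set is shifted toward more negative
correlations than the reference set.  A paired t-test compares mean
3'-pairing scores between decay-detected and translational-repression-
detected target sets across (miRNA, site-type) combinations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corr import R_CUT_DEFAULT

MIN_SET_SIZE = 10

LAYER_COLUMNS = {"mrna": "r_mrna", "protein": "r_protein", "ratio": "r_ratio"}


def ks_one_sided(sample_a, sample_b) -> tuple[float, float]:
    """One-sided two-sample KS test that ``a`` is stochastically smaller.

    D = sup_x (F_a(x) - F_b(x)), which is large when ``a`` is shifted toward
    smaller (more negative) values than ``b``.  The p-value is the one-sided
    asymptotic bound exp(-2 D^2 m n / (m + n)), clamped to (0, 1].
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    m, n = len(a), len(b)
    if m == 0 or n == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / m
    fb = np.searchsorted(b, pooled, side="right") / n
    d = float(np.max(fa - fb))
    d = max(d, 0.0)
    p = float(np.exp(-2.0 * d * d * m * n / (m + n)))
    return d, min(max(p, np.nextafter(0, 1)), 1.0)


@dataclass
class _SetComparison:
    feature: str
    level: str
    layer: str
    n_a: int
    n_b: int
    D: float
    p: float
    flag: str = ""


def _compare(values_a, values_b, feature, level, layer,
             min_set_size=MIN_SET_SIZE) -> _SetComparison:
    n_a, n_b = len(values_a), len(values_b)
    if n_a < min_set_size or n_b < min_set_size:
        return _SetComparison(feature, level, layer, n_a, n_b,
                              np.nan, np.nan, flag="set_below_min_size")
    d, p = ks_one_sided(values_a, values_b)
    return _SetComparison(feature, level, layer, n_a, n_b, d, p)


def _as_frame(rows) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["feature", "level", "layer", "n_a", "n_b",
                                 "D", "p", "flag"])


def _pair_key(df: pd.DataFrame) -> pd.Index:
    return pd.MultiIndex.from_frame(df[["mirna", "gene"]])


def _no_site_values(correlations: pd.DataFrame, sites: pd.DataFrame,
                    layer_col: str) -> pd.Series:
    """Correlation values for (miRNA, gene) pairs with no site in any region."""
    with_site = set(map(tuple, sites[["mirna", "gene"]].itertuples(index=False)))
    mask = [
        (m, g) not in with_site
        for m, g in correlations[["mirna", "gene"]].itertuples(index=False)
    ]
    return correlations.loc[mask, layer_col].dropna()


def site_type_efficacy(correlations: pd.DataFrame, sites: pd.DataFrame,
                       layer: str, min_set_size: int = MIN_SET_SIZE) -> pd.DataFrame:
    """KS efficacy of each 3'UTR site type against no-site pairs.

    For each type, the feature set pools correlation values over (miRNA,
    gene) pairs where the gene carries at least one 3'UTR site of that type
    for the miRNA; the reference set pools pairs whose gene has no site in
    any region for the miRNA.
    """
    col = LAYER_COLUMNS[layer]
    background = _no_site_values(correlations, sites, col)
    utr3 = sites[sites["region"] == "3UTR"]
    keyed = correlations.set_index(_pair_key(correlations))
    rows = []
    for site_type in ("8mer", "7mer-m8", "7mer-A1", "6mer"):
        pairs = utr3.loc[utr3["site_type"] == site_type, ["mirna", "gene"]]
        key = pd.MultiIndex.from_frame(pairs).unique()
        vals = keyed.loc[keyed.index.isin(key), col].dropna()
        rows.append(_compare(vals, background, "site_type", site_type, layer,
                             min_set_size))
    return _as_frame(rows)


def region_efficacy(correlations: pd.DataFrame, sites: pd.DataFrame,
                    layer: str, min_set_size: int = MIN_SET_SIZE) -> pd.DataFrame:
    """KS efficacy of 8mer sites per gene region against no-site pairs."""
    col = LAYER_COLUMNS[layer]
    background = _no_site_values(correlations, sites, col)
    eights = sites[sites["site_type"] == "8mer"]
    keyed = correlations.set_index(_pair_key(correlations))
    rows = []
    for region in ("3UTR", "ORF", "5UTR"):
        pairs = eights.loc[eights["region"] == region, ["mirna", "gene"]]
        key = pd.MultiIndex.from_frame(pairs).unique()
        vals = keyed.loc[keyed.index.isin(key), col].dropna()
        rows.append(_compare(vals, background, "region", region, layer,
                             min_set_size))
    return _as_frame(rows)


def single_8mer_sites(sites: pd.DataFrame) -> pd.DataFrame:
    """Sites of (miRNA, gene) pairs with exactly one 3'UTR 8mer site."""
    utr3 = sites[(sites["region"] == "3UTR") & (sites["site_type"] == "8mer")]
    counts = utr3.groupby(["mirna", "gene"]).size()
    singles = counts[counts == 1].index
    keyed = utr3.set_index(_pair_key(utr3))
    return keyed.loc[keyed.index.isin(singles)].reset_index(drop=True)


def au_quartile_efficacy(correlations: pd.DataFrame, sites: pd.DataFrame,
                         layer: str) -> _SetComparison:
    """High-AU (top quartile) vs low-AU (bottom quartile) single-8mer sites.

    Sites are ranked by AU score descending (ties broken by gene id, then
    miRNA id); quartile size is floor(n/4).  One-sided KS tests whether
    high-AU correlations are shifted negative relative to low-AU.
    """
    col = LAYER_COLUMNS[layer]
    singles = single_8mer_sites(sites)
    if len(singles) < 8:
        raise ValueError(f"only {len(singles)} single-8mer sites; need >= 8")
    ranked = singles.sort_values(["au_score", "gene", "mirna"],
                                 ascending=[False, True, True])
    q = len(ranked) // 4
    top = ranked.head(q)
    bottom = ranked.tail(q)
    keyed = correlations.set_index(_pair_key(correlations))
    vals_top = keyed.loc[keyed.index.isin(pd.MultiIndex.from_frame(top[["mirna", "gene"]])), col].dropna()
    vals_bot = keyed.loc[keyed.index.isin(pd.MultiIndex.from_frame(bottom[["mirna", "gene"]])), col].dropna()
    return _compare(vals_top, vals_bot, "au_quartile", "high_vs_low", layer,
                    min_set_size=2)


def pairing_class_efficacy(correlations: pd.DataFrame, sites: pd.DataFrame,
                           layer: str, good_cut: float = 4.0,
                           poor_cut: float = 1.0) -> pd.DataFrame:
    """Good (score > 4) vs poor (score < 1) 3'-pairing single-8mer sites.

    Both orientations are reported because good pairing can strengthen one
    mechanism while weakening the other.  Thresholds are strict: a score of
    exactly 4 or 1 belongs to neither class.
    """
    col = LAYER_COLUMNS[layer]
    singles = single_8mer_sites(sites)
    good = singles[singles["pairing3p_score"] > good_cut]
    poor = singles[singles["pairing3p_score"] < poor_cut]
    if good.empty or poor.empty:
        raise ValueError("empty 3'-pairing class (good: %d, poor: %d)"
                         % (len(good), len(poor)))
    keyed = correlations.set_index(_pair_key(correlations))
    v_good = keyed.loc[keyed.index.isin(pd.MultiIndex.from_frame(good[["mirna", "gene"]])), col].dropna()
    v_poor = keyed.loc[keyed.index.isin(pd.MultiIndex.from_frame(poor[["mirna", "gene"]])), col].dropna()
    rows = [
        _compare(v_good, v_poor, "pairing3p", "good_more_negative", layer, 2),
        _compare(v_poor, v_good, "pairing3p", "poor_more_negative", layer, 2),
    ]
    return _as_frame(rows)


def paired_pairing_ttest(correlations: pd.DataFrame, sites: pd.DataFrame,
                         r_cut: float = R_CUT_DEFAULT):
    """Paired t-test of 3'-pairing scores: decay-detected vs TR-detected.

    For every (miRNA, site type) combination with both a decay-detected set
    (pairs with r_mrna < r_cut) and a translational-repression-detected set
    (pairs with r_ratio < r_cut) the mean 3'-pairing score of each set is
    taken; the paired t-test runs across combinations on the differences
    (decay mean - TR mean).  Returns (t, two-sided p, n_combinations).
    """
    merged = sites[sites["region"] == "3UTR"].merge(
        correlations, on=["mirna", "gene"], how="inner")
    diffs = []
    for (_, _), grp in merged.groupby(["mirna", "site_type"]):
        decay = grp.loc[grp["r_mrna"] < r_cut, "pairing3p_score"]
        tr = grp.loc[grp["r_ratio"] < r_cut, "pairing3p_score"]
        if len(decay) and len(tr):
            diffs.append(decay.mean() - tr.mean())
    if len(diffs) < 2:
        raise ValueError(f"only {len(diffs)} paired combinations; need >= 2")
    diffs = np.asarray(diffs)
    if np.std(diffs, ddof=1) == 0:
        if np.all(diffs == 0):
            return 0.0, 1.0, len(diffs)
        # constant nonzero difference: t diverges; report the limit
        return float(np.sign(diffs[0]) * np.inf), 0.0, len(diffs)
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(t), float(p), len(diffs)
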