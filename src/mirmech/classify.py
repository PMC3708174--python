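"""Interaction prediction and six-category mechanism classification.

A miRNA-target interaction is called when (i) at least one of the three
correlations is significantly inverse and (ii) at least one sequence-based
prediction tool supports binding.  The significance pattern over
(mRNA, protein, ratio) then assigns the mechanism category:

==============  ========  ===========  =========
pattern (S/NS)  mRNA      protein      ratio
==============  ========  ===========  =========
RD              S         S            NS        mRNA decay
RD_o            S         NS           NS        decay + compensating mechanisms
TR              NS        S            S         translational repression
TR_o            NS        NS           S         repression + compensating mechanisms
B_s             S         S            S         both strong
B_w             NS        S            NS        both weak
anomalous       S         NS           S         should not occur
none            NS        NS           NS        no interaction
==============  ========  ===========  =========

The (S, NS, S) pattern is logically inconsistent (significant decay and
repression must show at the protein layer), so it is kept but flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .corr import R_CUT_DEFAULT, P_CUT_DEFAULT, SignificancePattern

logger = logging.getLogger(__name__)

CATEGORIES = ("RD", "RD_o", "TR", "TR_o", "B_s", "B_w")

_TRUTH_TABLE = {
    (True, True, False): "RD",
    (True, False, False): "RD_o",
    (False, True, True): "TR",
    (False, False, True): "TR_o",
    (True, True, True): "B_s",
    (False, True, False): "B_w",
    (True, False, True): "anomalous",
    (False, False, False): "none",
}


def assign_category(pattern: SignificancePattern) -> str:
    """Map a significance pattern to its mechanism category."""
    cat = _TRUTH_TABLE[pattern.as_tuple()]
    if cat == "anomalous":
        logger.warning(
            "anomalous pattern (mRNA S, protein NS, ratio S): significant "
            "decay and repression without a protein-level signal")
    return cat


def predict_interactions(triples: pd.DataFrame, binding: pd.DataFrame,
                         r_cut: float = R_CUT_DEFAULT,
                         p_cut: float = P_CUT_DEFAULT) -> pd.DataFrame:
    """Join correlation triples with binding evidence into interaction records.

    ``triples`` needs columns mirna, gene, r_/p_ for the three layers;
    ``binding`` needs mirna, gene, tool.  Pairs lacking any layer (NaN) are
    excluded and counted in the log.  Retained records have a category other
    than "none" and at least one supporting tool; anomalous records are kept
    but flagged for exclusion from summaries.
    """
    t = triples.copy()
    layer_cols = ["r_mrna", "p_mrna", "r_protein", "p_protein", "r_ratio", "p_ratio"]
    complete = t[layer_cols].notna().all(axis=1)
    if (~complete).any():
        logger.info("predict_interactions: %d pairs with a missing layer excluded",
                    int((~complete).sum()))
    t = t[complete]

    def sig(r, p):
        return (r < r_cut) & (p < p_cut)

    s_m = sig(t["r_mrna"], t["p_mrna"])
    s_p = sig(t["r_protein"], t["p_protein"])
    s_r = sig(t["r_ratio"], t["p_ratio"])
    t = t.assign(sig_mrna=s_m, sig_protein=s_p, sig_ratio=s_r)
    t["category"] = [
        _TRUTH_TABLE[(bool(a), bool(b), bool(c))]
        for a, b, c in zip(s_m, s_p, s_r)
    ]
    t = t[t["category"] != "none"]

    tools = (binding.groupby(["mirna", "gene"])["tool"]
             .agg(lambda s: ",".join(sorted(set(s)))).rename("binding_tools"))
    t = t.merge(tools, on=["mirna", "gene"], how="inner")
    n_anom = int((t["category"] == "anomalous").sum())
    if n_anom:
        logger.warning("%d anomalous (S,NS,S) interaction(s) retained but "
                       "excluded from category summaries", n_anom)
    return t.reset_index(drop=True)


@dataclass
class CategorySummary:
    """Per-category interaction counts and derived percentage shares."""
    counts: dict = field(default_factory=dict)
    total: int = 0
    shares: dict = field(default_factory=dict)         # exact fractions
    shares_pct: dict = field(default_factory=dict)     # rounded whole percent

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts), "total": self.total,
                "shares_pct": dict(self.shares_pct)}


_SHARE_DEFS = {
    "transcriptomics_only": ("RD", "RD_o", "B_s"),
    "proteomics_benefit": ("B_w", "TR", "TR_o"),
    "tr_major": ("TR", "TR_o"),
    "concordant": ("B_s", "B_w"),
    "tr_involved": ("TR", "TR_o", "B_s", "B_w"),
}


def summarize_categories(records) -> CategorySummary:
    """Count categories and derive the standard percentage shares.

    ``records`` is either an interaction DataFrame with a ``category`` column
    or a mapping category -> count.  Anomalous records never enter the counts
    or the total.
    """
    if isinstance(records, pd.DataFrame):
        vc = records.loc[records["category"].isin(CATEGORIES), "category"].value_counts()
        counts = {c: int(vc.get(c, 0)) for c in CATEGORIES}
    else:
        counts = {c: int(records.get(c, 0)) for c in CATEGORIES}
    total = sum(counts.values())
    summary = CategorySummary(counts=counts, total=total)
    if total == 0:
        return summary
    for name, cats in _SHARE_DEFS.items():
        frac = sum(counts[c] for c in cats) / total
        summary.shares[name] = frac
        summary.shares_pct[name] = round(100 * frac)
    return summary


def mirna_mechanism_preference(records: pd.DataFrame,
                               min_targets: int = 5) -> pd.DataFrame:
    """Per-miRNA mechanism-preference Fisher tests with BH correction.

    For every miRNA with at least ``min_targets`` (non-anomalous) targets,
    a 2x2 table of [TR-major (TR or TR_o) vs other] x [this miRNA vs all
    other miRNAs] is tested one-sided for TR-major enrichment; the symmetric
    test for decay preference (RD or RD_o) is reported alongside.  FDR is
    Benjamini-Hochberg across the tested miRNAs, per direction.
    """
    recs = records[records["category"].isin(CATEGORIES)]
    per = recs.groupby("mirna")
    sizes = per.size()
    tested = sizes.index[sizes >= min_targets]
    if len(tested) < 2:
        raise ValueError(f"only {len(tested)} miRNAs with >= {min_targets} targets")

    is_tr = recs["category"].isin(("TR", "TR_o"))
    is_rd = recs["category"].isin(("RD", "RD_o"))
    total = len(recs)
    total_tr = int(is_tr.sum())
    total_rd = int(is_rd.sum())

    rows = []
    for mirna in tested:
        mask = recs["mirna"] == mirna
        n_i = int(mask.sum())
        tr_i = int((mask & is_tr).sum())
        rd_i = int((mask & is_rd).sum())
        _, p_tr = stats.fisher_exact(
            [[tr_i, n_i - tr_i],
             [total_tr - tr_i, (total - n_i) - (total_tr - tr_i)]],
            alternative="greater")
        _, p_rd = stats.fisher_exact(
            [[rd_i, n_i - rd_i],
             [total_rd - rd_i, (total - n_i) - (total_rd - rd_i)]],
            alternative="greater")
        odds_tr = _odds_ratio(tr_i, n_i - tr_i, total_tr - tr_i,
                              (total - n_i) - (total_tr - tr_i))
        rows.append({"mirna": mirna, "n_targets": n_i, "n_tr_major": tr_i,
                     "n_rd_major": rd_i, "odds_ratio_tr": odds_tr,
                     "p_tr": p_tr, "p_rd": p_rd})
    out = pd.DataFrame(rows)
    out["fdr_tr"] = multipletests(out["p_tr"], method="fdr_bh")[1]
    out["fdr_rd"] = multipletests(out["p_rd"], method="fdr_bh")[1]
    return out.sort_values("p_tr").reset_index(drop=True)


def _odds_ratio(a, b, c, d) -> float:
    if b * c == 0:
        return np.inf if a * d > 0 else np.nan
    return (a * d) / (b * c)
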