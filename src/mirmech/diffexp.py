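"""Two-condition spectral-count differential expression.

Counts for a gene are modelled as Poisson with a log link,
``log mu = b0 + b1 * group + log(total)``, where the offset is the run's
total spectral count so sequencing-depth differences cancel.  The group
coefficient is tested with a Wald z-test and converted to a log2 fold
change; Benjamini-Hochberg adjustment runs across all genes tested.  No
overdispersion term is fitted -- a known simplification of the plain
Poisson model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm


def poisson_de(counts_a, counts_b, totals_a, totals_b) -> tuple[float, float]:
    """Poisson-regression comparison of one gene between two groups.

    Returns (log2 fold change B vs A, two-sided Wald p).  Raises on an
    all-zero gene, which carries no information under the model.
    """
    ya = np.asarray(counts_a, dtype=float)
    yb = np.asarray(counts_b, dtype=float)
    ta = np.asarray(totals_a, dtype=float)
    tb = np.asarray(totals_b, dtype=float)
    if len(ya) < 1 or len(yb) < 1:
        raise ValueError("need at least one replicate per group")
    if ya.sum() + yb.sum() == 0:
        raise ValueError("all-zero gene: fold change undefined")
    y = np.concatenate([ya, yb])
    group = np.concatenate([np.zeros(len(ya)), np.ones(len(yb))])
    X = sm.add_constant(group)
    offset = np.log(np.concatenate([ta, tb]))
    fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    b1 = float(fit.params[1])
    p = float(fit.pvalues[1])
    return b1 / np.log(2.0), p


def poisson_de_table(counts: pd.DataFrame, group_b_cols: list[str],
                     totals: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene Poisson DE over a count matrix, with BH-adjusted FDR.

    ``counts`` has genes as rows and replicate runs as columns;
    ``group_b_cols`` names the columns of the second condition.  ``totals``
    defaults to the column sums.  All-zero genes are reported with an
    ``all_zero`` flag and NaN statistics rather than dropped silently.
    """
    cols_b = list(group_b_cols)
    cols_a = [c for c in counts.columns if c not in set(cols_b)]
    if not cols_a or not cols_b:
        raise ValueError("both groups need at least one column")
    if totals is None:
        totals = counts.sum(axis=0)
    rows = []
    for gene, row in counts.iterrows():
        if row.sum() == 0:
            rows.append({"gene": gene, "log2fc": np.nan, "p": np.nan,
                         "flag": "all_zero"})
            continue
        lfc, p = poisson_de(row[cols_a], row[cols_b],
                            totals[cols_a], totals[cols_b])
        rows.append({"gene": gene, "log2fc": lfc, "p": p, "flag": ""})
    out = pd.DataFrame(rows)
    tested = out["p"].notna()
    out["fdr"] = np.nan
    if tested.any():
        from statsmodels.stats.multitest import multipletests
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p"],
                                               method="fdr_bh")[1]
    return out


def fold_change(a: float, b: float, pseudocount: float = 0.0) -> float:
    """log2((b + pseudocount) / (a + pseudocount)) on averaged abundances."""
    if a < 0 or b < 0:
        raise ValueError("abundances must be nonnegative")
    if pseudocount <= 0 and (a == 0 or b == 0):
        raise ValueError("zero abundance requires a positive pseudocount")
    return float(np.log2((b + pseudocount) / (a + pseudocount)))
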