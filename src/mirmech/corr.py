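"""The three correlation types and their significance.

For each miRNA-gene pair we correlate replicate-averaged, log2-scale
abundances across samples at three layers: mRNA (mRNA decay), protein
(combined output), and the protein-to-mRNA ratio (translational
efficiency).  Significance is one-sided toward negative association:
p is the lower t tail of r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
freedom, and a layer is called significant only when both r < r_cut and
p < p_cut hold strictly (defaults r_cut = -0.8, p_cut = 0.005).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

logger = logging.getLogger(__name__)

R_CUT_DEFAULT = -0.8
P_CUT_DEFAULT = 0.005


@dataclass(frozen=True)
class CorrelationTriple:
    mirna_id: str
    gene_id: str
    r_mrna: float
    p_mrna: float
    r_protein: float
    p_protein: float
    r_ratio: float
    p_ratio: float
    n: int


@dataclass(frozen=True)
class SignificancePattern:
    """Which of the three inverse correlations are significant."""
    sig_mrna: bool
    sig_protein: bool
    sig_ratio: bool

    def as_tuple(self) -> tuple[bool, bool, bool]:
        return (self.sig_mrna, self.sig_protein, self.sig_ratio)


def compute_ratio_matrix(protein: ExpressionMatrix,
                         mrna: ExpressionMatrix) -> ExpressionMatrix:
    """Protein-to-mRNA ratio rows: log2 protein minus log2 mRNA per sample."""
    if protein.scale != "log2" or mrna.scale != "log2":
        raise ValueError("ratio requires log2-scale matrices")
    shared = protein.data.index.intersection(mrna.data.index)
    if shared.empty:
        raise ValueError("no genes shared between protein and mRNA matrices")
    dropped = len(protein.data.index.union(mrna.data.index)) - len(shared)
    if dropped:
        logger.info("ratio matrix: %d genes present in only one layer excluded", dropped)
    cols = [c for c in protein.data.columns if c in set(mrna.data.columns)]
    if not cols:
        raise ValueError("no shared sample columns between protein and mRNA")
    ratio = protein.data.loc[shared, cols] - mrna.data.loc[shared, cols]
    return ExpressionMatrix(ratio, replicate_map={c: protein.replicate_map[c] for c in cols},
                            scale="log2")


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation with a one-sided (negative-association) p-value.

    The p-value is the lower tail of the t transform of r on n-2 degrees of
    freedom; for Spearman the same transform is applied to the rank
    correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input: correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y, alternative="less")
    elif method == "spearman":
        res = stats.spearmanr(x, y, alternative="less")
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def _row_standardize(df: pd.DataFrame, method: str) -> np.ndarray:
    a = df.to_numpy(dtype=float)
    if method == "spearman":
        a = np.apply_along_axis(stats.rankdata, 1, a)
    mu = a.mean(axis=1, keepdims=True)
    sd = a.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (a - mu) / sd
    return z


def _one_sided_p(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    return stats.t.cdf(t, df=n - 2)


def correlation_table(mirna: ExpressionMatrix, mrna: ExpressionMatrix,
                      protein: ExpressionMatrix, ratio: ExpressionMatrix,
                      method: str = "pearson") -> pd.DataFrame:
    """All miRNA x gene correlation triples, vectorized.

    Matrices must be replicate-averaged with identical sample columns.  Genes
    are the intersection of the mRNA, protein and ratio matrices; pairs where
    any layer has zero variance get NaN r/p at that layer and are logged
    (they are excluded from classification downstream, never coerced to 0).
    """
    cols = list(mirna.data.columns)
    for m in (mrna, protein, ratio):
        if list(m.data.columns) != cols:
            raise ValueError("all matrices must share identical sample columns")
    n = len(cols)
    genes = mrna.data.index.intersection(protein.data.index).intersection(ratio.data.index)
    zm = _row_standardize(mirna.data, method)
    layers = {}
    for name, mat in (("mrna", mrna), ("protein", protein), ("ratio", ratio)):
        zg = _row_standardize(mat.data.loc[genes], method)
        r = (zm @ zg.T) / (n - 1)
        r = np.clip(r, -1.0, 1.0)
        layers[name] = (r, _one_sided_p(r, n))
    n_nan = sum(int(np.isnan(r).sum()) for r, _ in layers.values())
    if n_nan:
        logger.info("correlation table: %d undefined correlations (zero variance)", n_nan)
    mi = pd.MultiIndex.from_product([mirna.data.index, genes], names=["mirna", "gene"])
    out = pd.DataFrame(index=mi).reset_index()
    for name in ("mrna", "protein", "ratio"):
        r, p = layers[name]
        out[f"r_{name}"] = r.ravel()
        out[f"p_{name}"] = p.ravel()
    out["n"] = n
    return out


def significance_pattern(triple, r_cut: float = R_CUT_DEFAULT,
                         p_cut: float = P_CUT_DEFAULT) -> SignificancePattern:
    """Apply the joint r/p threshold to each layer (strict inequalities)."""
    def sig(r, p):
        return bool(np.isfinite(r) and np.isfinite(p) and r < r_cut and p < p_cut)
    return SignificancePattern(
        sig_mrna=sig(triple.r_mrna, triple.p_mrna),
        sig_protein=sig(triple.r_protein, triple.p_protein),
        sig_ratio=sig(triple.r_ratio, triple.p_ratio),
    )


def partial_correlation(mirna_v, protein_v, mrna_v) -> tuple[float, float]:
    """First-order partial correlation of miRNA and protein given mRNA.

    r_mp.r = (r_mp - r_mr * r_pr) / sqrt((1 - r_mr^2)(1 - r_pr^2)); the
    one-sided (negative) p comes from the t transform on n-3 degrees of
    freedom.
    """
    x = np.asarray(mirna_v, dtype=float)
    y = np.asarray(protein_v, dtype=float)
    z = np.asarray(mrna_v, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    r_mp = np.corrcoef(x, y)[0, 1]
    r_mr = np.corrcoef(x, z)[0, 1]
    r_pr = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_mr ** 2) * (1 - r_pr ** 2)
    if not np.isfinite(denom) or denom <= 1e-12:
        raise ValueError("degenerate inputs: a conditioning correlation is +/-1")
    r = (r_mp - r_mr * r_pr) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    t = r * np.sqrt(df / max(1.0 - r * r, 1e-300))
    p = float(stats.t.cdf(t, df=df))
    return r, p
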