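"""Proteomics quantification arithmetic.

Decoy-based FDR estimation, protein-level identification filters, total
spectral-count normalization, gene-representative selection by interquartile
range, replicate averaging and the miRNA variance filter.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

PSM_COLUMNS = ["peptide", "protein", "decoy", "run", "spectra"]


def compute_decoy_fdr(n_forward: int, n_reverse: int) -> float:
    """Decoy-database FDR estimate, ``2R / (F + R)``, clamped to [0, 1].

    The factor 2 reflects that a random match is equally likely to hit the
    forward and the reversed database, so reverse hits estimate half of the
    false forward hits.
    """
    if n_forward < 0 or n_reverse < 0:
        raise ValueError("identification counts must be nonnegative")
    total = n_forward + n_reverse
    if total == 0:
        raise ValueError("empty identification set: forward + reverse = 0")
    return min(1.0, 2.0 * n_reverse / total)


def compute_decoy_fdr_from_table(psm: pd.DataFrame) -> float:
    """FDR of a PSM table, counting each row as one identification."""
    n_rev = int(psm["decoy"].sum())
    return compute_decoy_fdr(len(psm) - n_rev, n_rev)


def filter_proteins(psm: pd.DataFrame, min_peptides: int = 2,
                    min_spectra: int = 10) -> list[str]:
    """Protein ids passing the two-peptide and total-spectra filters.

    A protein is retained when it is supported by at least ``min_peptides``
    distinct (non-decoy) peptide sequences and at least ``min_spectra`` MS/MS
    spectra summed over all runs.  Both bounds are inclusive.
    """
    fwd = psm.loc[~psm["decoy"].astype(bool)]
    if fwd.empty:
        return []
    g = fwd.groupby("protein")
    n_pep = g["peptide"].nunique()
    n_spec = g["spectra"].sum()
    keep = n_pep.index[(n_pep >= min_peptides) & (n_spec >= min_spectra)]
    return sorted(keep)


def normalize_spectral_counts(m: ExpressionMatrix,
                              pseudocount: float = 1.0) -> ExpressionMatrix:
    """Total-spectral-count normalization followed by log2 transform.

    Every run is scaled so its column total equals the largest observed column
    total, then values are log2(x + pseudocount) transformed.  The pseudocount
    keeps zero counts at log2 value 0 for the default of 1.
    """
    if m.scale != "counts":
        raise ValueError(f"expected raw counts, got scale={m.scale!r}")
    totals = m.data.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"column(s) with zero total spectral count: {bad}")
    scaled = m.data * (totals.max() / totals)
    logged = np.log2(scaled + pseudocount)
    return m.copy_with(logged, scale="log2", replicate_map=dict(m.replicate_map))


def select_gene_representative(protein_matrix: ExpressionMatrix,
                               protein_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Pick, per gene, the mapped protein with the largest IQR.

    The interquartile range is computed across all columns with
    linear-interpolation quartiles; ties are broken by lexicographically
    smallest protein id so the choice is reproducible.  Output rows are exact
    copies of the winning protein rows, re-keyed by gene.
    """
    if protein_matrix.scale != "log2":
        raise ValueError("gene representative selection expects a log2-scale matrix")
    df = protein_matrix.data
    q1 = df.quantile(0.25, axis=1)
    q3 = df.quantile(0.75, axis=1)
    iqr = q3 - q1

    gene_to_proteins: dict[str, list[str]] = {}
    for prot, gene in protein_to_gene.items():
        gene_to_proteins.setdefault(gene, []).append(prot)

    rows, genes = [], []
    for gene in sorted(gene_to_proteins):
        present = sorted(p for p in gene_to_proteins[gene] if p in df.index)
        if not present:
            raise ValueError(f"gene {gene!r} has no mapped protein in the matrix")
        best = max(present, key=lambda p: (iqr[p], ))  # max IQR; ties -> first
        # sorted(present) guarantees lexicographic tie-break: max keeps the
        # first maximal element encountered.
        rows.append(df.loc[best])
        genes.append(gene)
    out = pd.DataFrame(rows, index=pd.Index(genes, name="gene"))
    return protein_matrix.copy_with(out, replicate_map=dict(protein_matrix.replicate_map))


def average_replicates(m: ExpressionMatrix) -> ExpressionMatrix:
    """Arithmetic mean of replicate columns per biological sample."""
    samples = m.samples
    cols = {}
    for s in samples:
        cc = m.columns_for(s)
        if not cc:
            raise ValueError(f"sample {s!r} has no replicate columns")
        cols[s] = m.data[cc].mean(axis=1)
    out = pd.DataFrame(cols)[samples]
    return ExpressionMatrix(out, replicate_map={s: s for s in samples}, scale=m.scale)


def filter_low_variance_mirnas(m: ExpressionMatrix,
                               threshold: float = 1.0) -> ExpressionMatrix:
    """Drop miRNAs whose across-sample variance is <= threshold.

    Variance is the unbiased (n-1 denominator) sample variance of the
    replicate-averaged values; the boundary is excluded (variance exactly at
    the threshold is filtered out).
    """
    var = m.data.var(axis=1, ddof=1)
    keep = var > threshold
    return m.copy_with(m.data.loc[keep], replicate_map=dict(m.replicate_map))
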