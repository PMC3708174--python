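"""Model/Results front end over the staged analysis.

``MirnaTargetModel`` holds the raw inputs (expression matrices, sequences,
binding evidence) together with the analysis thresholds; ``fit()`` runs the
full chain -- quantification, replicate averaging, variance filtering, the
three correlations, site annotation, interaction classification, feature
efficacy -- and returns a ``MirnaTargetResults`` carrying every table plus a
text ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import classify, corr, efficacy, quant, seqfeat
from .matrix import ExpressionMatrix
from .synthdata import SimulationConfig, generate_expression

logger = logging.getLogger(__name__)

_MECHANISM_TO_CATEGORIES = {
    "decay_only": ("RD", "RD_o"),
    "translation_only": ("TR", "TR_o"),
    "both_strong": ("B_s",),
    "both_weak": ("B_w",),
    "decay_compensated": ("RD", "RD_o"),
    "translation_compensated": ("TR", "TR_o"),
}


@dataclass
class MirnaTargetModel:
    """Integrative miRNA-mechanism analysis over matched omics matrices.

    ``protein`` may be raw spectral counts (normalized internally) or an
    already log2-scale matrix.  ``sequences``/``mirna_seqs`` are optional;
    without them site-feature analyses are skipped.  Without a protein
    matrix the model degrades to mRNA-correlation-only screening.
    """
    mirna: ExpressionMatrix
    mrna: ExpressionMatrix
    protein: ExpressionMatrix | None = None
    binding: pd.DataFrame | None = None
    sequences: dict | None = None                 # gene id -> GeneSequences
    mirna_seqs: list | None = None                # MatureMiRNA list
    protein_to_gene: dict | None = None
    r_cut: float = corr.R_CUT_DEFAULT
    p_cut: float = corr.P_CUT_DEFAULT
    variance_threshold: float = 1.0
    pseudocount: float = 1.0
    method: str = "pearson"
    min_set_size: int = efficacy.MIN_SET_SIZE
    truth: list = field(default_factory=list)     # planted interactions, if any

    @classmethod
    def from_simulation(cls, config: SimulationConfig, **kwargs) -> "MirnaTargetModel":
        sim = generate_expression(config)
        return cls(mirna=sim.mirna_matrix, mrna=sim.mrna_matrix,
                   protein=sim.protein_count_matrix, binding=sim.binding_table,
                   sequences=sim.sequences, mirna_seqs=sim.mirnas,
                   truth=sim.truth, **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "MirnaTargetResults":
        mirna_avg = quant.average_replicates(self.mirna)
        mirna_f = quant.filter_low_variance_mirnas(mirna_avg,
                                                   self.variance_threshold)
        n_dropped = len(mirna_avg.data) - len(mirna_f.data)
        logger.info("variance filter: %d of %d miRNAs retained",
                    len(mirna_f.data), len(mirna_avg.data))
        mrna_avg = quant.average_replicates(self.mrna)

        if self.protein is None:
            warnings.warn("no protein matrix: mechanism classification is "
                          "restricted to the mRNA-decay-detectable pattern "
                          "(RD_o only)", stacklevel=2)
            return self._fit_degraded(mirna_f, mrna_avg, n_dropped)

        prot = self.protein
        if prot.scale == "counts":
            prot = quant.normalize_spectral_counts(prot, self.pseudocount)
        if self.protein_to_gene is not None:
            prot = quant.select_gene_representative(prot, self.protein_to_gene)
        prot_avg = quant.average_replicates(prot)
        ratio = corr.compute_ratio_matrix(prot_avg, mrna_avg)

        genes = ratio.data.index
        triples = corr.correlation_table(
            mirna_f,
            mrna_avg.copy_with(mrna_avg.data.loc[genes],
                               replicate_map=dict(mrna_avg.replicate_map)),
            prot_avg.copy_with(prot_avg.data.loc[genes],
                               replicate_map=dict(prot_avg.replicate_map)),
            ratio, method=self.method)

        sites = self._site_table()
        interactions = None
        summary = None
        preference = None
        if self.binding is not None:
            interactions = classify.predict_interactions(
                triples, self.binding, r_cut=self.r_cut, p_cut=self.p_cut)
            summary = classify.summarize_categories(interactions)
            try:
                preference = classify.mirna_mechanism_preference(interactions)
            except ValueError as exc:
                logger.info("mechanism preference skipped: %s", exc)

        efficacy_tables = self._efficacy(triples, sites)
        return MirnaTargetResults(
            model=self, correlations=triples, sites=sites,
            interactions=interactions, category_summary=summary,
            preference=preference, efficacy_tables=efficacy_tables,
            n_mirnas_used=len(mirna_f.data), n_mirnas_filtered=n_dropped,
            n_genes_used=len(genes))

    def _fit_degraded(self, mirna_f, mrna_avg, n_dropped) -> "MirnaTargetResults":
        import numpy as np
        rows = []
        for mid in mirna_f.data.index:
            for gid in mrna_avg.data.index:
                r, p = corr.correlate(mirna_f.data.loc[mid],
                                      mrna_avg.data.loc[gid], self.method)
                rows.append({"mirna": mid, "gene": gid, "r_mrna": r,
                             "p_mrna": p, "r_protein": np.nan,
                             "p_protein": np.nan, "r_ratio": np.nan,
                             "p_ratio": np.nan, "n": mirna_f.data.shape[1]})
        triples = pd.DataFrame(rows)
        interactions = None
        if self.binding is not None:
            sig = (triples["r_mrna"] < self.r_cut) & (triples["p_mrna"] < self.p_cut)
            t = triples[sig].copy()
            t["category"] = "RD_o"
            tools = (self.binding.groupby(["mirna", "gene"])["tool"]
                     .agg(lambda s: ",".join(sorted(set(s)))).rename("binding_tools"))
            interactions = t.merge(tools, on=["mirna", "gene"], how="inner")
        return MirnaTargetResults(
            model=self, correlations=triples, sites=self._site_table(),
            interactions=interactions,
            category_summary=(classify.summarize_categories(interactions)
                              if interactions is not None else None),
            preference=None, efficacy_tables={},
            n_mirnas_used=len(mirna_f.data), n_mirnas_filtered=n_dropped,
            n_genes_used=len(mrna_avg.data))

    def _site_table(self) -> pd.DataFrame | None:
        if self.sequences is None or self.mirna_seqs is None:
            return None
        genes = list(self.sequences.values())
        return seqfeat.site_table(self.mirna_seqs, genes)

    def _efficacy(self, triples: pd.DataFrame, sites) -> dict:
        if sites is None or sites.empty:
            return {}
        tables: dict[str, object] = {}
        frames = []
        for layer in ("mrna", "ratio"):
            frames.append(efficacy.site_type_efficacy(
                triples, sites, layer, self.min_set_size))
            frames.append(efficacy.region_efficacy(
                triples, sites, layer, self.min_set_size))
        for layer in ("mrna", "ratio", "protein"):
            try:
                cmp_ = efficacy.au_quartile_efficacy(triples, sites, layer)
                frames.append(efficacy._as_frame([cmp_]))
            except ValueError as exc:
                logger.info("AU-quartile efficacy (%s) skipped: %s", layer, exc)
            try:
                frames.append(efficacy.pairing_class_efficacy(triples, sites, layer))
            except ValueError as exc:
                logger.info("3'-pairing efficacy (%s) skipped: %s", layer, exc)
        tables["features"] = pd.concat(frames, ignore_index=True)
        try:
            t, p, n = efficacy.paired_pairing_ttest(triples, sites, self.r_cut)
            tables["paired_pairing_ttest"] = {"t": t, "p": p, "n_combinations": n}
        except ValueError as exc:
            logger.info("paired 3'-pairing t-test skipped: %s", exc)
        return tables


@dataclass
class MirnaTargetResults:
    """Fitted results: correlation, site, interaction and efficacy tables."""
    model: MirnaTargetModel
    correlations: pd.DataFrame
    sites: pd.DataFrame | None
    interactions: pd.DataFrame | None
    category_summary: classify.CategorySummary | None
    preference: pd.DataFrame | None
    efficacy_tables: dict
    n_mirnas_used: int = 0
    n_mirnas_filtered: int = 0
    n_genes_used: int = 0

    # -- recovery diagnostics against planted truth ------------------------

    def confusion_matrix(self, truth=None) -> pd.DataFrame:
        """Planted mechanism x assigned category contingency table.

        Rows are planted mechanisms; columns the six categories plus
        ``anomalous`` and ``unassigned`` (planted pairs that did not survive
        prediction).
        """
        truth = truth if truth is not None else self.model.truth
        if not truth:
            raise ValueError("no planted truth available")
        if self.interactions is None:
            raise ValueError("no interactions: fit with binding evidence")
        assigned = {(r.mirna, r.gene): r.category
                    for r in self.interactions.itertuples()}
        cats = list(classify.CATEGORIES) + ["anomalous", "unassigned"]
        mechanisms = [m for m in _MECHANISM_TO_CATEGORIES]
        table = pd.DataFrame(0, index=mechanisms, columns=cats)
        for p in truth:
            if p.mechanism == "none":
                continue
            cat = assigned.get((p.mirna_id, p.gene_id), "unassigned")
            table.loc[p.mechanism, cat] += 1
        return table

    def recovery_rates(self, truth=None) -> dict[str, float]:
        """Fraction of planted interactions assigned a compatible category."""
        cm = self.confusion_matrix(truth)
        out = {}
        for mech, ok_cats in _MECHANISM_TO_CATEGORIES.items():
            n = cm.loc[mech].sum()
            if n:
                out[mech] = float(cm.loc[mech, list(ok_cats)].sum() / n)
        total = cm.to_numpy().sum()
        out["anomalous_fraction"] = float(cm["anomalous"].sum() / total) if total else 0.0
        return out

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        lines = ["miRNA-target mechanism analysis", "=" * 34]
        lines.append(f"miRNAs analysed: {self.n_mirnas_used} "
                     f"({self.n_mirnas_filtered} removed by variance filter)")
        lines.append(f"genes analysed:  {self.n_genes_used}")
        lines.append(f"thresholds:      r < {self.model.r_cut}, "
                     f"p < {self.model.p_cut} ({self.model.method}, one-sided)")
        if self.category_summary is not None:
            s = self.category_summary
            lines.append("")
            lines.append(f"predicted interactions: {s.total}")
            lines.append("  " + "  ".join(f"{c}={s.counts[c]}"
                                          for c in classify.CATEGORIES))
            for name, pct in s.shares_pct.items():
                lines.append(f"  {name:<22s} {pct:3d}%")
        if self.preference is not None and not self.preference.empty:
            top = self.preference.iloc[0]
            lines.append("")
            lines.append(f"strongest TR preference: {top['mirna']} "
                         f"({top['n_tr_major']}/{top['n_targets']} TR-major, "
                         f"Fisher p={top['p_tr']:.3g}, FDR={top['fdr_tr']:.3g})")
        t = self.efficacy_tables.get("paired_pairing_ttest")
        if t:
            lines.append(f"paired 3'-pairing t-test: t={t['t']:.3f} "
                         f"p={t['p']:.3g} over {t['n_combinations']} combinations")
        return "\n".join(lines)
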