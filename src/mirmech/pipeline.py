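"""End-to-end orchestration from a configuration file.

A run executes quantification, correlation, site annotation, efficacy and
classification in order and writes every stage table plus a human-readable
report and a JSON summary under the run directory.  Thresholds and the seed
are echoed into the run log so threshold-heavy analyses stay auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import corr, efficacy
from .matrix import ExpressionMatrix
from .model import MirnaTargetModel
from .seqfeat import MatureMiRNA, GeneSequences, write_site_report
from .synthdata import SimulationConfig, reference_config, write_omics_set, generate_expression

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration: either real input paths or synthetic mode."""
    # real-input mode
    mirna_tsv: str | None = None
    mrna_tsv: str | None = None
    protein_tsv: str | None = None
    protein_scale: str = "counts"
    binding_tsv: str | None = None
    mirna_fasta: str | None = None
    regions_fasta: str | None = None
    # synthetic mode
    synthetic: bool = False
    simulation: SimulationConfig | None = None
    # thresholds
    r_cut: float = corr.R_CUT_DEFAULT
    p_cut: float = corr.P_CUT_DEFAULT
    variance_threshold: float = 1.0
    pseudocount: float = 1.0
    method: str = "pearson"
    min_set_size: int = efficacy.MIN_SET_SIZE
    # run control
    out_dir: str = "mirmech_run"
    seed: int = 0

    def __post_init__(self):
        real = self.mirna_tsv is not None
        if real == self.synthetic:
            raise ValueError("exactly one of real-input and synthetic mode "
                             "must be configured")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw, simulation=None) if sim is None else None
        if sim is not None:
            from .synthdata import make_interaction, SiteSpec
            planted = []
            for row in sim.pop("planted_interactions", []):
                spec = row.pop("site_spec", None)
                planted.append(make_interaction(
                    **row, site_spec=SiteSpec(**spec) if spec else None))
            cfg = cls(**raw, simulation=SimulationConfig(
                planted_interactions=planted, **sim))
        return cfg


def _read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def load_model(config: PipelineConfig) -> MirnaTargetModel:
    import pandas as pd
    if config.synthetic:
        sim_cfg = config.simulation or reference_config(config.seed)
        if config.simulation is None:
            logger.info("no simulation block: using the reference configuration")
        model = MirnaTargetModel.from_simulation(
            sim_cfg, r_cut=config.r_cut, p_cut=config.p_cut,
            variance_threshold=config.variance_threshold,
            pseudocount=config.pseudocount, method=config.method,
            min_set_size=config.min_set_size)
        return model

    mirna = ExpressionMatrix.read_tsv(config.mirna_tsv, scale="log2")
    mrna = ExpressionMatrix.read_tsv(config.mrna_tsv, scale="log2")
    protein = (ExpressionMatrix.read_tsv(config.protein_tsv,
                                         scale=config.protein_scale)
               if config.protein_tsv else None)
    binding = (pd.read_csv(config.binding_tsv, sep="\t")
               if config.binding_tsv else None)
    mirna_seqs = sequences = None
    if config.mirna_fasta:
        mirna_seqs = [MatureMiRNA(i, s) for i, s in _read_fasta(config.mirna_fasta)]
    if config.regions_fasta:
        sequences = {}
        for name, seq in _read_fasta(config.regions_fasta):
            gene, _, region = name.partition(":")
            gs = sequences.setdefault(gene, GeneSequences(gene_id=gene))
            if region == "5UTR":
                gs.utr5 = seq.upper().replace("T", "U")
            elif region == "ORF":
                gs.orf = seq.upper().replace("T", "U")
            elif region == "3UTR":
                gs.utr3 = seq.upper().replace("T", "U")
    return MirnaTargetModel(
        mirna=mirna, mrna=mrna, protein=protein, binding=binding,
        sequences=sequences, mirna_seqs=mirna_seqs, r_cut=config.r_cut,
        p_cut=config.p_cut, variance_threshold=config.variance_threshold,
        pseudocount=config.pseudocount, method=config.method,
        min_set_size=config.min_set_size)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("mirmech")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        logger.info("thresholds: r_cut=%s p_cut=%s variance_threshold=%s "
                    "pseudocount=%s method=%s min_set_size=%s seed=%s",
                    config.r_cut, config.p_cut, config.variance_threshold,
                    config.pseudocount, config.method, config.min_set_size,
                    config.seed)
        stage = "load"
        try:
            model = load_model(config)
            if config.synthetic:
                sim_cfg = config.simulation or reference_config(config.seed)
                write_omics_set(generate_expression(sim_cfg), out / "inputs")
            stage = "fit"
            results = model.fit()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

        results.correlations.to_csv(out / "correlations.tsv", sep="\t",
                                    index=False, float_format="%.6g")
        if results.sites is not None:
            write_site_report(results.sites, out / "sites.tsv")
        if results.interactions is not None:
            results.interactions.to_csv(out / "interactions.tsv", sep="\t",
                                        index=False, float_format="%.6g")
        if results.preference is not None:
            results.preference.to_csv(out / "mirna_preference.tsv", sep="\t",
                                      index=False, float_format="%.6g")
        feats = results.efficacy_tables.get("features")
        if feats is not None:
            feats.to_csv(out / "efficacy.tsv", sep="\t", index=False,
                         float_format="%.6g")

        summary: dict = {"seed": config.seed,
                         "n_mirnas_used": results.n_mirnas_used,
                         "n_genes_used": results.n_genes_used}
        if results.category_summary is not None:
            summary["categories"] = results.category_summary.as_dict()
        t = results.efficacy_tables.get("paired_pairing_ttest")
        if t:
            summary["paired_pairing_ttest"] = t
        if config.synthetic and model.truth:
            cm = results.confusion_matrix()
            cm.to_csv(out / "confusion_matrix.tsv", sep="\t")
            summary["recovery"] = results.recovery_rates()
        (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     default=float))
        (out / "report.txt").write_text(results.summary() + "\n")
        return out
    finally:
        root.removeHandler(handler)
        handler.close()
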