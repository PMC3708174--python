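"""Synthetic multi-omics data with planted miRNA regulatory mechanisms.

The generator emulates the study design the analysis assumes: nine cell
lines measured in three replicates each, miRNA abundance varying on the
log2 scale across lines, and target genes responding through planted
mechanisms:

* ``decay_only``              -- negative log2 mRNA slope vs miRNA;
* ``translation_only``        -- negative log2(protein/mRNA) slope;
* ``both_strong``             -- both slopes strongly negative;
* ``both_weak``               -- both slopes weakly negative;
* ``decay_compensated``       -- strong decay plus a positive translation-layer
  slope that buffers the protein level;
* ``translation_compensated`` -- strong repression plus a positive mRNA-layer
  slope;
* ``none``                    -- background gene.

Protein abundance is observed as Poisson spectral counts whose per-run
expectations are proportional to linear protein abundance, scaled to a
configurable total depth.  Gene regions carry planted seed sites with
controlled type, region, flanking AU content and 3'-pairing level, plus a
binding-evidence table covering every planted pair.  A single integer seed
fixes all randomness end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .seqfeat import (
    MatureMiRNA, GeneSequences, revcomp, _COMPLEMENT, PAIRING_WINDOW,
)

MECHANISMS = (
    "decay_only", "translation_only", "both_strong", "both_weak",
    "decay_compensated", "translation_compensated", "none",
)
TOOLS = ("TargetScan", "miRanda", "MirTarget2")

STRONG_EFFECT = -1.5   # log2 slope of the planted strong mechanisms
WEAK_EFFECT = -0.05    # "weak": below the detection limit of a single layer
COMP_EFFECT = 1.5      # compensating positive slope at the opposite layer


@dataclass
class SiteSpec:
    """Planted seed-site description for one gene."""
    site_type: str = "8mer"            # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    region: str = "3UTR"               # 5UTR | ORF | 3UTR
    au: str = "neutral"                # high | low | neutral
    pairing: str = "neutral"           # good | poor | neutral

    def __post_init__(self):
        if self.site_type not in ("6mer", "7mer-A1", "7mer-m8", "8mer"):
            raise ValueError(f"unknown site type {self.site_type!r}")
        if self.region not in ("5UTR", "ORF", "3UTR"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class PlantedInteraction:
    mirna_id: str
    gene_id: str
    mechanism: str
    decay_effect: float = 0.0
    translation_effect: float = 0.0
    compensation_effect: float = 0.0
    site_spec: SiteSpec | None = None

    def __post_init__(self):
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.decay_effect > 0 or self.translation_effect > 0:
            raise ValueError("decay/translation effects must be <= 0")
        if self.compensation_effect < 0:
            raise ValueError("compensation effect must be >= 0")
        if self.compensation_effect > 0 and not self.mechanism.endswith("_compensated"):
            raise ValueError("compensation only applies to *_compensated mechanisms")
        checks = {
            "decay_only": self.translation_effect == 0,
            "translation_only": self.decay_effect == 0,
            "decay_compensated": self.translation_effect == 0,
            "translation_compensated": self.decay_effect == 0,
            "none": self.decay_effect == 0 and self.translation_effect == 0,
        }
        if not checks.get(self.mechanism, True):
            raise ValueError(
                f"effects inconsistent with mechanism {self.mechanism!r}")

    @property
    def mrna_slope(self) -> float:
        s = self.decay_effect
        if self.mechanism == "translation_compensated":
            s += self.compensation_effect
        return s

    @property
    def ratio_slope(self) -> float:
        s = self.translation_effect
        if self.mechanism == "decay_compensated":
            s += self.compensation_effect
        return s


def make_interaction(mirna_id: str, gene_id: str, mechanism: str,
                     strong: float = STRONG_EFFECT, weak: float = WEAK_EFFECT,
                     comp: float = COMP_EFFECT,
                     site_spec: SiteSpec | None = None) -> PlantedInteraction:
    """Build a planted interaction with the default effect magnitudes."""
    kw = dict(mirna_id=mirna_id, gene_id=gene_id, mechanism=mechanism,
              site_spec=site_spec)
    if mechanism == "decay_only":
        kw["decay_effect"] = strong
    elif mechanism == "translation_only":
        kw["translation_effect"] = strong
    elif mechanism == "both_strong":
        kw.update(decay_effect=strong, translation_effect=strong)
    elif mechanism == "both_weak":
        kw.update(decay_effect=weak, translation_effect=weak)
    elif mechanism == "decay_compensated":
        kw.update(decay_effect=strong, compensation_effect=comp)
    elif mechanism == "translation_compensated":
        kw.update(translation_effect=strong, compensation_effect=comp)
    elif mechanism != "none":
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return PlantedInteraction(**kw)


@dataclass
class SimulationConfig:
    n_mirnas: int = 10
    n_genes: int = 200
    n_samples: int = 9
    n_replicates: int = 3
    planted_interactions: list = field(default_factory=list)
    mirna_log_sd: float = 2.0        # across-sample sd of log2 miRNA abundance
    mirna_rep_sd: float = 0.05       # replicate noise of log2 miRNA
    noise_sd_mrna: float = 0.15      # residual log2 noise per mRNA replicate
    noise_sd_protein: float = 0.15   # residual log2 noise per protein replicate
    spectral_depth: float = 2e5      # expected total spectral counts per run
    gc_fraction: float = 0.5         # background sequence GC content
    utr5_len: int = 200
    orf_len: int = 600
    utr3_len: int = 600
    n_decoy_bindings: int = 100      # binding rows for non-planted pairs
    seed: int = 0

    def __post_init__(self):
        for name in ("n_mirnas", "n_genes", "n_samples", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("mirna_log_sd", "mirna_rep_sd", "noise_sd_mrna",
                     "noise_sd_protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.spectral_depth <= 0:
            raise ValueError("spectral_depth must be positive")
        genes = [p.gene_id for p in self.planted_interactions]
        if len(set(genes)) != len(genes):
            raise ValueError("planted gene ids collide (a gene may carry only "
                             "one planted interaction)")
        if set(genes) & {p.mirna_id for p in self.planted_interactions}:
            raise ValueError("planted gene and miRNA ids collide")

    @property
    def mirna_ids(self) -> list[str]:
        return [f"miR-{i + 1:03d}" for i in range(self.n_mirnas)]

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1:04d}" for i in range(self.n_genes)]


@dataclass
class SimulatedOmicsSet:
    mirna_matrix: ExpressionMatrix           # log2 scale, replicate columns
    mrna_matrix: ExpressionMatrix            # log2 scale, replicate columns
    protein_count_matrix: ExpressionMatrix   # raw spectral counts
    protein_log2_matrix: ExpressionMatrix    # pre-count log2 protein layer
    sequences: dict                          # gene id -> GeneSequences
    mirnas: list                             # MatureMiRNA objects
    binding_table: pd.DataFrame              # mirna, gene, tool
    truth: list                              # PlantedInteraction list
    site_truth: pd.DataFrame                 # planted site positions

    def truth_frame(self) -> pd.DataFrame:
        rows = [{
            "mirna": p.mirna_id, "gene": p.gene_id, "mechanism": p.mechanism,
            "decay_effect": p.decay_effect,
            "translation_effect": p.translation_effect,
            "compensation_effect": p.compensation_effect,
        } for p in self.truth]
        return pd.DataFrame(rows, columns=["mirna", "gene", "mechanism",
                                           "decay_effect", "translation_effect",
                                           "compensation_effect"])


# ---------------------------------------------------------------------------
# miRNA sequence design
# ---------------------------------------------------------------------------
# Synthetic miRNAs are 22 nt with a mixed-composition unique seed (so a pure
# A/U or pure G/C flank can never contain an accidental seed complement) and
# an all-A 3' half.  With the 3' half over {A}, filling a site's upstream
# pairing window with A (AU-rich context) or C (GC-rich context) guarantees
# zero Watson-Crick pairing, i.e. a 3'-pairing score of exactly 0 for "poor"
# sites, while "good" sites overwrite the canonical m13-m18 complement (all
# U) for a score of 5.

def _random_mixed_seed(rng, used: set) -> str:
    while True:
        seed = "".join(rng.choice(list("ACGU"), size=6))
        if set(seed) & set("AU") and set(seed) & set("GC") and seed not in used:
            used.add(seed)
            return seed


def generate_mirnas(config: SimulationConfig, rng) -> list[MatureMiRNA]:
    used: set = set()
    out = []
    for mid in config.mirna_ids:
        m1 = rng.choice(list("ACGU"))
        seed = _random_mixed_seed(rng, used)
        m8 = rng.choice(list("GC"))  # mixed-composition 8mer core, see above
        tail = "A" * 14              # positions 9..22
        out.append(MatureMiRNA(id=mid, seq=m1 + seed + m8 + tail))
    return out


# ---------------------------------------------------------------------------
# Sequences with planted sites
# ---------------------------------------------------------------------------

def _site_string(mirna: MatureMiRNA, site_type: str) -> str:
    core = revcomp(mirna.seed)
    m8c = _COMPLEMENT[mirna.nt(8)]
    return {
        "6mer": core,
        "7mer-A1": core + "A",
        "7mer-m8": m8c + core,
        "8mer": m8c + core + "A",
    }[site_type]


def _random_seq(rng, length: int, gc: float) -> list[str]:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return list(rng.choice(list("ACGU"), size=length, p=probs))


def _plant_site(region: list[str], mirna: MatureMiRNA, spec: SiteSpec,
                pos: int, rng) -> tuple[int, int, set[int]]:
    """Write the site and its engineered context into ``region`` at ``pos``.

    ``pos`` is the start of the written site string.  Returns the planted
    site's (start, end) and the set of engineered positions that the
    accidental-core scrub must not touch.  AU flanks cover 30 nt each side;
    for "high" AU the flanks are drawn from {A, U}, for "low" from {G, C}.
    The 16-nt pairing window upstream of the seed core is then overwritten
    with a non-pairing base, and "good" pairing adds the canonical
    complement of miRNA 13-18.
    """
    s = _site_string(mirna, spec.site_type)
    start, end = pos, pos + len(s)
    core_start = start + 1 if spec.site_type in ("8mer", "7mer-m8") else start
    protected = set(range(start, end))

    if spec.au == "high":
        flank_pool = "AU"
    elif spec.au == "low":
        flank_pool = "GC"
    else:
        flank_pool = None
    for k in range(1, 31):
        for p in (start - k, end - 1 + k):
            if 0 <= p < len(region) and flank_pool:
                region[p] = rng.choice(list(flank_pool))
                protected.add(p)

    # pairing window: non-pairing fill (A pairs nothing in the all-A 3' half;
    # C only pairs G, absent from the 3' half)
    fill = "C" if spec.au == "low" else "A"
    w_lo = core_start - 1 - PAIRING_WINDOW
    w_hi = core_start - 2
    for p in range(w_lo, w_hi + 1):
        if 0 <= p < len(region):
            region[p] = fill
            protected.add(p)
    if spec.pairing == "good":
        for j in range(13, 19):       # m13-m18 at canonical spacing
            t = core_start + 7 - j
            region[t] = _COMPLEMENT[mirna.nt(j)]
            protected.add(t)
    region[start:end] = list(s)

    # negative context: keep the planted type from upgrading by chance
    # (a preceding m8 complement or a following A would strengthen it)
    m8c = _COMPLEMENT[mirna.nt(8)]
    au_pool = {"high": "AU", "low": "GC", "neutral": "AC"}[
        spec.au if spec.au in ("high", "low") else "neutral"]
    if spec.site_type in ("6mer", "7mer-A1") and start > 0:
        region[start - 1] = next(b for b in au_pool if b != m8c)
        protected.add(start - 1)
    if spec.site_type in ("6mer", "7mer-m8") and end < len(region):
        region[end] = next(b for b in reversed(au_pool) if b != "A")
        protected.add(end)
    return start, end, protected


def _scrub_accidental_cores(region: list[str], cores: dict[str, str],
                            protected: set[int], rng) -> None:
    """Mutate accidental seed-complement occurrences outside planted sites."""
    text = "".join(region)
    for _ in range(10):
        dirty = False
        for core in cores.values():
            p = text.find(core)
            while p != -1:
                span = [q for q in range(p, p + 6) if q not in protected]
                if span:
                    q = span[len(span) // 2]
                    old = region[q]
                    region[q] = rng.choice([b for b in "ACGU" if b != old])
                    dirty = True
                p = text.find(core, p + 1)
        if not dirty:
            return
        text = "".join(region)


def generate_sequences(config: SimulationConfig,
                       mirnas: list[MatureMiRNA] | None = None,
                       rng=None) -> tuple[dict, list, pd.DataFrame]:
    """Per-gene region sequences with planted sites.

    Returns (gene id -> GeneSequences, miRNA list, planted-site table with
    recorded positions).  Background composition follows ``gc_fraction``;
    accidental seed complements of any simulated miRNA are scrubbed so the
    detected site table equals the planted one.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if mirnas is None:
        mirnas = generate_mirnas(config, rng)
    by_id = {m.id: m for m in mirnas}
    lengths = {"5UTR": config.utr5_len, "ORF": config.orf_len,
               "3UTR": config.utr3_len}
    planted_by_gene = {p.gene_id: p for p in config.planted_interactions}
    cores = {m.id: revcomp(m.seed) for m in mirnas}

    sequences: dict[str, GeneSequences] = {}
    site_rows = []
    for gene in config.gene_ids:
        regions = {name: _random_seq(rng, n, config.gc_fraction)
                   for name, n in lengths.items()}
        protected: dict[str, set[int]] = {name: set() for name in lengths}
        planted = planted_by_gene.get(gene)
        if planted is not None and planted.site_spec is not None:
            spec = planted.site_spec
            mirna = by_id[planted.mirna_id]
            region = regions[spec.region]
            s = _site_string(mirna, spec.site_type)
            need = 48 + len(s) + 30   # upstream context + site + downstream flank
            if len(region) < need:
                raise ValueError(
                    f"region {spec.region} too short for site plus flanks "
                    f"({len(region)} < {need})")
            pos = 48 + int(rng.integers(0, len(region) - need + 1))
            start, end, engineered = _plant_site(region, mirna, spec, pos, rng)
            protected[spec.region].update(engineered)
            site_rows.append({"mirna": planted.mirna_id, "gene": gene,
                              "region": spec.region, "start": start,
                              "end": end, "site_type": spec.site_type,
                              "au": spec.au, "pairing": spec.pairing})
        for name in lengths:
            _scrub_accidental_cores(regions[name], cores, protected[name], rng)
        # re-plant the site string in case scrubbing brushed its edge
        if planted is not None and planted.site_spec is not None:
            spec = planted.site_spec
            row = site_rows[-1]
            s = _site_string(by_id[planted.mirna_id], spec.site_type)
            regions[spec.region][row["start"]:row["end"]] = list(s)
        sequences[gene] = GeneSequences(
            gene_id=gene,
            utr5="".join(regions["5UTR"]),
            orf="".join(regions["ORF"]),
            utr3="".join(regions["3UTR"]),
            transcript_id=f"{gene}.t1",
        )
    site_truth = pd.DataFrame(site_rows, columns=["mirna", "gene", "region",
                                                  "start", "end", "site_type",
                                                  "au", "pairing"])
    return sequences, mirnas, site_truth


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def _columns(config: SimulationConfig) -> list[str]:
    return [f"S{s + 1}_r{r + 1}"
            for s in range(config.n_samples)
            for r in range(config.n_replicates)]


def generate_expression(config: SimulationConfig) -> SimulatedOmicsSet:
    """Generate the full simulated omics set from a configuration.

    log2 miRNA abundance per sample is Normal around a per-miRNA baseline;
    log2 mRNA responds linearly to the centred miRNA value through the
    planted mRNA-layer slope; log2 protein adds a translation baseline and
    the ratio-layer slope.  Replicates redraw residual noise independently,
    and spectral counts are Poisson draws with per-run expectations
    proportional to linear protein abundance scaled to ``spectral_depth``.
    """
    rng = np.random.default_rng(config.seed)
    cols = _columns(config)
    n_s, n_r = config.n_samples, config.n_replicates
    mirna_ids, gene_ids = config.mirna_ids, config.gene_ids
    missing_m = {p.mirna_id for p in config.planted_interactions} - set(mirna_ids)
    missing_g = {p.gene_id for p in config.planted_interactions} - set(gene_ids)
    if missing_m or missing_g:
        raise ValueError(f"planted ids outside the simulated universe: "
                         f"{sorted(missing_m | missing_g)}")

    # miRNA layer
    base_m = rng.normal(7.0, 1.0, size=config.n_mirnas)
    sample_m = base_m[:, None] + rng.normal(0.0, config.mirna_log_sd,
                                            size=(config.n_mirnas, n_s))
    # responses are anchored at the panel-minimum miRNA level: a target is
    # at its free baseline where its miRNA is lowest and is repressed (or
    # compensated) as the miRNA rises, so expression never exceeds baseline
    anchored = sample_m - sample_m.min(axis=1, keepdims=True)
    rep_m = (np.repeat(sample_m, n_r, axis=1)
             + rng.normal(0.0, config.mirna_rep_sd,
                          size=(config.n_mirnas, n_s * n_r)))
    mirna_matrix = ExpressionMatrix(
        pd.DataFrame(rep_m, index=pd.Index(mirna_ids, name="mirna"), columns=cols),
        scale="log2")

    # gene layers
    planted_by_gene = {p.gene_id: p for p in config.planted_interactions}
    m_index = {mid: i for i, mid in enumerate(mirna_ids)}
    base_g = rng.normal(6.0, 1.0, size=config.n_genes)
    trans_base = rng.normal(1.0, 0.5, size=config.n_genes)

    mrna_expected = np.tile(base_g[:, None], (1, n_s))
    protein_expected = mrna_expected + trans_base[:, None]
    for gi, gene in enumerate(gene_ids):
        p = planted_by_gene.get(gene)
        if p is None or p.mechanism == "none":
            continue
        z = anchored[m_index[p.mirna_id]]
        mrna_expected[gi] += p.mrna_slope * z
        protein_expected[gi] += (p.mrna_slope + p.ratio_slope) * z

    mrna_rep = (np.repeat(mrna_expected, n_r, axis=1)
                + rng.normal(0.0, config.noise_sd_mrna,
                             size=(config.n_genes, n_s * n_r)))
    mrna_matrix = ExpressionMatrix(
        pd.DataFrame(mrna_rep, index=pd.Index(gene_ids, name="gene"), columns=cols),
        scale="log2")

    prot_rep = (np.repeat(protein_expected, n_r, axis=1)
                + rng.normal(0.0, config.noise_sd_protein,
                             size=(config.n_genes, n_s * n_r)))
    protein_log2_matrix = ExpressionMatrix(
        pd.DataFrame(prot_rep.copy(), index=pd.Index(gene_ids, name="gene"),
                     columns=cols),
        scale="log2")
    linear = np.exp2(prot_rep)
    lam = linear / linear.sum(axis=0, keepdims=True) * config.spectral_depth
    counts = rng.poisson(lam)
    protein_matrix = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=pd.Index(gene_ids, name="protein"),
                     columns=cols),
        scale="counts")

    sequences, mirnas, site_truth = generate_sequences(
        config, rng=np.random.default_rng(config.seed + 1))

    binding = _binding_table(config, rng)
    return SimulatedOmicsSet(
        mirna_matrix=mirna_matrix, mrna_matrix=mrna_matrix,
        protein_count_matrix=protein_matrix,
        protein_log2_matrix=protein_log2_matrix, sequences=sequences,
        mirnas=mirnas, binding_table=binding,
        truth=list(config.planted_interactions), site_truth=site_truth)


def _binding_table(config: SimulationConfig, rng) -> pd.DataFrame:
    rows = []
    for p in config.planted_interactions:
        k = int(rng.integers(1, len(TOOLS) + 1))
        for tool in rng.choice(TOOLS, size=k, replace=False):
            rows.append({"mirna": p.mirna_id, "gene": p.gene_id, "tool": tool})
    planted = {(p.mirna_id, p.gene_id) for p in config.planted_interactions}
    n_added = 0
    while n_added < config.n_decoy_bindings:
        mirna = config.mirna_ids[int(rng.integers(config.n_mirnas))]
        gene = config.gene_ids[int(rng.integers(config.n_genes))]
        if (mirna, gene) in planted:
            continue
        rows.append({"mirna": mirna, "gene": gene,
                     "tool": TOOLS[int(rng.integers(len(TOOLS)))]})
        n_added += 1
    return pd.DataFrame(rows, columns=["mirna", "gene", "tool"])


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def generate_psm_table(n_forward: int, n_reverse: int,
                       config: SimulationConfig | None = None,
                       peptides_per_protein: int = 5,
                       single_peptide_proteins: int = 0,
                       seed: int = 0) -> pd.DataFrame:
    """PSM rows with the requested forward/reverse identification totals.

    Each row is one peptide identification (peptide, protein, decoy flag,
    run, spectra).  Forward identifications are distributed round-robin over
    proteins with ``peptides_per_protein`` distinct peptides each;
    ``single_peptide_proteins`` reserves that many proteins to receive a
    single peptide (useful for exercising the two-peptide filter).
    """
    if n_forward < 0 or n_reverse < 0:
        raise ValueError("identification counts must be >= 0")
    rng = np.random.default_rng(seed if config is None else config.seed)
    rows = []
    pep = 0
    fwd_left = n_forward
    prot = 0
    for _ in range(single_peptide_proteins):
        if fwd_left == 0:
            break
        prot += 1
        pep += 1
        rows.append({"peptide": f"PEP{pep:06d}", "protein": f"P{prot:05d}",
                     "decoy": False, "run": f"run{int(rng.integers(1, 4))}",
                     "spectra": int(rng.integers(1, 6))})
        fwd_left -= 1
    while fwd_left > 0:
        prot += 1
        for _ in range(min(peptides_per_protein, fwd_left)):
            pep += 1
            rows.append({"peptide": f"PEP{pep:06d}", "protein": f"P{prot:05d}",
                         "decoy": False, "run": f"run{int(rng.integers(1, 4))}",
                         "spectra": int(rng.integers(1, 6))})
            fwd_left -= 1
        if fwd_left <= 0:
            break
    for i in range(n_reverse):
        pep += 1
        rows.append({"peptide": f"PEP{pep:06d}", "protein": f"XXX_P{i + 1:05d}",
                     "decoy": True, "run": f"run{int(rng.integers(1, 4))}",
                     "spectra": int(rng.integers(1, 6))})
    return pd.DataFrame(rows, columns=["peptide", "protein", "decoy", "run",
                                       "spectra"])


# ---------------------------------------------------------------------------
# Reference study configuration
# ---------------------------------------------------------------------------

_REFERENCE_MECHANISMS = (
    ("decay_only", 24), ("translation_only", 24), ("both_strong", 8),
    ("both_weak", 12), ("decay_compensated", 16), ("translation_compensated", 16),
)


def reference_config(seed: int = 0) -> SimulationConfig:
    """The reference simulated study: 10 miRNAs, 200 genes, 100 planted.

    Mechanism mix: 24 decay-only, 24 translation-only, 8 both-strong,
    12 both-weak, 16 decay-compensated, 16 translation-compensated; strong
    effects -1.5, weak -0.05, compensation +1.5, residual noise 0.15.  The
    last miRNA receives only translation-flavoured targets, mirroring a
    translational-repression-biased miRNA.  Site specs rotate through site
    types, regions, AU and pairing levels so every feature class is
    populated.
    """
    mechanisms: list[str] = []
    for mech, n in _REFERENCE_MECHANISMS:
        mechanisms.extend([mech] * n)

    n_mirnas = 10
    mirna_ids = [f"miR-{i + 1:03d}" for i in range(n_mirnas)]
    tr_biased = mirna_ids[-1]

    site_rotation = [
        SiteSpec("8mer", "3UTR", "neutral", "neutral"),
        SiteSpec("8mer", "3UTR", "high", "neutral"),
        SiteSpec("8mer", "3UTR", "low", "neutral"),
        SiteSpec("8mer", "3UTR", "neutral", "good"),
        SiteSpec("8mer", "3UTR", "neutral", "poor"),
        SiteSpec("7mer-m8", "3UTR", "neutral", "neutral"),
        SiteSpec("7mer-A1", "3UTR", "neutral", "neutral"),
        SiteSpec("6mer", "3UTR", "neutral", "neutral"),
        SiteSpec("8mer", "ORF", "neutral", "neutral"),
        SiteSpec("8mer", "5UTR", "neutral", "neutral"),
    ]

    planted = []
    gi = 0
    rot = 0
    ordinary = [m for m in mirna_ids if m != tr_biased]
    k = 0
    for mech in mechanisms:
        gi += 1
        gene = f"G{gi:04d}"
        if mech in ("translation_only", "both_weak") and (k % 4 == 0):
            mirna = tr_biased
        else:
            mirna = ordinary[k % len(ordinary)]
        k += 1
        spec = replace(site_rotation[rot % len(site_rotation)])
        rot += 1
        planted.append(make_interaction(mirna, gene, mech, site_spec=spec))

    return SimulationConfig(
        n_mirnas=n_mirnas, n_genes=200, n_samples=9, n_replicates=3,
        planted_interactions=planted, seed=seed)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_omics_set(simset: SimulatedOmicsSet, outdir) -> None:
    """Write the simulated set as TSV/FASTA under ``outdir``."""
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    simset.mirna_matrix.to_tsv(out / "mirna_log2.tsv")
    simset.mrna_matrix.to_tsv(out / "mrna_log2.tsv")
    simset.protein_count_matrix.to_tsv(out / "protein_counts.tsv")
    simset.binding_table.to_csv(out / "binding.tsv", sep="\t", index=False)
    simset.truth_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    simset.site_truth.to_csv(out / "site_truth.tsv", sep="\t", index=False)
    _write_fasta(out / "mirnas.fasta",
                 [(m.id, m.seq) for m in simset.mirnas])
    records = []
    for gene, gs in simset.sequences.items():
        for region, seq in (("5UTR", gs.utr5), ("ORF", gs.orf), ("3UTR", gs.utr3)):
            if seq:
                records.append((f"{gene}:{region}", seq))
    _write_fasta(out / "regions.fasta", records)


def _write_fasta(path, records) -> None:
    # written as DNA (U -> T); readers convert back to RNA
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq.replace('U', 'T')}\n")
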