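"""Seed-site detection and context scoring.

Canonical miRNA target sites are defined by Watson-Crick complementarity to
the seed (miRNA nucleotides 2-7, counting from the 5' end):

* ``6mer``     -- match to positions 2-7 only;
* ``7mer-A1``  -- seed match plus an A in the message opposite position 1;
* ``7mer-m8``  -- match extended to position 8;
* ``8mer``     -- both the position-8 match and the opposite-1 A.

Two context features are scored per site: local AU content of the 30-nt
flanks with distance weights 1/k, and supplementary pairing between the
miRNA 3' region (centred on nucleotides 13-16) and the message upstream of
the seed match, with half-point offset penalties beyond 2 nt.
Only Watson-Crick pairs count; G:U wobbles never score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")  # strongest first
REGIONS = ("5UTR", "ORF", "3UTR")

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

# 3'-pairing search geometry: candidate duplexes live in the 16 nt of message
# immediately 5' of the seed match; offsets are limited to +/-8.
PAIRING_WINDOW = 16
MAX_OFFSET = 8


def to_rna(seq: str) -> str:
    """Uppercase and convert DNA T to RNA U; validates the alphabet."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA sequence, 5'->3'; position 1 is the 5' nucleotide."""
    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", to_rna(self.seq))
        if len(self.seq) < 16:
            raise ValueError(f"miRNA {self.id}: length {len(self.seq)} < 16")

    def nt(self, pos: int) -> str:
        """1-based access: nt(1) is the 5' nucleotide."""
        return self.seq[pos - 1]

    @property
    def seed(self) -> str:
        """Positions 2-7."""
        return self.seq[1:7]


@dataclass
class GeneSequences:
    """Per-gene region sequences (any region may be empty)."""
    gene_id: str
    utr5: str = ""
    orf: str = ""
    utr3: str = ""
    transcript_id: str = ""

    def __post_init__(self):
        self.utr5 = to_rna(self.utr5) if self.utr5 else ""
        self.orf = to_rna(self.orf) if self.orf else ""
        self.utr3 = to_rna(self.utr3) if self.utr3 else ""

    def region(self, name: str) -> str:
        return {"5UTR": self.utr5, "ORF": self.orf, "3UTR": self.utr3}[name]


@dataclass
class SeedSiteMatch:
    """One detected site; coordinates are 0-based half-open on the region."""
    mirna_id: str
    gene_id: str
    region: str
    start: int
    end: int
    site_type: str
    au_score: float | None = None
    pairing3p_score: float | None = None

    @property
    def core_start(self) -> int:
        """Start of the 6-nt seed-complement core within the region."""
        return self.start + 1 if self.site_type in ("8mer", "7mer-m8") else self.start


def select_longest_region(transcripts: Sequence[GeneSequences]) -> GeneSequences:
    """Collapse transcript isoforms: per region, keep the longest candidate.

    Regions are chosen independently; length ties go to the transcript that
    sorts first by transcript id.
    """
    if not transcripts:
        raise ValueError("no transcripts supplied")
    ordered = sorted(transcripts, key=lambda t: t.transcript_id)
    gene_id = ordered[0].gene_id
    best = {}
    for name in REGIONS:
        best[name] = max((t.region(name) for t in ordered), key=len)
    return GeneSequences(gene_id=gene_id, utr5=best["5UTR"], orf=best["ORF"],
                         utr3=best["3UTR"], transcript_id="longest-per-region")


def find_seed_sites(mirna: MatureMiRNA, gene: GeneSequences,
                    region: str) -> list[SeedSiteMatch]:
    """Scan one region for canonical seed sites.

    Each seed-complement locus is reported once, at its strongest compatible
    type (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    seq = gene.region(region)
    out: list[SeedSiteMatch] = []
    if not seq:
        return out
    core = revcomp(mirna.seed)                 # matches miRNA 2-7
    m8c = _COMPLEMENT[mirna.nt(8)]             # message base pairing position 8
    p = seq.find(core)
    while p != -1:
        has_m8 = p > 0 and seq[p - 1] == m8c
        has_a1 = p + 6 < len(seq) and seq[p + 6] == "A"
        if has_m8 and has_a1:
            out.append(SeedSiteMatch(mirna.id, gene.gene_id, region, p - 1, p + 7, "8mer"))
        elif has_m8:
            out.append(SeedSiteMatch(mirna.id, gene.gene_id, region, p - 1, p + 6, "7mer-m8"))
        elif has_a1:
            out.append(SeedSiteMatch(mirna.id, gene.gene_id, region, p, p + 7, "7mer-A1"))
        else:
            out.append(SeedSiteMatch(mirna.id, gene.gene_id, region, p, p + 6, "6mer"))
        p = seq.find(core, p + 1)
    return out


def score_au_context(seq: str, site: SeedSiteMatch, window: int = 30) -> float:
    """Distance-weighted A/U fraction of the site's flanks.

    The k-th nucleotide away from either site boundary carries weight 1/k
    (k = 1..window); weights of positions falling outside the sequence are
    dropped from the normalization, so the score stays in [0, 1].
    """
    seq = to_rna(seq)
    total_w = 0.0
    au_w = 0.0
    for k in range(1, window + 1):
        for pos in (site.start - k, site.end - 1 + k):
            if 0 <= pos < len(seq):
                w = 1.0 / k
                total_w += w
                if seq[pos] in "AU":
                    au_w += w
    if total_w == 0.0:
        return 0.0
    return au_w / total_w


def _pairing_runs(mirna: MatureMiRNA, seq: str, core_start: int, offset: int):
    """Maximal contiguous Watson-Crick runs of miRNA 9..L at a given offset.

    miRNA position j sits canonically opposite message index
    core_start + 7 - j (position 8 pairs just 5' of the core); ``offset``
    shifts that placement.  Only message indices within the search window
    [core_start - 1 - PAIRING_WINDOW, core_start - 2] are eligible.
    """
    lo = core_start - 1 - PAIRING_WINDOW
    hi = core_start - 2
    runs = []
    current: list[int] = []
    for j in range(9, len(mirna.seq) + 1):
        t = core_start + 7 - j - offset
        ok = (lo <= t <= hi and 0 <= t < len(seq)
              and seq[t] == _COMPLEMENT[mirna.nt(j)])
        if ok:
            current.append(j)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    return runs


def score_3p_pairing(mirna: MatureMiRNA, seq: str, site: SeedSiteMatch) -> float:
    """Supplementary 3'-pairing score of a seed site.

    For each offset o in [-8, 8] the best single contiguous duplex between
    miRNA positions 9..L and the 16-nt window upstream of the seed match is
    scored: one point per paired nucleotide within miRNA 13-16, half a point
    per paired nucleotide elsewhere, minus 0.5 per nucleotide of offset
    beyond 2.  The maximum over offsets and duplexes is returned, floored
    at 0.
    """
    seq = to_rna(seq)
    core_start = site.core_start
    best = 0.0
    for o in range(-MAX_OFFSET, MAX_OFFSET + 1):
        penalty = 0.5 * max(0, abs(o) - 2)
        for run in _pairing_runs(mirna, seq, core_start, o):
            s = sum(1.0 if 13 <= j <= 16 else 0.5 for j in run) - penalty
            if s > best:
                best = s
    return best


def annotate_sites(mirna: MatureMiRNA, gene: GeneSequences,
                   regions: Iterable[str] = REGIONS,
                   au_window: int = 30) -> list[SeedSiteMatch]:
    """Detect sites in the requested regions and attach both context scores."""
    sites = []
    for region in regions:
        for site in find_seed_sites(mirna, gene, region):
            seq = gene.region(region)
            site.au_score = score_au_context(seq, site, window=au_window)
            site.pairing3p_score = score_3p_pairing(mirna, seq, site)
            sites.append(site)
    return sites


def site_table(mirnas: Sequence[MatureMiRNA], genes: Sequence[GeneSequences],
               regions: Iterable[str] = REGIONS) -> pd.DataFrame:
    """All annotated sites for every miRNA x gene combination.

    Columns: mirna, gene, region, start, end, site_type, au_score,
    pairing3p_score, utr3_len.  Coordinates are 0-based half-open here;
    written reports convert to 1-based inclusive.
    """
    rows = []
    for g in genes:
        for m in mirnas:
            for s in annotate_sites(m, g, regions=regions):
                rows.append({
                    "mirna": s.mirna_id, "gene": s.gene_id, "region": s.region,
                    "start": s.start, "end": s.end, "site_type": s.site_type,
                    "au_score": s.au_score, "pairing3p_score": s.pairing3p_score,
                    "utr3_len": len(g.utr3),
                })
    cols = ["mirna", "gene", "region", "start", "end", "site_type",
            "au_score", "pairing3p_score", "utr3_len"]
    return pd.DataFrame(rows, columns=cols)


def write_site_report(sites: pd.DataFrame, path) -> None:
    """Write the per-site TSV with 1-based inclusive coordinates."""
    out = sites.copy()
    if not out.empty:
        out["start"] = out["start"] + 1
        out = out.rename(columns={"end": "end_1based"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")
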