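import numpy as np
import pandas as pd
import pytest

from mirmech import (
    GeneSequences,
    SimulationConfig,
    SiteSpec,
    compute_decoy_fdr,
    filter_proteins,
    find_seed_sites,
    generate_expression,
    generate_psm_table,
    generate_sequences,
    score_3p_pairing,
    score_au_context,
)
from mirmech.quant import average_replicates
from mirmech.seqfeat import SeedSiteMatch
from mirmech.synthdata import make_interaction
from mirmech.quant import compute_decoy_fdr_from_table

from conftest import small_config


class TestConfigValidation:
    def test_gene_collision_rejected(self):
        planted = [make_interaction("miR-001", "G0001", "decay_only"),
                   make_interaction("miR-002", "G0001", "translation_only")]
        with pytest.raises(ValueError, match="collide"):
            SimulationConfig(n_mirnas=2, n_genes=5,
                             planted_interactions=planted)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd_mrna=-0.1)

    def test_mechanism_effect_consistency(self):
        with pytest.raises(ValueError, match="inconsistent"):
            make_interaction("m", "g", "decay_only").__class__(
                mirna_id="m", gene_id="g", mechanism="decay_only",
                decay_effect=-1.0, translation_effect=-1.0)

    def test_compensation_only_for_compensated(self):
        from mirmech.synthdata import PlantedInteraction
        with pytest.raises(ValueError, match="compensation"):
            PlantedInteraction("m", "g", "decay_only", decay_effect=-1.0,
                               compensation_effect=0.5)


class TestSeedDeterminism:
    def test_identical_outputs_for_identical_seeds(self):
        s1 = generate_expression(small_config(seed=42))
        s2 = generate_expression(small_config(seed=42))
        pd.testing.assert_frame_equal(s1.mirna_matrix.data, s2.mirna_matrix.data)
        pd.testing.assert_frame_equal(s1.mrna_matrix.data, s2.mrna_matrix.data)
        pd.testing.assert_frame_equal(s1.protein_count_matrix.data,
                                      s2.protein_count_matrix.data)
        pd.testing.assert_frame_equal(s1.binding_table, s2.binding_table)
        assert all(s1.sequences[g].utr3 == s2.sequences[g].utr3
                   for g in s1.sequences)

    def test_different_seeds_differ(self):
        s1 = generate_expression(small_config(seed=1))
        s2 = generate_expression(small_config(seed=2))
        assert not s1.mirna_matrix.data.equals(s2.mirna_matrix.data)


class TestMechanismSeparability:
    def _noise_free(self, mechanism, seed=3):
        planted = [make_interaction("miR-001", "G0001", mechanism)]
        cfg = small_config(seed=seed, planted_interactions=planted,
                          noise_sd_mrna=0.0, noise_sd_protein=0.0,
                          mirna_rep_sd=0.0)
        return generate_expression(cfg)

    def test_decay_only_perfect_mrna_flat_ratio(self):
        sim = self._noise_free("decay_only")
        m = average_replicates(sim.mirna_matrix).data.loc["miR-001"]
        r = average_replicates(sim.mrna_matrix).data.loc["G0001"]
        prot = average_replicates(sim.protein_log2_matrix).data.loc["G0001"]
        assert np.corrcoef(m, r)[0, 1] == pytest.approx(-1.0, abs=1e-12)
        ratio = prot - r
        assert np.ptp(ratio.to_numpy()) < 1e-9  # constant: no ratio response
        assert abs(np.cov(m, ratio)[0, 1]) < 1e-9

    def test_translation_only_flat_mrna_perfect_ratio(self):
        sim = self._noise_free("translation_only")
        m = average_replicates(sim.mirna_matrix).data.loc["miR-001"]
        r = average_replicates(sim.mrna_matrix).data.loc["G0001"]
        prot = average_replicates(sim.protein_log2_matrix).data.loc["G0001"]
        assert np.ptp(r.to_numpy()) < 1e-9
        assert np.corrcoef(m, prot - r)[0, 1] == pytest.approx(-1.0, abs=1e-12)


class TestSequences:
    def test_planted_8mer_round_trip(self):
        cfg = small_config(seed=5)
        seqs, mirnas, site_truth = generate_sequences(cfg)
        by_id = {m.id: m for m in mirnas}
        planted = site_truth[site_truth.site_type == "8mer"]
        assert not planted.empty
        for row in planted.itertuples():
            gene = seqs[row.gene]
            found = [s for s in find_seed_sites(by_id[row.mirna], gene,
                                                row.region)
                     if s.site_type == "8mer"]
            assert len(found) == 1
            assert (found[0].start, found[0].end) == (row.start, row.end)

    def test_no_accidental_sites_for_other_mirnas(self):
        cfg = small_config(seed=6)
        seqs, mirnas, site_truth = generate_sequences(cfg)
        planted = {(r.mirna, r.gene) for r in site_truth.itertuples()}
        for gene_id in list(seqs)[:10]:
            for m in mirnas:
                for region in ("5UTR", "ORF", "3UTR"):
                    hits = find_seed_sites(m, seqs[gene_id], region)
                    if (m.id, gene_id) not in planted:
                        assert hits == []

    def test_high_au_scores_above_low_au(self):
        planted = [
            make_interaction("miR-001", "G0001", "decay_only",
                             site_spec=SiteSpec("8mer", "3UTR", "high")),
            make_interaction("miR-001", "G0002", "decay_only",
                             site_spec=SiteSpec("8mer", "3UTR", "low")),
        ]
        cfg = small_config(seed=7, planted_interactions=planted)
        seqs, mirnas, site_truth = generate_sequences(cfg)
        by_id = {m.id: m for m in mirnas}
        scores = {}
        for row in site_truth.itertuples():
            site = SeedSiteMatch(row.mirna, row.gene, row.region, row.start,
                                 row.end, row.site_type)
            scores[row.gene] = score_au_context(seqs[row.gene].utr3, site)
        assert scores["G0001"] > 0.9 > 0.1 > scores["G0002"]

    @pytest.mark.parametrize("pairing, check", [
        ("good", lambda s: s > 4.0),
        ("poor", lambda s: s < 1.0),
    ])
    def test_pairing_levels_meet_class_thresholds(self, pairing, check):
        planted = [make_interaction("miR-001", "G0001", "decay_only",
                                    site_spec=SiteSpec("8mer", "3UTR",
                                                       "neutral", pairing))]
        cfg = small_config(seed=8, planted_interactions=planted)
        seqs, mirnas, site_truth = generate_sequences(cfg)
        row = site_truth.iloc[0]
        site = SeedSiteMatch(row.mirna, row.gene, row.region, row.start,
                             row.end, row.site_type)
        score = score_3p_pairing(mirnas[0], seqs[row.gene].utr3, site)
        assert check(score)

    def test_short_region_rejected(self):
        planted = [make_interaction("miR-001", "G0001", "decay_only",
                                    site_spec=SiteSpec("8mer", "5UTR"))]
        cfg = small_config(seed=9, planted_interactions=planted, utr5_len=50)
        with pytest.raises(ValueError, match="too short"):
            generate_sequences(cfg)


class TestExpressionStructure:
    def test_replicate_columns_and_poisson_counts(self):
        cfg = small_config(seed=10)
        sim = generate_expression(cfg)
        assert sim.protein_count_matrix.data.shape == (30, 27)
        counts = sim.protein_count_matrix.data.to_numpy()
        assert np.all(counts >= 0)
        assert np.allclose(counts, np.round(counts))
        # depth approximately respected per run
        totals = counts.sum(axis=0)
        assert np.all(totals > 0.5 * cfg.spectral_depth)

    def test_binding_covers_all_planted_pairs(self):
        cfg = small_config(seed=11)
        sim = generate_expression(cfg)
        pairs = set(map(tuple, sim.binding_table[["mirna", "gene"]]
                        .itertuples(index=False)))
        for p in cfg.planted_interactions:
            assert (p.mirna_id, p.gene_id) in pairs


class TestPsmTable:
    def test_empty_request_empty_table(self):
        assert generate_psm_table(0, 0).empty

    def test_decoy_fdr_round_trip(self):
        psm = generate_psm_table(95, 5)
        assert compute_decoy_fdr_from_table(psm) == pytest.approx(0.1)
        assert compute_decoy_fdr(95, 5) == pytest.approx(0.1)

    def test_single_peptide_proteins_removed_by_filter(self):
        psm = generate_psm_table(50, 0, single_peptide_proteins=3)
        singles = (psm[~psm.decoy].groupby("protein")["peptide"].nunique() == 1)
        single_ids = set(singles.index[singles])
        assert len(single_ids) >= 3
        kept = set(filter_proteins(psm, min_peptides=2, min_spectra=1))
        assert kept.isdisjoint(single_ids)
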