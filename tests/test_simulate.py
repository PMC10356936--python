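"""Synthetic-data generators: determinism, planted truths, config validation."""

import numpy as np
import pandas as pd
import pytest

from diazoscan.abundance import abundance_matrix
from diazoscan.simulate import (
    ConfigurationError,
    NifProfile,
    SimulationConfig,
    default_archetypes,
    make_genomes,
    make_ko_sets,
    make_primer_targets,
    make_survey,
)
from diazoscan.mcr import evaluate_mcr


class TestConfigValidation:
    def test_fragmented_profile_with_nifk_rejected(self):
        with pytest.raises(ConfigurationError):
            NifProfile("g", frozenset({"nifH", "nifD", "nifK"}), fragmented=True)

    def test_fragmented_profile_needs_nifh_and_nifd(self):
        with pytest.raises(ConfigurationError):
            NifProfile("g", frozenset({"nifH"}), fragmented=True)

    def test_unknown_nif_gene_rejected(self):
        with pytest.raises(ConfigurationError):
            NifProfile("g", frozenset({"nifZ"}))

    def test_negative_noise_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(noise=-1)

    def test_overlapping_latitude_bands_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(latitude_bands=(("a", (0.0, 70.0)), ("b", (60.0, 90.0))))


class TestMakeGenomes:
    def test_deterministic_across_calls(self):
        cfg = SimulationConfig(seed=5, n_genomes=6)
        g1, s1, t1 = make_genomes(cfg)
        g2, s2, t2 = make_genomes(cfg)
        assert s1 == s2
        assert t1.equals(t2)
        assert [g.genome_id for g in g1] == [g.genome_id for g in g2]
        assert all(a.contig_lengths == b.contig_lengths for a, b in zip(g1, g2))

    def test_requested_nif_genes_exactly_present(self):
        profile = NifProfile("g", frozenset({"nifH", "nifD", "nifE"}))
        cfg = SimulationConfig(seed=5, nif_profiles=[profile])
        [genome], _, _ = make_genomes(cfg)
        nif_labels = {g.gene_id.rsplit("_", 1)[1] for g in genome.genes
                      if g.gene_id.rsplit("_", 1)[1].startswith("nif")}
        assert nif_labels == {"nifH", "nifD", "nifE"}

    def test_fragmented_places_nifH_nifD_terminal_in_operon_order(self):
        profile = NifProfile("g", frozenset({"nifH", "nifD", "nifE", "nifN", "nifB"}),
                             fragmented=True)
        cfg = SimulationConfig(seed=5, nif_profiles=[profile])
        [genome], _, _ = make_genomes(cfg)
        nifd = next(g for g in genome.genes if g.gene_id.endswith("nifD"))
        contig_genes = genome.genes_on_contig(nifd.contig_id)
        assert contig_genes[-1].gene_id.endswith("nifD")
        assert contig_genes[-2].gene_id.endswith("nifH")

    def test_coordinates_within_contigs(self):
        genomes, _, _ = make_genomes(SimulationConfig(seed=5, n_genomes=10))
        for genome in genomes:
            for gene in genome.genes:
                assert 1 <= gene.start <= gene.end
                assert gene.end <= genome.contig_lengths[gene.contig_id]


class TestMakeSurvey:
    def test_absent_archetype_all_zero(self):
        cfg = SimulationConfig(seed=5, n_genomes=8, n_samples=36)
        genomes, _, _ = make_genomes(cfg)
        summary, _, truth = make_survey(cfg, genomes)
        absent = truth[truth.archetype == "absent"]["genome"]
        assert len(absent) > 0
        for gid in absent:
            assert all(g != gid for (_, g) in summary.counts)

    def test_zero_noise_counts_equal_rounded_means(self):
        cfg = SimulationConfig(seed=5, n_genomes=4, n_samples=36, noise=0)
        genomes, _, truth = make_genomes(cfg)
        summary, meta, survey_truth = make_survey(cfg, genomes)
        lengths = {g.genome_id: g.genome_length for g in genomes}
        for (sample, gid), count in summary.counts.items():
            mu = cfg.mean_depth_of_coverage * lengths[gid] / cfg.read_length
            assert count == int(round(mu))

    def test_deterministic(self):
        cfg = SimulationConfig(seed=5, n_genomes=8, n_samples=36)
        genomes, _, _ = make_genomes(cfg)
        s1, m1, t1 = make_survey(cfg, genomes)
        s2, m2, t2 = make_survey(cfg, genomes)
        assert s1.counts == s2.counts
        assert m1.equals(m2)

    def test_archetype_needs_band_coverage(self):
        cfg = SimulationConfig(
            seed=5, n_genomes=4, n_samples=12,
            latitude_bands=(("arctic", (66.5, 90.0)),),
            archetype_assignments={f"SG{i:03d}": "low_latitude_endemic"
                                   for i in range(4)})
        genomes, _, _ = make_genomes(cfg)
        with pytest.raises(ConfigurationError):
            make_survey(cfg, genomes)

    def test_incomplete_assignment_rejected(self):
        cfg = SimulationConfig(seed=5, n_genomes=4, n_samples=36,
                               archetype_assignments={"SG000": "absent"})
        genomes, _, _ = make_genomes(cfg)
        with pytest.raises(ConfigurationError):
            make_survey(cfg, genomes)

    def test_every_genome_one_archetype(self):
        cfg = SimulationConfig(seed=5, n_genomes=10)
        assignments = default_archetypes(cfg)
        assert sorted(assignments) == cfg.genome_ids()

    def test_mapped_never_exceeds_total(self):
        cfg = SimulationConfig(seed=5, n_genomes=8, n_samples=36)
        genomes, _, _ = make_genomes(cfg)
        summary, _, _ = make_survey(cfg, genomes)
        summary.validate()
        abundance_matrix(summary)  # no error; invariants hold downstream


class TestMakePrimerTargets:
    def test_truth_table_half_and_half(self):
        targets, truth = make_primer_targets(SimulationConfig(seed=5), n_targets=20)
        assert truth["compatible"].sum() == 10
        assert len(targets) == 20

    def test_deterministic(self):
        cfg = SimulationConfig(seed=5)
        t1, tr1 = make_primer_targets(cfg)
        t2, tr2 = make_primer_targets(cfg)
        assert t1 == t2 and tr1.equals(tr2)

    def test_primer_longer_than_target_rejected(self):
        with pytest.raises(ConfigurationError):
            make_primer_targets(SimulationConfig(seed=5), target_length=10)


class TestMakeKoSets:
    def test_planted_completion_matches_arithmetic(self):
        cfg = SimulationConfig(seed=5, n_genomes=6)
        ko_sets, modules, truth = make_ko_sets(cfg)
        for row in truth.itertuples():
            n_leaves = len(modules[row.module].expression.required_leaves())
            planted = ko_sets[row.genome] & modules[row.module].expression.leaves()
            assert row.mcr == pytest.approx(100.0 * len(planted) / n_leaves)

    def test_extremes_plant_all_or_none(self):
        cfg = SimulationConfig(seed=5, n_genomes=20)
        ko_sets, modules, truth = make_ko_sets(cfg)
        full = truth[truth.mcr == 100.0]
        empty = truth[truth.mcr == 0.0]
        assert len(full) > 0 and len(empty) > 0
        for row in pd.concat([full.head(3), empty.head(3)]).itertuples():
            assert evaluate_mcr(modules[row.module], ko_sets[row.genome]) == row.mcr
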