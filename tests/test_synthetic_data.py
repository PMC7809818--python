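import math

import pytest

from mitocomp import (
    FeatureType,
    classify_start_stop,
    feature_sequence,
    junction_window,
    region_summary,
    spacer_table,
    tables,
    validate_gene_order,
)
from mitocomp.codon_usage import GeneticCode
from mitocomp.synthetic_data import (
    DivergenceSpec,
    GenomeSpec,
    SpecError,
    diverge_gene,
    generate_mitogenome,
    generate_panel,
)


class TestGenerateMitogenome:
    def test_default_spec_matches_template_arithmetic(self, synthetic_genome):
        assert len(synthetic_genome) == 16_636
        assert len(synthetic_genome.features) == 39
        sp = {(r.upstream, r.downstream): r.spacer
              for r in spacer_table(synthetic_genome)}
        assert sp[("atp8", "atp6")] == -10
        assert sp[("nd4l", "nd4")] == -7

    def test_deterministic_given_seed(self):
        a = generate_mitogenome(GenomeSpec(seed=3))
        b = generate_mitogenome(GenomeSpec(seed=3))
        assert a.sequence == b.sequence

    def test_different_seeds_differ(self):
        a = generate_mitogenome(GenomeSpec(seed=3))
        b = generate_mitogenome(GenomeSpec(seed=4))
        assert a.sequence != b.sequence

    def test_planted_motifs_recovered(self, synthetic_genome):
        assert junction_window(synthetic_genome, "atp8", "atp6", 0) == "ATGGCAATAA"
        assert junction_window(synthetic_genome, "nd4l", "nd4", 0) == "ATGCTAA"

    def test_passes_gene_order_validation(self, synthetic_genome):
        assert validate_gene_order(synthetic_genome,
                                   tables.canonical_order()).matches_template

    def test_pcgs_are_valid_orfs(self, synthetic_genome, code):
        for f in synthetic_genome.features_of_type(FeatureType.PCG):
            cds = feature_sequence(synthetic_genome, f.name)
            body_len = len(cds) // 3 * 3
            for i in range(3, body_len - 3, 3):
                assert not code.is_stop(cds[i : i + 3]), (f.name, i)

    def test_stop_class_matches_length_mod3(self, synthetic_genome):
        n = len(synthetic_genome)
        for f in synthetic_genome.features_of_type(FeatureType.PCG):
            call = classify_start_stop(feature_sequence(synthetic_genome, f.name))
            r = f.length(n) % 3
            assert {0: call.stop_class in ("TAA", "TAG", "AGA", "AGG"),
                    1: call.stop_class == "T--",
                    2: call.stop_class == "TA-"}[r]

    def test_composition_targets_recovered_within_sampling_bounds(self):
        """Empirical base fractions land within 3 sigma binomial bounds
        of the planted targets in unconstrained regions."""
        g = generate_mitogenome(GenomeSpec(seed=21))
        for region in ("rRNA", "CR"):
            s = region_summary(g, region)
            target = tables.DEFAULT_COMPOSITION[region]
            for base, pct in (("A", s.a_pct), ("T", s.t_pct),
                              ("C", s.c_pct), ("G", s.g_pct)):
                p = target[base]
                sigma = 100 * math.sqrt(p * (1 - p) / s.size)
                assert abs(pct - 100 * p) < 3.5 * sigma, (region, base)

    def test_infeasible_motif_rejected(self):
        spec = GenomeSpec(seed=0)
        spec.motifs[("atp8", "atp6")] = "ATGGCAATAAA"  # 11 bp into a 10 bp overlap
        with pytest.raises(SpecError):
            generate_mitogenome(spec)

    def test_wrong_stop_class_for_length_rejected(self):
        spec = GenomeSpec(seed=0)
        spec.stop_classes["nd1"] = "T--"  # nd1 length is a codon multiple
        with pytest.raises(SpecError):
            generate_mitogenome(spec)

    def test_ground_truth_sidecar_contents(self):
        spec = GenomeSpec(seed=6)
        truth = spec.ground_truth()
        assert truth["seed"] == 6
        assert truth["motifs"]["atp8/atp6"] == "ATGGCAATAA"
        assert len(truth["features"]) == 39

    def test_round_trips_through_genome_io(self, synthetic_genome, tmp_path):
        from mitocomp import read_genbank, write_genbank

        write_genbank(synthetic_genome, tmp_path / "g.gb")
        back = read_genbank(tmp_path / "g.gb")
        assert back.sequence == synthetic_genome.sequence
        assert len(back.features) == 39


class TestDivergeGene:
    def test_zero_substitutions_is_identity(self, synthetic_genome):
        cds = feature_sequence(synthetic_genome, "nd5")
        assert diverge_gene(cds, DivergenceSpec(0, 0, seed=1)) == cds

    def test_synonymous_only_preserves_protein(self, synthetic_genome, code):
        cds = feature_sequence(synthetic_genome, "cox2")
        div = diverge_gene(cds, DivergenceSpec(n_syn=5, n_nonsyn=0, seed=2))
        translate = lambda s: "".join(code.translate(s[i:i + 3])
                                      for i in range(0, len(s) // 3 * 3, 3))
        assert translate(div) == translate(cds)
        assert sum(a != b for a, b in zip(cds, div)) == 5

    def test_nonsynonymous_changes_protein_at_exact_count(self, synthetic_genome, code):
        cds = feature_sequence(synthetic_genome, "nd4l")
        div = diverge_gene(cds, DivergenceSpec(n_syn=0, n_nonsyn=4, seed=3))
        translate = lambda s: "".join(code.translate(s[i:i + 3])
                                      for i in range(0, len(s) // 3 * 3, 3))
        diffs = sum(a != b for a, b in zip(translate(cds), translate(div)))
        assert diffs == 4
        assert sum(a != b for a, b in zip(cds, div)) == 4

    def test_estimator_cross_check_nd_zero(self, synthetic_genome):
        from mitocomp import ng86_pair

        cds = feature_sequence(synthetic_genome, "cox1")
        cds = cds[: len(cds) // 3 * 3]
        div = diverge_gene(cds, DivergenceSpec(n_syn=8, n_nonsyn=0, seed=5))
        r = ng86_pair(cds, div)
        assert r.nd == 0.0 and r.sd == 8.0

    def test_deterministic(self, synthetic_genome):
        cds = feature_sequence(synthetic_genome, "cytb")
        s = DivergenceSpec(n_syn=3, n_nonsyn=3, seed=9)
        assert diverge_gene(cds, s) == diverge_gene(cds, s)

    def test_impossible_request_rejected(self):
        with pytest.raises(SpecError):
            diverge_gene("ATGAAATAA", DivergenceSpec(n_syn=50, n_nonsyn=0, seed=0))


class TestGeneratePanel:
    def test_panel_size_and_determinism(self):
        a, _ = generate_panel(5, seed=7)
        b, _ = generate_panel(5, seed=7)
        assert len(a) == 5
        assert [g.sequence for g in a] == [g.sequence for g in b]

    def test_each_genome_is_fully_annotated(self):
        genomes, _ = generate_panel(3, seed=1)
        for g in genomes:
            assert len(g.features) == 39
            assert validate_gene_order(g, tables.canonical_order()).matches_template

    def test_at_content_spans_gradient(self):
        genomes, truth = generate_panel(6, gradient=(55.0, 65.0), seed=4)
        at = [region_summary(g, "CR").at_pct for g in genomes]
        assert at[0] < at[-1]
        assert at[0] == pytest.approx(55.0, abs=0.5)
        assert at[-1] == pytest.approx(65.0, abs=0.5)

    def test_n_below_two_rejected(self):
        with pytest.raises(SpecError):
            generate_panel(1, seed=0)
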