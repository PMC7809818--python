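import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp import (
    feature_sequence,
    gene_omega,
    ng86_pair,
    ng86_site_counts,
    p_distance_matrix,
)
from mitocomp.codon_usage import GeneticCode
from mitocomp.model import MitocompError
from mitocomp.synthetic_data import DivergenceSpec, diverge_gene

from .oracles import brute_pathway_counts, brute_site_counts

SENSE = GeneticCode().sense_codons
STOPS = ("TAA", "TAG", "AGA", "AGG")


class TestSiteCounts:
    @pytest.mark.parametrize("codon", SENSE)
    def test_sites_sum_to_three_exactly(self, codon):
        s, n = ng86_site_counts(codon)
        assert s + n == 3.0

    @pytest.mark.parametrize("codon", SENSE)
    def test_matches_brute_force_enumeration(self, codon):
        s, n = ng86_site_counts(codon)
        bs, bn = brute_site_counts(codon)
        assert math.isclose(s, bs, abs_tol=1e-12)
        assert math.isclose(n, bn, abs_tol=1e-12)

    def test_phe_third_position(self):
        # TTT: of the pos-3 mutants TTC/TTA/TTG only TTC is synonymous
        s, n = ng86_site_counts("TTT")
        assert math.isclose(s, 1 / 3) and math.isclose(n, 8 / 3)

    def test_fourfold_codon_has_full_synonymous_site(self):
        s, _ = ng86_site_counts("CTC")
        assert s == 1.0

    @pytest.mark.parametrize("stop", STOPS)
    def test_stop_codon_is_domain_error(self, stop):
        with pytest.raises(MitocompError):
            ng86_site_counts(stop)


class TestPairwise:
    def test_identical_sequences(self):
        r = ng86_pair("ATGAAATTT", "ATGAAATTT")
        assert r.sd == r.nd == 0.0 and r.omega is None and r.ds == 0.0

    def test_single_synonymous_difference(self):
        r = ng86_pair("TTTGAA", "TTCGAA")
        assert r.sd == 1.0 and r.nd == 0.0
        assert math.isclose(r.s_sites, 2 / 3)
        assert math.isclose(r.n_sites, 16 / 3)

    def test_two_position_pathway_average(self):
        # TTT->GTA via GTT (1 syn step) or TTA (0 syn steps): mean 0.5/1.5
        r = ng86_pair("TTT", "GTA")
        assert math.isclose(r.sd, 0.5) and math.isclose(r.nd, 1.5)

    def test_matches_pathway_oracle_on_all_near_pairs(self):
        """Exhaustive agreement with the brute-force pathway oracle on
        every sense-codon pair differing at <= 2 positions."""
        checked = 0
        for c1, c2 in product(SENSE, SENSE):
            ndiff = sum(a != b for a, b in zip(c1, c2))
            if not 1 <= ndiff <= 2:
                continue
            r = ng86_pair(c1, c2)
            bs, bn = brute_pathway_counts(c1, c2)
            assert math.isclose(r.sd, bs, abs_tol=1e-12), (c1, c2)
            assert math.isclose(r.nd, bn, abs_tol=1e-12), (c1, c2)
            checked += 1
        assert checked > 1000

    @given(st.lists(st.sampled_from(SENSE), min_size=2, max_size=40), st.integers(0, 5))
    @settings(max_examples=50)
    def test_symmetry(self, codons, seed):
        s1 = "".join(codons)
        s2 = diverge_gene(s1 + "TAA", DivergenceSpec(
            n_syn=min(2, len(codons) - 1), n_nonsyn=0, seed=seed))[:-3] \
            if len(codons) > 2 else s1
        assert ng86_pair(s1, s2) == ng86_pair(s2, s1)

    def test_gap_codons_skipped(self):
        r = ng86_pair("TTT---GAA", "TTCAAAGAA")
        assert r.n_codons == 2 and r.sd == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(MitocompError):
            ng86_pair("ATGAAA", "ATG")


class TestGeneOmega:
    def test_identical_alignment_has_no_defined_omega(self):
        s = gene_omega(["ATGAAATTT"] * 3)
        assert s.n_defined == 0 and s.omega_pooled is None and s.omega_mean is None

    def test_purely_synonymous_divergence_gives_omega_zero(self, synthetic_genome):
        cds = feature_sequence(synthetic_genome, "cox1")
        cds = cds[: len(cds) // 3 * 3]
        div = diverge_gene(cds, DivergenceSpec(n_syn=10, n_nonsyn=0, seed=4))
        s = gene_omega([cds, div])
        assert s.omega_pooled == 0.0

    def test_planted_omega_recovered_on_long_alignment(self):
        """Divergence planted at a known nonsyn:syn count ratio on NG86
        sites is re-estimated within +/-20% at 5,000 codons."""
        rng = np.random.default_rng(42)
        codons = [c for c in SENSE if c not in ("ATG",)]
        base = "ATG" + "".join(rng.choice(codons, size=4_999)) + "TAA"
        r0 = ng86_pair(base[:-3], base[:-3])
        n_syn, n_nonsyn = 150, 150
        div = diverge_gene(base, DivergenceSpec(n_syn=n_syn, n_nonsyn=n_nonsyn, seed=7))
        target = (n_nonsyn / r0.n_sites) / (n_syn / r0.s_sites)
        got = gene_omega([base[:-3], div[:-3]]).omega_pooled
        assert got == pytest.approx(target, rel=0.20)

    def test_neutral_simulation_omega_near_one(self):
        """Substitutions hitting syn/nonsyn in proportion to NG86 site
        counts give pooled omega ~ 1."""
        rng = np.random.default_rng(3)
        base = "ATG" + "".join(rng.choice(SENSE, size=4_999)) + "TAA"
        r0 = ng86_pair(base[:-3], base[:-3])
        total = 300
        n_syn = int(round(total * r0.s_sites / (r0.s_sites + r0.n_sites)))
        div = diverge_gene(base, DivergenceSpec(n_syn=n_syn, n_nonsyn=total - n_syn,
                                                seed=9))
        got = gene_omega([base[:-3], div[:-3]]).omega_pooled
        assert 0.8 < got < 1.25

    def test_too_few_sequences_rejected(self):
        with pytest.raises(MitocompError):
            gene_omega(["ATGAAA"])


class TestPDistance:
    def test_identical_pair(self):
        m = p_distance_matrix(["ACGTACGTAC"] * 2)
        assert m.values[0, 1] == 0.0 and m.similarity()[0, 1] == 100.0

    def test_one_difference_in_ten(self):
        m = p_distance_matrix(["ACGTACGTAC", "ACGTACGTAT"])
        assert m.values[0, 1] == 0.1

    def test_gaps_and_ns_excluded_from_denominator(self):
        m = p_distance_matrix(["ACGT-N", "ACTTAN"])
        # comparable sites: first 4; one differs
        assert m.values[0, 1] == 0.25

    def test_matrix_symmetric_zero_diagonal(self, synthetic_genome):
        seqs = [synthetic_genome.sequence[:500],
                synthetic_genome.sequence[500:1000],
                synthetic_genome.sequence[1000:1500]]
        m = p_distance_matrix(seqs)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_random_uniform_pair_near_three_quarters(self):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), size=10_000))
        b = "".join(rng.choice(list("ACGT"), size=10_000))
        p = p_distance_matrix([a, b]).values[0, 1]
        sigma = math.sqrt(0.75 * 0.25 / 10_000)
        assert abs(p - 0.75) < 3 * sigma
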