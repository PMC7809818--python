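import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocomp import (
    GeneticCode,
    classify_start_stop,
    codon_counts,
    feature_sequence,
    rscu,
)
from mitocomp.codon_usage import ALL_CODONS, TruncationError

#: Genes of the reference annotation whose lengths are not codon
#: multiples, hence end in truncated stops completed by polyadenylation.
TRUNCATED_GENES = {"nd2": "T--", "cox3": "T--", "nd3": "T--",
                   "nd4": "TA-", "cytb": "T--"}


class TestGeneticCode:
    def test_vertebrate_mito_particulars(self, code):
        assert code.is_stop("AGA") and code.is_stop("AGG")
        assert code.translate("ATA") == "M"
        assert code.translate("TGA") == "W"
        assert len(code.sense_codons) == 60

    def test_split_family_labels(self, code):
        assert code.family_map["TTA"] == "L(UUR)"
        assert code.family_map["CTA"] == "L(CUN)"
        assert code.family_map["AGT"] == "S(AGY)"
        assert code.family_map["TCT"] == "S(UCN)"

    def test_merged_convention_pools_sixfold_families(self):
        merged = GeneticCode(family_convention="merged")
        assert len(merged.families["L"]) == 6
        assert len(merged.families["S"]) == 6

    def test_families_partition_sense_codons(self, code):
        members = [c for codons in code.families.values() for c in codons]
        assert sorted(members) == sorted(code.sense_codons)


class TestClassifyStartStop:
    def test_simple_complete_orf(self):
        call = classify_start_stop("ATGAAATAA")
        assert (call.start_codon, call.stop_class) == ("ATG", "TAA")

    def test_truncated_one_base_tail(self):
        call = classify_start_stop("ATGAAA" + "T")
        assert call.stop_class == "T--"

    def test_truncated_two_base_tail(self):
        call = classify_start_stop("ATGAAA" + "TA")
        assert call.stop_class == "TA-"

    def test_bad_tail_is_truncation_error(self):
        with pytest.raises(TruncationError):
            classify_start_stop("ATGAAAG")

    def test_non_stop_final_codon_reported_not_fatal(self):
        call = classify_start_stop("ATGAAACCC")
        assert call.stop_class == "CCC" and not call.stop_is_canonical

    def test_reference_annotation_start_stop_calls(self, synthetic_genome):
        """Start codons and stop classes across the whole annotation:
        cox1 starts GTG, truncated stops exactly where length mod 3 != 0."""
        calls = {}
        for f in synthetic_genome.features:
            if f.ftype.value != "PCG":
                continue
            calls[f.name] = classify_start_stop(
                feature_sequence(synthetic_genome, f.name), f.name)
        assert calls["cox1"].start_codon == "GTG"
        assert all(c.start_codon == "ATG" for n, c in calls.items() if n != "cox1")
        truncated = {n: c.stop_class for n, c in calls.items()
                     if c.stop_class in ("TA-", "T--")}
        assert truncated == TRUNCATED_GENES

    def test_stop_class_consistent_with_length_mod3(self, synthetic_genome):
        for f in synthetic_genome.features:
            if f.ftype.value != "PCG":
                continue
            call = classify_start_stop(feature_sequence(synthetic_genome, f.name))
            n = f.length(len(synthetic_genome))
            expected = {0: ("TAA", "TAG", "AGA", "AGG"), 1: ("T--",), 2: ("TA-",)}
            assert call.stop_class in expected[n % 3]


class TestCodonCounts:
    def test_single_gene_counts(self):
        u = codon_counts(["ATGAAATAA"])
        assert u.counts == {"ATG": 1, "AAA": 1} and u.n_codons == 2

    def test_additivity(self):
        once = codon_counts(["ATGAAACCCTAA"])
        twice = codon_counts(["ATGAAACCCTAA"] * 2)
        assert twice.counts == {c: 2 * n for c, n in once.counts.items()}

    def test_gene_order_irrelevant(self, synthetic_genome):
        genes = [feature_sequence(synthetic_genome, n) for n in ("nd1", "cox1", "cytb")]
        assert codon_counts(genes).counts == codon_counts(genes[::-1]).counts

    def test_cdpt_sums_to_1000(self, synthetic_genome):
        genes = [feature_sequence(synthetic_genome, f.name)
                 for f in synthetic_genome.features if f.ftype.value == "PCG"]
        u = codon_counts(genes)
        assert math.isclose(sum(u.cdpt.values()), 1000.0, abs_tol=1e-9)

    def test_truncated_tail_excluded(self):
        # 2-codon body + TA tail: the tail is not a counted codon
        u = codon_counts(["ATGAAATA"])
        assert u.n_codons == 2


class TestRSCU:
    def test_uniform_family_gives_unit_rscu(self):
        u = codon_counts(["ATG" + "GTT" + "GTC" + "GTA" + "GTG" + "TAA"])
        vals = rscu(u)
        assert all(math.isclose(vals[c], 1.0) for c in ("GTT", "GTC", "GTA", "GTG"))

    def test_two_codon_family_boundary(self):
        u = codon_counts(["ATG" + "TGT" + "TGT" + "TAA"])  # Cys via TGT only
        vals = rscu(u)
        assert vals["TGT"] == 2.0 and vals["TGC"] == 0.0

    def test_phe_family_direct_formula(self):
        u = codon_counts(["ATG" + "TTT" * 3 + "TTC" + "TAA"])
        vals = rscu(u)
        assert math.isclose(vals["TTT"], 1.5) and math.isclose(vals["TTC"], 0.5)

    def test_unused_family_is_missing(self):
        vals = rscu(codon_counts(["ATGAAATAA"]))
        assert vals["TGT"] is None and vals["TGC"] is None

    @given(body=st.lists(st.sampled_from([c for c in ALL_CODONS
                                          if c not in ("TAA", "TAG", "AGA", "AGG")]),
                         min_size=4, max_size=120))
    def test_family_mean_is_one(self, body, code):
        """Mean RSCU over any family with nonzero usage is exactly 1."""
        u = codon_counts(["".join(body) + "TAA"])
        vals = rscu(u)
        for codons in code.families.values():
            family_vals = [vals[c] for c in codons]
            if any(v is not None for v in family_vals):
                assert math.isclose(sum(family_vals) / len(family_vals), 1.0,
                                    abs_tol=1e-12)

    def test_stop_codons_have_no_rscu(self, code):
        vals = rscu(codon_counts(["ATGAAATAA"]))
        assert "TAA" not in vals and "AGA" not in vals
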