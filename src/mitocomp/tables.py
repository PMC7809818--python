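"""Reference annotation layout and composition targets.

The canonical layout shipped with the package is the *Cobitis
macrostigma* mitogenome annotation (GenBank MT259034): the standard
vertebrate gene order of 13 PCGs, 22 tRNAs, 2 rRNAs, OL and CR on a
16,636 bp circle, including its characteristic junctions — the 10 bp
atp8/atp6 and 7 bp nd4l/nd4 gene overlaps and the tRNA-Asp/cox2
intergenic spacer.

Composition targets are the published per-region base percentages of
the same genome, used as defaults by the synthetic generator so that
simulated genomes match the base-composition regime of real loach
mitogenomes (AT-rich overall, negative GC skew, T-biased PCGs).
"""

from __future__ import annotations

from importlib.resources import files

__all__ = [
    "canonical_features",
    "canonical_order",
    "START_CODONS",
    "STOP_ASSIGNMENTS",
    "DEFAULT_COMPOSITION",
    "JUNCTION_MOTIFS",
    "PCG_NAMES",
]

PCG_NAMES = (
    "nd1", "nd2", "cox1", "cox2", "atp8", "atp6", "cox3",
    "nd3", "nd4l", "nd4", "nd5", "nd6", "cytb",
)

#: Annotated start codon of each PCG (cox1 uses GTG, the rest ATG).
START_CODONS: dict[str, str] = {name: "ATG" for name in PCG_NAMES}
START_CODONS["cox1"] = "GTG"

#: Stop class of each PCG in the reference annotation.  Truncated stops
#: ("TA-", "T--") are completed post-transcriptionally by polyadenylation
#: and occur where the gene length is not a multiple of 3.
STOP_ASSIGNMENTS: dict[str, str] = {
    "nd1": "TAA",
    "nd2": "T--",
    "cox1": "TAA",
    "cox2": "TAA",
    "atp8": "TAA",
    "atp6": "TAA",
    "cox3": "T--",
    "nd3": "T--",
    "nd4l": "TAA",
    "nd4": "TA-",
    "nd5": "TAG",
    "nd6": "TAA",
    "cytb": "T--",
}

#: Conserved junction motifs of loach mitogenomes: the shared bases of
#: the two long PCG overlaps.  atp8/atp6 carries a 3 bp GCA insertion
#: relative to the ATGATAA motif of other Cypriniformes.
JUNCTION_MOTIFS: dict[tuple[str, str], str] = {
    ("atp8", "atp6"): "ATGGCAATAA",
    ("nd4l", "nd4"): "ATGCTAA",
}

#: Per-region base composition targets as fractions of (A, C, G, T),
#: from the reference genome's published region summaries.
DEFAULT_COMPOSITION: dict[str, dict[str, float]] = {
    "all": {"A": 0.295, "C": 0.251, "G": 0.166, "T": 0.288},
    "PCG": {"A": 0.273, "C": 0.254, "G": 0.159, "T": 0.315},
    "PCG_pos1": {"A": 0.262, "C": 0.247, "G": 0.259, "T": 0.232},
    "PCG_pos2": {"A": 0.182, "C": 0.273, "G": 0.136, "T": 0.409},
    "PCG_pos3": {"A": 0.373, "C": 0.243, "G": 0.082, "T": 0.302},
    "tRNA": {"A": 0.283, "C": 0.216, "G": 0.232, "T": 0.269},
    "rRNA": {"A": 0.332, "C": 0.230, "G": 0.217, "T": 0.221},
    "CR": {"A": 0.344, "C": 0.194, "G": 0.143, "T": 0.320},
    "OL": {"A": 0.25, "C": 0.30, "G": 0.25, "T": 0.20},
    "spacer": {"A": 0.295, "C": 0.251, "G": 0.166, "T": 0.288},
}


def _load_feature_rows() -> list[tuple[str, str, int, int, str, str | None]]:
    text = files("mitocomp.data").joinpath("c_macrostigma_table2.tsv").read_text()
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        name, ftype, start, end, strand = parts[:5]
        anticodon = parts[5] if len(parts) > 5 and parts[5] else None
        rows.append((name, ftype, int(start), int(end), strand, anticodon))
    return rows


def canonical_features():
    """The reference annotation as a list of :class:`GeneFeature`."""
    from .model import FeatureType, GeneFeature

    return [
        GeneFeature(name=n, ftype=FeatureType(t), start=s, end=e,
                    strand=st, anticodon=ac)
        for n, t, s, e, st, ac in _load_feature_rows()
    ]


def canonical_order() -> list[str]:
    """Gene symbols of the canonical vertebrate order, by start position."""
    return [row[0] for row in _load_feature_rows()]


CANONICAL_GENOME_LENGTH = 16_636
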