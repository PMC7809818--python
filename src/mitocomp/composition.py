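"""Base composition and strand-skew statistics.

Strand compositional asymmetry of mtDNA is summarised by

    AT-skew = (A% - T%) / (A% + T%)
    GC-skew = (G% - C%) / (G% + C%)

computed per region: the whole molecule, the concatenated PCGs (whole
and split by codon position), the concatenated tRNAs and rRNAs, and the
control region.  PCG/tRNA/rRNA material is assembled on the coding
strand by default (L-strand genes reverse-complemented), which is the
sense in which the T-over-A bias of mitochondrial PCGs is visible; a
``strand_mode="reference"`` switch keeps raw H-strand slices instead.

Codon-position splits drop each gene's terminal stop codon, complete or
truncated, so the three positions have equal size; N bases are excluded
from every percentage denominator.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .genome_io import feature_sequence
from .model import FeatureType, MitocompError, Mitogenome, check_alphabet

__all__ = [
    "REGIONS",
    "RegionSummary",
    "RegionError",
    "base_counts",
    "skew",
    "region_sequence",
    "region_summary",
    "composition_matrix",
]

#: Closed region vocabulary.
REGIONS = ("all", "PCG", "PCG_pos1", "PCG_pos2", "PCG_pos3", "tRNA", "rRNA", "CR")

_REGION_FTYPE = {"PCG": FeatureType.PCG, "tRNA": FeatureType.TRNA, "rRNA": FeatureType.RRNA}


class RegionError(MitocompError):
    """The genome lacks the features a region requires."""


@dataclass(frozen=True)
class RegionSummary:
    """Composition and skew of one region (one row of a composition table)."""

    region_id: str
    size: int
    a_pct: float
    t_pct: float
    c_pct: float
    g_pct: float
    at_pct: float
    gc_pct: float
    at_skew: float | None
    gc_skew: float | None


def base_counts(sequence: str) -> dict[str, int]:
    """Counts of A, C, G, T and N; any other character is an error."""
    check_alphabet(sequence)
    c = Counter(sequence)
    return {b: c.get(b, 0) for b in "ACGTN"}


def skew(counts: dict[str, int]) -> tuple[float | None, float | None]:
    """(AT-skew, GC-skew) from base counts; ``None`` when a denominator
    is zero."""
    a, t = counts.get("A", 0), counts.get("T", 0)
    g, c = counts.get("G", 0), counts.get("C", 0)
    at = (a - t) / (a + t) if a + t > 0 else None
    gc = (g - c) / (g + c) if g + c > 0 else None
    return at, gc


def _strip_stop(seq: str) -> str:
    """Drop a gene's terminal stop codon, complete (3 bases) or
    truncated (the 1- or 2-base remainder)."""
    r = len(seq) % 3
    return seq[: len(seq) - (3 if r == 0 else r)]


def _feature_seqs(genome: Mitogenome, ftype: FeatureType, strand_mode: str) -> list[str]:
    feats = genome.features_of_type(ftype)
    if not feats:
        raise RegionError(f"{genome.id}: no {ftype.value} features annotated")
    if strand_mode == "reference":
        return [genome.slice(f.start, f.end) for f in feats]
    return [feature_sequence(genome, f.name) for f in feats]


def region_sequence(genome: Mitogenome, region_id: str, strand_mode: str = "coding") -> str:
    """Assemble the material a region's statistics are computed on.

    Overlapping bases are counted once per feature they belong to, so
    the PCG region size equals the sum of gene lengths.
    """
    if region_id not in REGIONS:
        raise RegionError(f"unknown region {region_id!r}; expected one of {REGIONS}")
    if strand_mode not in ("coding", "reference"):
        raise ValueError(f"strand_mode must be 'coding' or 'reference', got {strand_mode!r}")
    if region_id == "all":
        return genome.require_sequence()
    if region_id == "CR":
        crs = genome.features_of_type(FeatureType.CR)
        if not crs:
            raise RegionError(f"{genome.id}: no control region annotated")
        return genome.slice(crs[0].start, crs[0].end)
    if region_id in _REGION_FTYPE:
        return "".join(_feature_seqs(genome, _REGION_FTYPE[region_id], strand_mode))
    # PCG_pos1/2/3: positional comb over complete codons, stops dropped
    pos = int(region_id[-1])
    genes = _feature_seqs(genome, FeatureType.PCG, strand_mode)
    return "".join(_strip_stop(g)[pos - 1 :: 3] for g in genes)


def region_summary(genome: Mitogenome, region_id: str,
                   strand_mode: str = "coding") -> RegionSummary:
    """Composition and skew of one region of one genome."""
    seq = region_sequence(genome, region_id, strand_mode)
    counts = base_counts(seq)
    counted = sum(counts[b] for b in "ACGT")
    if counted == 0:
        pct = {b: math.nan for b in "ACGT"}
    else:
        pct = {b: 100.0 * counts[b] / counted for b in "ACGT"}
    at_skew, gc_skew = skew(counts)
    return RegionSummary(
        region_id=region_id,
        size=len(seq),
        a_pct=pct["A"], t_pct=pct["T"], c_pct=pct["C"], g_pct=pct["G"],
        at_pct=pct["A"] + pct["T"], gc_pct=pct["G"] + pct["C"],
        at_skew=at_skew, gc_skew=gc_skew,
    )


def composition_matrix(genomes: list[Mitogenome], regions: tuple[str, ...] = REGIONS,
                       strand_mode: str = "coding") -> pd.DataFrame:
    """Long-format table: one row per (genome, region).

    Rows whose region cannot be assembled for a genome are reported as
    missing with a warning rather than failing the whole table.
    """
    import logging

    rows = []
    for g in genomes:
        for region in regions:
            try:
                s = region_summary(g, region, strand_mode)
            except (RegionError, MitocompError) as exc:
                logging.getLogger(__name__).warning("%s/%s: %s", g.id, region, exc)
                continue
            rows.append({"genome": g.id, **s.__dict__})
    return pd.DataFrame(rows)
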