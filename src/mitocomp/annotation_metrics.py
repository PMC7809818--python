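"""Annotation arithmetic on the mitogenome circle.

Adjacent annotated features are separated by a signed number of bases:
positive values are intergenic spacers (IGS), negative values are gene
overlaps, zero means the features abut.  The sign convention is

    spacer = start(downstream) - end(upstream) - 1

computed on start-sorted order along the H strand, with the last->first
junction closed circularly.  On a fully tiled circular annotation the
feature lengths and spacers sum exactly to the genome length.

Vertebrate mitogenomes show a handful of characteristic junctions: long
overlaps at atp8/atp6 and nd4l/nd4 (whose shared bases carry conserved
motifs), small tRNA/tRNA overlaps, and long spacers at OL and
tRNA-Asp/cox2.  ``junction_window`` extracts the H-strand sequence of
any such junction for logo or consensus analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .model import CoordinateError, GeneFeature, Mitogenome

__all__ = [
    "JunctionRecord",
    "OrderReport",
    "spacer_table",
    "junction_window",
    "validate_gene_order",
    "tiling_check",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JunctionRecord:
    """One junction between adjacent features on the circle."""

    upstream: str
    downstream: str
    spacer: int
    junction_seq: str | None = None


@dataclass(frozen=True)
class OrderReport:
    """Result of comparing a genome's cyclic gene order to a template."""

    matches_template: bool
    breakpoints: tuple[tuple[str, str], ...]
    template_id: str = "canonical-vertebrate"


def _sorted_features(genome: Mitogenome) -> list[GeneFeature]:
    feats = sorted(genome.features, key=lambda f: f.start)
    for prev, nxt in zip(feats, feats[1:]):
        if (nxt.start >= prev.start and nxt.end <= prev.end
                and not prev.wraps and not nxt.wraps):
            raise CoordinateError(
                f"{genome.id}: feature {nxt.name} is nested inside {prev.name}; "
                "spacer arithmetic is undefined for nested features"
            )
    return feats


def spacer_table(genome: Mitogenome, *, with_sequence: bool = False,
                 flank: int = 0) -> list[JunctionRecord]:
    """Signed spacer/overlap for every adjacent feature pair.

    One record per adjacent pair in start order, plus the wrap-around
    junction on circular genomes.  With ``with_sequence=True`` (requires
    a sequence) each record carries its ``junction_window``.
    """
    feats = _sorted_features(genome)
    if len(feats) < 2:
        return []
    n = len(genome)
    records = []
    pairs = list(zip(feats, feats[1:]))
    if genome.circular:
        pairs.append((feats[-1], feats[0]))
    for up, down in pairs:
        down_start = down.start + n if down.start < up.start else down.start
        up_end = up.end + n if up.wraps else up.end
        spacer = down_start - up_end - 1
        seq = None
        if with_sequence:
            seq = junction_window(genome, up.name, down.name, flank)
        records.append(JunctionRecord(up.name, down.name, spacer, seq))
    return records


def junction_window(genome: Mitogenome, upstream: str, downstream: str,
                    flank: int = 0) -> str:
    """H-strand window over the junction between two features.

    The core of the window is the overlap (shared bases) for negative
    spacers or the intergenic bases for positive spacers; ``flank``
    bases are added on both sides.  For a pure overlap with ``flank=0``
    this is exactly the shared sequence; for abutting features it is
    empty.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    up = genome.feature(upstream)
    down = genome.feature(downstream)
    n = len(genome)
    down_start = down.start + n if down.start < up.start else down.start
    up_end = up.end + n if up.wraps else up.end
    core_start = min(down_start, up_end + 1)
    core_end = max(up_end, down_start - 1)
    length = core_end - core_start + 1 + 2 * flank
    if length <= 0:
        return ""
    window = genome.slice(core_start - flank, core_end + flank)
    assert len(window) == length
    return window


def validate_gene_order(genome: Mitogenome, template: list[str],
                        template_id: str = "canonical-vertebrate") -> OrderReport:
    """Compare the genome's cyclic gene order to a template order.

    Symbols present in the genome but absent from the template are
    ignored with a warning; the template may be a subset.  A breakpoint
    is an adjacent pair (on the genome circle, restricted to shared
    symbols) that is not adjacent in the template's cyclic order.
    """
    genome_order = [f.name for f in _sorted_features(genome)]
    extra = [s for s in genome_order if s not in template]
    if extra:
        logger.warning("%s: symbols not in template ignored: %s", genome.id, extra)
    shared_genome = [s for s in genome_order if s in template]
    shared_template = [s for s in template if s in shared_genome]
    if len(shared_genome) < 2:
        return OrderReport(True, (), template_id)

    def successor_map(order: list[str]) -> dict[str, str]:
        return {a: order[(i + 1) % len(order)] for i, a in enumerate(order)}

    g_succ = successor_map(shared_genome)
    t_succ = successor_map(shared_template)
    breakpoints = tuple(
        (a, g_succ[a]) for a in shared_genome if g_succ[a] != t_succ[a]
    )
    return OrderReport(not breakpoints, breakpoints, template_id)


def tiling_check(genome: Mitogenome) -> tuple[int, int]:
    """(sum of feature lengths + spacers, genome length); equal on a
    fully annotated circular genome."""
    n = len(genome)
    total = sum(f.length(n) for f in genome.features)
    total += sum(r.spacer for r in spacer_table(genome))
    return total, n
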