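"""Codon statistics under the vertebrate mitochondrial genetic code.

The vertebrate mitochondrial code (NCBI translation table 2) differs
from the standard code in AGA/AGG being stops, ATA coding Met and TGA
coding Trp.  Mitochondrial PCGs may also end in truncated stop codons
("TA-" or "T--") that are completed to UAA post-transcriptionally by
polyadenylation; these are recognised from the gene length modulo 3.

Reported statistics:

* per-codon counts and CDpT (codons per thousand codons),
* RSCU, the relative synonymous codon usage: a codon's count divided by
  the mean count of its synonymous family, so a uniformly used family
  has RSCU 1 for every member,
* per-gene start codon and stop class.

Synonymous families follow the plotting convention that keeps the two
leucine (UUR/CUN) and two serine (UCN/AGY) codon blocks separate;
``family_convention="merged"`` collapses them into six-fold families.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

from .model import MitocompError, check_alphabet

__all__ = [
    "GeneticCode",
    "StartStopCall",
    "CodonUsage",
    "classify_start_stop",
    "codon_counts",
    "rscu",
    "TruncationError",
]

logger = logging.getLogger(__name__)

ALL_CODONS = tuple("".join(p) for p in product("TCAG", repeat=3))

_RNA = str.maketrans("T", "U")


class TruncationError(MitocompError):
    """Gene length is not a codon multiple and the tail is not a
    recognisable truncated stop."""


class GeneticCode:
    """A genetic code plus its synonymous-family structure.

    Parameters
    ----------
    table_id:
        NCBI translation table number (default 2, vertebrate
        mitochondrial).
    family_convention:
        "split" keeps codon blocks with distinct first two bases as
        separate families (Leu(UUR)/Leu(CUN), Ser(UCN)/Ser(AGY));
        "merged" pools all codons of an amino acid.
    """

    def __init__(self, table_id: int = 2, family_convention: str = "split"):
        if family_convention not in ("split", "merged"):
            raise ValueError("family_convention must be 'split' or 'merged'")
        self.table_id = table_id
        self.family_convention = family_convention
        table = CodonTable.unambiguous_dna_by_id[table_id]
        self.stop_codons = frozenset(table.stop_codons)
        self.forward = dict(table.forward_table)  # sense codon -> 1-letter aa
        self.sense_codons = tuple(c for c in ALL_CODONS if c not in self.stop_codons)
        self.family_map = self._build_families()
        self.families: dict[str, tuple[str, ...]] = {}
        for codon, label in self.family_map.items():
            self.families.setdefault(label, ())
            self.families[label] += (codon,)

    def translate(self, codon: str) -> str:
        """1-letter amino acid, or '*' for a stop codon."""
        return "*" if codon in self.stop_codons else self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def _build_families(self) -> dict[str, str]:
        blocks: dict[tuple[str, str], list[str]] = {}
        for codon in self.sense_codons:
            aa = self.forward[codon]
            key = (aa, codon[:2]) if self.family_convention == "split" else (aa, "")
            blocks.setdefault(key, []).append(codon)
        aa_block_count: dict[str, int] = {}
        for aa, _ in blocks:
            aa_block_count[aa] = aa_block_count.get(aa, 0) + 1
        fam_map: dict[str, str] = {}
        for (aa, prefix), codons in blocks.items():
            if self.family_convention == "split" and aa_block_count[aa] > 1:
                thirds = frozenset(c[2] for c in codons)
                suffix = {frozenset("TCAG"): "N", frozenset("AG"): "R",
                          frozenset("TC"): "Y"}.get(thirds, "/".join(sorted(thirds)))
                label = f"{aa}({prefix.translate(_RNA)}{suffix})"
            else:
                label = aa
            for c in codons:
                fam_map[c] = label
        return fam_map


@dataclass(frozen=True)
class StartStopCall:
    """Annotated start codon and stop class of one gene."""

    gene: str
    start_codon: str
    stop_class: str  # TAA/TAG/AGA/AGG or truncated TA-/T--
    stop_is_canonical: bool = True


@dataclass
class CodonUsage:
    """Codon counts over one or more genes (terminal stops excluded)."""

    counts: dict[str, int]
    n_codons: int
    code: GeneticCode = field(repr=False)

    @property
    def cdpt(self) -> dict[str, float]:
        """Codons per thousand codons."""
        if self.n_codons == 0:
            return {c: 0.0 for c in ALL_CODONS}
        return {c: 1000.0 * self.counts.get(c, 0) / self.n_codons for c in ALL_CODONS}


def classify_start_stop(coding_seq: str, gene: str = "", *,
                        code: GeneticCode | None = None) -> StartStopCall:
    """Classify the annotated start codon and stop class of a coding
    sequence (5'->3', length >= 6).

    The stop class is "T--" for a 1-base T tail, "TA-" for a 2-base TA
    tail, and otherwise the final complete codon; a final codon that is
    not a stop of the configured code is reported with
    ``stop_is_canonical=False`` and a warning rather than an error.
    """
    code = code or GeneticCode()
    check_alphabet(coding_seq)
    if len(coding_seq) < 6:
        raise MitocompError(f"{gene or 'gene'}: coding sequence shorter than 6 bases")
    start = coding_seq[:3]
    r = len(coding_seq) % 3
    if r == 1:
        if coding_seq[-1] != "T":
            raise TruncationError(
                f"{gene or 'gene'}: 1-base tail {coding_seq[-1]!r} is not a truncated stop"
            )
        return StartStopCall(gene, start, "T--")
    if r == 2:
        if coding_seq[-2:] != "TA":
            raise TruncationError(
                f"{gene or 'gene'}: 2-base tail {coding_seq[-2:]!r} is not a truncated stop"
            )
        return StartStopCall(gene, start, "TA-")
    last = coding_seq[-3:]
    if not code.is_stop(last):
        logger.warning("%s: final codon %s is not a stop under table %d",
                       gene or "gene", last, code.table_id)
        return StartStopCall(gene, start, last, stop_is_canonical=False)
    return StartStopCall(gene, start, last)


def _strip_terminal_stop(seq: str, code: GeneticCode) -> str:
    r = len(seq) % 3
    if r:
        return seq[:-r]
    return seq[:-3] if code.is_stop(seq[-3:]) else seq


def codon_counts(genes: list[str], *, code: GeneticCode | None = None) -> CodonUsage:
    """Count complete codons over a set of coding sequences, excluding
    each gene's terminal stop codon (complete or truncated)."""
    code = code or GeneticCode()
    counts: dict[str, int] = {}
    total = 0
    for seq in genes:
        check_alphabet(seq)
        if len(seq) < 6:
            raise MitocompError("coding sequence shorter than 6 bases")
        body = _strip_terminal_stop(seq, code)
        for i in range(0, len(body) - 2, 3):
            codon = body[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] = counts.get(codon, 0) + 1
            total += 1
    return CodonUsage(counts=counts, n_codons=total, code=code)


def rscu(usage: CodonUsage) -> dict[str, float | None]:
    """Relative synonymous codon usage per sense codon.

    rscu(c) = count(c) * |family(c)| / sum of counts over family(c);
    families with zero total usage have RSCU missing for all members.
    Stop codons are not part of any family.
    """
    code = usage.code
    out: dict[str, float | None] = {}
    for label, codons in code.families.items():
        total = sum(usage.counts.get(c, 0) for c in codons)
        for c in codons:
            out[c] = None if total == 0 else usage.counts.get(c, 0) * len(codons) / total
    return out
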