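"""Core data model for annotated circular mitochondrial genomes.

A vertebrate mitogenome is a circular molecule of ~16-17 kb carrying 13
protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs, the light-strand
replication origin (OL) and the control region (CR).  The reference
strand held in :class:`Mitogenome.sequence` is the heavy (H) strand read
5'->3'; features annotated on the light (L) strand are read as its
reverse complement.

Coordinates are 1-based inclusive throughout the public interface, the
convention used by GenBank feature tables.  On a circular genome a
feature whose ``start`` exceeds its ``end`` wraps through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator

__all__ = [
    "FeatureType",
    "GeneFeature",
    "Mitogenome",
    "reverse_complement",
    "MitocompError",
    "AlphabetError",
    "CoordinateError",
    "FeatureLookupError",
    "NoSequenceError",
]

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class MitocompError(Exception):
    """Base class for errors raised by this package."""


class AlphabetError(MitocompError):
    """Sequence contains characters outside {A, C, G, T, N}."""


class CoordinateError(MitocompError):
    """Feature coordinates are inconsistent with the genome."""


class FeatureLookupError(MitocompError, KeyError):
    """Requested feature name is not annotated on the genome."""


class NoSequenceError(MitocompError):
    """A sequence-dependent operation was called on a record without one."""


def reverse_complement(seq: str) -> str:
    """Return the reverse complement of ``seq`` (alphabet A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def check_alphabet(seq: str) -> str:
    bad = set(seq) - VALID_BASES
    if bad:
        raise AlphabetError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


class FeatureType(str, Enum):
    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    OL = "OL"
    CR = "CR"


@dataclass(frozen=True)
class GeneFeature:
    """One annotated element of a mitogenome.

    ``start``/``end`` are 1-based inclusive on the H strand; ``strand``
    is "H" or "L".  ``anticodon`` is only meaningful for tRNAs.
    """

    name: str
    ftype: FeatureType
    start: int
    end: int
    strand: str = "H"
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"{self.name}: coordinates are 1-based, got {self.start}..{self.end}"
            )
        if self.strand not in ("H", "L"):
            raise CoordinateError(f"{self.name}: strand must be 'H' or 'L'")

    @property
    def wraps(self) -> bool:
        """True when the feature crosses the circular origin."""
        return self.start > self.end

    def length(self, genome_length: int | None = None) -> int:
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError(
                f"{self.name} wraps the origin; genome length required"
            )
        return genome_length - self.start + 1 + self.end


@dataclass
class Mitogenome:
    """An annotated mitochondrial genome record.

    Features are kept sorted by start coordinate; names are unique
    within a record.  ``sequence`` may be empty for coordinate-only
    records (e.g. a feature table without its sequence), in which case
    sequence-dependent operations raise :class:`NoSequenceError`.
    """

    id: str
    sequence: str = ""
    organism: str = ""
    circular: bool = True
    length: int | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence:
            check_alphabet(self.sequence)
            if self.length is None:
                self.length = len(self.sequence)
            elif self.length != len(self.sequence):
                raise CoordinateError(
                    f"{self.id}: declared length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
        self.features = sorted(self.features, key=lambda f: f.start)
        names = [f.name for f in self.features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise CoordinateError(f"{self.id}: duplicate feature names {sorted(dupes)}")
        if self.length is not None:
            for f in self.features:
                if f.start > self.length or f.end > self.length:
                    raise CoordinateError(
                        f"{self.id}: feature {f.name} ({f.start}..{f.end}) "
                        f"exceeds genome length {self.length}"
                    )
                if f.wraps and not self.circular:
                    raise CoordinateError(
                        f"{self.id}: feature {f.name} wraps but topology is linear"
                    )

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        if self.length is None:
            raise NoSequenceError(f"{self.id}: no sequence or length available")
        return self.length

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise FeatureLookupError(name)

    def has_feature(self, name: str) -> bool:
        return any(f.name == name for f in self.features)

    def features_of_type(self, ftype: FeatureType) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype is ftype]

    def feature_length(self, name: str) -> int:
        return self.feature(name).length(self.length)

    # -- sequence access -------------------------------------------------

    def require_sequence(self) -> str:
        if not self.sequence:
            raise NoSequenceError(f"{self.id}: operation requires a sequence")
        return self.sequence

    def slice(self, start: int, end: int) -> str:
        """H-strand slice, 1-based inclusive, wrapping through the origin
        when ``start > end`` on a circular genome."""
        seq = self.require_sequence()
        n = len(seq)
        start = ((start - 1) % n) + 1
        end = ((end - 1) % n) + 1
        if start <= end:
            return seq[start - 1 : end]
        if not self.circular:
            raise CoordinateError(
                f"{self.id}: slice {start}..{end} wraps but topology is linear"
            )
        return seq[start - 1 :] + seq[:end]

    def with_features(self, features: Iterable[GeneFeature]) -> "Mitogenome":
        return replace(self, features=list(features))

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)
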