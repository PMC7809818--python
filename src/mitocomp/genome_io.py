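"""Reading and writing annotated mitogenomes.

Three on-disk representations are supported:

* GenBank flat files (via Biopython), the format mitogenome accessions
  are distributed in.  Only LOCUS/ORGANISM/FEATURES/ORIGIN are needed;
  qualifiers beyond ``/gene`` and ``/product`` are ignored.
* FASTA for bare sequences.
* A plain feature-table TSV dialect
  (``name<TAB>type<TAB>start<TAB>end<TAB>strand[<TAB>anticodon]``,
  ``#`` comments allowed) mirroring the layout of published annotation
  tables, usable with or without an accompanying FASTA sequence.

Coordinates in every file and every returned record are 1-based
inclusive.
"""

from __future__ import annotations

import logging
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    CoordinateError,
    FeatureType,
    GeneFeature,
    MitocompError,
    Mitogenome,
    reverse_complement,
)

__all__ = [
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "feature_sequence",
    "ParseError",
]

logger = logging.getLogger(__name__)


class ParseError(MitocompError):
    """Input file could not be interpreted."""


# GenBank feature keys handled, and their internal types.
_GB_KEY_TO_TYPE = {
    "CDS": FeatureType.PCG,
    "tRNA": FeatureType.TRNA,
    "rRNA": FeatureType.RRNA,
    "rep_origin": FeatureType.OL,
    "D-loop": FeatureType.CR,
}
_TYPE_TO_GB_KEY = {v: k for k, v in _GB_KEY_TO_TYPE.items()}

# Common long-form names seen across submitting labs, normalised to the
# compact symbols used internally.
_NAME_ALIASES = {
    "12s ribosomal rna": "rrnS",
    "12s rrna": "rrnS",
    "s-rrna": "rrnS",
    "16s ribosomal rna": "rrnL",
    "16s rrna": "rrnL",
    "l-rrna": "rrnL",
    "control region": "CR",
    "d-loop": "CR",
    "nad1": "nd1", "nad2": "nd2", "nad3": "nd3", "nad4": "nd4",
    "nad4l": "nd4l", "nad5": "nd5", "nad6": "nd6",
    "cob": "cytb", "cytochrome b": "cytb",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "atpase6": "atp6", "atpase8": "atp8",
}

_AA3_TO_TRN = {
    "Phe": "trnF", "Val": "trnV", "Ile": "trnI", "Gln": "trnQ",
    "Met": "trnM", "Trp": "trnW", "Ala": "trnA", "Asn": "trnN",
    "Cys": "trnC", "Tyr": "trnY", "Asp": "trnD", "Lys": "trnK",
    "Gly": "trnG", "Arg": "trnR", "His": "trnH", "Glu": "trnE",
    "Thr": "trnT", "Pro": "trnP",
}


def _normalise_name(raw: str, ftype: FeatureType) -> str:
    name = raw.strip()
    alias = _NAME_ALIASES.get(name.lower())
    if alias:
        return alias
    if ftype is FeatureType.TRNA and name.startswith("tRNA-"):
        aa = name[5:]
        if aa in _AA3_TO_TRN:
            return _AA3_TO_TRN[aa]
        # the two Leu/Ser isoacceptors need their codon family kept
        low = aa.lower()
        if low.startswith("leu"):
            return "trnL1" if "uur" in low or "taa" in low else "trnL2"
        if low.startswith("ser"):
            return "trnS2" if "ucn" in low or "tga" in low else "trnS1"
    return name


# ---------------------------------------------------------------------------
# GenBank


def read_genbank(path: str | Path) -> Mitogenome:
    """Read a GenBank flat file into a :class:`Mitogenome`.

    Feature kinds other than CDS/gene/tRNA/rRNA/rep_origin/D-loop are
    skipped with a warning.  A file without an ORIGIN sequence block is
    a parse error.
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not a readable GenBank record ({exc})") from exc
    try:
        sequence = str(record.seq).upper()
    except Exception as exc:  # undefined Seq => no ORIGIN block
        raise ParseError(f"{path}: missing ORIGIN sequence block") from exc
    if not sequence:
        raise ParseError(f"{path}: missing ORIGIN sequence block")

    circular = record.annotations.get("topology", "circular") != "linear"
    features: list[GeneFeature] = []
    seen: set[str] = set()
    for feat in record.features:
        if feat.type == "gene":
            continue  # paired with a CDS/tRNA/rRNA carrying the same span
        ftype = _GB_KEY_TO_TYPE.get(feat.type)
        if ftype is None:
            if feat.type != "source":
                logger.warning("%s: skipping unhandled feature kind %r", path, feat.type)
            continue
        quals = feat.qualifiers
        raw = (quals.get("gene") or quals.get("product") or [feat.type])[0]
        name = _normalise_name(raw, ftype)
        if name in seen:
            logger.warning("%s: duplicate feature %s skipped", path, name)
            continue
        seen.add(name)
        start, end = _location_bounds(feat, len(sequence))
        strand = "L" if feat.location.strand == -1 else "H"
        anticodon = None
        if "anticodon" in quals:
            ac = quals["anticodon"][0]
            anticodon = ac.split("seq:")[-1].rstrip(")").upper() if "seq:" in ac else ac.upper()
        features.append(
            GeneFeature(name=name, ftype=ftype, start=start, end=end,
                        strand=strand, anticodon=anticodon)
        )

    return Mitogenome(
        id=record.id or record.name,
        sequence=sequence,
        organism=record.annotations.get("organism", ""),
        circular=circular,
        features=features,
    )


def _location_bounds(feat: SeqFeature, genome_length: int) -> tuple[int, int]:
    loc = feat.location
    parts = getattr(loc, "parts", [loc])
    if len(parts) == 2 and int(parts[0].end) == genome_length and int(parts[1].start) == 0:
        # join(x..N,1..y): wrap through the circular origin
        return int(parts[0].start) + 1, int(parts[1].end)
    start, end = int(loc.start) + 1, int(loc.end)
    if end > genome_length:
        raise CoordinateError(
            f"feature at {start}..{end} exceeds sequence length {genome_length}"
        )
    return start, end


def write_genbank(genome: Mitogenome, path: str | Path) -> None:
    """Write a :class:`Mitogenome` as a GenBank flat file."""
    seq = genome.require_sequence()
    n = len(seq)
    record = SeqRecord(
        Seq(seq),
        id=genome.id,
        name=genome.id.split(".")[0][:16] or "mitogenome",
        description=genome.organism or "mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
            "organism": genome.organism,
        },
    )
    for f in genome.features:
        strand = -1 if f.strand == "L" else 1
        if f.wraps:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, n, strand),
                 SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f.anticodon]
        record.features.append(SeqFeature(loc, type=_TYPE_TO_GB_KEY[f.ftype], qualifiers=quals))
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Mitogenome:
    """Read the first record of a FASTA file as an unannotated genome."""
    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise ParseError(f"{path}: empty FASTA file")
    return Mitogenome(id=record.id, sequence=str(record.seq).upper())


def write_fasta(genome: Mitogenome, path: str | Path, width: int = 70) -> None:
    seq = genome.require_sequence()
    with open(path, "w") as fh:
        header = f">{genome.id}"
        if genome.organism:
            header += f" {genome.organism}"
        fh.write(header + "\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Feature-table TSV


def read_feature_table(
    path: str | Path,
    sequence_path: str | Path | None = None,
    *,
    genome_id: str | None = None,
    circular: bool = True,
    length: int | None = None,
) -> Mitogenome:
    """Read the plain-text feature table dialect.

    Columns: ``name  type  start  end  strand  [anticodon]``, tab
    separated; lines starting with ``#`` are comments.  When no FASTA is
    supplied the record is coordinate-only (its length defaults to the
    largest end coordinate, which for a fully tiled circular annotation
    is the genome length) and sequence-dependent operations refuse to
    run on it.
    """
    features: list[GeneFeature] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ParseError(f"{path}:{lineno}: expected >=5 tab-separated columns")
        name, ftype_s, start_s, end_s, strand = (p.strip() for p in parts[:5])
        anticodon = parts[5].strip() if len(parts) > 5 and parts[5].strip() else None
        try:
            ftype = FeatureType(ftype_s)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: unknown feature type {ftype_s!r}") from exc
        feat = GeneFeature(
            name=name, ftype=ftype, start=int(start_s), end=int(end_s),
            strand=strand, anticodon=anticodon,
        )
        if feat.wraps and not circular:
            raise CoordinateError(
                f"{path}:{lineno}: {name} has start > end on a linear genome"
            )
        features.append(feat)

    sequence = ""
    if sequence_path is not None:
        sequence = read_fasta(sequence_path).sequence
    if length is None and not sequence:
        length = max((max(f.start, f.end) for f in features), default=None)
    return Mitogenome(
        id=genome_id or Path(path).stem,
        sequence=sequence,
        circular=circular,
        length=length,
        features=features,
    )


def write_feature_table(genome: Mitogenome, path: str | Path) -> None:
    lines = [f"# feature table for {genome.id}", "# name\ttype\tstart\tend\tstrand\tanticodon"]
    for f in genome.features:
        lines.append(
            "\t".join(
                [f.name, f.ftype.value, str(f.start), str(f.end), f.strand, f.anticodon or ""]
            ).rstrip("\t")
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Feature sequences


def feature_sequence(genome: Mitogenome, name: str) -> str:
    """5'->3' coding-strand sequence of a named feature.

    H-strand features are reference slices; L-strand features are the
    reverse complement of the slice.  Wrap-around features concatenate
    the end and the start of the circle.
    """
    f = genome.feature(name)
    raw = genome.slice(f.start, f.end)
    return reverse_complement(raw) if f.strand == "L" else raw
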