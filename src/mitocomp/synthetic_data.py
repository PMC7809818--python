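"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates the structure of a loach mitochondrial genome so
every pipeline stage can be exercised without downloading accessions:

* the canonical vertebrate layout (13 PCGs, 22 tRNAs, 2 rRNAs, OL, CR)
  at the reference coordinates of the 16,636 bp template, including its
  gene overlaps and intergenic spacers;
* PCGs that are valid ORFs under the vertebrate mitochondrial code with
  the assigned start codons and stop classes (complete or truncated);
* the conserved junction motifs planted verbatim in the atp8/atp6 and
  nd4l/nd4 overlaps;
* per-region base composition matching configurable targets (defaults:
  the reference genome's published region compositions).

Because overlapping reading frames constrain shared bases, constraints
(start/stop codons projected onto the reference strand plus planted
motifs) are collected first and every sampled codon is drawn from the
sense codons consistent with them.  A single integer seed drives one
deterministic generator stream.

``diverge_gene`` introduces an exact, known number of synonymous and
nonsynonymous substitutions into an ORF (ground truth for dN/dS
recovery); ``generate_panel`` builds a genome panel whose region AT%
spans a gradient with a planted linear skew-content relationship
(ground truth for regression recovery).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import tables
from .codon_usage import GeneticCode, classify_start_stop
from .genome_io import feature_sequence, write_fasta, write_genbank
from .model import (
    FeatureType,
    GeneFeature,
    MitocompError,
    Mitogenome,
    reverse_complement,
)

__all__ = [
    "GenomeSpec",
    "DivergenceSpec",
    "SpecError",
    "generate_mitogenome",
    "diverge_gene",
    "generate_panel",
    "write_genome_bundle",
]

_BASES = "ACGT"
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}

_TRUNCATED_TAILS = {"T--": "T", "TA-": "TA"}


class SpecError(MitocompError):
    """The generator specification is infeasible or inconsistent."""


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic mitogenome.

    Defaults reproduce the reference template: canonical coordinates,
    published per-region composition, annotated start/stop assignments
    and the conserved overlap motifs.
    """

    features: list[GeneFeature] = field(default_factory=tables.canonical_features)
    composition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in tables.DEFAULT_COMPOSITION.items()}
    )
    start_codons: dict[str, str] = field(default_factory=lambda: dict(tables.START_CODONS))
    stop_classes: dict[str, str] = field(default_factory=lambda: dict(tables.STOP_ASSIGNMENTS))
    motifs: dict[tuple[str, str], str] = field(
        default_factory=lambda: dict(tables.JUNCTION_MOTIFS)
    )
    genome_id: str = "synthetic"
    organism: str = "synthetic loach"
    table_id: int = 2
    exact_counts: bool = False
    seed: int = 0

    @property
    def length(self) -> int:
        return max(max(f.start, f.end) for f in self.features)

    def validate(self) -> None:
        for region, comp in self.composition.items():
            total = sum(comp[b] for b in _BASES)
            # targets quoted as rounded percentages may miss 1 by a little
            if abs(total - 1.0) > 0.02:
                raise SpecError(f"composition for {region!r} sums to {total}, not 1")
            if any(comp[b] < 0 for b in _BASES):
                raise SpecError(f"composition for {region!r} has negative fractions")
            self.composition[region] = {b: comp[b] / total for b in _BASES}
        feats = {f.name: f for f in self.features}
        for name, stop in self.stop_classes.items():
            f = feats.get(name)
            if f is None:
                continue
            r = f.length(self.length) % 3
            want = {0: None, 1: "T--", 2: "TA-"}[r]
            if r == 0 and stop in _TRUNCATED_TAILS:
                raise SpecError(f"{name}: length is a codon multiple but stop class {stop}")
            if r != 0 and stop != want:
                raise SpecError(
                    f"{name}: length mod 3 = {r} requires stop class {want}, got {stop}"
                )
        for (up, down), motif in self.motifs.items():
            if up not in feats or down not in feats:
                raise SpecError(f"motif junction {up}/{down} not in template")
            overlap = feats[up].end - feats[down].start + 1
            if overlap != len(motif):
                raise SpecError(
                    f"{up}/{down}: motif length {len(motif)} != overlap {overlap}"
                )

    def ground_truth(self) -> dict:
        """Everything the generator planted, for sidecar emission."""
        return {
            "genome_id": self.genome_id,
            "seed": self.seed,
            "length": self.length,
            "composition_targets": self.composition,
            "start_codons": self.start_codons,
            "stop_classes": self.stop_classes,
            "motifs": {f"{u}/{d}": m for (u, d), m in self.motifs.items()},
            "features": [
                {"name": f.name, "type": f.ftype.value, "start": f.start,
                 "end": f.end, "strand": f.strand}
                for f in self.features
            ],
        }


@dataclass(frozen=True)
class DivergenceSpec:
    """Planted substitution counts for :func:`diverge_gene`."""

    n_syn: int
    n_nonsyn: int
    seed: int = 0


# ---------------------------------------------------------------------------
# Coordinate helpers


def _coding_to_ref(f: GeneFeature, p: int, genome_length: int) -> int:
    """1-based coding position -> 1-based reference position."""
    if f.strand == "H":
        pos = f.start + p - 1
    else:
        pos = f.end - p + 1
    return ((pos - 1) % genome_length) + 1


def _ref_base_for(f: GeneFeature, coding_base: str) -> str:
    return coding_base if f.strand == "H" else _COMP[coding_base]


# ---------------------------------------------------------------------------
# Genome generation


def _collect_constraints(spec: GenomeSpec) -> dict[int, str]:
    """Fixed reference-strand bases implied by start/stop codons of
    every PCG and by planted junction motifs."""
    n = spec.length
    fixed: dict[int, str] = {}

    def set_base(pos: int, base: str, why: str) -> None:
        if fixed.get(pos, base) != base:
            raise SpecError(
                f"conflicting constraints at position {pos}: "
                f"{fixed[pos]} vs {base} ({why})"
            )
        fixed[pos] = base

    feats = {f.name: f for f in spec.features}
    for f in spec.features:
        if f.ftype is not FeatureType.PCG:
            continue
        start_codon = spec.start_codons.get(f.name, "ATG")
        stop = spec.stop_classes.get(f.name)
        if stop is None:
            raise SpecError(f"{f.name}: no stop class assigned")
        length = f.length(n)
        for i, base in enumerate(start_codon, start=1):
            set_base(_coding_to_ref(f, i, n), _ref_base_for(f, base), f"{f.name} start")
        tail = _TRUNCATED_TAILS.get(stop, stop)
        for i, base in enumerate(tail, start=length - len(tail) + 1):
            set_base(_coding_to_ref(f, i, n), _ref_base_for(f, base), f"{f.name} stop")
    for (up, down), motif in spec.motifs.items():
        u, d = feats[up], feats[down]
        for i, base in enumerate(motif):
            pos = ((d.start + i - 1) % n) + 1
            set_base(pos, base, f"{up}/{down} motif")
    return fixed


def _sample_codon(rng: np.random.Generator, code: GeneticCode,
                  fixed: dict[int, str], weights: list[dict[str, float]],
                  gene: str) -> str:
    """Draw a sense codon consistent with fixed bases, weighted by the
    position-specific per-base composition targets."""
    candidates = [
        c for c in code.sense_codons
        if all(c[i] == b for i, b in fixed.items())
    ]
    if not candidates:
        raise SpecError(f"{gene}: no sense codon matches fixed bases {fixed}")
    w = np.array([np.prod([weights[i][b] for i, b in enumerate(c)]) for c in candidates])
    total = w.sum()
    if total <= 0:
        w = np.ones(len(candidates))
        total = w.sum()
    return candidates[rng.choice(len(candidates), p=w / total)]


def _exact_count_bases(rng: np.random.Generator, n: int,
                       comp: dict[str, float]) -> list[str]:
    """A shuffled multiset of n bases with counts as close to the target
    fractions as integers allow (largest-remainder rounding)."""
    raw = {b: comp[b] * n for b in _BASES}
    counts = {b: int(raw[b]) for b in _BASES}
    short = n - sum(counts.values())
    for b in sorted(_BASES, key=lambda b: raw[b] - counts[b], reverse=True)[:short]:
        counts[b] += 1
    pool = [b for b in _BASES for _ in range(counts[b])]
    rng.shuffle(pool)
    return pool


_REGION_OF_TYPE = {
    FeatureType.PCG: "PCG",
    FeatureType.TRNA: "tRNA",
    FeatureType.RRNA: "rRNA",
    FeatureType.OL: "OL",
    FeatureType.CR: "CR",
}


def generate_mitogenome(spec: GenomeSpec) -> Mitogenome:
    """Generate one annotated genome matching the spec exactly.

    The result is deterministic given ``spec.seed``; every PCG is a
    valid ORF with the assigned start/stop class and every planted
    motif is present verbatim (verified before returning).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    code = GeneticCode(table_id=spec.table_id)
    n = spec.length
    constraints = _collect_constraints(spec)
    seq: list[str | None] = [None] * n
    locked = [False] * n
    for pos, base in constraints.items():
        seq[pos - 1] = base
        locked[pos - 1] = True

    feats = sorted(spec.features, key=lambda f: f.start)
    for f in feats:
        region = _REGION_OF_TYPE[f.ftype]
        comp = spec.composition.get(region, spec.composition["all"])
        if f.ftype is FeatureType.PCG:
            pos_comp = [spec.composition.get(f"PCG_pos{i}", comp) for i in (1, 2, 3)]
            _write_pcg(spec, f, rng, code, pos_comp, seq, locked, n)
        else:
            _write_plain(spec, f, rng, comp, seq, locked, n)

    # intergenic gaps
    gap_comp = spec.composition.get("spacer", spec.composition["all"])
    gaps = [i for i in range(n) if seq[i] is None]
    if gaps:
        if spec.exact_counts:
            pool = _exact_count_bases(rng, len(gaps), gap_comp)
            for i, b in zip(gaps, pool):
                seq[i] = b
        else:
            draws = rng.choice(list(_BASES), size=len(gaps),
                               p=[gap_comp[b] for b in _BASES])
            for i, b in zip(gaps, draws):
                seq[i] = b

    genome = Mitogenome(
        id=spec.genome_id,
        sequence="".join(seq),  # type: ignore[arg-type]
        organism=spec.organism,
        circular=True,
        features=list(spec.features),
    )
    _verify(genome, spec, code)
    return genome


def _write_pcg(spec, f, rng, code, pos_comp, seq, locked, n) -> None:
    length = f.length(n)
    n_codons, r = divmod(length, 3)
    coding: list[str] = []
    start_codon = spec.start_codons.get(f.name, "ATG")
    stop = spec.stop_classes[f.name]
    # bulk-draw codons for the common unconstrained case; constrained
    # codons fall back to the filtered sampler
    w = np.array([np.prod([pos_comp[i][b] for i, b in enumerate(c)])
                  for c in code.sense_codons])
    bulk = rng.choice(len(code.sense_codons), size=n_codons, p=w / w.sum())
    for k in range(n_codons):
        fixed: dict[int, str] = {}
        for i in range(3):
            p = 3 * k + i + 1
            ref = _coding_to_ref(f, p, n)
            if locked[ref - 1]:
                fixed[i] = seq[ref - 1] if f.strand == "H" else _COMP[seq[ref - 1]]
        if k == 0:
            codon = start_codon
            if any(codon[i] != b for i, b in fixed.items()):
                raise SpecError(f"{f.name}: start codon conflicts with constraints")
        elif k == n_codons - 1 and r == 0:
            codon = stop
            if any(codon[i] != b for i, b in fixed.items()):
                raise SpecError(f"{f.name}: stop codon conflicts with constraints")
        elif not fixed:
            codon = code.sense_codons[bulk[k]]
        else:
            codon = _sample_codon(rng, code, fixed, pos_comp, f.name)
        coding.extend(codon)
    coding.extend(_TRUNCATED_TAILS.get(stop, "")[: r] if r else "")
    if len(coding) != length:
        raise SpecError(f"{f.name}: assembled {len(coding)} of {length} bases")
    for p, base in enumerate(coding, start=1):
        ref = _coding_to_ref(f, p, n)
        seq[ref - 1] = _ref_base_for(f, base)
        locked[ref - 1] = True


def _write_plain(spec, f, rng, comp, seq, locked, n) -> None:
    # composition targets apply in coding sense; L-strand features are
    # sampled in sense and complemented into the reference
    positions = [((f.start + i - 1) % n) for i in range(f.length(n))]
    free = [i for i in positions if not locked[i]]
    if spec.exact_counts:
        pool = _exact_count_bases(rng, len(free), comp)
    else:
        pool = rng.choice(list(_BASES), size=len(free), p=[comp[b] for b in _BASES])
    for i, b in zip(free, pool):
        seq[i] = b if f.strand == "H" else _COMP[b]


def _verify(genome: Mitogenome, spec: GenomeSpec, code: GeneticCode) -> None:
    from .annotation_metrics import junction_window

    for f in genome.features_of_type(FeatureType.PCG):
        cds = feature_sequence(genome, f.name)
        call = classify_start_stop(cds, f.name, code=code)
        if call.start_codon != spec.start_codons.get(f.name, "ATG"):
            raise SpecError(f"{f.name}: start codon {call.start_codon} != assigned")
        if call.stop_class != spec.stop_classes[f.name]:
            raise SpecError(f"{f.name}: stop class {call.stop_class} != assigned")
        n_complete = len(cds) // 3
        stop_is_complete = len(cds) % 3 == 0
        for k in range(1, n_complete):
            codon = cds[3 * k : 3 * k + 3]
            if code.is_stop(codon) and not (stop_is_complete and k == n_complete - 1):
                raise SpecError(f"{f.name}: internal stop {codon} at codon {k + 1}")
    for (up, down), motif in spec.motifs.items():
        window = junction_window(genome, up, down, flank=0)
        if window != motif:
            raise SpecError(f"{up}/{down}: planted motif not recovered ({window!r})")


# ---------------------------------------------------------------------------
# Divergence


def _codon_mutants(codon: str, code: GeneticCode) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous) single-base sense mutants."""
    syn, nonsyn = [], []
    aa = code.translate(codon)
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(mut):
                continue
            (syn if code.translate(mut) == aa else nonsyn).append(mut)
    return syn, nonsyn


def diverge_gene(coding_seq: str, spec: DivergenceSpec, *,
                 table_id: int = 2) -> str:
    """Apply exactly ``n_syn`` synonymous and ``n_nonsyn`` nonsynonymous
    single-base substitutions to an ORF, at most one per codon, never
    creating a stop codon.  Deterministic given ``spec.seed``."""
    code = GeneticCode(table_id=table_id)
    rng = np.random.default_rng(spec.seed)
    r = len(coding_seq) % 3
    body_len = len(coding_seq) - (3 if r == 0 else r)  # exclude terminal stop
    codons = [coding_seq[i : i + 3] for i in range(0, body_len, 3)]
    order = rng.permutation(len(codons))
    chosen: dict[int, str] = {}
    need = [("syn", spec.n_syn), ("nonsyn", spec.n_nonsyn)]
    for kind, n_needed in need:
        placed = 0
        for idx in order:
            if placed == n_needed:
                break
            if idx == 0:
                continue  # keep the annotated start codon intact
            if idx in chosen or "N" in codons[idx] or code.is_stop(codons[idx]):
                continue
            syn, nonsyn = _codon_mutants(codons[idx], code)
            options = syn if kind == "syn" else nonsyn
            if not options:
                continue
            chosen[idx] = options[rng.integers(len(options))]
            placed += 1
        if placed < n_needed:
            raise SpecError(
                f"not enough eligible codons for {n_needed} {kind} substitutions"
            )
    out = [chosen.get(i, c) for i, c in enumerate(codons)]
    return "".join(out) + coding_seq[body_len:]


# ---------------------------------------------------------------------------
# Panels


def generate_panel(
    n: int,
    spec: GenomeSpec | None = None,
    gradient: tuple[float, float] = (56.0, 62.0),
    seed: int = 0,
    *,
    slope: float = -0.0166,
    intercept: float = 0.9047,
    noise: float = 0.0,
) -> tuple[list[Mitogenome], dict]:
    """Generate a genome panel with a planted skew-content relationship.

    Region AT% targets span ``gradient`` linearly over the panel and
    each genome's AT-skew target is ``intercept + slope * AT% +
    N(0, noise)``.  Per-genome targets are applied uniformly to every
    region; with the default ``exact_counts`` mode, unconstrained
    regions (CR, rRNA, tRNA, spacers) realise them to integer rounding.

    Returns the genomes and a ground-truth dict (per-genome targets and
    the planted line).
    """
    if n < 2:
        raise SpecError("panel needs n >= 2 genomes")
    base = spec or GenomeSpec()
    rng = np.random.default_rng(seed)
    xs = np.linspace(gradient[0], gradient[1], n)
    genomes: list[Mitogenome] = []
    truth_rows = []
    for i, x in enumerate(xs):
        y = intercept + slope * x + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        if not -1.0 < y < 1.0:
            raise SpecError(f"planted AT-skew {y:.3f} outside (-1, 1)")
        comp = {}
        for region, c in base.composition.items():
            gc_frac = 1.0 - x / 100.0
            _, gc_skew_r = _comp_skews(c)
            comp[region] = _comp_from_targets(x / 100.0, y, gc_frac, gc_skew_r)
        child = dataclasses.replace(
            base,
            composition=comp,
            genome_id=f"{base.genome_id}-{i+1:03d}",
            exact_counts=True,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        genomes.append(generate_mitogenome(child))
        truth_rows.append({"genome_id": child.genome_id, "at_pct": float(x),
                           "at_skew": float(y), "seed": child.seed})
    truth = {"slope": slope, "intercept": intercept, "noise": noise,
             "gradient": list(gradient), "seed": seed, "genomes": truth_rows}
    return genomes, truth


def _comp_skews(comp: dict[str, float]) -> tuple[float, float]:
    at = comp["A"] + comp["T"]
    gc = comp["G"] + comp["C"]
    return (
        (comp["A"] - comp["T"]) / at if at else 0.0,
        (comp["G"] - comp["C"]) / gc if gc else 0.0,
    )


def _comp_from_targets(at_frac: float, at_skew: float,
                       gc_frac: float, gc_skew: float) -> dict[str, float]:
    return {
        "A": at_frac * (1 + at_skew) / 2,
        "T": at_frac * (1 - at_skew) / 2,
        "G": gc_frac * (1 + gc_skew) / 2,
        "C": gc_frac * (1 - gc_skew) / 2,
    }


# ---------------------------------------------------------------------------
# Output bundle


def write_genome_bundle(genome: Mitogenome, spec: GenomeSpec, outdir: str | Path) -> None:
    """Write GenBank + FASTA + feature table + ground-truth sidecar."""
    from .genome_io import write_feature_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genbank(genome, outdir / f"{genome.id}.gb")
    write_fasta(genome, outdir / f"{genome.id}.fasta")
    write_feature_table(genome, outdir / f"{genome.id}.features.tsv")
    (outdir / f"{genome.id}.truth.json").write_text(
        json.dumps(spec.ground_truth(), indent=2) + "\n"
    )
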