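"""Nei-Gojobori (1986) dN/dS and pairwise p-distances.

The NG86 counting method estimates selective pressure on a pair of
codon-aligned sequences from first principles:

* Each codon position contributes a *fractional synonymous site*: the
  share of its three single-nucleotide mutants (stops excluded) that
  preserve the encoded amino acid.  The three fractions sum with their
  complements to exactly 3 sites per codon.
* Observed differences between a codon pair differing at k positions
  are averaged over all k! mutational pathways (orderings of the single
  base changes), excluding pathways that pass through a stop codon;
  each step is scored synonymous or nonsynonymous by translation.
* Proportions ps = Sd/S and pn = Nd/N are Jukes-Cantor corrected,
  d = -3/4 ln(1 - 4p/3), and omega = dN/dS.

omega < 1 indicates purifying selection; mitochondrial PCGs typically
show omega well below 0.5, lowest in the cox family.

``p_distance_matrix`` gives the companion identity statistic used for
whole-genome similarity: the proportion of differing sites among
comparable (non-gap, non-N) columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from .codon_usage import GeneticCode
from .model import MitocompError

__all__ = [
    "PairwiseRates",
    "OmegaSummary",
    "DistanceMatrix",
    "ng86_site_counts",
    "ng86_pair",
    "gene_omega",
    "p_distance_matrix",
    "jukes_cantor",
]

_BASES = "ACGT"


def jukes_cantor(p: float) -> float | None:
    """Jukes-Cantor multiple-hit correction; None when p >= 3/4."""
    if p >= 0.75:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@lru_cache(maxsize=8)
def _code(table_id: int) -> GeneticCode:
    return GeneticCode(table_id=table_id)


@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, table_id: int) -> tuple[float, float]:
    code = _code(table_id)
    if code.is_stop(codon):
        raise MitocompError(f"{codon} is a stop codon; sites are undefined")
    aa = code.translate(codon)
    s = 0.0
    for pos in range(3):
        sense = syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(mut):
                continue  # mutations to stops excluded at this position
            sense += 1
            if code.translate(mut) == aa:
                syn += 1
        if sense:
            s += syn / sense
    return s, 3.0 - s


def ng86_site_counts(codon: str, *, code: GeneticCode | None = None) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) of one sense codon.

    Always sums to exactly 3; a stop codon is a domain error.
    """
    table_id = (code or _code(2)).table_id
    return _site_counts_cached(codon.upper(), table_id)


def _pathway_counts(c1: str, c2: str, code: GeneticCode) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between
    two sense codons."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        sd = nd = 0
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and nxt != c2 and not allow_stops:
                return None
            if not code.is_stop(cur) and not code.is_stop(nxt) and \
                    code.translate(cur) == code.translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    results = [r for order in permutations(diff) if (r := walk(order, False)) is not None]
    if not results:
        # every ordering passes through a stop: fall back to scoring all
        # orderings, stop-crossing steps counted nonsynonymous
        results = [walk(order, True) for order in permutations(diff)]
    sd = sum(r[0] for r in results) / len(results)
    nd = sum(r[1] for r in results) / len(results)
    return sd, nd


@dataclass(frozen=True)
class PairwiseRates:
    """NG86 site/difference counts and rates for one sequence pair."""

    s_sites: float
    n_sites: float
    sd: float
    nd: float
    n_codons: int
    ps: float | None
    pn: float | None
    ds: float | None
    dn: float | None
    omega: float | None


def ng86_pair(seq1: str, seq2: str, *, code: GeneticCode | None = None) -> PairwiseRates:
    """NG86 estimates for one pair of codon-aligned sequences.

    Sequences must have equal length, a multiple of 3.  Codon pairs
    containing a gap, an N, or a stop codon are skipped (complete-codon
    pairwise deletion).
    """
    code = code or _code(2)
    if len(seq1) != len(seq2):
        raise MitocompError(f"alignment length mismatch: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3:
        raise MitocompError("aligned length must be a multiple of 3")
    seq1, seq2 = seq1.upper(), seq2.upper()

    s1 = s2 = sd = nd = 0.0
    n_codons = 0
    for i in range(0, len(seq1), 3):
        c1, c2 = seq1[i : i + 3], seq2[i : i + 3]
        if set(c1 + c2) - set(_BASES):
            continue  # gap or ambiguity in either codon
        if code.is_stop(c1) or code.is_stop(c2):
            continue
        n_codons += 1
        a1, _ = ng86_site_counts(c1, code=code)
        a2, _ = ng86_site_counts(c2, code=code)
        s1 += a1
        s2 += a2
        d_s, d_n = _pathway_counts(c1, c2, code)
        sd += d_s
        nd += d_n

    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else None
    pn = nd / n_sites if n_sites > 0 else None
    ds = jukes_cantor(ps) if ps is not None else None
    dn = jukes_cantor(pn) if pn is not None else None
    omega = dn / ds if ds is not None and dn is not None and ds > 0 else None
    return PairwiseRates(s_sites, n_sites, sd, nd, n_codons, ps, pn, ds, dn, omega)


@dataclass(frozen=True)
class OmegaSummary:
    """Per-gene omega over an alignment of >= 2 sequences."""

    omega_pooled: float | None
    omega_mean: float | None
    n_pairs: int
    n_defined: int


def gene_omega(alignment: list[str], *, code: GeneticCode | None = None) -> OmegaSummary:
    """omega for a multiple codon alignment.

    Reports the mean of defined pairwise omegas and the pooled estimate
    from summed site and difference counts over all pairs (the stabler
    headline number).
    """
    code = code or _code(2)
    if len(alignment) < 2:
        raise MitocompError("gene_omega needs at least 2 sequences")
    pair_rates = [
        ng86_pair(alignment[i], alignment[j], code=code)
        for i in range(len(alignment))
        for j in range(i + 1, len(alignment))
    ]
    defined = [r.omega for r in pair_rates if r.omega is not None]
    s = sum(r.s_sites for r in pair_rates)
    n = sum(r.n_sites for r in pair_rates)
    sd = sum(r.sd for r in pair_rates)
    nd = sum(r.nd for r in pair_rates)
    pooled = None
    if s > 0 and n > 0:
        ds = jukes_cantor(sd / s)
        dn = jukes_cantor(nd / n)
        if ds is not None and dn is not None and ds > 0:
            pooled = dn / ds
    mean = sum(defined) / len(defined) if defined else None
    return OmegaSummary(pooled, mean, len(pair_rates), len(defined))


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric p-distance matrix with sequence labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def similarity(self) -> np.ndarray:
        """Percent identity, 100 * (1 - p)."""
        return 100.0 * (1.0 - self.values)


def p_distance_matrix(sequences: list[str],
                      labels: list[str] | None = None) -> DistanceMatrix:
    """Pairwise p-distances over equal-length aligned sequences.

    p = differing sites / sites where both sequences have an unambiguous
    base; an entry with zero comparable sites is NaN.
    """
    if not sequences:
        raise MitocompError("no sequences given")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise MitocompError(f"aligned sequences differ in length: {sorted(lengths)}")
    labels = labels or [f"seq{i+1}" for i in range(len(sequences))]
    arr = np.frombuffer("".join(s.upper() for s in sequences).encode(),
                        dtype="S1").reshape(len(sequences), -1)
    ok = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n = len(sequences)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            m = comparable.sum()
            if m == 0:
                values[i, j] = values[j, i] = np.nan
                continue
            diff = (arr[i] != arr[j]) & comparable
            values[i, j] = values[j, i] = diff.sum() / m
    return DistanceMatrix(tuple(labels), values)
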