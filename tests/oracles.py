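"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: translation goes
through Biopython's Seq.translate, and site/pathway counting is a
direct enumeration written from the definitions.
"""

from __future__ import annotations

from itertools import permutations

from Bio.Seq import Seq

BASES = "ACGT"


def translate(codon: str, table: int = 2) -> str:
    return str(Seq(codon).translate(table=table))


def is_stop(codon: str, table: int = 2) -> bool:
    return translate(codon, table) == "*"


def brute_site_counts(codon: str, table: int = 2) -> tuple[float, float]:
    """Fractional synonymous/nonsynonymous sites by direct enumeration
    of all 9 single-base mutants, stops excluded per position."""
    aa = translate(codon, table)
    s = 0.0
    for pos in range(3):
        mutants = [codon[:pos] + b + codon[pos + 1 :] for b in BASES if b != codon[pos]]
        sense = [m for m in mutants if not is_stop(m, table)]
        if sense:
            s += sum(translate(m, table) == aa for m in sense) / len(sense)
    return s, 3.0 - s


def brute_pathway_counts(c1: str, c2: str, table: int = 2) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences by enumerating every
    ordering of the differing positions; stop-crossing pathways are
    excluded unless all are blocked."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def score(order, allow):
        cur, sd, nd = c1, 0, 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if is_stop(nxt, table) and nxt != c2 and not allow:
                return None
            if not is_stop(cur, table) and not is_stop(nxt, table) and \
                    translate(cur, table) == translate(nxt, table):
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    scored = [s for p in permutations(diff) if (s := score(p, False)) is not None]
    if not scored:
        scored = [score(p, True) for p in permutations(diff)]
    return (sum(s for s, _ in scored) / len(scored),
            sum(n for _, n in scored) / len(scored))
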