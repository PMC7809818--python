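#!/usr/bin/env python
"""Start/stop codon usage and RSCU of the reference-like genome.

Writes the per-gene start/stop table and the 64-row codon table
(count, CDpT, RSCU) to results/codon/.
"""

import csv
from pathlib import Path

from mitocomp import FeatureType, classify_start_stop, codon_counts, \
    feature_sequence, read_genbank, rscu
from mitocomp.codon_usage import GeneticCode

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "codon"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = read_genbank(ROOT / "simulated" / "reference-synthetic.gb")
    code = GeneticCode()
    genes = {f.name: feature_sequence(genome, f.name)
             for f in genome.features_of_type(FeatureType.PCG)}

    calls = [classify_start_stop(seq, name, code=code) for name, seq in genes.items()]
    with open(OUT / "start_stop.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene", "start_codon", "stop_class"])
        for c in calls:
            w.writerow([c.gene, c.start_codon, c.stop_class])
    truncated = [c.gene for c in calls if c.stop_class in ("TA-", "T--")]
    print(f"start codons: {sorted({c.start_codon for c in calls})}; "
          f"{len(truncated)} genes with truncated stops: {', '.join(truncated)}")

    usage = codon_counts(list(genes.values()), code=code)
    vals = rscu(usage)
    cdpt = usage.cdpt
    with open(OUT / "codon_usage.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["codon", "family", "count", "cdpt", "rscu"])
        for c in sorted(cdpt):
            w.writerow([c, code.family_map.get(c, "*"), usage.counts.get(c, 0),
                        round(cdpt[c], 2),
                        "" if vals.get(c) is None else round(vals[c], 3)])
    top = sorted(usage.counts.items(), key=lambda kv: -kv[1])[:3]
    print(f"{usage.n_codons} codons counted; most frequent: "
          + ", ".join(f"{c} ({n})" for c, n in top))


if __name__ == "__main__":
    main()
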