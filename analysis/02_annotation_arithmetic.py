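#!/usr/bin/env python
"""Annotation arithmetic of the reference layout: feature lengths, the
signed spacer/overlap column, tiling identity and gene-order check.

Needs only coordinates (no sequence).  Writes results/annotation/.
"""

import csv
from pathlib import Path

from mitocomp import FeatureType, Mitogenome, spacer_table, tables, \
    tiling_check, validate_gene_order

OUT = Path(__file__).resolve().parent.parent / "results" / "annotation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = Mitogenome(id="reference", length=16_636, circular=True,
                        features=tables.canonical_features())
    n = len(genome)

    with open(OUT / "features.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["feature", "type", "start", "end", "strand", "length"])
        for f in genome.features:
            w.writerow([f.name, f.ftype.value, f.start, f.end, f.strand, f.length(n)])

    junctions = spacer_table(genome)
    with open(OUT / "spacers.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["upstream", "downstream", "spacer"])
        for r in junctions:
            w.writerow([r.upstream, r.downstream, r.spacer])

    overlaps = [r for r in junctions if r.spacer < 0]
    igs = [r for r in junctions if r.spacer > 0]
    pcg = [f.length(n) for f in genome.features_of_type(FeatureType.PCG)]
    tiled, total = tiling_check(genome)
    order = validate_gene_order(genome, tables.canonical_order())

    print(f"genome length {total} bp; tiling sum {tiled} (identity holds: {tiled == total})")
    print(f"13 PCGs total {sum(pcg)} bp (min {min(pcg)}, max {max(pcg)})")
    print(f"{len(overlaps)} overlaps, longest: "
          + ", ".join(f"{r.upstream}/{r.downstream} ({-r.spacer} bp)"
                      for r in sorted(overlaps, key=lambda r: r.spacer)[:2]))
    print(f"{len(igs)} intergenic spacers, longest: "
          + ", ".join(f"{r.upstream}/{r.downstream} ({r.spacer} bp)"
                      for r in sorted(igs, key=lambda r: -r.spacer)[:2]))
    print(f"gene order matches canonical vertebrate template: {order.matches_template}")


if __name__ == "__main__":
    main()
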