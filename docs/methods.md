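# Methods

## Data model and coordinates

A `Mitogenome` holds the heavy-strand (H) sequence 5'→3', a circular
topology flag, and start-sorted `GeneFeature`s with unique names. All
file formats and all reported coordinates are 1-based inclusive, the
GenBank convention. On a circular genome a feature with `start > end`
wraps through the origin; wrap-aware length and slicing are applied
before any arithmetic. Light-strand (L) features are read as the
reverse complement of the reference slice. `N` is the only ambiguity
code accepted; it is excluded from the numerator and denominator of
every percentage, so composition statistics are reproducible across
submissions of varying quality. Other IUPAC codes are rejected at parse
time.

The package ships one reference layout: the canonical vertebrate gene
order on a 16,636 bp circle (13 PCGs, 22 tRNAs, 2 rRNAs, OL, CR),
including its two long PCG overlaps (atp8/atp6, 10 bp; nd4l/nd4, 7 bp),
the small tRNA overlaps (trnI/trnQ, trnT/trnP, −2 bp each), and the
long tRNA-Asp/cox2 spacer (13 bp). Two discrepancies in the source
annotation's prose are resolved in favour of coordinate arithmetic:
the concatenated PCG length is 11,472 bp (not 11,427), OL is 30 bp by
its printed coordinates (the text says 31), and the longest PCG is nd5
at 1,839 bp.

## Annotation arithmetic

Adjacency is defined on start-sorted order along the H-strand circle
regardless of feature strand, which reproduces published interleaved
spacer columns including negative tRNA overlaps. The signed spacer is
`start(downstream) − end(upstream) − 1`, with the last→first junction
closed circularly; on a fully tiled circle Σ lengths + Σ spacers equals
the genome length exactly (checked by `tiling_check`). Nested features
are rejected: spacer semantics are undefined for them and they do not
occur in vertebrate mitogenomes. Gene-order validation compares cyclic
successor maps over the shared symbol set, so it is rotation-invariant
and reports exactly the violated adjacencies.

`junction_window` returns the H-strand window whose core is the overlap
(negative spacer) or the intergenic bases (positive spacer), plus a
configurable flank on each side — for a pure overlap at flank 0 this is
exactly the shared bases, satisfying
`len = max(0, −spacer) + 2·flank` for spacer ≤ 0.

## Composition and skews

Skews are `(A% − T%)/(A% + T%)` and `(G% − C%)/(G% + C%)`; a zero
denominator yields a missing value, never 0. Region material: `all` is
the whole H strand; `PCG`/`tRNA`/`rRNA` concatenate coding-strand
feature sequences in annotation order (a `strand_mode="reference"`
switch keeps raw H-strand slices — the coding-strand default is what
makes the T-bias of PCGs and the sign structure of the codon-position
skews visible); `CR` is the control-region slice. Overlapping bases
count once per feature, so the PCG region size equals the sum of gene
lengths (11,472 bp here).

Codon-position splits (`PCG_pos1/2/3`) drop each gene's terminal stop
codon — complete (3 bases) or truncated (the 1–2 base remainder) —
before combing every 1st/2nd/3rd base. This makes the three positions
equal-sized (3,814 bp per position for the reference layout: 3,822
complete codons minus 8 complete stops) and matches how published
per-position tables are computed. Reports round percentages to 1
decimal and skews to 3; full precision is kept internally.

## Codon usage

The genetic code defaults to NCBI translation table 2 (vertebrate
mitochondrial: AGA/AGG stops, ATA → Met, TGA → Trp), configurable by
table id via Biopython's code tables. Stop classes form a closed
vocabulary {TAA, TAG, AGA, AGG, TA-, T--}: a gene of length ≡ 1 (mod 3)
must end in T (class `T--`), ≡ 2 (mod 3) in TA (`TA-`); otherwise the
final codon must be a stop. A non-stop final codon is reported with a
warning rather than an error, since it indicates an annotation problem
the user should see, not a crash. Start codons are taken as annotated
(first trinucleotide), never re-scanned.

Codon counts exclude every gene's terminal stop codon; CDpT is
`1000·count/n_codons` (so Σ CDpT = 1000), and
`RSCU(c) = count(c)·|family(c)| / Σ_family counts` with stop codons in
no family and zero-usage families reported missing. The default family
convention keeps the two leucine (UUR/CUN) and serine (UCN/AGY) codon
blocks as separate families — the convention used in comparative
mitogenomics plots — with a `merged` switch for classic six-fold
families. Whether CDpT should exclude stop codons is not standardised;
this implementation excludes them, consistently with the RSCU universe.

## NG86 selection statistics

`ng86_site_counts` gives each codon position a fractional synonymous
site: among its three single-base mutants, stops are excluded from both
numerator and denominator, and the synonymous fraction of the remaining
sense mutants is counted; s + n = 3 exactly per codon. Pairwise
differences average over all k! mutational pathways between codons
differing at k positions, excluding pathways through stop codons; in
the rare case every ordering is blocked, all orderings are scored with
stop-crossing steps counted nonsynonymous (the pair is not silently
dropped). Sites are averaged between the two sequences; `ps = Sd/S`,
`pn = Nd/N`, Jukes–Cantor corrected `d = −¾·ln(1 − 4p/3)` (missing when
p ≥ 3/4), ω = dN/dS defined only when dS > 0. Codon pairs containing a
gap, N, or stop are deleted pairwise (complete-codon deletion), which
maximises data use. For multiple alignments both the mean of defined
pairwise ω and the pooled estimate from summed counts are reported;
pooled is the headline because it is stable when individual pairs have
few synonymous differences. NG86 with JC correction was chosen as the
simplest standard estimator reproducible from first principles, with no
codon-frequency nuisance parameters; it is conservative relative to ML
codon models at high divergence.

p-distance is the fraction of differing sites among columns where both
sequences have an unambiguous base; similarity = 100·(1 − p).

## Conservation profiles and regressions

Column information content is `2 − H` bits over the observed base
frequencies (gaps excluded), uncorrected by default — logo profiles
here are descriptive; an optional small-sample correction subtracts
`3/(2·ln2·n)`. The consensus reports the modal base where its frequency
reaches the threshold (must exceed 0.5), else N; raising the threshold
can only turn letters into N. Regressions are plain unweighted OLS
(via `scipy.stats.linregress`) of skew on content, matching the
`y = a + bx, R²` form such studies print; the region and axis are
required explicit parameters since published captions often leave them
ambiguous.

## Synthetic genomes

The generator is constraint-first: every PCG's start codon and stop
class, plus the planted junction motifs, are projected onto reference
coordinates before any base is drawn; a conflict is a `SpecError`
rather than a silently broken ORF. PCGs are then built codon-by-codon
from sense codons consistent with the fixed bases, weighted by
position-specific composition targets (defaults: the reference genome's
published codon-position compositions, which reproduces the
characteristic positive/negative/positive per-position AT-skew
pattern); L-strand genes are built in coding sense and complemented
into the reference. Overlapping reading frames resolve automatically
because the downstream gene sees the upstream gene's bases as
constraints — the default overlaps are known-feasible (the motifs embed
the downstream start and the upstream stop). Non-coding features sample
i.i.d. from their region's target composition; with `exact_counts`
(used by panels) they instead receive an exactly rounded base multiset,
so realised composition equals the target up to integer quantisation.
Every generated genome is verified before being returned: ORFs
translate without internal stops, stop classes match the assignment,
motifs are recovered verbatim.

Consequences worth knowing: realised PCG composition tracks but does
not exactly equal its target (sense-codon filtering and overlap
constraints bias the draw), and whole-genome summaries are emergent
mixtures of region realisations rather than planted values, so
whole-genome skews scatter around the neighbourhood of the reference
values rather than reproducing them digit-for-digit. What the generator
does **not** emulate: phylogenetic covariance between panel genomes
(each is drawn independently), indels, tRNA secondary structure, CR
domain architecture, and real codon bias beyond base composition. Tests
that pass on these genomes therefore validate the *arithmetic and
estimators*, not claims about real sequence evolution.

`diverge_gene` plants exactly `n_syn` synonymous and `n_nonsyn`
nonsynonymous single-base substitutions, at most one per codon (so NG86
sees pure single-hit codons), never touching the start codon or
creating a stop. `generate_panel` spreads region AT% linearly across a
gradient (default 56–62%, the spread such panels show) and sets each
genome's AT-skew target to `intercept + slope·AT% + N(0, σ)`; the
default slope −0.0166 is the published panel-wide regression
coefficient, with the intercept's sign taken as positive (+0.9047) —
the printed negative sign would place every skew below −1, outside the
statistic's range. At σ = 0 the slope is recoverable to ~1e-3
(quantisation of integer base counts in the 917 bp CR), not to machine
precision.

## Problem sizes and tolerances

Simulation-based checks use: 5,000-codon genes for ω recovery (planted
ω re-estimated within ±20%; neutral pooled ω within [0.8, 1.25]),
58-genome panels for regressions (slope within 2 SE under noise, 1e-3
absolute at zero noise), and 3.5σ binomial bounds for composition
recovery — sizes chosen so each statistic's sampling error is small
against the effect being checked while the whole suite runs in
seconds. The NG86 implementation is checked exhaustively against an
independent brute-force mutant/pathway enumerator on all 60 sense
codons and all codon pairs differing at ≤ 2 positions.

## Known limitations

* Stop-class assignments are annotation-driven; the package never
  re-annotates or scans for ORFs.
* The NG86/JC estimator saturates (missing dS/dN) when p ≥ 3/4 and, as
  a counting method, underestimates rates at high divergence.
* Gene-order validation compares order only, not strand orientation.
* Reproducing a specific published panel's coefficients requires the
  actual accession sequences; the package reads them from user-supplied
  GenBank files but does not fetch from the network.
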