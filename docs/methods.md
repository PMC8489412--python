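# Methods

This note records the models and procedures implemented in `mitoshift`,
the parameters that matter, and the design choices made where the design
was genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and the genome model

All coordinates are 1-based inclusive (GFF3 convention). A feature with
`start > end` is legal only on a circular sequence and denotes a span
wrapping the origin; its length is `L − start + 1 + end`. Conversion to
0-based half-open happens only inside I/O helpers. Exon order within a
gene is taken from an explicit integer `part=` attribute in the GFF3
dialect, never from genome order, because genome order is meaningless for
trans-spliced genes; the synthetic generator always writes it. `U` is
mapped to `T` on FASTA input so RNA-style files are accepted; residues
outside `{A,C,G,T,N}` are rejected with their position.

## Local alignment engine

A deterministic seed-and-extend aligner stands in for BLASTN everywhere
the pipeline needs local homology (repeats, MTPTs, exon location, intron
synteny). Seeding is by exact 11-mers; seeds on one diagonal are merged
and extended ungapped with an X-drop of 20 under match +1, mismatch −2;
collinear segments separated by short gaps are then joined with gap open
−5 and gap extend −2. No E-value is computed: at these database sizes the
operative filters are alignment span ≥ `min_len` and identity ≥
`min_ident`, plus a noise floor of `(3·min_ident/100 − 2)·min_len` score
units, which is exactly the score of the weakest hit admitted by the
other two filters, so it never removes a hit they would keep. Overlapping
candidates are reduced by greedy score-ordered selection (ties broken by
coordinates, so output is deterministic). Circular sequences are extended
by up to 5 kb past the origin before the search; hits that merely repeat
an earlier hit one full turn later are dropped, and hits spanning the
origin are reported with wrapped intervals.

On substitution-divergence homologies the X-drop extension attains the
full Smith–Waterman optimum over the reported interval pair (verified
against a DP oracle in the test suite); indel-rich homologies beyond the
short-gap joining band may be split into multiple hits, which downstream
consumers (exon chaining, MTPT merging, frame-shift detection) handle.

## Intron classification

Consecutive exon placements (in CDS order) are *contiguous* when they are
on the same strand, colinear in the transcription direction of the
upstream exon, and separated by a gap of 0–`max_intron_len` nt
(default 10,000; plant mitochondrial cis introns are at most a few kb,
while observed trans fragment separations are ≥ 14 kb). A circular wrap
counts as contiguous when the wrapped gap satisfies the length rule.
Anything else is a raw split, called trans. Contiguous introns whose
registry entry is flagged ancestral-trans are still called trans
(`override_applied`); the override only widens the trans set.

Intron names use the upstream exon's final CDS coordinate. Because local
alignment can overrun a splice boundary by a few bases when the intron
happens to begin with bases matching the CDS continuation, a computed
insertion position within 15 nt of a registry entry for the same gene is
snapped to that entry; 15 nt matches the extension tolerance used for
breakpoint mapping, and the registry's closest same-gene entries are 22 nt
apart, so snapping is unambiguous. The shipped registry carries only the
twelve intron names with established published identities (five flagged
ancestral-trans); additional introns are supplied via a TSV and positions
are defined on whatever reference CDS the user provides.

Breakpoint synteny aligns the ancestral (cis) intron of a reference
genome against the neighborhood of the two split exons: a hit containing
the reference's first base (±15 nt) near the upstream exon gives the
retained 5′ length, a hit containing the last base near the downstream
exon gives the retained 3′ length, and the remainder is reported lost.
"Near" means within intron-length + 2 kb of the exon boundary, measured
circularly.

## Repeat-mediated recombination support

For a repeat pair with copies A and B (forward-strand contexts
`A_L·R_A·A_R` and `B_L·R_B·B_R`, flanks 300 nt), the alternative
conformations are `A_L·R·B_R` / `B_L·R·A_R` for direct repeats and
`A_L·R·revcomp(B_L)` / `revcomp(B_R)·R·A_R` for inverted repeats, where R
is copy A's own repeat sequence: when the copies diverge (identity down to
80%), the per-mate mismatch cap absorbs the difference rather than
inventing a consensus. Read placement is exhaustive, ungapped and
end-to-end: both mates full length, ≤ 2 mismatches each, forward–reverse
orientation with ordered intervals; a tie for best total mismatches means
no placement. A pair supports an alternative conformation only if it also
fails on *both* principal references and its fragment span reaches ≥ 5 nt
into each flank of the alternative, which guarantees junction-spanning
evidence; each read id counts at most once per repeat. Only pairs shorter
than the 350 bp insert cap are assessed — a fragment cannot span both
junction flanks of a longer repeat.

Recombination at an inverted repeat inverts the segment between the
copies, an involution returning one circle. At a direct repeat it
necessarily splits the circle into two subcircles (each carrying one
repeat copy and one novel junction); no single-molecule representation
exists, so `make_recombined_genome` returns a list of product molecules.
The read simulator's mixture helper splits the recombined fraction across
products in proportion to length, giving per-base-uniform coverage of the
recombined state.

## MTPT scanning and gene status

Hits of mitogenome vs plastome with length ≥ 101 (">100 bp" read as a
strict inequality) and identity ≥ 80% are merged when they overlap on
mitochondrial coordinates (merge gap 0: adjacent but non-overlapping hits
stay separate regions, matching per-hit reporting); region identity is
the length-weighted mean and the plastid interval is that of the longest
component. Genome coverage is the union of region intervals, so
double-counting is impossible. Gene status is decided in fixed order:
coverage of the gene by the transferred copy < 95% → `pseudo_truncated`
(the 95% threshold operationalizes "substantial truncation" and is
configurable); any alignment-implied net indel ≢ 0 (mod 3) →
`pseudo_frameshift`; an internal stop in the in-frame translation of the
reconstructed copy → `pseudo_internal_stop`; otherwise `intact`. rRNA
genes use the coverage rule only.

## Chimera screen

The conversion statistic is a declared approximation in the GENECONV
family, not a re-derivation of GENECONV's fragment formulas: condense to
gap-free polymorphic columns; per unordered taxon pair score +1 for
agreement and −P for disagreement with
`P = scale · ceil((1 − p̂)/p̂)` (`scale` = 1 by default), p̂ the pair's
disagreement fraction over polymorphic columns (pairs with p̂ = 0 are
skipped); candidate fragments are the maximal non-overlapping
positive-scoring segments (recursive Kadane). Significance: the
polymorphic-column order is permuted (one shared permutation across
pairs per replicate) and the null statistic is the maximum segment score
across all pairs, so fragment p-values
`(1 + #{null ≥ score})/(n_perm + 1)` are family-wise controlled over
taxon pairs; fragments with p < 0.05 are reported in original-alignment
coordinates (masked columns are tracked through a column map). Because
the null maximum is dominated by the least-divergent taxon pairs, the
screen's power is a function of how uniform the pairwise divergences are
— one reason the region-level origin assignment, not the fragment screen
alone, carries the final verdict.

Gene splitting is exact tiling: k breakpoints give k+1 contiguous 1-based
regions. `split_even` divides a region into k spans whose first k−1
lengths equal a comparand length when given (so subregions match the
length of the region they are compared against), else floor(length/k),
remainder on the last span.

Trees are neighbor joining (scikit-bio) on Jukes–Cantor distances
`d = −(3/4)·ln(1 − 4p/3)` with pairwise gap deletion; saturated pairs
(p ≥ 0.75) fall back to the p-distance and are flagged. Negative NJ
branch lengths are clamped to zero. Bootstrap support is the percentage
of column-resampled trees containing each bipartition of the full-data
tree (default 1,000 replicates; deterministic per seed). Origin
assignment roots at the declared outgroup and finds the smallest clade
containing the focal taxon, with at least one other member, whose
support meets the threshold (default BS ≥ 70): all-native membership →
native; membership within one declared foreign lineage → foreign;
anything else, or no supported clade, → unresolved. Walking past
unsupported nodes matters because a focal taxon nested star-like inside
the donor clade often has a weakly supported immediate sister but a
strongly supported enclosing donor clade. Very short regions (tens of nt)
typically yield no supported clade and come out unresolved, which is the
intended behavior for uninformative regions.

## Synthetic data

The generator emulates the feature classes of a rearranged plant
mitogenome on a 60,000 nt circle (background GC 44%, cosmetic): seven
protein-coding genes with random translatable CDSs and eleven introns
whose planted arrangements mirror the observed pattern (two cis
arrangements, one cis arrangement overridden to trans by ancestry, eight
genuine splits including a 14 kb relocation with an 866 nt middle loss
and two inverted splits); six repeat pairs of 60–420 bp (one above the
insert cap, one at 96% identity); ten plastid insertions of 150–2,500 bp
at 0–5% divergence copied from a generated 30 kb toy plastome (insertion
lengths are drawn jointly under a total-space budget so a dense draw
cannot exhaust the genome). nad5 is planted with i1455 only: the 22 nt
exon between i1455 and i1477 is below any reliable alignment length, so
the i1477 name lives in the registry but is not exercised by the default
genome. Features are placed uniformly at random without origin wrap and
with ≥ 120 nt spacing; fragments downstream of a planted split are
constrained to land outside contiguity range (including the wrap-around
gap) so planted trans arrangements cannot be accidentally contiguous.

Reads are error-prone (substitution rate 0.001) 150 nt pairs with insert
sizes drawn from Normal(300, 30) redrawn below a floor of 2×read length;
with the default parameters the floor sits at the mean, so the realized
insert mean is the lower-truncated-normal mean μ + σ·√(2/π) ≈ 324 nt.
Positions are uniform on each circle of a weighted genome mixture.

The clade simulator evolves a 1,506 nt gene down a fixed three-clade
topology (outgroup; native clade containing the focal taxon; foreign
donor clade) by per-branch per-site substitution: stems 2%, tips 4%,
outgroup 10%. The conversion segment (columns 1138–1493 by default,
mirroring a real chimeric atp1's region II) is copied from the donor tip
into the focal taxon and drifted at 2%, so donor–recipient divergence in
the segment is ~2% against a ~8% within-clade background — the
calibration at which the screen is meant to operate, and one that
reproduces the identity contrast seen in real chimeras (focal ~86–88%
identical to native relatives inside the segment but ~89–98% to the donor
clade). No indel process is simulated, so alignments are trivially
correct; real alignments add gap and alignment-error noise that these
tests do not probe.

What passing the closed-loop tests shows — and what it does not: the
pipeline recovers planted features under substitution-only divergence,
uniform coverage, and correct alignments. It does not demonstrate
robustness to assembly errors, coverage bias, indel-rich divergence, or
misalignment, which real data add on top.

## Problem sizes and numerical choices

The acceptance suite uses 100 seeded genomes for intron concordance, 200
null replicates at 1,000 permutations for screen calibration, 50
planted-conversion replicates at 1,000 permutations and 300 bootstrap
replicates, and an 8,000-pair library for the recombination-support
grid; `scripts/acceptance.py` uses 30/120/30 replicates at the same
permutation depths. These sizes give stable rates while keeping runs to
minutes on one CPU. The closed-form recombination expectation integrates
the junction-spanning probability over the discretized truncated-normal
insert distribution and the mixture weights; observed support is checked
within 3 binomial standard deviations. Permutation p-values use the
add-one estimator, so they are never zero; bootstrap and permutation
draws come from `numpy.random.default_rng` seeded explicitly, making
every reported number reproducible.
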