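# Methods

## Coordinate model

All coordinates are 0-based half-open on a circular genome; an interval
with `end <= start` wraps the origin and has length `(end − start) mod n`.
File formats (GFF3, GenBank) are 1-based inclusive and converted at the
boundary. The first base of the input FASTA is offset 0 and every report
uses that frame unless a record is explicitly re-origined. Ambiguity
codes other than N are rejected at parse time: in an assembled organelle
genome they indicate an assembly problem, and silently complementing
them would corrupt repeat and IR detection.

## Inverted-repeat detection and the quadripartite partition

The IR pair is defined as the longest pair of disjoint segments on the
circle such that one is the reverse complement of the other. Detection
seeds on 31-mers shared between the sequence and its reverse complement
(hash index over the doubled sequence so origin-spanning arms are
found), extends each seed greedily to the maximal exact match, and
deduplicates by diagonal. Exact matching (`max_mismatch_rate = 0`) is
the default because assembled plastome IR copies are near-perfect; a
mismatch-budgeted extension is available but reports only the exact
common core trimmed of terminal mismatches.

Classes: `quadripartite` (IR ≥ 2,000 bp), `residual_ir` (detected but
< 2,000 bp — "depleted" IRs), `ir_free` (nothing ≥ `min_ir_len`,
default 100 bp; the whole circle is then reported as LSC by
convention). The longer inter-copy arc is LSC, the shorter SSC; IRb is
the copy whose 3′ junction abuts SSC in the orientation
LSC → IRb → SSC → IRa. Ties between equal-length candidate pairs break
to the smallest IRb start offset. All thresholds are configurable.

A junction sits between bases j−1 and j. A gene *spans* a junction only
if the cut falls strictly inside it; a gene ending exactly at the
junction is the nearest gene at distance 0. Boundary comparison between
two annotated genomes computes the sets of gene names fully inside
either IR copy; genes gained by the target's IR are expansions, genes
lost are contractions, attributed to the LSC-side junction pair (JLB,
JLA) or SSC-side pair (JSB, JSA) according to which single-copy region
holds the gene in the genome where it is single copy. If one junction
side shows both gains and losses, the direction with more genes wins
(both lists are always reported).

## Repeat catalog

The catalog contains all maximal exact repeated substrings of length
≥ 30 bp, on both strands. The engine seeds on exact `min_len`-words
from a hash index and extends maximally; an independent full
diagonal-scanning oracle in the test suite checks exact agreement on
sequences up to 5 kb. Nonredundancy: copies are grouped by canonical
representative (the lexicographically smaller of the repeat and its
reverse complement); a copy wholly contained in a copy of a strictly
longer unit is suppressed, and a unit is dropped only when no copy
survives. Tandem arrays — maximal matches whose period is shorter than
the unit — are excluded; the catalog targets dispersed repeats. The
scan is linear in the input origin frame, so a repeat copy spanning the
origin is outside the contract (the generator never plants one). With
`exclude_ir`, the IRa interval is excised first so the genome-wide IR
does not swamp the dispersed-repeat counts.

Localization is strand-aware: a copy overlapping a gene span is
`internal`; otherwise the nearest gene within the window (default
1,000 bp — "upstream" is not given a length by the underlying protocol,
so it is exposed as a parameter) on the gene's 5′ side makes the copy
`upstream`, on the 3′ side `downstream`; ties break to the smaller
distance, then upstream over downstream, then the lexicographically
smaller gene name. Hotspot percentages count repeat *copies*
(occurrences) in the focal contexts (internal + upstream by default)
over all copies, to 2 decimals.

## Homology search and gene calling

The aligner implements the BLASTn-parameter contract used for plastid
gene verification: reward +2, penalty −3, gap open 5, gap extend 2
(a gap of length g costs 5 + 2g), word size 9, no dust filtering,
E ≤ 1e−5 with Karlin–Altschul `E = K·m·n·exp(−λS)` and the published
constants for the (2, −3) pair, λ = 0.625, K = 0.41. Exact 9-word seeds
on both strands pass an ungapped x-drop extension filter (trigger 22),
and surviving regions are resolved by a full affine-gap Smith–Waterman
(numba kernels) on a window padded by the query length, which
reproduces the unrestricted optimum whenever the true alignment
contains one exact word — guaranteed for the homologies this package
classifies and asserted against an independent dynamic-programming
oracle on the fixture suite. Circular targets are doubled and hits
deduplicated modulo genome length.

Gene status from the best locus' query coverage: ≥ 0.90 intact (for
protein genes, only if the in-frame translation from the hit's query
offset has no internal stop; a stop in the final query codon is the
legitimate terminator), ≥ 0.90 with an internal stop → premature-stop
pseudogene, 0.20–0.90 → truncated pseudogene, < 0.20 → fragment, no
hit → absent. The underlying protocol distinguishes only "partial
sequence" from "remnant fragment", so both cutoffs are parameters and
are echoed in output headers. Copy number counts disjoint hit loci at
≥ 0.20 coverage; when only sub-threshold fragments exist the fragment
loci are counted instead, so a fragment is never reported absent.
RNA-editing rescue of internal stops is not modelled. Intron loss:
each reference exon is aligned independently and an intron is called
lost when consecutive exon hits are separated by < 30 bp on the target.
The five-way status collapses to four matrix symbols: `2` (two intact
copies), `1` (one intact copy), `P` (any pseudogene or fragment), `-`
(absent).

## Synteny blocks and structural types

Genomes are IR-reduced first (both IR copies present would leave no
unique IR k-mers). Anchors are 21-mers occurring exactly once in each
genome (either strand of the second); anchors are chained while
orientation is constant and both coordinates advance monotonically with
gaps ≤ 2,000 bp; chains spanning ≥ 500 bp become blocks. This
deliberately replaces a progressive-alignment LCB finder: at
plastome-scale divergence the single-copy regions are essentially
collinear between breakpoints, and the contract needed downstream is
only block order and orientation. Because pairwise blocks collapse
adjacencies differently per genome, typing re-segments the reference at
the union of all pairwise breakpoints (clustered within 2k bp) and maps
each shared segment into each genome through its covering block; the
resulting signed permutations are directly comparable, and genomes
grouped by identical permutation form types labelled A, B, … in first
occurrence over sorted genome ids. Genomes are linearized at the input
origin; re-origining at a marker gene is left to the caller. The
circular signed breakpoint distance counts adjacencies that do not
follow the identity in either reading direction, so a whole-genome
reversal and a rotation both have distance 0.

## Flip-flop isomers from long reads

Given two disjoint inverted copies of a repeat, isomer 2 is the genome
with the segment between the copies' inner edges reverse-complemented
in place — the copies themselves are regenerated unchanged, the flip is
an involution, and a direct (non-inverted) pair is rejected because its
flip could not regenerate the repeats. Each isomer contributes two
junction windows (flank + repeat + flank, flank default 1,000 bp,
origin wrap allowed, overlapping windows rejected).

A read supports a window only if its best local alignment covers the
window end to end — the full repeat core plus the full flank on both
sides — at ≥ 0.8 identity, on either read strand. Zero end-slack keeps
the geometric rule exact: a read shorter than repeat + 2·flank can
never count. Candidate read/window pairs are prescreened with sampled
15-mers; a candidate must seed in *both* flanks at a consistent
diagonal (the flank unique to the other configuration never seeds,
which rejects wrong-isomer windows cheaply), exact containment is
accepted as the optimal alignment, and only noisy candidates reach the
Smith–Waterman kernel. Each read is assigned to at most one isomer by
best window score; equal best scores on both isomers void the read.
Per-isomer support is the mean count over its two windows (counts are
averaged after isomer assignment; raw per-window counts are reported
alongside), and the inverted-isomer frequency is
`100 · mean2 / (mean1 + mean2)`, null when nothing spans. The paired
short-read check asks, per isomer, whether ≥ 3 pairs straddle a
junction with one mate wholly in each flank in a way unique to that
isomer.

## Synthetic data

The generator emulates the observed study conditions: i.i.d. background
at GC 36.5 % (the observed genomes span 35.8–37.5 %), region lengths
taken from the observed extremes (IR from 0 to 33,169 bp, genomes
110,388–143,493 bp), genes as seeded random ORFs (start codon, sense
codons, stop) auto-placed with 80–250 bp gaps, IR-resident genes
mirrored into IRa automatically, pseudogene lesions (truncation to a
fraction, premature TAA at the middle codon, deletion), dispersed
repeat units planted at chosen single-copy loci, rearrangement scripts
tracked into an expected signed permutation, and a 679 bp inverted pair
bracketing a 60 kb segment for the isomer scenario. Junction-adjacent
bases are pinned after planting so the IR maximal pair ends exactly at
the declared coordinates (otherwise a chance matching base just outside
both copies would silently lengthen the true answer and the manifest
would be wrong). Long reads are drawn with uniform circular starts,
uniform 5–15 kb lengths, optional per-base mismatch/indel rates, and
names encoding template, start, length and strand as the test oracle.

What the generator does **not** emulate: real gene sequences and codon
usage, homopolymer-biased ONT error profiles, compositional
heterogeneity along the genome, tandem/microsatellite repeats, and
mixed populations beyond the two-isomer model. Passing tests therefore
demonstrate correctness of the algorithms under clean, well-posed
structural scenarios — not robustness to every artifact of real
sequencing data.

## Problem sizes and numerical choices

The acceptance checks run at the sizes the analyses target: full-length
genomes (110–143 kb) for IR recovery (100 seeded fixtures), 100
gene-status calls on a ~75 kb genome, 50 single-inversion plants of
1–60 kb in 70–90 kb genomes, 50 repeat fixtures ≤ 5 kb against the
quadratic oracle, 100 alignment pairs ≤ 1 kb against the independent
Smith–Waterman, and a 10,000-read isomer simulation. With ~1.3 k reads
spanning a junction at those settings, the binomial standard error of
the recovered 1 % frequency is ≈ 0.26 percentage points; single-seed
estimates scatter accordingly around the truth.

Determinism: every stochastic step takes an explicit seed
(`numpy.random.default_rng`); identical seeds give byte-identical
fixtures and reports. Thread count never affects results.

## Known limitations

- Origin-spanning dispersed repeats and origin-spanning planted genes
  are outside the generator/catalog contract (the IR detector itself is
  fully circular).
- `structure_class` boundaries (residual < 2 kb) are conventions, not
  biology; borderline IRs should be inspected.
- The aligner's seed-first design can in principle miss an optimal
  alignment with no exact 9-word; irrelevant for the ≥ 80 % identity
  homologies classified here, and excluded on the fixture suite by the
  oracle tests.
- Boundary-shift attribution assumes the two IR copies move together;
  asymmetric single-junction shifts are folded into the same report.
- Structural type labels depend on the chosen reference genome;
  permutations are reported so types can be re-derived against any
  other reference.
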