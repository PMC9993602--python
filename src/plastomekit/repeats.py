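"""Nonredundant non-tandem repeat cataloguing and gene-context hotspots.

Finds all maximal exact repeated substrings above a length cutoff
(default 30 bp), on both strands (direct and inverted copies), reduces
them to nonredundant units, and localizes each copy relative to the gene
annotation (internal / upstream / downstream / other intergenic). The
plastome-wide IR pair can be excluded by analysing the IR-reduced
sequence, mirroring how repeat content is reported for quadripartite
genomes.

Tandem arrays (a maximal self-overlapping match, i.e. period shorter
than the unit) are excluded: the catalog targets dispersed repeats.
Analysis is linear in the input origin frame; repeats spanning the
origin of the circular sequence are not searched for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .model import GenomeInterval, PlastomeRecord, reverse_complement


@dataclass(frozen=True)
class RepeatUnit:
    unit_id: str
    representative: str

    @property
    def length(self) -> int:
        return len(self.representative)


@dataclass(frozen=True)
class RepeatCopy:
    unit_id: str
    interval: GenomeInterval  # strand - means the copy reads as the
    # reverse complement of the unit representative


@dataclass(frozen=True)
class RepeatCatalog:
    units: tuple
    copies: tuple
    genome_length: int

    @property
    def n_units(self) -> int:
        return len(self.units)

    @property
    def n_copies(self) -> int:
        return len(self.copies)


@dataclass(frozen=True)
class RepeatLocalization:
    copy: RepeatCopy
    context: str  # internal | upstream | downstream | intergenic_other
    anchor_gene: str | None
    distance: int


@dataclass(frozen=True)
class HotspotSummary:
    per_gene_counts: dict
    total_copies: int
    per_gene_percent: dict


def maximal_repeat_pairs(seq: str, min_len: int) -> tuple:
    """All maximal exact repeated pairs of length >= min_len.

    Returns (direct, inverted): direct pairs are (p1, p2, L) with
    p1 < p2 and seq[p1:p1+L] == seq[p2:p2+L], excluding tandem
    (self-overlapping) pairs; inverted pairs are (p1, p2, L) with
    seq[p2:p2+L] == rc(seq[p1:p1+L]) and the two intervals distinct.
    """
    n = len(seq)
    k = min_len
    if n < 2 * k:
        return (), ()
    index: dict = {}
    for p in range(n - k + 1):
        index.setdefault(seq[p:p + k], []).append(p)

    def _covered(ranges, pos):
        return any(s <= pos < e for s, e in ranges)

    direct = set()
    covered: dict = {}  # diagonal -> list of already-extended p1 ranges
    for word, positions in index.items():
        if len(positions) < 2:
            continue
        for i in range(len(positions)):
            for j in range(i + 1, len(positions)):
                p1, p2 = positions[i], positions[j]
                d = p2 - p1
                ranges = covered.setdefault(d, [])
                if _covered(ranges, p1):
                    continue
                lo = 0
                while p1 + lo - 1 >= 0 and seq[p1 + lo - 1] == seq[p2 + lo - 1]:
                    lo -= 1
                hi = k
                while p2 + hi < n and seq[p1 + hi] == seq[p2 + hi]:
                    hi += 1
                ranges.append((p1 + lo, p1 + hi))
                length = hi - lo
                a, b = p1 + lo, p2 + lo
                if length >= min_len and b - a >= length:  # non-tandem
                    direct.add((a, b, length))

    rc = reverse_complement(seq)
    inv = set()
    covered = {}
    for q in range(n - k + 1):
        word = rc[q:q + k]
        hits = index.get(word)
        if not hits:
            continue
        for p in hits:
            d = q - p
            ranges = covered.setdefault(d, [])
            if _covered(ranges, q):
                continue
            lo = 0
            while p + lo - 1 >= 0 and q + lo - 1 >= 0 \
                    and seq[p + lo - 1] == rc[q + lo - 1]:
                lo -= 1
            hi = k
            while p + hi < n and q + hi < n and seq[p + hi] == rc[q + hi]:
                hi += 1
            ranges.append((q + lo, q + hi))
            length = hi - lo
            if length < min_len:
                continue
            a = p + lo
            b = n - (q + lo) - length  # partner in forward coordinates
            if a == b:
                continue  # an interval is its own reverse complement
            inv.add((min(a, b), max(a, b), length))
    return tuple(sorted(direct)), tuple(sorted(inv))


def reduce_to_catalog(seq: str, direct, inverted, min_len: int) -> RepeatCatalog:
    """Group maximal pairs into nonredundant units with strand-aware copies.

    Copies are grouped by canonical representative (the lexicographically
    smaller of the repeat sequence and its reverse complement); a copy
    wholly contained in a copy of a strictly longer unit is suppressed.
    """
    n = len(seq)
    groups: dict = {}  # canonical representative -> set of (start, strand)

    def add(rep_key, start, strand, length):
        groups.setdefault(rep_key, set()).add((start, strand))

    for a, b, length in direct:
        s = seq[a:a + length]
        canon = min(s, reverse_complement(s))
        strand = "+" if s == canon else "-"
        add(canon, a, strand, length)
        add(canon, b, strand, length)
    for a, b, length in inverted:
        s = seq[a:a + length]
        canon = min(s, reverse_complement(s))
        add(canon, a, "+" if s == canon else "-", length)
        s2 = seq[b:b + length]
        add(canon, b, "+" if s2 == canon else "-", length)

    ordered = sorted(groups.items(),
                     key=lambda kv: (-len(kv[0]), min(p for p, _ in kv[1])))
    longer_spans: list = []  # (start, end) of copies of longer units
    units = []
    copies = []
    uid = 0
    for rep, locs in ordered:
        length = len(rep)
        kept = []
        for start, strand in sorted(locs):
            end = start + length
            if any(s <= start and end <= e and (e - s) > length
                   for s, e in longer_spans):
                continue
            kept.append((start, strand))
        if not kept:
            continue
        uid += 1
        unit_id = f"R{uid}"
        units.append(RepeatUnit(unit_id, rep))
        for start, strand in kept:
            iv = GenomeInterval(start, start + length, strand,
                                genome_length=n)
            copies.append(RepeatCopy(unit_id, iv))
        longer_spans.extend((s, s + length) for s, _ in kept)
    return RepeatCatalog(tuple(units), tuple(copies), n)


def find_repeats(record: PlastomeRecord, min_len: int = 30,
                 exclude_ir: bool = False, partition=None) -> RepeatCatalog:
    """Nonredundant catalog of repeats >= min_len bp (direct + inverted).

    With ``exclude_ir`` and a quadripartite ``partition``, the second IR
    copy (IRa) is excised first so the genome-wide IR does not swamp the
    dispersed-repeat catalog; coordinates are then in the IR-reduced
    frame starting at the original origin.
    """
    seq = record.sequence.residues
    if exclude_ir and partition is not None \
            and partition.structure_class != "ir_free":
        ira = partition.ira
        if ira.wraps_origin:
            seq = record.sequence.residues[ira.end:ira.start]
        else:
            seq = seq[:ira.start] + seq[ira.end:]
    if len(seq) < 2 * min_len:
        return RepeatCatalog((), (), len(seq))
    direct, inverted = maximal_repeat_pairs(seq, min_len)
    return reduce_to_catalog(seq, direct, inverted, min_len)


def localize_repeats(catalog: RepeatCatalog, features,
                     upstream_window: int = 1000) -> list:
    """Assign each repeat copy a gene context.

    Overlap with a gene span -> internal (distance 0); otherwise the
    nearest gene within the window on the copy's 5' side of that gene ->
    upstream (strand-aware), 3' side -> downstream; else
    intergenic_other. Ties break to the smaller distance, then upstream
    over downstream, then the lexicographically smaller gene name.
    """
    n = catalog.genome_length
    out = []
    for copy in catalog.copies:
        iv = copy.interval
        best = None  # (distance, pref, name, context)
        for f in features:
            span = f.span
            if span.genome_length != n:
                continue
            if span.overlaps(iv):
                cand = (0, -1, f.name, "internal")
            else:
                if f.strand == "+":
                    d_up = (span.start - iv.end) % n
                    d_down = (iv.start - span.end) % n
                else:
                    d_up = (iv.start - span.end) % n
                    d_down = (span.start - iv.end) % n
                cand = None
                if d_up <= upstream_window:
                    cand = (d_up, 0, f.name, "upstream")
                if d_down <= upstream_window and (cand is None
                                                  or d_down < cand[0]):
                    cand = (d_down, 1, f.name, "downstream")
            if cand is not None and (best is None or cand < best):
                best = cand
        if best is None:
            out.append(RepeatLocalization(copy, "intergenic_other", None, -1))
        else:
            dist, _, name, ctx = best
            out.append(RepeatLocalization(copy, ctx, name, dist))
    return out


def hotspot_summary(localizations,
                    focal_contexts=("internal", "upstream")) -> HotspotSummary:
    """Per-gene share of repeat copies found in the focal contexts.

    Percentages are of ALL copies (the denominator includes copies in
    non-focal contexts), reported to 2 decimals — so e.g. 1,013 focal
    copies out of 4,931 total gives 20.54%.
    """
    total = len(localizations)
    counts: dict = {}
    for loc in localizations:
        if loc.context in focal_contexts and loc.anchor_gene is not None:
            counts[loc.anchor_gene] = counts.get(loc.anchor_gene, 0) + 1
    if total == 0:
        warnings.warn("no repeat copies: hotspot percentages are all zero")
        return HotspotSummary({}, 0, {g: 0.0 for g in counts})
    pct = {g: round(100.0 * c / total, 2) for g, c in counts.items()}
    return HotspotSummary(counts, total, pct)
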