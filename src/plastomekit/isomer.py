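"""Flip-flop plastome isomers mediated by a short inverted-repeat pair.

Intramolecular recombination between two inverted copies of a repeat
flips the segment between them, producing two coexisting configurations
(isomer 1 = the assembled reference, isomer 2 = the flipped form). Long
reads decide between them: a read supports a configuration only if its
best local alignment spans one repeat copy plus a full flank (default
1,000 bp) on both sides of it — a short read can never testify, because
both configurations contain the same repeat.

Counting: each read is assigned to at most one isomer by best window
score (reads scoring equally on both isomers count for neither). The
per-isomer support is the mean over its two junction windows, and the
inverted-isomer frequency is 100 * mean2 / (mean1 + mean2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .align import ScoringScheme, sw_align
from .model import (GenomeInterval, NucleotideSequence, PlastomeRecord,
                    reverse_complement)


@dataclass(frozen=True)
class IsomerPair:
    isomer1: PlastomeRecord
    isomer2: PlastomeRecord
    repeat1: GenomeInterval  # first copy, genome frame of isomer1
    repeat2: GenomeInterval  # second copy


@dataclass(frozen=True)
class JunctionWindow:
    isomer: int  # 1 or 2
    side: str  # left | right
    sequence: str
    repeat_core: tuple  # (start, end) of the repeat inside the window
    flank: int


@dataclass(frozen=True)
class ReadSupport:
    counts: dict  # (isomer, side) -> spanning-read count
    mean1: float
    mean2: float
    frequency_percent: float | None  # None when nothing spans
    ambiguous: int
    total_reads: int


def build_isomer(record: PlastomeRecord, repeat1: GenomeInterval,
                 repeat2: GenomeInterval) -> IsomerPair:
    """The alternative configuration: inter-repeat segment flipped in place.

    The two repeat copies must be disjoint, non-wrapping, and exact
    reverse complements; the flip runs between their inner edges, so
    both copies are regenerated unchanged in isomer 2 and applying the
    flip twice restores isomer 1.
    """
    if repeat1.start > repeat2.start:
        repeat1, repeat2 = repeat2, repeat1
    if repeat1.wraps_origin or repeat2.wraps_origin:
        raise ValueError("origin-wrapping repeat copies are not supported; "
                         "rotate the genome first")
    if repeat1.overlaps(repeat2):
        raise ValueError("repeat copies overlap")
    s = record.sequence.residues
    c1 = s[repeat1.start:repeat1.end]
    c2 = s[repeat2.start:repeat2.end]
    if c1 != reverse_complement(c2):
        raise ValueError("repeat copies are not an inverted pair (a direct "
                         "pair cannot regenerate itself after the flip)")
    inner = s[repeat1.end:repeat2.start]
    flipped = (s[:repeat1.end] + reverse_complement(inner) + s[repeat2.start:])
    iso2 = PlastomeRecord(
        id=record.id + "_isomer2",
        sequence=NucleotideSequence(flipped, circular=True))
    return IsomerPair(record, iso2, repeat1, repeat2)


def junction_windows(pair: IsomerPair, flank: int = 1000) -> list:
    """The four repeat-plus-flank windows (two per isomer).

    Window = flank + repeat copy + flank; circular wrap at the origin is
    allowed, but the two windows of one isomer must not overlap.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    out = []
    for iso_idx, rec in ((1, pair.isomer1), (2, pair.isomer2)):
        n = len(rec)
        s2 = rec.sequence.residues * 2
        spans = []
        for side, rep in (("left", pair.repeat1), ("right", pair.repeat2)):
            start = (rep.start - flank) % n
            length = len(rep) + 2 * flank
            if length > n:
                raise ValueError("flank too large for the genome")
            spans.append((start, length))
            out.append(JunctionWindow(
                iso_idx, side, s2[start:start + length],
                (flank, flank + len(rep)), flank))
        a, la = spans[0]
        b, lb = spans[1]
        if (b - a) % n < la or (a - b) % n < lb:
            raise ValueError("flank so large that the two junction windows "
                             "overlap")
    return out


LONG_READ_SCHEME = ScoringScheme(seed_word=15)


def _scan_read(read: str, window_kmers: dict, k: int, stride: int):
    """Per-window (diag, window_pos) votes for one read.

    diag is the read offset at which the window would start if the seed
    were part of an end-to-end match.
    """
    votes: dict = {}
    for i in range(0, len(read) - k + 1, stride):
        hit = window_kmers.get(read[i:i + k])
        if hit is None:
            continue
        for widx, wpos in hit:
            votes.setdefault(widx, []).append((i - wpos, wpos))
    return votes


def _window_alignment(window: JunctionWindow, read: str, diag: int,
                      scheme: ScoringScheme, margin: int = 300):
    """Align the full window against the read region suggested by a seed."""
    wlen = len(window.sequence)
    lo = max(0, diag - margin)
    hi = min(len(read), diag + wlen + margin)
    if hi - lo < wlen // 2:
        return None
    seg = read[lo:hi]
    pos = seg.find(window.sequence)
    if pos >= 0:  # exact containment is the optimal local alignment
        return (wlen * scheme.match_reward, 0, wlen, 1.0)
    hit = sw_align(window.sequence, seg, scheme)
    if hit is None:
        return None
    return (hit.score, hit.query_start, hit.query_end, hit.identity)


def count_spanning_reads(windows, reads, min_identity: float = 0.8,
                         scheme: ScoringScheme = LONG_READ_SCHEME,
                         prescreen_stride: int = 48) -> ReadSupport:
    """Per-isomer junction-spanning read counts and isomer-2 frequency.

    ``reads`` are (name, sequence) pairs. A read supports a window iff
    its best local alignment covers the window end to end — the repeat
    core plus the full flank on both sides — at >= ``min_identity``
    (checked on both read strands). Each read counts for at most one
    isomer: the one holding its best supporting window; equal best
    scores on both isomers void the read.
    """
    windows = list(windows)
    k = scheme.seed_word
    window_kmers: dict = {}
    for widx, w in enumerate(windows):
        seq = w.sequence
        for i in range(0, len(seq) - k + 1):
            window_kmers.setdefault(seq[i:i + k], []).append((widx, i))
    counts = {(w.isomer, w.side): 0 for w in windows}
    ambiguous = 0
    total = 0
    for name, seq in reads:
        total += 1
        best = {}  # isomer -> (score, window index)
        for strand_seq in (seq, reverse_complement(seq)):
            votes = _scan_read(strand_seq, window_kmers, k, prescreen_stride)
            for widx, pairs in votes.items():
                w = windows[widx]
                wlen = len(w.sequence)
                if len(strand_seq) < wlen:
                    continue  # cannot span: shorter than repeat + 2*flank
                diags = sorted(d for d, _ in pairs)
                diag = diags[len(diags) // 2]
                slack = max(50, wlen // 10)
                if diag < -slack or diag + wlen > len(strand_seq) + slack:
                    continue  # window cannot fit inside the read here
                # spanning requires seeds in BOTH flanks at this diagonal;
                # the flank unique to the other configuration never seeds,
                # which rejects wrong-isomer windows without an alignment
                core_s, core_e = w.repeat_core
                good = [p for d, p in pairs if abs(d - diag) <= slack]
                if not (any(p + k <= core_s for p in good)
                        and any(p >= core_e for p in good)):
                    continue
                res = _window_alignment(w, strand_seq, diag, scheme)
                if res is None:
                    continue
                score, qs, qe, ident = res
                if qs > 0 or qe < len(w.sequence) or ident < min_identity:
                    continue  # does not span core + both full flanks
                cur = best.get(w.isomer)
                if cur is None or score > cur[0]:
                    best[w.isomer] = (score, widx)
        if not best:
            continue
        if len(best) == 2 and best[1][0] == best[2][0]:
            ambiguous += 1
            continue
        iso = max(best, key=lambda i: best[i][0])
        w = windows[best[iso][1]]
        counts[(w.isomer, w.side)] += 1
    mean1 = (counts[(1, "left")] + counts[(1, "right")]) / 2.0
    mean2 = (counts[(2, "left")] + counts[(2, "right")]) / 2.0
    if mean1 + mean2 > 0:
        freq = 100.0 * mean2 / (mean1 + mean2)
    else:
        freq = None
    return ReadSupport(counts, mean1, mean2, freq, ambiguous, total)


def short_read_configuration_check(windows, read_pairs,
                                   min_pairs: int = 3,
                                   scheme: ScoringScheme = LONG_READ_SCHEME,
                                   min_identity: float = 0.9) -> dict:
    """Do paired short reads support each configuration?

    A pair supports an isomer when its two mates land on opposite sides
    of a junction window of that isomer — one mate wholly in the
    repeat-distal flank, the other in the repeat-proximal flank — in a
    way unique to that isomer (pairs matching both isomers equally are
    uninformative). Returns {1: bool, 2: bool}. Mates too short or an
    insert smaller than the repeat cannot straddle and never count.
    """
    windows = list(windows)
    for p in read_pairs:
        if len(p) != 2:
            raise ValueError("short-read input must be (mate1, mate2) pairs")
    votes = {1: 0, 2: 0}
    for m1, m2 in read_pairs:
        support = {1: 0, 2: 0}
        for w in windows:
            core_s, core_e = w.repeat_core
            sides = []
            for mate in (m1, m2):
                placed = None
                for s in (mate, reverse_complement(mate)):
                    pos = w.sequence.find(s)
                    if pos < 0:
                        continue
                    if pos + len(s) <= core_s:
                        placed = "left_flank"
                    elif pos >= core_e:
                        placed = "right_flank"
                    break
                sides.append(placed)
            if set(sides) == {"left_flank", "right_flank"}:
                support[w.isomer] += 1
        if support[1] > 0 and support[2] == 0:
            votes[1] += 1
        elif support[2] > 0 and support[1] == 0:
            votes[2] += 1
    if read_pairs and votes[1] == 0 and votes[2] == 0:
        warnings.warn("no read pair straddles a junction (insert shorter "
                      "than the repeat?)")
    return {1: votes[1] >= min_pairs, 2: votes[2] >= min_pairs}
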