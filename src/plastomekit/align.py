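"""Seeded affine-gap local alignment (BLASTn-style contract).

The search follows the classic word seeding design: exact ``seed_word``
matches on both strands trigger ungapped x-drop extension; surviving seed
regions are resolved by a full affine-gap Smith-Waterman restricted to a
window around the seeds, so the top hit score equals the unrestricted
optimum whenever the true alignment contains one exact word (always the
case for the homologies this package targets). E-values use the
Karlin-Altschul form E = K*m*n*exp(-lambda*S) with the published
constants for the (+2, -3) scoring pair: lambda = 0.625, K = 0.41.

Default scoring matches the homology-search protocol used for plastid
gene calling: reward +2, penalty -3, gap open 5, gap extend 2, word size
9, E-value cutoff 1e-5, no low-complexity masking. A gap of length g
costs open + g*extend.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import reverse_complement

_ENC = np.zeros(128, dtype=np.uint8)
for _i, _c in enumerate("ACGTN"):
    _ENC[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N as uint8 0..4."""
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass(frozen=True)
class ScoringScheme:
    match_reward: int = 2
    mismatch_penalty: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    seed_word: int = 9
    evalue_threshold: float = 1e-5
    ka_lambda: float = 0.625
    ka_k: float = 0.41

    def __post_init__(self) -> None:
        if self.match_reward <= 0:
            raise ValueError("match reward must be positive")
        if self.mismatch_penalty > 0 or self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("penalties/costs must not reward differences")
        if self.seed_word < 4:
            raise ValueError("seed word length must be >= 4")

    def evalue(self, score: int, query_len: int, target_len: int) -> float:
        return self.ka_k * query_len * target_len * math.exp(
            -self.ka_lambda * score)


@dataclass(frozen=True)
class AlignmentHit:
    """One gapped local alignment of query against target.

    Intervals are 0-based half-open in the original (forward) coordinates
    of each sequence; ``strand`` is the target strand the query matched.
    """

    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    score: int
    identity: float
    evalue: float
    aln_len: int = 0
    matches: int = 0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start


@njit(cache=True)
def _sw(q, t, match, mismatch, open_cost, ext):
    """Full affine-gap Smith-Waterman with traceback.

    Returns (score, qs, qe, ts, te, matches, aln_len) for the best local
    alignment. open_cost already includes the first extension step.
    """
    m = q.shape[0]
    n = t.shape[0]
    NEG = -10 ** 9
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    # pointers: H 0 stop, 1 diag, 2 from E, 3 from F; E/F 1 = opened here
    PH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    PF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            e_open = H[i, j - 1] - open_cost
            e_ext = E[i, j - 1] - ext
            if e_open >= e_ext:
                E[i, j] = e_open
                PE[i, j] = 1
            else:
                E[i, j] = e_ext
                PE[i, j] = 0
            f_open = H[i - 1, j] - open_cost
            f_ext = F[i - 1, j] - ext
            if f_open >= f_ext:
                F[i, j] = f_open
                PF[i, j] = 1
            else:
                F[i, j] = f_ext
                PF[i, j] = 0
            if qi == t[j - 1] and qi != 4:
                diag = H[i - 1, j - 1] + match
            else:
                diag = H[i - 1, j - 1] + mismatch
            h = 0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            PH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback
    i = bi
    j = bj
    matches = 0
    aln = 0
    state = 0  # 0 in H, 1 in E, 2 in F
    while i > 0 and j > 0:
        if state == 0:
            p = PH[i, j]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == t[j - 1] and q[i - 1] != 4:
                    matches += 1
                aln += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = PE[i, j]
            aln += 1
            j -= 1
            if opened == 1:
                state = 0
        else:
            opened = PF[i, j]
            aln += 1
            i -= 1
            if opened == 1:
                state = 0
    return best, i, bi, j, bj, matches, aln


def sw_align(query: str, target: str, scheme: ScoringScheme) -> AlignmentHit | None:
    """Optimal local alignment of two strings (forward strands only)."""
    if not query or not target:
        raise ValueError("empty sequence")
    score, qs, qe, ts, te, matches, aln = _sw(
        encode(query), encode(target), scheme.match_reward,
        scheme.mismatch_penalty, scheme.gap_open + scheme.gap_extend,
        scheme.gap_extend)
    if score <= 0:
        return None
    return AlignmentHit(
        query_start=int(qs), query_end=int(qe), target_start=int(ts),
        target_end=int(te), strand="+", score=int(score),
        identity=matches / aln if aln else 0.0,
        evalue=scheme.evalue(int(score), len(query), len(target)),
        aln_len=int(aln), matches=int(matches))


def _seed_positions(query: str, target_index: dict, w: int):
    """(query_pos, target_pos) pairs of exact shared words."""
    out = []
    for i in range(0, len(query) - w + 1):
        word = query[i:i + w]
        hits = target_index.get(word)
        if hits:
            for j in hits:
                out.append((i, j))
    return out


def build_word_index(target: str, w: int) -> dict:
    idx: dict = {}
    for j in range(0, len(target) - w + 1):
        idx.setdefault(target[j:j + w], []).append(j)
    return idx


def _ungapped_score(query: str, target: str, qi: int, tj: int, w: int,
                    match: int, mismatch: int, xdrop: int = 12) -> int:
    """Greedy x-drop ungapped extension score around an exact word seed."""
    score = best = match * w
    i, j = qi + w, tj + w
    while i < len(query) and j < len(target):
        score += match if query[i] == target[j] else mismatch
        if score > best:
            best = score
        if best - score > xdrop:
            break
        i += 1
        j += 1
    score = best
    i, j = qi - 1, tj - 1
    while i >= 0 and j >= 0:
        score += match if query[i] == target[j] else mismatch
        if score > best:
            best = score
        if best - score > xdrop:
            break
        i -= 1
        j -= 1
    return best


def seeded_local_align(query: str, target: str, scheme: ScoringScheme = None,
                       circular_target: bool = False,
                       seed_trigger: int = 22, target_index: dict = None) -> list:
    """BLASTn-style search of ``query`` against both strands of ``target``.

    Circular targets are doubled before the search and hits deduplicated
    modulo the genome length (a hit may then end past the genome length,
    meaning it wraps the origin). Hits are returned sorted by (score desc,
    target start); hits whose query and target intervals are both
    contained in a better hit on the same strand are suppressed.
    ``target_index`` may carry a prebuilt ``build_word_index`` of the
    (doubled, if circular) target to amortize indexing across queries.
    """
    if scheme is None:
        scheme = ScoringScheme()
    if not query or not target:
        raise ValueError("empty sequence")
    n = len(target)
    search_target = target + target if circular_target else target
    w = scheme.seed_word
    index = target_index if target_index is not None \
        else build_word_index(search_target, w)
    hits = []
    m = len(query)
    for strand in "+-":
        q = query if strand == "+" else reverse_complement(query)
        if len(q) < w:
            continue
        seeds = _seed_positions(q, index, w)
        regions = _seed_regions(q, search_target, seeds, w, scheme, seed_trigger)
        for lo, hi in regions:
            wlo = max(0, lo - m)
            whi = min(len(search_target), hi + m)
            hit = sw_align(q, search_target[wlo:whi], scheme)
            if hit is None:
                continue
            qs, qe = hit.query_start, hit.query_end
            if strand == "-":
                qs, qe = m - hit.query_end, m - hit.query_start
            ev = scheme.evalue(hit.score, m, n)
            if ev > scheme.evalue_threshold:
                continue
            hits.append(AlignmentHit(
                query_start=qs, query_end=qe,
                target_start=wlo + hit.target_start,
                target_end=wlo + hit.target_end,
                strand=strand, score=hit.score, identity=hit.identity,
                evalue=ev, aln_len=hit.aln_len, matches=hit.matches))
    if circular_target:
        hits = _dedup_circular(hits, n)
    hits = _suppress_contained(hits)
    hits.sort(key=lambda h: (-h.score, h.target_start))
    return hits


def _seed_regions(q, t, seeds, w, scheme, trigger):
    """Cluster seeds passing ungapped extension into target regions."""
    kept = []
    seen_diag = set()
    for qi, tj in seeds:
        d = tj - qi
        key = (d, tj // max(w, 16))
        if key in seen_diag:
            continue
        seen_diag.add(key)
        s = _ungapped_score(q, t, qi, tj, w, scheme.match_reward,
                            scheme.mismatch_penalty)
        if s >= trigger:
            kept.append(tj)
    if not kept:
        return []
    kept.sort()
    regions = []
    lo = hi = kept[0]
    for tj in kept[1:]:
        if tj - hi <= len(q):
            hi = tj
        else:
            regions.append((lo, hi + w))
            lo = hi = tj
    regions.append((lo, hi + w))
    return regions


def _dedup_circular(hits, n):
    out = []
    seen = set()
    for h in sorted(hits, key=lambda h: (-h.score, h.target_start % n)):
        key = (h.query_start, h.query_end, h.target_start % n, h.strand)
        if key in seen:
            continue
        seen.add(key)
        if h.target_start >= n:
            h = AlignmentHit(
                query_start=h.query_start, query_end=h.query_end,
                target_start=h.target_start - n, target_end=h.target_end - n,
                strand=h.strand, score=h.score, identity=h.identity,
                evalue=h.evalue, aln_len=h.aln_len, matches=h.matches)
        out.append(h)
    return out


def _suppress_contained(hits):
    hits = sorted(hits, key=lambda h: -h.score)
    out = []
    for h in hits:
        contained = False
        for better in out:
            if (better.strand == h.strand
                    and better.query_start <= h.query_start
                    and h.query_end <= better.query_end
                    and better.target_start <= h.target_start
                    and h.target_end <= better.target_end):
                contained = True
                break
        if not contained:
            out.append(h)
    return out
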