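"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the seed-and-extend code paths of the package:
repeats are found by scanning every diagonal of the full comparison
matrix, circular extraction by doubling and linear slicing, and optimal
alignment scores come from Bio.Align.PairwiseAligner.
"""

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def extract_circular(seq: str, start: int, length: int, strand: str = "+"):
    doubled = seq + seq
    sub = doubled[start:start + length]
    return rc(sub) if strand == "-" else sub


def _runs(mask):
    """(start, length) of every maximal run of True in a 1-D bool array."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def brute_maximal_pairs(seq: str, min_len: int):
    """Every maximal repeated pair >= min_len by full diagonal scanning.

    Returns (direct, inverted) exactly in the conventions of the package
    catalog: direct pairs (p1, p2, L) with p1 < p2 and period >= L
    (tandem arrays excluded); inverted pairs (a, b, L) canonically
    ordered with a != b.
    """
    n = len(seq)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    rarr = np.frombuffer(rc(seq).encode(), dtype=np.uint8)

    direct = set()
    for d in range(1, n):
        m = arr[:n - d] == arr[d:]
        for start, length in _runs(m):
            if length >= min_len and d >= length:
                direct.add((start, start + d, length))

    inverted = set()
    # a match seq[p + t] == rc(seq)[q + t] has constant c = q - p
    for c in range(-(n - 1), n):
        if c >= 0:
            m = arr[: n - c] == rarr[c:]
            p0 = 0
        else:
            m = arr[-c:] == rarr[: n + c]
            p0 = -c
        for start, length in _runs(m):
            if length < min_len:
                continue
            p = p0 + start
            q = p + c
            a = p
            b = n - q - length
            if a == b:
                continue
            inverted.add((min(a, b), max(a, b), length))
    return direct, inverted


def pairwise_sw_score(query: str, target: str, match=2, mismatch=-3,
                      gap_open=5, gap_extend=2) -> float:
    """Optimal local alignment score, BLAST gap convention."""
    from Bio import Align
    a = Align.PairwiseAligner(mode="local", match_score=match,
                              mismatch_score=mismatch,
                              open_gap_score=-(gap_open + gap_extend),
                              extend_gap_score=-gap_extend)
    return max(a.score(target, query), a.score(target, rc(query)))
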