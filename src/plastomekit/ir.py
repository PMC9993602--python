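"""Inverted-repeat detection and quadripartite structure.

A canonical plastome is LSC - IRb - SSC - IRa on a circle, the two IRs
being exact (or near-exact) reverse complements. Detection finds the
longest disjoint reverse-complementary segment pair by shared-k-mer
seeding against the reverse complement with greedy extension; assembled
plastome IR copies are near-perfect, so the default is exact matching.

Structure classes: ``quadripartite`` (IR >= residual threshold),
``residual_ir`` (a detectable but depleted IR, < 2 kb by default) and
``ir_free`` (no pair above the minimum length; the whole circle is
reported as LSC by convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import GenomeInterval, PlastomeRecord, reverse_complement

JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")


@dataclass(frozen=True)
class QuadripartitePartition:
    """LSC/SSC/IRb/IRa tiling of a circular plastome."""

    lsc: GenomeInterval
    ssc: GenomeInterval | None
    irb: GenomeInterval | None
    ira: GenomeInterval | None
    ir_length: int
    structure_class: str
    genome_length: int

    def junction_positions(self) -> dict:
        """Offsets of the four junctions (each between base j-1 and j)."""
        if self.structure_class == "ir_free":
            raise ValueError("no junctions on an IR-free plastome")
        return {
            "JLB": self.irb.start,
            "JSB": self.ssc.start,
            "JSA": self.ira.start,
            "JLA": self.lsc.start,
        }


@dataclass(frozen=True)
class JunctionContext:
    junction_id: str
    position: int
    spanning_gene: str | None
    nearest_gene_each_side: tuple  # ((name, dist_bp) or None) for (5', 3') side


@dataclass(frozen=True)
class BoundaryShift:
    junction_id: str
    direction: str  # expansion | contraction | unchanged
    genes_gained_by_ir: tuple
    genes_lost_by_ir: tuple


def _inverted_pair_candidates(seq: str, min_len: int, k: int = 31,
                              max_mismatch_rate: float = 0.0):
    """Disjoint circular interval pairs (a, b, L) with s[b..] = rc(s[a..])."""
    n = len(seq)
    if n < 2 * min_len + 2:
        return []
    k = min(k, min_len)
    rc = reverse_complement(seq)
    index: dict = {}
    dseq = seq + seq[:k - 1]
    for p in range(n):
        index.setdefault(dseq[p:p + k], []).append(p)
    drc = rc + rc[:k - 1]
    covered: dict = {}  # diagonal -> q covered up to (exclusive)
    found = set()
    cap = n // 2
    for q in range(n):
        hits = index.get(drc[q:q + k])
        if not hits:
            continue
        for p in hits:
            d = (q - p) % n
            if covered.get(d, -1) >= q:
                continue
            length, p0, q0 = _extend_inverted(seq, rc, p, q, k, cap,
                                              max_mismatch_rate)
            covered[d] = q0 + length  # q-range covered on this diagonal
            if length < min_len:
                continue
            a = p0 % n
            b = (n - q0 - length) % n
            key = (min(a, b), max(a, b), length)
            found.add(key)
    out = []
    for a, b, length in found:
        ia = GenomeInterval(a, (a + length - 1) % n + 1, "+", genome_length=n)
        ib = GenomeInterval(b, (b + length - 1) % n + 1, "+", genome_length=n)
        if ia.overlaps(ib):
            continue
        out.append((a, b, length))
    return out


def _extend_inverted(seq, rc, p, q, k, cap, rate):
    """Maximal (mismatch-budgeted) circular extension of a (p, q) seed."""
    n = len(seq)

    def ok(t):
        return seq[(p + t) % n] == rc[(q + t) % n]

    lo, hi = 0, k  # matched t-range [lo, hi)
    if rate == 0.0:
        while hi - lo < cap and ok(hi):
            hi += 1
        while hi - lo < cap and ok(lo - 1):
            lo -= 1
    else:
        mism = 0
        while hi - lo < cap:
            good = ok(hi)
            if not good and (mism + 1) / (hi - lo + 1) > rate:
                break
            mism += 0 if good else 1
            hi += 1
        while hi - lo < cap:
            good = ok(lo - 1)
            if not good and (mism + 1) / (hi - lo + 1) > rate:
                break
            mism += 0 if good else 1
            lo -= 1
        while hi > lo and not ok(hi - 1):
            hi -= 1
        while lo < hi and not ok(lo):
            lo += 1
    return hi - lo, p + lo, q + lo


def detect_inverted_repeat(record: PlastomeRecord, min_ir_len: int = 100,
                           max_mismatch_rate: float = 0.0,
                           residual_threshold: int = 2000,
                           seed_k: int = 31) -> QuadripartitePartition:
    """Partition a circular plastome into LSC/SSC/IRb/IRa.

    The longest disjoint reverse-complementary pair >= ``min_ir_len``
    becomes the IR; the longer arc between the copies is LSC, the shorter
    SSC. IRb is the copy whose 3' junction abuts SSC in the orientation
    LSC -> IRb -> SSC -> IRa. Ties on length break to the smallest IRb
    start offset.
    """
    if not record.sequence.circular:
        raise ValueError("quadripartite partition is defined on circular "
                         "sequences only")
    s = record.sequence.residues
    n = len(s)
    cands = _inverted_pair_candidates(s, min_ir_len, k=seed_k,
                                      max_mismatch_rate=max_mismatch_rate)
    if not cands:
        lsc = GenomeInterval(0, n, "+", genome_length=n)
        return QuadripartitePartition(lsc, None, None, None, 0, "ir_free", n)
    best_len = max(c[2] for c in cands)
    best = None
    for a, b, length in cands:
        if length != best_len:
            continue
        try:
            part = _partition_from_pair(n, a, b, length, residual_threshold)
        except ValueError:
            continue  # adjacent copies leave no single-copy arc
        if best is None or part.irb.start < best.irb.start:
            best = part
    if best is None:
        lsc = GenomeInterval(0, n, "+", genome_length=n)
        return QuadripartitePartition(lsc, None, None, None, 0, "ir_free", n)
    return best


def _partition_from_pair(n, a, b, length, residual_threshold):
    end_a = (a + length - 1) % n + 1
    end_b = (b + length - 1) % n + 1
    arc_ab = (b - end_a) % n  # arc from end of copy A to start of copy B
    arc_ba = (a - end_b) % n
    if arc_ab == 0 or arc_ba == 0:
        raise ValueError("IR copies are adjacent; no single-copy arcs")

    def arc(from_end, to_start):
        return GenomeInterval(from_end % n, (to_start - 1) % n + 1, "+",
                              genome_length=n)

    ia = GenomeInterval(a, end_a, "+", genome_length=n)
    ib = GenomeInterval(b, end_b, "+", genome_length=n)
    if arc_ab <= arc_ba:
        ssc, lsc, irb, ira = arc(end_a, b), arc(end_b, a), ia, ib
    else:
        ssc, lsc, irb, ira = arc(end_b, a), arc(end_a, b), ib, ia
    cls = "residual_ir" if length < residual_threshold else "quadripartite"
    return QuadripartitePartition(lsc, ssc, irb, ira, length, cls, n)


def _circular_dist(frm, to, n):
    return (to - frm) % n


def junction_context(partition: QuadripartitePartition, features) -> list:
    """Gene context at each of the four junctions.

    A gene spans a junction iff the cut between bases j-1 and j falls
    strictly inside the gene (a gene ending exactly at the junction is
    the nearest gene at distance 0, not spanning).
    """
    import warnings
    if partition.structure_class == "ir_free":
        raise ValueError("junction contexts need an IR-containing plastome")
    if not features:
        warnings.warn("no features: junction contexts have no genes")
    n = partition.genome_length
    out = []
    for jid, pos in partition.junction_positions().items():
        spanning = None
        for f in features:
            span = f.span
            prev = (pos - 1) % n
            if span.contains_position(prev) and span.contains_position(pos):
                spanning = f.name
                break
        left = right = None
        for f in features:
            if f.name == spanning:
                continue
            span = f.span
            dl = _circular_dist(span.end % n, pos, n)
            dr = _circular_dist(pos, span.start, n)
            if left is None or dl < left[1]:
                left = (f.name, dl)
            if right is None or dr < right[1]:
                right = (f.name, dr)
        out.append(JunctionContext(jid, pos, spanning, (left, right)))
    return out


def genes_in_ir(partition: QuadripartitePartition, features) -> set:
    """Names of genes whose span lies fully inside either IR copy."""
    if partition.structure_class == "ir_free":
        return set()
    out = set()
    for f in features:
        span = f.span
        for arm in (partition.irb, partition.ira):
            if _interval_contains(arm, span):
                out.add(f.name)
    return out


def _interval_contains(outer: GenomeInterval, inner: GenomeInterval) -> bool:
    n = outer.genome_length
    off = (inner.start - outer.start) % n
    return off + len(inner) <= len(outer)


def compare_boundaries(target, reference) -> list:
    """Per-junction IR gains/losses of the target relative to a reference.

    ``target`` and ``reference`` are (partition, features) pairs sharing
    gene nomenclature. A gene the target IR holds but the reference IR
    does not is a gain (expansion); the converse is a loss (contraction).
    Changes are attributed to the junction pair on the single-copy side
    the gene occupies in the genome where it is single copy.
    """
    t_part, t_feats = target
    r_part, r_feats = reference
    t_names = {f.name for f in t_feats}
    r_names = {f.name for f in r_feats}
    if not (t_names & r_names):
        raise ValueError("no shared gene names between genomes")
    t_ir = genes_in_ir(t_part, t_feats)
    r_ir = genes_in_ir(r_part, r_feats)
    gained = (t_ir - r_ir) & r_names
    lost = (r_ir - t_ir) & t_names
    side_of = {}
    for name in gained:
        side_of[name] = _sc_side(r_part, r_feats, name)
    for name in lost:
        side_of[name] = _sc_side(t_part, t_feats, name)
    out = []
    for jid in JUNCTIONS:
        side = "LSC" if jid in ("JLB", "JLA") else "SSC"
        g = tuple(sorted(x for x in gained if side_of.get(x) == side))
        l = tuple(sorted(x for x in lost if side_of.get(x) == side))
        if g and not l:
            direction = "expansion"
        elif l and not g:
            direction = "contraction"
        elif not g and not l:
            direction = "unchanged"
        else:
            direction = "expansion" if len(g) >= len(l) else "contraction"
        out.append(BoundaryShift(jid, direction, g, l))
    return out


def _sc_side(partition, features, name):
    for f in features:
        if f.name != name:
            continue
        span = f.span
        if partition.structure_class == "ir_free":
            return "LSC"
        if partition.ssc is not None and _interval_contains(partition.ssc, span):
            return "SSC"
        return "LSC"
    return "LSC"


def gc_percent(seq: str) -> float:
    return round(100.0 * (seq.count("G") + seq.count("C")) / len(seq), 2)


def partition_table(records, partitions=None, **detect_kwargs) -> pd.DataFrame:
    """Per-genome summary: sizes of the four regions, GC%, class."""
    if partitions is None:
        partitions = [detect_inverted_repeat(r, **detect_kwargs)
                      for r in records]
    rows = []
    for rec, part in zip(records, partitions):
        rows.append({
            "id": rec.id,
            "genome_size": len(rec),
            "lsc": len(part.lsc) if part.structure_class != "ir_free"
            else len(rec),
            "ssc": len(part.ssc) if part.ssc is not None else 0,
            "ir": part.ir_length,
            "gc_percent": gc_percent(rec.sequence.residues),
            "structure_class": part.structure_class,
        })
    return pd.DataFrame(rows)
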