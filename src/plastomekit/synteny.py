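"""IR-reduced synteny blocks, signed permutations, and structural typing.

Pairwise collinear blocks are built from unique shared k-mers (anchors)
chained by position and orientation — adequate at plastome-scale
divergence, where single-copy sequence is essentially colinear between
rearrangement breakpoints. Block order and orientation relative to a
reference genome give a signed permutation; genomes sharing a signed
permutation form one structural type, and a simple breakpoint distance
quantifies how far an arrangement is from the reference.

The second IR copy must be removed first (``strip_second_ir``): with
both copies present every IR k-mer occurs twice and anchors vanish.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

from .model import (GeneFeature, GenomeInterval, NucleotideSequence,
                    PlastomeRecord, reverse_complement)


@dataclass(frozen=True)
class Anchor:
    position_a: int
    position_b: int
    strand: str


@dataclass(frozen=True)
class SyntenyBlock:
    block_id: int
    interval_a: tuple  # (start, end) on genome a
    interval_b: tuple  # (start, end) on genome b
    orientation: str  # + collinear, - inverted
    anchor_count: int


@dataclass(frozen=True)
class SignedPermutation:
    """Order of reference blocks as they appear along genome b."""

    signed_ids: tuple

    def __len__(self) -> int:
        return len(self.signed_ids)


@dataclass(frozen=True)
class StructuralType:
    label: str
    permutation: SignedPermutation
    members: tuple


def strip_second_ir(record: PlastomeRecord, partition) -> PlastomeRecord:
    """Excise IRa, shifting features; IR-free genomes pass through.

    Features fully inside IRa are dropped; a feature spanning the
    SSC/IRa junction is truncated at the junction and renamed with a
    ``*`` suffix to flag the cut.
    """
    if partition.structure_class == "ir_free":
        return record
    ira = partition.ira
    n = len(record)
    seq = record.sequence.residues
    if ira.wraps_origin:
        reduced = seq[ira.end:ira.start]
        offset_base = ira.end  # new origin in old frame
    else:
        reduced = seq[:ira.start] + seq[ira.end:]
        offset_base = 0
    m = len(reduced)

    def map_pos(p):
        if ira.wraps_origin:
            rel = (p - ira.end) % n
            return rel if rel < m else None
        if p < ira.start:
            return p
        if p >= ira.end:
            return p - len(ira)
        return None

    new_feats = []
    for f in record.features:
        exons = []
        cut = False
        for e in f.exons:
            s_m = map_pos(e.start)
            last_m = map_pos((e.end - 1) % n)
            if s_m is None and last_m is None:
                continue  # exon inside IRa: dropped
            if s_m is None:  # exon starts inside IRa: cut at the junction
                s_m = map_pos(ira.end % n)
                cut = True
            if last_m is None:  # exon ends inside IRa
                last_m = map_pos((ira.start - 1) % n)
                cut = True
            if last_m is None or s_m is None or last_m < s_m:
                continue
            exons.append(GenomeInterval(s_m, last_m + 1, e.strand,
                                        genome_length=m))
        if not exons:
            continue
        name = f.name + "*" if cut else f.name
        try:
            new_feats.append(GeneFeature(name, f.kind, tuple(exons), f.strand))
        except ValueError:
            continue  # truncation left an invalid model
    return PlastomeRecord(
        id=record.id,
        sequence=NucleotideSequence(reduced, circular=True),
        features=new_feats,
    )


def _unique_kmers(seq: str, k: int) -> dict:
    counts: dict = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        if w in counts:
            counts[w] = None  # repeated: disqualified
        else:
            counts[w] = i
    return {w: p for w, p in counts.items() if p is not None}


def find_anchors(a: str, b: str, k: int = 21) -> list:
    """k-mers occurring exactly once in each genome (either strand of b)."""
    ua = _unique_kmers(a, k)
    ub_f = _unique_kmers(b, k)
    rb = reverse_complement(b)
    ub_r = _unique_kmers(rb, k)
    anchors = []
    for w, pa in ua.items():
        pf = ub_f.get(w)
        pr = ub_r.get(w)
        if pf is not None and pr is not None:
            continue  # present on both strands of b: not unique in b
        if pf is not None:
            anchors.append(Anchor(pa, pf, "+"))
        elif pr is not None:
            anchors.append(Anchor(pa, len(b) - pr - k, "-"))
    anchors.sort(key=lambda x: x.position_a)
    return anchors


def build_blocks(a, b, k: int = 21, min_block_len: int = 500,
                 max_anchor_gap: int = 2000) -> list:
    """Chain unique shared k-mers into collinear blocks.

    ``a`` and ``b`` are sequences or IR-reduced PlastomeRecords. Chains
    keep one orientation, advance monotonically in both genomes, and
    allow gaps up to ``max_anchor_gap``; chains spanning at least
    ``min_block_len`` on genome a become blocks, numbered 1..n along a.
    """
    sa = a.sequence.residues if isinstance(a, PlastomeRecord) else a
    sb = b.sequence.residues if isinstance(b, PlastomeRecord) else b
    anchors = find_anchors(sa, sb, k)
    if not anchors:
        warnings.warn("no unique shared k-mers: no synteny blocks")
        return []
    chains = []
    cur = [anchors[0]]
    for anc in anchors[1:]:
        prev = cur[-1]
        gap_a = anc.position_a - prev.position_a
        if anc.strand == prev.strand and gap_a <= max_anchor_gap:
            gap_b = (anc.position_b - prev.position_b if anc.strand == "+"
                     else prev.position_b - anc.position_b)
            if 0 < gap_b <= max_anchor_gap:
                cur.append(anc)
                continue
        chains.append(cur)
        cur = [anc]
    chains.append(cur)
    blocks = []
    bid = 0
    for chain in chains:
        first, last = chain[0], chain[-1]
        span_a = last.position_a + k - first.position_a
        if span_a < min_block_len:
            continue
        bid += 1
        if first.strand == "+":
            ib = (first.position_b, last.position_b + k)
        else:
            ib = (last.position_b, first.position_b + k)
        blocks.append(SyntenyBlock(
            block_id=bid,
            interval_a=(first.position_a, last.position_a + k),
            interval_b=ib,
            orientation=first.strand,
            anchor_count=len(chain)))
    return blocks


def signed_permutations(ref, genomes: dict, k: int = 21,
                        min_block_len: int = 500,
                        max_anchor_gap: int = 2000) -> dict:
    """Signed permutations of all genomes over one shared segmentation.

    Pairwise blocks collapse adjacencies differently per genome, so raw
    per-pair block ids are not comparable across genomes. Here the
    reference is re-segmented at the union of every pairwise breakpoint
    (clustered within 2k bp), and each shared segment is located in each
    genome through its covering pairwise block. Returns genome id ->
    SignedPermutation, all over the same segment ids.
    """
    blocks_by = {gid: build_blocks(ref, g, k=k, min_block_len=min_block_len,
                                   max_anchor_gap=max_anchor_gap)
                 for gid, g in genomes.items()}
    bounds: set = set()
    for blocks in blocks_by.values():
        for blk in blocks:
            bounds.update(blk.interval_a)
    merged: list = []
    for x in sorted(bounds):
        if merged and x - merged[-1] <= 2 * k:
            continue
        merged.append(x)
    segments = [(a, b) for a, b in zip(merged, merged[1:])
                if b - a >= min_block_len]
    perms = {}
    for gid, blocks in blocks_by.items():
        placed = []
        for sid, (a, b) in enumerate(segments, 1):
            mid = (a + b) // 2
            blk = next((x for x in blocks
                        if x.interval_a[0] <= mid < x.interval_a[1]), None)
            if blk is None:
                continue  # segment absent from this genome
            if blk.orientation == "+":
                pos = blk.interval_b[0] + (a - blk.interval_a[0])
            else:
                pos = blk.interval_b[0] + (blk.interval_a[1] - b)
            placed.append((pos, sid if blk.orientation == "+" else -sid))
        placed.sort()
        perms[gid] = SignedPermutation(tuple(s for _, s in placed))
    return perms


def signed_permutation(blocks) -> SignedPermutation:
    """Block order along genome b; sign is block orientation."""
    ordered = sorted(blocks, key=lambda blk: blk.interval_b[0])
    return SignedPermutation(tuple(
        blk.block_id if blk.orientation == "+" else -blk.block_id
        for blk in ordered))


def breakpoint_distance(perm: SignedPermutation) -> int:
    """Circular signed breakpoint distance to the identity arrangement.

    An adjacency (u, v) is conserved when v follows u in the identity
    read in either direction: v == u+1 (mod n) with both signs +, or
    |u| == |v|+1 (mod n) with both signs -.
    """
    ids = perm.signed_ids
    n = len(ids)
    if n == 0:
        return 0
    seen = sorted(abs(x) for x in ids)
    if seen != list(range(1, n + 1)):
        raise ValueError("permutation must contain each block id once")
    bad = 0
    for u, v in zip(ids, ids[1:] + ids[:1]):
        if u > 0 and v > 0 and v == u % n + 1:
            continue
        if u < 0 and v < 0 and -u == (-v) % n + 1:
            continue
        bad += 1
    return bad


def classify_structural_types(permutations: dict) -> list:
    """Group genomes by identical signed permutation.

    ``permutations`` maps genome id -> SignedPermutation against one
    shared reference. Labels A, B, ... follow first occurrence over
    genome ids sorted for cross-run stability.
    """
    order = sorted(permutations)
    groups: dict = {}
    labels = []
    for gid in order:
        key = permutations[gid].signed_ids
        if key not in groups:
            groups[key] = []
            labels.append(key)
        groups[key].append(gid)
    out = []
    for i, key in enumerate(labels):
        label = chr(ord("A") + i) if i < 26 else f"T{i + 1}"
        out.append(StructuralType(label, SignedPermutation(key),
                                  tuple(groups[key])))
    return out
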