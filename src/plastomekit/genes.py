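"""Homology-based gene calling and pseudogene classification.

Each reference gene is searched against a genome with the seeded
affine-gap local aligner; hits are clustered into disjoint loci and the
best locus' query coverage drives a five-way status:

  intact                    coverage >= intact_cov and (non-coding gene,
                            or an in-frame translation without an
                            internal stop codon)
  pseudogene_premature_stop coverage >= intact_cov but an internal stop
  pseudogene_truncated      frag_cov <= coverage < intact_cov
  fragment                  0 < coverage < frag_cov
  absent                    no significant hit

Coverage thresholds default to intact_cov=0.90 and frag_cov=0.20; the
underlying protocol distinguishes only "partial sequence" (pseudogene)
from "remnant fragment", so both cutoffs are configurable. Copy number
counts disjoint loci reaching frag_cov coverage (all hit loci when only
sub-threshold fragments exist, so a fragment is never "absent").
RNA-editing rescue of internal stops is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import ScoringScheme, build_word_index, seeded_local_align
from .model import PlastomeRecord, reverse_complement

STOP_CODONS = ("TAA", "TAG", "TGA")

STATUS_SYMBOLS = {
    "intact_2copy": "2",
    "intact": "1",
    "pseudogene_truncated": "P",
    "pseudogene_premature_stop": "P",
    "fragment": "P",
    "absent": "-",
}


@dataclass(frozen=True)
class GeneCall:
    gene: str
    kind: str
    status: str
    copy_number: int
    coverage: float
    evidence: tuple

    def __post_init__(self) -> None:
        if (self.status == "absent") != (self.copy_number == 0):
            raise ValueError("absent status must mean zero copies")
        if self.status == "pseudogene_premature_stop" and self.kind != "PCG":
            raise ValueError("premature stop applies to protein genes only")


@dataclass(frozen=True)
class IntronStatus:
    gene: str
    introns_expected: int
    introns_found: int
    lost: bool
    undetermined: bool = False


def genome_word_index(record: PlastomeRecord, scheme: ScoringScheme = None) -> dict:
    """Word index of the (doubled, circular) genome, shareable across queries."""
    scheme = scheme or ScoringScheme()
    target = record.sequence.residues
    if record.sequence.circular:
        target = target + target
    return build_word_index(target, scheme.seed_word)


def _cluster_loci(hits, genome_length):
    """Group hits into disjoint target loci (greedy, best score first)."""
    loci = []  # list of [lo, hi, hits]
    for h in sorted(hits, key=lambda h: -h.score):
        lo, hi = h.target_start, h.target_end
        placed = False
        for locus in loci:
            a, b = locus[0], locus[1]
            if lo < b and a < hi or (lo - genome_length) < b and a < (hi - genome_length):
                locus[0] = min(a, lo)
                locus[1] = max(b, hi)
                locus[2].append(h)
                placed = True
                break
        if not placed:
            loci.append([lo, hi, [h]])
    return loci


def _query_coverage(hits, qlen):
    ivs = sorted((h.query_start, h.query_end) for h in hits)
    cov = 0
    cur_lo, cur_hi = None, None
    for lo, hi in ivs:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                cov += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        cov += cur_hi - cur_lo
    return cov / qlen


def _has_internal_stop(query: str, genome: str, hit) -> bool:
    """Scan the aligned target segment for an in-frame premature stop.

    The reading frame comes from the hit's query offset; the query is
    the full-length gene including its terminal stop codon, so a stop in
    the final query codon is not premature.
    """
    n = len(genome)
    g2 = genome + genome
    seg = g2[hit.target_start:hit.target_end]
    if hit.strand == "-":
        seg = reverse_complement(seg)
    qs = hit.query_start
    pad = (3 - qs % 3) % 3
    last_codon = len(query) // 3 - 1
    for off in range(pad, len(seg) - 2, 3):
        codon_index = (qs + off) // 3
        if codon_index >= last_codon:
            break
        if seg[off:off + 3] in STOP_CODONS:
            return True
    return False


def call_gene(gene_name: str, query: str, kind: str,
              record: PlastomeRecord, scheme: ScoringScheme = None,
              intact_cov: float = 0.90, frag_cov: float = 0.20,
              target_index: dict = None) -> GeneCall:
    """Classify one reference gene against a genome."""
    scheme = scheme or ScoringScheme()
    query = query.upper()
    if "N" in query:
        raise ValueError(f"query {gene_name} contains N")
    genome = record.sequence.residues
    hits = seeded_local_align(query, genome, scheme,
                              circular_target=record.sequence.circular,
                              target_index=target_index)
    if not hits:
        return GeneCall(gene_name, kind, "absent", 0, 0.0, ())
    loci = _cluster_loci(hits, len(genome))
    covs = [(_query_coverage(l[2], len(query)), l[2]) for l in loci]
    covs.sort(key=lambda c: -c[0])
    best_cov, best_hits = covs[0]
    copy_number = sum(1 for c, _ in covs if c >= frag_cov)
    if copy_number == 0:
        copy_number = len(covs)  # fragments still occupy loci
    if best_cov >= intact_cov:
        if kind == "PCG" and _has_internal_stop(
                query, genome, max(best_hits, key=lambda h: h.score)):
            status = "pseudogene_premature_stop"
        else:
            status = "intact"
    elif best_cov >= frag_cov:
        status = "pseudogene_truncated"
    else:
        status = "fragment"
    return GeneCall(gene_name, kind, status, copy_number, best_cov,
                    tuple(hits))


def call_genes(queries, record: PlastomeRecord,
               scheme: ScoringScheme = None, **kwargs) -> list:
    """Classify many (name, sequence, kind) queries, sharing one index."""
    scheme = scheme or ScoringScheme()
    index = genome_word_index(record, scheme)
    return [call_gene(name, seq, kind, record, scheme,
                      target_index=index, **kwargs)
            for name, seq, kind in queries]


def detect_intron_loss(gene_name: str, exon_seqs, record: PlastomeRecord,
                       scheme: ScoringScheme = None,
                       junction_gap: int = 30,
                       target_index: dict = None) -> IntronStatus:
    """Check whether the introns of a multi-exon gene model survive.

    Each reference exon is aligned independently; consecutive exon hits
    closer than ``junction_gap`` bp on the target mean that intron was
    lost (e.g. a cDNA-like insertion of the spliced gene).
    """
    scheme = scheme or ScoringScheme()
    exon_seqs = list(exon_seqs)
    if len(exon_seqs) < 2:
        raise ValueError("intron analysis needs a model with >= 2 exons")
    expected = len(exon_seqs) - 1
    best_hits = []
    for seq in exon_seqs:
        hits = seeded_local_align(seq, record.sequence.residues, scheme,
                                  circular_target=record.sequence.circular,
                                  target_index=target_index)
        if not hits:
            return IntronStatus(gene_name, expected, 0, False,
                                undetermined=True)
        best_hits.append(hits[0])
    found = 0
    for prev, nxt in zip(best_hits, best_hits[1:]):
        if prev.strand != nxt.strand:
            return IntronStatus(gene_name, expected, 0, False,
                                undetermined=True)
        if prev.strand == "+":
            gap = nxt.target_start - prev.target_end
        else:
            gap = prev.target_start - nxt.target_end
        if gap >= junction_gap:
            found += 1
    return IntronStatus(gene_name, expected, found, found < expected)


def gene_matrix(calls_by_genome: dict) -> pd.DataFrame:
    """Gene x genome status-symbol matrix.

    Symbols: "2" two intact copies, "1" one intact copy, "P" pseudogene
    or fragment (truncated, premature stop, or remnant), "-" absent.
    """
    genomes = sorted(calls_by_genome)
    genes: list = []
    for gid in genomes:
        for call in calls_by_genome[gid]:
            if call.gene not in genes:
                genes.append(call.gene)
    data = {}
    for gid in genomes:
        lookup = {c.gene: c for c in calls_by_genome[gid]}
        col = []
        for g in genes:
            c = lookup.get(g)
            if c is None:
                col.append("-")
            elif c.status == "intact" and c.copy_number >= 2:
                col.append(STATUS_SYMBOLS["intact_2copy"])
            else:
                col.append(STATUS_SYMBOLS[c.status])
        data[gid] = col
    return pd.DataFrame(data, index=genes)
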