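"""Seeded synthetic plastome and long-read generator.

Everything the pipeline detects can be planted here with known ground
truth: quadripartite genomes with IR lengths from 0 to ~37 kb, gene
models (single- and multi-exon, both strands, IR-resident duplicates),
pseudogene lesions (truncation, premature stop, deletion), dispersed
repeats near a focal gene, rearrangement scripts over block
decompositions, and a short inverted-repeat pair bracketing a long
segment whose flip yields the two plastome isomers. Long reads are
drawn uniformly from the circular templates with optional per-base
error rates. Identical seeds give byte-identical output.

Background composition is i.i.d. with GC 36.5% by default, matching the
GC range typical of these genomes (35.8-37.5%). Gene sequences are
random open reading frames (start codon, no internal stop, stop codon),
not real plastid genes; real query FASTAs can be used wherever these
fixtures are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import (GeneFeature, GenomeInterval, NucleotideSequence,
                    PlastomeRecord, reverse_complement)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOPS]


@dataclass(frozen=True)
class GeneSpec:
    """One gene to plant: region LSC|SSC|IR, auto-placed left to right."""

    name: str
    kind: str = "PCG"
    region: str = "LSC"
    length: int = 300
    exon_lengths: tuple | None = None
    intron_lengths: tuple | None = None
    strand: str = "+"


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    lsc_len: int
    ssc_len: int
    ir_len: int
    gc: float = 0.365
    genes: tuple = ()
    # ((unit_length, ((genome_offset, strand), ...)), ...)
    planted_repeats: tuple = ()
    # ((gene, "truncate", fraction) | (gene, "premature_stop") |
    #  (gene, "delete"), ...)
    pseudogene_plan: tuple = ()
    # (repeat_len, bracketed_span, lsc_offset) or None
    isomer_repeat: tuple | None = None

    def __post_init__(self) -> None:
        if self.lsc_len < self.ssc_len:
            raise ValueError("LSC must be at least as long as SSC")
        if min(self.lsc_len, self.ir_len) < 0 or self.ssc_len < 0:
            raise ValueError("negative region length")

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass(frozen=True)
class ReadSimSpec:
    seed: int
    n_reads: int
    min_len: int = 5000
    max_len: int = 15000
    mismatch: float = 0.0
    insertion: float = 0.0
    deletion: float = 0.0
    isomer2_proportion: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.mismatch, self.insertion, self.deletion):
            if not 0 <= r <= 0.2:
                raise ValueError("error rates must be within [0, 0.2]")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not 0 <= self.isomer2_proportion <= 1:
            raise ValueError("isomer2_proportion must be in [0, 1]")


def random_sequence(rng, n: int, gc: float = 0.365) -> str:
    if n == 0:
        return ""
    at = (1 - gc) / 2
    g = gc / 2
    idx = rng.choice(4, size=n, p=[at, g, g, at])
    return _B_ARR[idx].tobytes().decode()


def random_orf(rng, length: int) -> str:
    """ATG + sense codons + stop; ``length`` is rounded up to codons."""
    ncod = max(3, -(-length // 3))
    body = rng.choice(len(_SENSE_CODONS), size=ncod - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def _lesion(seq: str, plan) -> tuple:
    """Apply a pseudogene lesion; returns (planted_seq|None, status)."""
    if plan is None:
        return seq, "intact"
    mode = plan[0]
    if mode == "delete":
        return None, "absent"
    if mode == "truncate":
        frac = plan[1]
        kept = seq[: max(0, int(round(len(seq) * frac)))]
        if not kept:
            return None, "absent"
        status = "pseudogene_truncated" if frac >= 0.2 else "fragment"
        return kept, status
    if mode == "premature_stop":
        ncod = len(seq) // 3
        at = ncod // 2
        mutated = seq[: 3 * at] + "TAA" + seq[3 * at + 3:]
        return mutated, "pseudogene_premature_stop"
    raise ValueError(f"unknown lesion mode {mode!r}")


def generate_plastome(spec: SyntheticSpec):
    """Build one synthetic plastome.

    Returns (PlastomeRecord, manifest). The manifest is a JSON-ready
    dict with the true partition, every planted gene (reference
    sequence, realized interval, expected status), repeat loci, and the
    isomer-mediating pair if any.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.genome_length
    regions = {
        "LSC": list(random_sequence(rng, spec.lsc_len, spec.gc)),
        "IR": list(random_sequence(rng, spec.ir_len, spec.gc)),
        "SSC": list(random_sequence(rng, spec.ssc_len, spec.gc)),
    }
    region_offsets = {"LSC": 0, "IR": spec.lsc_len,
                      "SSC": spec.lsc_len + spec.ir_len}
    plan_by_gene = {p[0]: tuple(p[1:]) for p in spec.pseudogene_plan}
    cursor = {"LSC": 150, "IR": 150, "SSC": 150}
    manifest_genes = []
    features = []
    placed = []  # (genome_start, genome_end, name) of planted material

    for g in spec.genes:
        if g.region not in regions:
            raise ValueError(f"gene {g.name}: unknown region {g.region}")
        if g.exon_lengths:
            ref_parts = []
            total_coding = sum(g.exon_lengths)
            ref = random_orf(rng, total_coding) if g.kind == "PCG" else \
                random_sequence(rng, total_coding, spec.gc)
            off = 0
            for el in g.exon_lengths:
                ref_parts.append(ref[off:off + el])
                off += el
            introns = [random_sequence(rng, il, spec.gc)
                       for il in (g.intron_lengths or ())]
        else:
            ref = random_orf(rng, g.length) if g.kind == "PCG" else \
                random_sequence(rng, g.length, spec.gc)
            ref_parts, introns = [ref], []
        planted, status = _lesion(ref, plan_by_gene.get(g.name))
        gap = int(rng.integers(80, 250))
        start_in_region = cursor[g.region] + gap
        if planted is None:
            manifest_genes.append({
                "name": g.name, "kind": g.kind, "status": status,
                "reference": ref, "intervals": []})
            continue
        if g.exon_lengths and status == "intact":
            pieces = []
            for i, part in enumerate(ref_parts):
                pieces.append(part)
                if i < len(introns):
                    pieces.append(introns[i])
            genomic = "".join(pieces)
            exon_bounds = []
            off = 0
            for i, part in enumerate(ref_parts):
                exon_bounds.append((off, off + len(part)))
                off += len(part)
                if i < len(introns):
                    off += len(introns[i])
        else:
            genomic = planted
            exon_bounds = [(0, len(planted))]
        if g.strand == "-":
            glen = len(genomic)
            genomic = reverse_complement(genomic)
            exon_bounds = [(glen - e, glen - s) for s, e in exon_bounds][::-1]
        end_in_region = start_in_region + len(genomic)
        if end_in_region > len(regions[g.region]) - 150:
            raise ValueError(
                f"infeasible placement: gene {g.name} does not fit in "
                f"{g.region} (needs {end_in_region} of "
                f"{len(regions[g.region])} bp)")
        regions[g.region][start_in_region:end_in_region] = list(genomic)
        cursor[g.region] = end_in_region
        gstart = region_offsets[g.region] + start_in_region
        exons = [GenomeInterval(gstart + s, gstart + e, g.strand,
                                genome_length=n) for s, e in exon_bounds]
        if g.strand == "-":
            exons = exons[::-1]
        intervals = [(gstart, gstart + len(genomic), g.strand)]
        try:
            features.append(GeneFeature(g.name, g.kind, tuple(exons),
                                        g.strand))
        except ValueError:
            pass  # lesioned remnant too short for a valid model
        placed.append((gstart, gstart + len(genomic), g.name))
        if g.region == "IR" and spec.ir_len > 0:
            # the IRa mirror copy
            o = start_in_region
            glen = len(genomic)
            ira_base = spec.lsc_len + spec.ir_len + spec.ssc_len
            ms = ira_base + spec.ir_len - o - glen
            mstrand = "-" if g.strand == "+" else "+"
            mirror = GenomeInterval(ms, ms + glen, mstrand, genome_length=n)
            try:
                features.append(GeneFeature(g.name, g.kind, (mirror,),
                                            mstrand))
            except ValueError:
                pass
            intervals.append((ms, ms + glen, mstrand))
        manifest_genes.append({
            "name": g.name, "kind": g.kind, "status": status,
            "reference": ref, "intervals": intervals})

    genome = (regions["LSC"] + regions["IR"] + regions["SSC"]
              + list(reverse_complement("".join(regions["IR"]))))
    assert len(genome) == n

    manifest_repeats = []
    for length, loci in spec.planted_repeats:
        unit = random_sequence(rng, length, spec.gc)
        unit_loci = []
        for offset, strand in loci:
            end = offset + length
            _check_plantable(offset, end, spec, placed, f"repeat({length})")
            frag = unit if strand == "+" else reverse_complement(unit)
            genome[offset:end] = list(frag)
            unit_loci.append((offset, end, strand))
        manifest_repeats.append({"length": length, "unit": unit,
                                 "loci": unit_loci})

    manifest_isomer = None
    if spec.isomer_repeat is not None:
        rep_len, span, off = spec.isomer_repeat
        unit = random_sequence(rng, rep_len, spec.gc)
        s1, e1 = off, off + rep_len
        s2 = off + rep_len + span
        e2 = s2 + rep_len
        _check_plantable(s1, e1, spec, placed, "isomer repeat copy 1")
        _check_plantable(s2, e2, spec, placed, "isomer repeat copy 2")
        genome[s1:e1] = list(unit)
        genome[s2:e2] = list(reverse_complement(unit))
        manifest_isomer = {"length": rep_len, "copy1": (s1, e1),
                           "copy2": (s2, e2), "unit": unit}

    if spec.ir_len > 0 and spec.ssc_len >= 2 and spec.lsc_len >= 2:
        _pin_ir_boundaries(genome, spec)

    record = PlastomeRecord(
        id=f"synthetic_{spec.seed}",
        sequence=NucleotideSequence("".join(genome), circular=True),
        features=features)
    manifest = {
        "seed": int(spec.seed),
        "genome_length": n,
        "partition": {
            "lsc": (0, spec.lsc_len),
            "irb": (spec.lsc_len, spec.lsc_len + spec.ir_len),
            "ssc": (spec.lsc_len + spec.ir_len,
                    spec.lsc_len + spec.ir_len + spec.ssc_len),
            "ira": (spec.lsc_len + spec.ir_len + spec.ssc_len, n),
            "ir_length": spec.ir_len,
        },
        "genes": manifest_genes,
        "repeats": manifest_repeats,
        "isomer_repeat": manifest_isomer,
    }
    return record, manifest


_COMP1 = {"A": "T", "T": "A", "G": "C", "C": "G"}


def _pin_ir_boundaries(genome, spec):
    """Make the planted IR pair non-extendable by chance.

    The manifest declares the IR at exact coordinates; a single matching
    base just outside both copies would silently lengthen the true
    maximal pair. Pin the first LSC base and the last SSC base (both
    150 bp clear of any planted gene) so the match stops at the planted
    junctions.
    """
    a1 = spec.lsc_len  # IRb start; a1-1 is the last LSC base
    e1 = spec.lsc_len + spec.ir_len  # first SSC base
    a2 = e1 + spec.ssc_len  # IRa start; a2-1 is the last SSC base
    if genome[0] == _COMP1[genome[a1 - 1]]:
        genome[0] = next(b for b in "ACGT"
                         if b != _COMP1[genome[a1 - 1]])
    if genome[a2 - 1] == _COMP1[genome[e1]]:
        genome[a2 - 1] = next(b for b in "ACGT"
                              if b != _COMP1[genome[e1]])


def _check_plantable(start, end, spec, placed, what):
    lsc_ok = 0 <= start and end <= spec.lsc_len
    ssc_lo = spec.lsc_len + spec.ir_len
    ssc_ok = ssc_lo <= start and end <= ssc_lo + spec.ssc_len
    if not (lsc_ok or ssc_ok):
        raise ValueError(f"infeasible placement: {what} at [{start}, {end}) "
                         "is not inside a single-copy region")
    for s, e, name in placed:
        if start < e and s < end:
            raise ValueError(f"infeasible placement: {what} overlaps gene "
                             f"{name} at [{s}, {e})")


# ---------------------------------------------------------------------------
# rearrangements

def apply_rearrangement(record: PlastomeRecord, script):
    """Apply inversion/translocation events in order.

    Events: ("inversion", start, end) reverse-complements [start, end);
    ("translocation", start, end, dest) cuts [start, end) and reinserts
    it at offset ``dest`` of the remaining sequence. Returns
    (new_record, SignedPermutation-ready tuple) where the tuple is the
    expected signed block order implied by the accumulated breakpoints.
    """
    seq = record.sequence.residues
    pieces = [(0, len(seq), +1)]
    for ev in script:
        kind = ev[0]
        if kind == "inversion":
            _, s, e = ev
            if not 0 <= s < e <= len(seq):
                raise ValueError(f"inversion [{s}, {e}) out of range")
            seq = seq[:s] + reverse_complement(seq[s:e]) + seq[e:]
            pieces = _split(pieces, s)
            pieces = _split(pieces, e)
            pieces = (_take(pieces, 0, s)
                      + [(a, b, -sg) for a, b, sg in
                         reversed(_take(pieces, s, e))]
                      + _take(pieces, e, len(seq)))
        elif kind == "translocation":
            _, s, e, dest = ev
            if not 0 <= s < e <= len(seq):
                raise ValueError(f"translocation [{s}, {e}) out of range")
            if not 0 <= dest <= len(seq) - (e - s):
                raise ValueError("translocation destination out of range")
            seg = seq[s:e]
            rest = seq[:s] + seq[e:]
            seq = rest[:dest] + seg + rest[dest:]
            pieces = _split(pieces, s)
            pieces = _split(pieces, e)
            moved = _take(pieces, s, e)
            left = _take(pieces, 0, s) + _take(pieces, e, len(seq))
            left = _split(left, dest)  # dest is an offset into the remainder
            acc = 0
            cut = len(left)
            for i, (a, b, _sg) in enumerate(left):
                if acc >= dest:
                    cut = i
                    break
                acc += b - a
            pieces = left[:cut] + moved + left[cut:]
        else:
            raise ValueError(f"unknown event {kind!r}")
        pieces = _merge(pieces)
    order = sorted({(a, b) for a, b, _ in pieces})
    ids = {ab: i + 1 for i, ab in enumerate(order)}
    perm = tuple(ids[(a, b)] * sg for a, b, sg in pieces)
    new_record = PlastomeRecord(
        id=record.id + "_rearranged",
        sequence=NucleotideSequence(seq, circular=record.sequence.circular))
    return new_record, perm


def _split(pieces, cut):
    """Split the piece list at current-coordinate offset ``cut``."""
    out = []
    pos = 0
    for a, b, sg in pieces:
        ln = b - a
        if pos < cut < pos + ln:
            off = cut - pos
            if sg > 0:
                out.append((a, a + off, sg))
                out.append((a + off, b, sg))
            else:
                out.append((b - off, b, sg))
                out.append((a, b - off, sg))
        else:
            out.append((a, b, sg))
        pos += ln
    return out


def _take(pieces, lo, hi):
    out = []
    pos = 0
    for a, b, sg in pieces:
        ln = b - a
        if lo <= pos and pos + ln <= hi:
            out.append((a, b, sg))
        pos += ln
    return out


def _merge(pieces):
    out = [pieces[0]]
    for a, b, sg in pieces[1:]:
        pa, pb, psg = out[-1]
        if sg == psg == 1 and a == pb:
            out[-1] = (pa, b, sg)
        elif sg == psg == -1 and b == pa:
            out[-1] = (a, pb, sg)
        else:
            out.append((a, b, sg))
    return out


# ---------------------------------------------------------------------------
# long reads

_B_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def simulate_long_reads(template_or_pair, read_spec: ReadSimSpec):
    """Uniform circular long reads from one record or an IsomerPair.

    Read names encode the ground truth:
    ``read<i>|tmpl=isomer<1|2>|start=<s>|len=<L>|strand=<+/->``.
    """
    from .isomer import IsomerPair
    rng = np.random.default_rng(read_spec.seed)
    if isinstance(template_or_pair, IsomerPair):
        templates = {1: template_or_pair.isomer1.sequence.residues,
                     2: template_or_pair.isomer2.sequence.residues}
    else:
        templates = {1: template_or_pair.sequence.residues}
    doubled = {k: v + v for k, v in templates.items()}
    n = len(templates[1])
    reads = []
    which = rng.random(read_spec.n_reads) < read_spec.isomer2_proportion
    starts = rng.integers(0, n, size=read_spec.n_reads)
    lens = rng.integers(read_spec.min_len, read_spec.max_len + 1,
                        size=read_spec.n_reads)
    flips = rng.random(read_spec.n_reads) < 0.5
    noisy = (read_spec.mismatch + read_spec.insertion
             + read_spec.deletion) > 0
    for i in range(read_spec.n_reads):
        tmpl = 2 if (which[i] and 2 in templates) else 1
        start = int(starts[i])
        length = int(min(lens[i], n))
        seq = doubled[tmpl][start:start + length]
        if noisy:
            seq = _inject_errors(seq, rng, read_spec)
        strand = "-" if flips[i] else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        reads.append((f"read{i}|tmpl=isomer{tmpl}|start={start}"
                      f"|len={length}|strand={strand}", seq))
    return reads


def _inject_errors(seq: str, rng, spec: ReadSimSpec) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.zeros(arr.shape, dtype=np.uint8)
    for v, c in zip(_B_ARR, range(4)):
        code[arr == v] = c
    keep = rng.random(code.size) >= spec.deletion
    code = code[keep]
    mism = rng.random(code.size) < spec.mismatch
    code[mism] = (code[mism] + rng.integers(1, 4, size=int(mism.sum()))) % 4
    ins_at = np.nonzero(rng.random(code.size) < spec.insertion)[0]
    if ins_at.size:
        code = np.insert(code, ins_at,
                         rng.integers(0, 4, size=ins_at.size).astype(np.uint8))
    return _B_ARR[code].tobytes().decode()


# ---------------------------------------------------------------------------
# canonical fixtures

#: (lsc, ssc, ir) triples spanning the observed structural range: an
#: IR-free genome, a residual 437 bp IR (110,388 bp genome), 1,964 bp
#: (119,769 bp), 10,191 bp (123,009 bp) and a 33,169 bp IR (143,493 bp).
PARTITION_SPECS = (
    (80000, 30000, 0),
    (81002, 28512, 437),
    (83710, 32131, 1964),
    (79737, 22890, 10191),
    (53377, 23778, 33169),
)

REARRANGEMENT_TYPES = {
    "A": (1, 2, 3, 4, 5, 6),
    "B": (1, -3, -2, 4, 5, 6),
    "C": (1, 2, -5, -4, -3, 6),
    "D": (1, 4, 5, 2, 3, 6),
    "E": (-2, -1, 3, 4, -6, -5),
}

TYPE_MEMBERSHIP = ("A", "A", "A", "B", "B", "B", "B", "C", "C", "C",
                   "D", "D", "E", "E")


def gene_status_genome(seed: int = 7, per_status: int = 20,
                       gene_length: int = 360):
    """A genome with ``per_status`` genes planted under each status.

    Returns (record, manifest, queries) where queries are (name, ref
    sequence, kind) ready for the gene caller.
    """
    statuses = [("intact", None),
                ("pseudogene_truncated", ("truncate", 0.5)),
                ("pseudogene_premature_stop", ("premature_stop",)),
                ("fragment", ("truncate", 0.1)),
                ("absent", ("delete",))]
    genes = []
    plan = []
    rng = np.random.default_rng(seed)
    i = 0
    for status, lesion in statuses:
        for _ in range(per_status):
            i += 1
            name = f"g{i:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            region = "LSC" if rng.random() < 0.8 else "SSC"
            genes.append(GeneSpec(name, "PCG", region, gene_length,
                                  strand=strand))
            if lesion is not None:
                plan.append((name,) + lesion)
    n_lsc_genes = sum(1 for g in genes if g.region == "LSC")
    n_ssc_genes = len(genes) - n_lsc_genes
    lsc_len = (gene_length + 400) * (n_lsc_genes + 2)
    ssc_len = (gene_length + 400) * (n_ssc_genes + 2)
    spec = SyntheticSpec(seed=seed, lsc_len=max(lsc_len, ssc_len),
                         ssc_len=min(lsc_len, ssc_len), ir_len=1200,
                         genes=tuple(genes), pseudogene_plan=tuple(plan))
    record, manifest = generate_plastome(spec)
    queries = [(g["name"], g["reference"], g["kind"])
               for g in manifest["genes"]]
    return record, manifest, queries


def arrangement_genomes(seed: int = 11, n_blocks: int = 6,
                        block_len_range=(3000, 9000),
                        membership=TYPE_MEMBERSHIP):
    """Genomes realizing the five planted block arrangements.

    Returns (genomes, truth): genomes maps genome id -> PlastomeRecord
    (IR-reduced, i.e. no IR is planted); truth maps genome id -> the
    planted signed block order.
    """
    rng = np.random.default_rng(seed)
    blocks = [random_sequence(rng, int(rng.integers(*block_len_range)))
              for _ in range(n_blocks)]
    genomes = {}
    truth = {}
    for i, type_label in enumerate(membership):
        order = REARRANGEMENT_TYPES[type_label]
        parts = []
        for sid in order:
            b = blocks[abs(sid) - 1]
            parts.append(b if sid > 0 else reverse_complement(b))
        gid = f"G{i + 1:02d}"
        genomes[gid] = PlastomeRecord(
            id=gid, sequence=NucleotideSequence("".join(parts),
                                                circular=True))
        truth[gid] = order
    return genomes, truth


def isomer_fixture(seed: int = 23, repeat_len: int = 679,
                   bracket_span: int = 60000):
    """The flip-flop scenario: a short inverted pair bracketing ~60 kb.

    Returns (pair, manifest): an IsomerPair built on a ~110 kb
    quadripartite genome whose LSC carries the inverted repeat pair.
    """
    from .isomer import build_isomer
    spec = SyntheticSpec(seed=seed, lsc_len=70000, ssc_len=20000,
                         ir_len=10000,
                         isomer_repeat=(repeat_len, bracket_span, 2000))
    record, manifest = generate_plastome(spec)
    iso = manifest["isomer_repeat"]
    n = len(record)
    r1 = GenomeInterval(*iso["copy1"], "+", genome_length=n)
    r2 = GenomeInterval(*iso["copy2"], "-", genome_length=n)
    pair = build_isomer(record, r1, r2)
    return pair, manifest


def fixture_suite(seed: int = 0):
    """The canonical fixture set used across the test suite.

    Returns a dict with quadripartite genomes over the observed IR range
    ('partitions'), a five-status gene genome ('gene_status'), 14
    genomes in 5 planted arrangements ('rearrangement'), and the isomer
    scenario ('isomer'). Reads are simulated separately so callers
    control depth.
    """
    partitions = []
    for j, (lsc, ssc, ir_len) in enumerate(PARTITION_SPECS):
        spec = SyntheticSpec(seed=seed * 1000 + j, lsc_len=lsc, ssc_len=ssc,
                             ir_len=ir_len)
        partitions.append((spec, generate_plastome(spec)))
    record, manifest, queries = gene_status_genome(seed=seed + 7,
                                                   per_status=20)
    genomes, truth = arrangement_genomes(seed=seed + 11)
    pair, iso_manifest = isomer_fixture(seed=seed + 23)
    return {
        "partitions": partitions,
        "gene_status": (record, manifest, queries),
        "rearrangement": (genomes, truth),
        "isomer": (pair, iso_manifest),
    }
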