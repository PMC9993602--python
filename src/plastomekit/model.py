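"""Core data model: circular nucleotide sequences, intervals, features.

Coordinates are 0-based half-open internally. On a circular sequence an
interval with ``end <= start`` wraps the origin; its length is
``(end - start) mod n``. File boundaries (GFF3/GenBank) are 1-based
inclusive and converted on the way in/out.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string (N maps to N)."""
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"invalid residues for reverse complement: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NucleotideSequence:
    """An uppercase A/C/G/T/N sequence, optionally circular.

    Ambiguity codes other than N are rejected: degenerate bases in an
    assembled organelle genome are an assembly defect, not data.
    """

    residues: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("empty sequence")
        res = self.residues.upper()
        bad = set(res) - _VALID
        if bad:
            raise ValueError(
                f"sequence contains residues outside A/C/G/T/N: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", res)

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(reverse_complement(self.residues), self.circular)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a genome of length ``genome_length``.

    ``end <= start`` encodes an origin-wrapping interval on a circular
    genome. Zero-length intervals are not representable (``end == start``
    means full wrap is disallowed; lengths are always in ``1..n``).
    """

    start: int
    end: int
    strand: str = "+"
    genome_length: int = 0

    def __post_init__(self) -> None:
        n = self.genome_length
        if n <= 0:
            raise ValueError("genome_length must be positive")
        if not (0 <= self.start < n):
            raise ValueError(f"start {self.start} outside [0, {n})")
        if not (0 < self.end <= n):
            raise ValueError(f"end {self.end} outside (0, {n}]")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def wraps_origin(self) -> bool:
        return self.end <= self.start

    def __len__(self) -> int:
        if self.wraps_origin:
            return self.genome_length - self.start + self.end
        return self.end - self.start

    def contains_position(self, pos: int) -> bool:
        if self.wraps_origin:
            return pos >= self.start or pos < self.end
        return self.start <= pos < self.end

    def positions(self):
        """Iterate genome offsets covered, 5'->3' in genome frame."""
        n = self.genome_length
        p = self.start
        for _ in range(len(self)):
            yield p
            p = (p + 1) % n

    def overlaps(self, other: "GenomeInterval") -> bool:
        if self.genome_length != other.genome_length:
            raise ValueError("intervals on different genomes")
        mine = self._arcs()
        theirs = other._arcs()
        return any(a < d and c < b for a, b in mine for c, d in theirs)

    def _arcs(self):
        """Linear (start, end) pieces; wrapping intervals split in two."""
        if self.wraps_origin:
            return [(self.start, self.genome_length), (0, self.end)]
        return [(self.start, self.end)]

    def shifted(self, offset: int) -> "GenomeInterval":
        n = self.genome_length
        return replace(self, start=(self.start + offset) % n,
                       end=(self.end - 1 + offset) % n + 1)


@dataclass(frozen=True)
class GeneFeature:
    """A gene with one or more exons, all on one strand.

    kind is one of PCG (protein-coding), tRNA, rRNA. Exons are ordered
    5'->3' on the coding strand.
    """

    name: str
    kind: str
    exons: tuple
    strand: str

    KINDS = ("PCG", "tRNA", "rRNA")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        exons = tuple(self.exons)
        if not exons:
            raise ValueError("gene needs at least one exon")
        for a, b in zip(exons, exons[1:]):
            if a.overlaps(b):
                raise ValueError(f"overlapping exons in {self.name}")
        if self.kind == "PCG" and sum(len(e) for e in exons) < 3:
            raise ValueError(f"PCG {self.name} shorter than one codon")
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> GenomeInterval:
        """Interval from first exon start to last exon end (genome frame)."""
        first = self.exons[0] if self.strand == "+" else self.exons[-1]
        last = self.exons[-1] if self.strand == "+" else self.exons[0]
        lo = min(e.start for e in (first, last))
        hi = max(e.end for e in (first, last))
        n = first.genome_length
        if any(e.wraps_origin for e in self.exons):
            # conservative: span is the union hull through the origin
            return GenomeInterval(self.exons[0].start, self.exons[-1].end,
                                  self.strand, n)
        return GenomeInterval(lo, hi, self.strand, n)

    def length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class PlastomeRecord:
    """A plastid genome: id, circular sequence, gene features."""

    id: str
    sequence: NucleotideSequence
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            for e in f.exons:
                if e.genome_length != n:
                    raise ValueError(
                        f"feature {f.name} coordinates not on genome of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def extract(self, interval: GenomeInterval) -> str:
        return extract_interval(self, interval)

    def gene_sequence(self, feature: GeneFeature) -> str:
        """Spliced 5'->3' sequence of a feature."""
        parts = [extract_interval(self, replace(e, strand=feature.strand))
                 for e in feature.exons]
        return "".join(parts)


def extract_interval(record: PlastomeRecord, interval: GenomeInterval) -> str:
    """Subsequence of ``record`` covered by ``interval``.

    Origin-wrapping intervals concatenate tail+head; minus-strand intervals
    return the reverse complement of the genome-frame slice.
    """
    s = record.sequence.residues
    n = len(s)
    if interval.genome_length != n:
        raise ValueError("interval not on this genome")
    if interval.wraps_origin:
        if not record.sequence.circular:
            raise ValueError("origin-wrapping interval on a linear sequence")
        sub = s[interval.start:] + s[: interval.end]
    else:
        sub = s[interval.start: interval.end]
    if not sub:
        raise ValueError("zero-length interval")
    return reverse_complement(sub) if interval.strand == "-" else sub
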