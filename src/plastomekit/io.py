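"""Readers/writers for FASTA, GFF3, GenBank and FASTQ.

FASTA/FASTQ/GenBank go through Bio.SeqIO. GFF3 is the minimal 9-column
ID/Parent dialect used throughout organelle annotation; coordinates are
1-based inclusive in files and converted to the internal 0-based
half-open convention.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import GeneFeature, GenomeInterval, NucleotideSequence, PlastomeRecord

_GFF_KIND = {"gene": None, "CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
             "exon": None}
_KIND_TO_GFF = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_sequences(path, circular: bool = True) -> list:
    """Read a (multi-)FASTA into PlastomeRecords (no features)."""
    path = Path(path)
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            records.append(PlastomeRecord(
                id=rec.id,
                sequence=NucleotideSequence(str(rec.seq), circular=circular),
            ))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_sequences(records, path) -> None:
    seqrecs = [SeqRecord(Seq(r.sequence.residues), id=r.id, description="")
               for r in records]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_annotations(path, genome_length: int, fmt: str = "gff3") -> list:
    """Read gene features from GFF3 or a GenBank flat file.

    File coordinates (1-based inclusive) become 0-based half-open. CDS/exon
    lines sharing a Parent (or ID) are joined into one multi-exon gene.
    """
    if fmt == "gff3":
        return _read_gff3(path, genome_length)
    if fmt == "genbank":
        return _read_genbank(path, genome_length)
    raise ValueError(f"unsupported annotation format {fmt!r}")


def _read_gff3(path, genome_length: int) -> list:
    groups: dict = {}
    order: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            if ftype == "gene":
                continue
            kind = _GFF_KIND.get(ftype, "unknown")
            if kind == "unknown":
                warnings.warn(f"{path}:{lineno}: skipping unknown type {ftype}")
                continue
            if kind is None and ftype == "exon":
                continue
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            name = attr.get("gene") or attr.get("Name") or attr.get("Parent") \
                or attr.get("ID")
            if name is None:
                raise ValueError(f"{path}:{lineno}: feature without identifier")
            start_i, end_i = int(start), int(end)
            if end_i > genome_length:
                raise ValueError(
                    f"{path}:{lineno}: feature end {end_i} exceeds genome "
                    f"length {genome_length}")
            iv = GenomeInterval(start_i - 1, end_i, strand,
                                genome_length=genome_length)
            key = attr.get("Parent") or attr.get("ID") or name
            if key not in groups:
                groups[key] = (name, kind, strand, [])
                order.append(key)
            groups[key][3].append(iv)
    features = []
    for key in order:
        name, kind, strand, exons = groups[key]
        exons.sort(key=lambda e: e.start)
        if strand == "-":
            exons = exons[::-1]  # 5'->3' on the coding strand
        features.append(GeneFeature(name=name, kind=kind,
                                    exons=tuple(exons), strand=strand))
    return features


def write_gff3(record: PlastomeRecord, path) -> None:
    n = len(record)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {record.id} 1 {n}\n")
        for i, f in enumerate(record.features):
            gid = f"{f.name}.{i}"
            ftype = _KIND_TO_GFF[f.kind]
            exons = list(f.exons)
            span_lo = min(e.start for e in exons)
            span_hi = max(e.end for e in exons)
            fh.write("\t".join([
                record.id, "plastomekit", "gene", str(span_lo + 1),
                str(span_hi), ".", f.strand, ".",
                f"ID=gene-{gid};Name={f.name}"]) + "\n")
            for e in exons:
                fh.write("\t".join([
                    record.id, "plastomekit", ftype, str(e.start + 1),
                    str(e.end), ".", f.strand, "0" if ftype == "CDS" else ".",
                    f"ID=cds-{gid};Parent=gene-{gid};gene={f.name}"]) + "\n")


def _read_genbank(path, genome_length: int) -> list:
    features = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "genbank"):
            n = genome_length or len(rec.seq)
            for feat in rec.features:
                kind = _GFF_KIND.get(feat.type, "unknown")
                if feat.type == "gene" or kind is None:
                    continue
                if kind == "unknown":
                    warnings.warn(f"skipping unknown feature type {feat.type}")
                    continue
                name = (feat.qualifiers.get("gene") or
                        feat.qualifiers.get("locus_tag") or ["?"])[0]
                strand = "-" if feat.location.strand == -1 else "+"
                exons = []
                for part in feat.location.parts:
                    if int(part.end) > n:
                        raise ValueError(
                            f"feature {name} exceeds sequence length {n}")
                    exons.append(GenomeInterval(int(part.start), int(part.end),
                                                strand, genome_length=n))
                exons.sort(key=lambda e: e.start)
                if strand == "-":
                    exons = exons[::-1]
                features.append(GeneFeature(name=name, kind=kind,
                                            exons=tuple(exons), strand=strand))
    return features


def read_fastq(path) -> list:
    """Read FASTQ (Phred+33) into (name, sequence) tuples."""
    reads = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            reads.append((rec.id, str(rec.seq).upper()))
    return reads


def write_fastq(reads, path) -> None:
    """Write (name, sequence) tuples as FASTQ with uniform high quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
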