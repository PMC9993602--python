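"""Whole-genome-set orchestration: structure -> repeats -> genes -> synteny.

``run_pipeline`` consumes a RunConfig, runs each requested stage over
the genome set and writes TSV/JSON reports plus a provenance block with
every effective parameter. Determinism: identical config and seed give
identical report content.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io as pio
from .align import ScoringScheme
from .genes import call_genes, gene_matrix, genome_word_index
from .ir import detect_inverted_repeat, junction_context, partition_table
from .isomer import build_isomer, count_spanning_reads, junction_windows
from .model import GenomeInterval
from .repeats import find_repeats, hotspot_summary, localize_repeats
from .synteny import (build_blocks, classify_structural_types,
                      signed_permutation, strip_second_ir)

log = logging.getLogger("plastomekit")


@dataclass
class RunConfig:
    fasta: list
    gff: list = field(default_factory=list)
    queries: str | None = None  # reference gene FASTA for gene calling
    out_dir: str = "plastomekit_out"
    seed: int = 0
    min_ir_len: int = 100
    residual_threshold: int = 2000
    min_repeat_len: int = 30
    exclude_ir: bool = True
    upstream_window: int = 1000
    intact_cov: float = 0.90
    frag_cov: float = 0.20
    synteny_k: int = 21
    min_block_len: int = 500
    max_anchor_gap: int = 2000
    isomer_repeat: tuple | None = None  # ((s1, e1), (s2, e2)) on fasta[0]
    long_reads: str | None = None
    flank: int = 1000
    min_identity: float = 0.8

    def validate(self) -> None:
        if not self.fasta:
            raise ValueError("no input genomes")
        for p in list(self.fasta) + list(self.gff):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def run_pipeline(config: RunConfig) -> dict:
    """Run all applicable stages; returns the consolidated report dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"provenance": _provenance(config)}

    records = []
    for i, fp in enumerate(config.fasta):
        recs = pio.read_sequences(fp)
        gff = config.gff[i] if i < len(config.gff) else None
        for rec in recs:
            if gff:
                rec.features = pio.read_annotations(gff, len(rec))
            records.append(rec)
    log.info("loaded %d genomes", len(records))

    partitions = [detect_inverted_repeat(
        r, min_ir_len=config.min_ir_len,
        residual_threshold=config.residual_threshold) for r in records]
    table = partition_table(records, partitions)
    table.to_csv(out / "partition_table.tsv", sep="\t", index=False)
    report["partition_table"] = table.to_dict("records")

    junctions = {}
    for rec, part in zip(records, partitions):
        if part.structure_class != "ir_free" and rec.features:
            junctions[rec.id] = [asdict(j) for j in
                                 junction_context(part, rec.features)]
    (out / "junctions.json").write_text(json.dumps(junctions, indent=1))
    report["junctions"] = junctions

    all_localizations = []
    repeat_rows = []
    for rec, part in zip(records, partitions):
        catalog = find_repeats(rec, min_len=config.min_repeat_len,
                               exclude_ir=config.exclude_ir, partition=part)
        locs = localize_repeats(catalog, rec.features,
                                upstream_window=config.upstream_window)
        all_localizations.extend(locs)
        for loc in locs:
            repeat_rows.append({
                "genome": rec.id, "unit_id": loc.copy.unit_id,
                "start": loc.copy.interval.start,
                "end": loc.copy.interval.end,
                "strand": loc.copy.interval.strand,
                "context": loc.context, "anchor_gene": loc.anchor_gene,
                "distance": loc.distance})
    _write_tsv(out / "repeat_catalog.tsv", repeat_rows)
    hs = hotspot_summary(all_localizations)
    report["repeat_hotspots"] = {"total_copies": hs.total_copies,
                                 "per_gene_percent": hs.per_gene_percent}
    (out / "hotspots.json").write_text(json.dumps(
        report["repeat_hotspots"], indent=1))

    if config.queries:
        queries = [(r.id, r.sequence.residues, "PCG")
                   for r in pio.read_sequences(config.queries)]
        calls = {}
        for rec in records:
            calls[rec.id] = call_genes(
                queries, rec, ScoringScheme(),
                intact_cov=config.intact_cov, frag_cov=config.frag_cov)
        matrix = gene_matrix(calls)
        matrix.to_csv(out / "gene_matrix.tsv", sep="\t")
        report["gene_matrix"] = matrix.to_dict()

    if len(records) > 1:
        reduced = [strip_second_ir(r, p)
                   for r, p in zip(records, partitions)]
        ref = reduced[0]
        perms = {}
        for other in reduced:
            blocks = build_blocks(ref, other, k=config.synteny_k,
                                  min_block_len=config.min_block_len,
                                  max_anchor_gap=config.max_anchor_gap)
            perms[other.id] = signed_permutation(blocks)
        types = classify_structural_types(perms)
        report["structural_types"] = [
            {"label": t.label, "members": list(t.members),
             "permutation": list(t.permutation.signed_ids)} for t in types]
        (out / "structural_types.json").write_text(
            json.dumps(report["structural_types"], indent=1))

    if config.isomer_repeat and config.long_reads:
        rec = records[0]
        n = len(rec)
        (s1, e1), (s2, e2) = config.isomer_repeat
        pair = build_isomer(rec,
                            GenomeInterval(s1, e1, "+", genome_length=n),
                            GenomeInterval(s2, e2, "-", genome_length=n))
        windows = junction_windows(pair, flank=config.flank)
        reads = pio.read_fastq(config.long_reads)
        support = count_spanning_reads(windows, reads,
                                       min_identity=config.min_identity)
        report["isomer_support"] = {
            "counts": {f"isomer{i}_{s}": c
                       for (i, s), c in support.counts.items()},
            "mean_isomer1": support.mean1, "mean_isomer2": support.mean2,
            "isomer2_frequency_percent": support.frequency_percent,
            "ambiguous_reads": support.ambiguous,
            "total_reads": support.total_reads}
        (out / "isomer_support.json").write_text(
            json.dumps(report["isomer_support"], indent=1))

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _provenance(config: RunConfig) -> dict:
    d = asdict(config)
    d["package"] = "plastomekit"
    from . import __version__
    d["version"] = __version__
    return d


def _write_tsv(path, rows) -> None:
    import pandas as pd
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
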