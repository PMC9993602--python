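import numpy as np
import pytest

from plastomekit.ir import (QuadripartitePartition, compare_boundaries,
                            detect_inverted_repeat, gc_percent,
                            junction_context, partition_table)
from plastomekit.model import (GeneFeature, GenomeInterval,
                               NucleotideSequence, PlastomeRecord,
                               reverse_complement)
from plastomekit.simulate import SyntheticSpec, generate_plastome, random_sequence

from oracles import brute_maximal_pairs


def _record(seq):
    return PlastomeRecord("t", NucleotideSequence(seq))


class TestDetectInvertedRepeat:
    def test_random_circle_is_ir_free(self, rng):
        rec = _record(random_sequence(rng, 10000))
        part = detect_inverted_repeat(rec, min_ir_len=100)
        assert part.structure_class == "ir_free"
        assert part.ir_length == 0
        assert len(part.lsc) == 10000 and part.ssc is None

    def test_planted_pair_recovered_exactly(self, rng):
        core = random_sequence(rng, 1500)
        lsc = random_sequence(rng, 12000)
        ssc = random_sequence(rng, 5000)
        # pin the four junction-adjacent bases so the planted pair cannot
        # extend by chance and the true maximal pair is exactly the plant
        lsc = "A" + lsc[1:-1] + "A"
        ssc = "A" + ssc[1:-1] + "A"
        seq = lsc + core + ssc + reverse_complement(core)
        part = detect_inverted_repeat(_record(seq), min_ir_len=100)
        assert part.structure_class == "residual_ir"
        assert (part.irb.start, part.irb.end) == (12000, 13500)
        assert (part.ira.start, part.ira.end) == (18500, 20000)
        assert (part.lsc.start, len(part.lsc)) == (20000 % 20000, 12000)
        assert (part.ssc.start, len(part.ssc)) == (13500, 5000)

    def test_agrees_with_brute_force_on_miniature(self, rng):
        # 2 kb circle: the detector's seed-and-extend pair must equal the
        # longest disjoint inverted pair from full diagonal scanning
        core = random_sequence(rng, 150)
        seq = (random_sequence(rng, 700) + core + random_sequence(rng, 500)
               + reverse_complement(core) + random_sequence(rng, 550))
        _, inverted = brute_maximal_pairs(seq, 100)
        best = max(inverted, key=lambda t: t[2])
        part = detect_inverted_repeat(_record(seq), min_ir_len=100)
        a, b, length = best
        assert part.ir_length == length
        assert {part.irb.start, part.ira.start} == {a, b}

    def test_linear_sequence_rejected(self):
        rec = PlastomeRecord("t", NucleotideSequence("ACGT" * 200,
                                                     circular=False))
        with pytest.raises(ValueError):
            detect_inverted_repeat(rec)

    @pytest.mark.parametrize("ir_len", [300, 1000, 10000])
    def test_tiling_invariant(self, ir_len, rng):
        spec = SyntheticSpec(seed=int(rng.integers(2 ** 31)), lsc_len=30000,
                             ssc_len=9000, ir_len=ir_len)
        rec, _ = generate_plastome(spec)
        part = detect_inverted_repeat(rec)
        total = len(part.lsc) + len(part.ssc) + 2 * part.ir_length
        assert total == len(rec)
        ivs = [part.lsc, part.ssc, part.irb, part.ira]
        for i, x in enumerate(ivs):
            for y in ivs[i + 1:]:
                assert not x.overlaps(y)

    def test_orientation_canonicalization(self):
        spec = SyntheticSpec(seed=5, lsc_len=12000, ssc_len=4000,
                             ir_len=1500)
        rec, _ = generate_plastome(spec)
        part = detect_inverted_repeat(rec)
        n = len(rec)
        shift = part.ssc.start + len(part.ssc) // 2  # new origin inside SSC
        s = rec.sequence.residues
        rotated = _record(s[shift:] + s[:shift])
        part2 = detect_inverted_repeat(rotated)
        assert part2.ir_length == part.ir_length
        # map the rotated partition back into the original frame
        def back(iv):
            return ((iv.start + shift) % n, (iv.end - 1 + shift) % n + 1)
        assert back(part2.irb) == (part.irb.start, part.irb.end)
        assert back(part2.ira) == (part.ira.start, part.ira.end)
        assert back(part2.ssc) == (part.ssc.start, part.ssc.end)


def _manual_partition(n, lsc, irb, ssc, ira, ir_length):
    mk = lambda t: GenomeInterval(t[0], t[1], "+", genome_length=n)
    return QuadripartitePartition(mk(lsc), mk(ssc), mk(irb), mk(ira),
                                  ir_length, "quadripartite", n)


def _gene(name, start, end, n, strand="+", kind="PCG"):
    return GeneFeature(name, kind,
                       (GenomeInterval(start, end, strand, genome_length=n),),
                       strand)


class TestJunctionContext:
    def test_spanning_gene(self):
        n = 20000
        part = _manual_partition(n, (0, 12000), (12000, 15000),
                                 (15000, 17000), (17000, 20000), 3000)
        feats = [_gene("rps19", 11900, 12100, n)]  # straddles JLB at 12000
        ctx = {c.junction_id: c for c in junction_context(part, feats)}
        assert ctx["JLB"].spanning_gene == "rps19"

    def test_gene_ending_exactly_at_junction_is_nearest_not_spanning(self):
        n = 20000
        part = _manual_partition(n, (0, 12000), (12000, 15000),
                                 (15000, 17000), (17000, 20000), 3000)
        feats = [_gene("rpl2", 11700, 12000, n)]
        ctx = {c.junction_id: c for c in junction_context(part, feats)}
        assert ctx["JLB"].spanning_gene is None
        left, right = ctx["JLB"].nearest_gene_each_side
        assert left == ("rpl2", 0)

    def test_ir_capture_places_genes_inside_ira(self):
        # emulate an IR expanded over the trnH-psbA-matK-trnK block
        from plastomekit.simulate import GeneSpec
        spec = SyntheticSpec(
            seed=9, lsc_len=14000, ssc_len=5000, ir_len=3000,
            genes=(GeneSpec("trnH", "tRNA", "IR", 75),
                   GeneSpec("psbA", "PCG", "IR", 500),
                   GeneSpec("matK", "PCG", "IR", 500),
                   GeneSpec("trnK", "tRNA", "IR", 75)))
        rec, _ = generate_plastome(spec)
        part = detect_inverted_repeat(rec)
        from plastomekit.ir import genes_in_ir
        assert genes_in_ir(part, rec.features) == {"trnH", "psbA", "matK",
                                                   "trnK"}
        ira_names = {f.name for f in rec.features
                     if part.ira.contains_position(f.span.start)}
        assert ira_names == {"trnH", "psbA", "matK", "trnK"}

    def test_empty_features_warns(self):
        n = 20000
        part = _manual_partition(n, (0, 12000), (12000, 15000),
                                 (15000, 17000), (17000, 20000), 3000)
        with pytest.warns(UserWarning):
            ctx = junction_context(part, [])
        assert all(c.spanning_gene is None for c in ctx)


class TestCompareBoundaries:
    n = 20000

    def _ref(self):
        part = _manual_partition(self.n, (0, 12000), (12000, 15000),
                                 (15000, 17000), (17000, 20000), 3000)
        feats = [_gene("rpl2", 12100, 12400, self.n),
                 _gene("trnM", 12500, 12575, self.n, kind="tRNA")]
        return part, feats

    def test_identity_is_unchanged(self):
        ref = self._ref()
        shifts = compare_boundaries(ref, ref)
        assert all(s.direction == "unchanged" for s in shifts)
        assert all(not s.genes_gained_by_ir and not s.genes_lost_by_ir
                   for s in shifts)

    def test_contraction_lists_lost_gene(self):
        ref = self._ref()
        tgt_part = _manual_partition(self.n, (0, 12450), (12450, 15000),
                                     (15000, 17450), (17450, 20000), 2550)
        tgt = (tgt_part, ref[1])
        shifts = {s.junction_id: s for s in compare_boundaries(tgt, ref)}
        assert shifts["JLB"].direction == "contraction"
        assert shifts["JLB"].genes_lost_by_ir == ("rpl2",)
        assert shifts["JSB"].direction == "unchanged"

    def test_expansion_lists_exactly_the_captured_genes(self):
        part = _manual_partition(self.n, (0, 12000), (12000, 15000),
                                 (15000, 17000), (17000, 20000), 3000)
        names = [f"g{i}" for i in range(7)]
        feats = [_gene(nm, 5200 + 800 * i, 5200 + 800 * i + 400, self.n)
                 for i, nm in enumerate(names)]
        ref = (part, feats)
        tgt_part = _manual_partition(self.n, (0, 5000), (5000, 15000),
                                     (15000, 17000), (17000, 20000), 10000)
        shifts = {s.junction_id: s
                  for s in compare_boundaries((tgt_part, feats), ref)}
        assert shifts["JLB"].direction == "expansion"
        assert shifts["JLB"].genes_gained_by_ir == tuple(sorted(names))

    def test_disjoint_nomenclature_errors(self):
        ref = self._ref()
        other = (ref[0], [_gene("zzz", 100, 200, self.n)])
        with pytest.raises(ValueError):
            compare_boundaries(other, ref)


class TestPartitionTable:
    def test_gc_values(self):
        assert gc_percent("GGCC") == 100.00
        assert gc_percent("ATGC") == 50.00

    def test_table_contents(self, small_quadripartite):
        rec, man = small_quadripartite
        df = partition_table([rec])
        row = df.iloc[0]
        assert row["genome_size"] == len(rec)
        assert row["ir"] == man["partition"]["ir_length"]
        assert row["lsc"] + row["ssc"] + 2 * row["ir"] == row["genome_size"]
        assert 30.0 < row["gc_percent"] < 45.0
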