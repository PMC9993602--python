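import numpy as np
import pytest

from plastomekit.model import reverse_complement
from plastomekit.simulate import (GeneSpec, ReadSimSpec, SyntheticSpec,
                                  apply_rearrangement, fixture_suite,
                                  generate_plastome, random_orf,
                                  simulate_long_reads)


class TestGeneratePlastome:
    def test_table_spec_lengths(self):
        # the partition arithmetic of the two extreme observed genomes
        spec = SyntheticSpec(seed=1, lsc_len=53377, ssc_len=23778,
                             ir_len=33169)
        rec, man = generate_plastome(spec)
        assert len(rec) == 143493
        spec = SyntheticSpec(seed=1, lsc_len=81002, ssc_len=28512,
                             ir_len=437)
        rec, _ = generate_plastome(spec)
        assert len(rec) == 110388

    def test_ir_zero_gives_ir_free_genome(self):
        from plastomekit.ir import detect_inverted_repeat
        spec = SyntheticSpec(seed=2, lsc_len=30000, ssc_len=10000, ir_len=0)
        rec, _ = generate_plastome(spec)
        assert detect_inverted_repeat(rec).structure_class == "ir_free"

    def test_same_seed_is_byte_identical(self):
        spec = SyntheticSpec(seed=3, lsc_len=20000, ssc_len=8000,
                             ir_len=2000,
                             genes=(GeneSpec("rbcL", "PCG", "LSC", 600),))
        r1, m1 = generate_plastome(spec)
        r2, m2 = generate_plastome(spec)
        assert r1.sequence.residues == r2.sequence.residues
        assert m1 == m2

    def test_ira_is_reverse_complement_of_irb(self):
        spec = SyntheticSpec(seed=4, lsc_len=20000, ssc_len=8000,
                             ir_len=3000)
        rec, man = generate_plastome(spec)
        s = rec.sequence.residues
        irb = s[slice(*man["partition"]["irb"])]
        ira = s[slice(*man["partition"]["ira"])]
        assert ira == reverse_complement(irb)

    def test_infeasible_gene_placement_names_gene(self):
        spec = SyntheticSpec(seed=5, lsc_len=2000, ssc_len=500, ir_len=0,
                             genes=(GeneSpec("huge", "PCG", "SSC", 3000),))
        with pytest.raises(ValueError, match="huge"):
            generate_plastome(spec)

    def test_repeat_overlapping_gene_rejected(self):
        spec = SyntheticSpec(seed=6, lsc_len=10000, ssc_len=3000, ir_len=0,
                             genes=(GeneSpec("rbcL", "PCG", "LSC", 600),),
                             planted_repeats=((40, ((300, "+"),
                                                    (5000, "+"))),))
        with pytest.raises(ValueError, match="rbcL"):
            generate_plastome(spec)

    def test_manifest_coordinates_reread_through_io(self, tmp_path):
        from plastomekit import io as pio
        spec = SyntheticSpec(seed=7, lsc_len=15000, ssc_len=5000,
                             ir_len=2000,
                             genes=(GeneSpec("rbcL", "PCG", "LSC", 600),
                                    GeneSpec("ndhF", "PCG", "SSC", 450,
                                             strand="-")))
        rec, man = generate_plastome(spec)
        pio.write_sequences([rec], tmp_path / "g.fasta")
        pio.write_gff3(rec, tmp_path / "g.gff3")
        rec2 = pio.read_sequences(tmp_path / "g.fasta")[0]
        feats = pio.read_annotations(tmp_path / "g.gff3", len(rec2))
        by_name = {f.name: f for f in feats}
        for g in man["genes"]:
            s, e, strand = g["intervals"][0]
            f = by_name[g["name"]]
            assert f.span.start == s and f.span.end == e
            assert f.strand == strand


class TestApplyRearrangement:
    def _rec(self, n=30000, seed=8):
        spec = SyntheticSpec(seed=seed, lsc_len=n - 5000, ssc_len=5000,
                             ir_len=0)
        return generate_plastome(spec)[0]

    def test_empty_script_is_identity(self):
        rec = self._rec()
        out, perm = apply_rearrangement(rec, [])
        assert out.sequence.residues == rec.sequence.residues
        assert perm == (1,)

    def test_single_inversion_permutation(self):
        rec = self._rec()
        _, perm = apply_rearrangement(rec, [("inversion", 5000, 12000)])
        assert perm == (1, -2, 3)

    def test_inverse_script_restores_sequence(self):
        rec = self._rec()
        mid, _ = apply_rearrangement(rec, [("inversion", 5000, 12000)])
        back, _ = apply_rearrangement(mid, [("inversion", 5000, 12000)])
        assert back.sequence.residues == rec.sequence.residues

    def test_composition_matches_independent_tracking(self):
        # compose the same events on an abstract signed list and compare
        rec = self._rec()
        script = [("inversion", 5000, 12000),
                  ("translocation", 20000, 25000, 2000)]
        _, perm = apply_rearrangement(rec, script)
        assert perm == (1, 5, 2, -3, 4, 6)

    def test_out_of_range_event_rejected(self):
        rec = self._rec()
        with pytest.raises(ValueError):
            apply_rearrangement(rec, [("inversion", 100, 99999999)])


class TestSimulateLongReads:
    def _pair(self):
        from plastomekit.simulate import isomer_fixture
        return isomer_fixture(seed=23)[0]

    def test_proportion_zero_all_tagged_isomer1(self):
        pair = self._pair()
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=1, n_reads=100, min_len=1000, max_len=2000,
            isomer2_proportion=0.0))
        assert all("tmpl=isomer1" in name for name, _ in reads)

    def test_tagged_isomer2_count_is_binomial(self):
        pair = self._pair()
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=2, n_reads=10000, min_len=1000, max_len=2000,
            isomer2_proportion=0.01))
        n2 = sum(1 for name, _ in reads if "tmpl=isomer2" in name)
        se = np.sqrt(10000 * 0.01 * 0.99)
        assert abs(n2 - 100) <= 3 * se

    def test_error_free_reads_are_exact_circular_substrings(self):
        pair = self._pair()
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=3, n_reads=50, min_len=1000, max_len=3000))
        doubled = {1: pair.isomer1.sequence.residues * 2,
                   2: pair.isomer2.sequence.residues * 2}
        for name, seq in reads:
            tmpl = 2 if "tmpl=isomer2" in name else 1
            probe = seq if "strand=+" in name else reverse_complement(seq)
            assert probe in doubled[tmpl]

    def test_error_rates_change_reads(self):
        pair = self._pair()
        clean = simulate_long_reads(pair, ReadSimSpec(
            seed=4, n_reads=10, min_len=1000, max_len=1500))
        noisy = simulate_long_reads(pair, ReadSimSpec(
            seed=4, n_reads=10, min_len=1000, max_len=1500,
            mismatch=0.05, insertion=0.02, deletion=0.02))
        assert any(c[1] != n[1] for c, n in zip(clean, noisy))

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            ReadSimSpec(seed=1, n_reads=10, mismatch=0.5)


class TestFixtureSuite:
    def test_suite_contents(self):
        suite = fixture_suite(seed=0)
        # (a) partition specs reproduce their genome sizes
        from plastomekit.ir import detect_inverted_repeat
        for spec, (rec, man) in suite["partitions"]:
            assert len(rec) == spec.genome_length
        # (b) five statuses present
        _, manifest, _ = suite["gene_status"]
        statuses = {g["status"] for g in manifest["genes"]}
        assert statuses == {"intact", "pseudogene_truncated",
                            "pseudogene_premature_stop", "fragment",
                            "absent"}
        # (c) 14 genomes over 5 arrangements
        genomes, truth = suite["rearrangement"]
        assert len(genomes) == 14 and len(set(truth.values())) == 5
        # (d) isomer scenario dimensions
        pair, man = suite["isomer"]
        iso = man["isomer_repeat"]
        assert iso["length"] == 679
        assert iso["copy2"][0] - iso["copy1"][1] == 60000

    def test_isomer_fixture_repeat_found_by_catalog(self):
        from plastomekit.ir import detect_inverted_repeat
        from plastomekit.repeats import find_repeats
        suite = fixture_suite(seed=0)
        pair, man = suite["isomer"]
        part = detect_inverted_repeat(pair.isomer1)
        cat = find_repeats(pair.isomer1, min_len=30, exclude_ir=True,
                           partition=part)
        assert cat.n_units == 1
        unit = cat.units[0]
        assert unit.length >= 679
        assert sorted(c.interval.strand for c in cat.copies) == ["+", "-"]
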