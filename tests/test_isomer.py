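import numpy as np
import pytest

from plastomekit.isomer import (build_isomer, count_spanning_reads,
                                junction_windows,
                                short_read_configuration_check)
from plastomekit.model import (GenomeInterval, NucleotideSequence,
                               PlastomeRecord, reverse_complement)
from plastomekit.simulate import (ReadSimSpec, random_sequence,
                                  simulate_long_reads)


def _mini_pair(rng, rep_len=120, span=3000, genome=12000):
    """Small flip-flop scenario for fast unit tests."""
    unit = random_sequence(rng, rep_len)
    s1 = 1000
    s2 = s1 + rep_len + span
    seq = list(random_sequence(rng, genome))
    seq[s1:s1 + rep_len] = list(unit)
    seq[s2:s2 + rep_len] = list(reverse_complement(unit))
    rec = PlastomeRecord("mini", NucleotideSequence("".join(seq)))
    r1 = GenomeInterval(s1, s1 + rep_len, "+", genome_length=genome)
    r2 = GenomeInterval(s2, s2 + rep_len, "-", genome_length=genome)
    return build_isomer(rec, r1, r2), unit


class TestBuildIsomer:
    def test_flip_is_involution(self, rng):
        pair, _ = _mini_pair(rng)
        again = build_isomer(pair.isomer2, pair.repeat1, pair.repeat2)
        assert again.isomer2.sequence.residues == \
            pair.isomer1.sequence.residues

    def test_difference_is_exactly_the_bracketed_segment(self, rng):
        pair, _ = _mini_pair(rng)
        s1, s2 = pair.isomer1.sequence.residues, \
            pair.isomer2.sequence.residues
        assert len(s1) == len(s2)
        diff = [i for i in range(len(s1)) if s1[i] != s2[i]]
        lo, hi = pair.repeat1.end, pair.repeat2.start
        assert diff and lo <= min(diff) and max(diff) < hi
        assert s2[lo:hi] == reverse_complement(s1[lo:hi])

    def test_repeat_copies_conserved_in_both_isomers(self, rng):
        pair, unit = _mini_pair(rng)
        for rec in (pair.isomer1, pair.isomer2):
            s = rec.sequence.residues
            assert s[pair.repeat1.start:pair.repeat1.end] == unit
            assert s[pair.repeat2.start:pair.repeat2.end] == \
                reverse_complement(unit)

    def test_direct_pair_rejected(self, rng):
        unit = random_sequence(rng, 100)
        seq = list(random_sequence(rng, 8000))
        seq[1000:1100] = list(unit)
        seq[5000:5100] = list(unit)  # direct, not inverted
        rec = PlastomeRecord("d", NucleotideSequence("".join(seq)))
        with pytest.raises(ValueError):
            build_isomer(rec,
                         GenomeInterval(1000, 1100, "+", genome_length=8000),
                         GenomeInterval(5000, 5100, "+", genome_length=8000))


class TestJunctionWindows:
    def test_window_length_arithmetic(self, isomer_pair_fixture):
        pair, man = isomer_pair_fixture
        windows = junction_windows(pair, flank=1000)
        assert len(windows) == 4
        assert all(len(w.sequence) == 679 + 2000 for w in windows)

    def test_windows_share_core_and_differ_in_one_flank(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        w = {(x.isomer, x.side): x for x in junction_windows(pair, flank=400)}
        w1, w2 = w[(1, "left")], w[(2, "left")]
        core = slice(400, 520)
        assert w1.sequence[core] == w2.sequence[core]
        assert w1.sequence[:400] == w2.sequence[:400]  # distal flank shared
        assert w1.sequence[520:] != w2.sequence[520:]  # proximal differs

    def test_zero_flank_rejected(self, rng):
        pair, _ = _mini_pair(rng)
        with pytest.raises(ValueError):
            junction_windows(pair, flank=0)

    def test_overlapping_windows_rejected(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=600)
        with pytest.raises(ValueError):
            junction_windows(pair, flank=2000)


class TestCountSpanningReads:
    def test_pure_isomer1_reads_give_zero_frequency(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        windows = junction_windows(pair, flank=400)
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=1, n_reads=400, min_len=2000, max_len=4000,
            isomer2_proportion=0.0))
        sup = count_spanning_reads(windows, reads)
        assert sup.mean2 == 0
        assert sup.frequency_percent == 0.0
        assert sup.mean1 > 0

    def test_short_reads_never_counted(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        windows = junction_windows(pair, flank=400)
        # shorter than repeat + 2*flank = 920
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=2, n_reads=300, min_len=400, max_len=900))
        sup = count_spanning_reads(windows, reads)
        assert all(c == 0 for c in sup.counts.values())
        assert sup.frequency_percent is None

    def test_empty_read_set(self, rng):
        pair, _ = _mini_pair(rng)
        windows = junction_windows(pair, flank=400)
        sup = count_spanning_reads(windows, [])
        assert sup.frequency_percent is None and sup.total_reads == 0

    def test_balanced_mixture_recovered(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        windows = junction_windows(pair, flank=400)
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=3, n_reads=600, min_len=2000, max_len=4000,
            isomer2_proportion=0.5))
        sup = count_spanning_reads(windows, reads)
        n_span = 2 * (sup.mean1 + sup.mean2)
        se = 100 * np.sqrt(0.25 / n_span)
        assert abs(sup.frequency_percent - 50.0) <= 3 * se

    def test_counted_reads_match_template_truth(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        windows = junction_windows(pair, flank=400)
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=4, n_reads=400, min_len=2000, max_len=4000,
            isomer2_proportion=0.3))
        # count each tagged subset separately: no read may support the
        # configuration it was not drawn from
        iso1_reads = [r for r in reads if "tmpl=isomer1" in r[0]]
        iso2_reads = [r for r in reads if "tmpl=isomer2" in r[0]]
        assert count_spanning_reads(windows, iso1_reads).mean2 == 0
        assert count_spanning_reads(windows, iso2_reads).mean1 == 0

    def test_flank_monotonicity(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=5, n_reads=300, min_len=1500, max_len=3000,
            isomer2_proportion=0.5))
        totals = []
        for flank in (200, 400, 700):
            windows = junction_windows(pair, flank=flank)
            sup = count_spanning_reads(windows, reads)
            totals.append(sum(sup.counts.values()))
        assert totals == sorted(totals, reverse=True)

    def test_noisy_reads_still_assigned(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        windows = junction_windows(pair, flank=400)
        reads = simulate_long_reads(pair, ReadSimSpec(
            seed=6, n_reads=120, min_len=2000, max_len=3500,
            mismatch=0.03, insertion=0.01, deletion=0.01,
            isomer2_proportion=0.0))
        sup = count_spanning_reads(windows, reads)
        assert sup.mean1 > 0
        assert sup.mean2 == 0


class TestShortReadCheck:
    def _pairs_from(self, rec, rng, n, insert, read_len):
        s2 = rec.sequence.residues * 2
        n_genome = len(rec)
        out = []
        for _ in range(n):
            start = int(rng.integers(n_genome))
            frag = s2[start:start + insert]
            out.append((frag[:read_len],
                        reverse_complement(frag[-read_len:])))
        return out

    def test_single_configuration(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        windows = junction_windows(pair, flank=400)
        pairs = self._pairs_from(pair.isomer1, rng, 800, insert=500,
                                 read_len=120)
        res = short_read_configuration_check(windows, pairs)
        assert res == {1: True, 2: False}

    def test_both_configurations(self, rng):
        pair, _ = _mini_pair(rng, rep_len=120, span=3000)
        windows = junction_windows(pair, flank=400)
        pairs = (self._pairs_from(pair.isomer1, rng, 700, 500, 120)
                 + self._pairs_from(pair.isomer2, rng, 700, 500, 120))
        res = short_read_configuration_check(windows, pairs)
        assert res == {1: True, 2: True}

    def test_insert_shorter_than_repeat_cannot_straddle(self, rng):
        pair, _ = _mini_pair(rng, rep_len=300, span=3000)
        windows = junction_windows(pair, flank=400)
        pairs = self._pairs_from(pair.isomer1, rng, 300, insert=250,
                                 read_len=80)
        with pytest.warns(UserWarning):
            res = short_read_configuration_check(windows, pairs)
        assert res == {1: False, 2: False}

    def test_unpaired_input_rejected(self, rng):
        pair, _ = _mini_pair(rng)
        windows = junction_windows(pair, flank=400)
        with pytest.raises(ValueError):
            short_read_configuration_check(windows, [("ACGT",)])
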