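import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circkit.circ_model import CircRNA
from circkit.degradome import (
    CleavagePeak,
    FivePrimePileup,
    JunctionReference,
    binomial_peak_pvalue,
    build_5p_pileup,
    build_junction_reference,
    call_degradome_peaks,
    locate_peak_vs_circ,
    map_junction_spanning_reads,
)
from circkit.errors import (
    ChromMismatch,
    EmptyPileup,
    InvalidParameters,
    PositionOutOfRange,
    ReadTooShort,
)
from circkit.io_formats import AlignedRead, GenomicInterval, SequenceRecord
from circkit.sequtil import periodic_slice

from oracles import binomial_tail_sum, brute_force_peaks


def _read(pos, n_hits=1, ref="t1", strand="+", rid="r", length=20):
    if strand == "+":
        iv = GenomicInterval(ref, pos, pos + length, strand)
    else:
        iv = GenomicInterval(ref, pos - length + 1, pos + 1, strand)
    return AlignedRead(rid, iv, n_hits=n_hits)


class TestPileup:
    def test_unique_read_weight_one(self):
        piles = build_5p_pileup([_read(100)], {"t1": 500})
        assert piles[("t1", "+")].weights[100] == 1.0

    def test_multimapper_quarter_weights(self):
        reads = [_read(p, n_hits=4, rid="r1") for p in (10, 50, 90, 130)]
        piles = build_5p_pileup(reads, {"t1": 500})
        w = piles[("t1", "+")].weights
        for p in (10, 50, 90, 130):
            assert w[p] == 0.25

    def test_weight_conservation(self, rng):
        reads = []
        for i in range(50):
            n = int(rng.integers(1, 5))
            for _ in range(n):
                reads.append(
                    _read(int(rng.integers(0, 480)), n_hits=n, rid=f"r{i}")
                )
        piles = build_5p_pileup(reads, {"t1": 500})
        total = sum(p.total for p in piles.values())
        assert total == pytest.approx(50.0, abs=1e-9)

    def test_strands_separate(self):
        piles = build_5p_pileup(
            [_read(100, strand="+"), _read(100, strand="-")], {"t1": 500}
        )
        assert set(piles) == {("t1", "+"), ("t1", "-")}

    def test_out_of_range(self):
        with pytest.raises(PositionOutOfRange):
            build_5p_pileup([_read(100)], {"t1": 50})


class TestBinomialTail:
    def test_single_trial(self):
        assert binomial_peak_pvalue(1, 1, 0.5) == pytest.approx(0.5)

    def test_k_equals_n(self):
        for n, p0 in ((5, 0.3), (10, 0.01), (7, 0.9)):
            assert binomial_peak_pvalue(n, n, p0) == pytest.approx(
                p0 ** n, rel=1e-12
            )

    def test_against_summation_oracle(self):
        assert binomial_peak_pvalue(6, 10, 0.01) == pytest.approx(
            binomial_tail_sum(6, 10, 0.01), abs=1e-12
        )

    def test_k_zero_is_one(self):
        assert binomial_peak_pvalue(0, 10, 0.2) == pytest.approx(1.0)

    @given(n=st.integers(1, 100), p0=st.sampled_from([1 / 21, 0.01, 0.5]))
    @settings(max_examples=50)
    def test_monotone_in_k(self, n, p0):
        vals = [binomial_peak_pvalue(k, n, p0) for k in range(n + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameters):
            binomial_peak_pvalue(5, 4, 0.5)
        with pytest.raises(InvalidParameters):
            binomial_peak_pvalue(1, 1, 0.0)


def _pileup(weights, ref="t1", strand="+"):
    w = np.asarray(weights, dtype=float)
    return FivePrimePileup(ref, strand, len(w), w)


class TestPeakCalling:
    def test_dominant_position_called(self):
        w = np.zeros(200)
        w[100] = 6.0
        for off in (-8, -3, 4, 9):
            w[100 + off] = 1.0
        peaks = call_degradome_peaks(_pileup(w))
        assert [p.position for p in peaks] == [100]
        assert peaks[0].fraction == pytest.approx(0.6)

    def test_uniform_pileup_no_peaks(self):
        assert call_degradome_peaks(_pileup(np.ones(100))) == []

    def test_empty_pileup_raises(self):
        with pytest.raises(EmptyPileup):
            call_degradome_peaks(_pileup(np.zeros(50)))

    def test_emitted_peaks_satisfy_thresholds(self, rng):
        w = rng.poisson(0.3, 300).astype(float)
        w[50] = 40
        for p in call_degradome_peaks(_pileup(w)):
            assert p.fraction >= 0.5
            assert p.p_value <= 0.05

    @pytest.mark.parametrize("null_mode", ["transcript", "window"])
    def test_matches_brute_force(self, rng, null_mode):
        for _ in range(20):
            L = int(rng.integers(30, 300))
            w = np.zeros(L)
            n_reads = int(rng.integers(1, 40))
            positions = rng.integers(0, L, n_reads)
            hits = rng.integers(1, 5, n_reads)
            for p, n in zip(positions, hits):
                w[p] += 1.0 / n
            peaks = call_degradome_peaks(_pileup(w), null_mode=null_mode)
            expect = brute_force_peaks(w, null_mode=null_mode)
            assert [p.position for p in peaks] == expect

    def test_edge_window_truncated_denominator(self):
        # single read at position 0: window denominator restricted, fraction 1
        w = np.zeros(100)
        w[0] = 30.0
        (peak,) = call_degradome_peaks(_pileup(w))
        assert peak.position == 0
        assert peak.fraction == 1.0


class TestPeakLocation:
    def _circ(self, strand="+"):
        iv = GenomicInterval("chr1", 100, 200, strand)
        return CircRNA(id="c", interval=iv, exons=[iv])

    def _peak(self, pos, ref="chr1"):
        return CleavagePeak(ref, pos, 1, 1, 1.0, 0.01)

    def test_within(self):
        assert locate_peak_vs_circ(self._peak(150), self._circ()) == "within"

    def test_upstream_plus(self):
        assert locate_peak_vs_circ(self._peak(50), self._circ()) == "upstream"

    def test_upstream_minus(self):
        assert locate_peak_vs_circ(self._peak(250), self._circ("-")) == "upstream"

    def test_downstream_minus(self):
        assert locate_peak_vs_circ(self._peak(50), self._circ("-")) == "downstream"

    def test_chrom_mismatch(self):
        with pytest.raises(ChromMismatch):
            locate_peak_vs_circ(self._peak(50, ref="chr2"), self._circ())


class TestJunctionReference:
    def _circ_seq(self, genome, start, end):
        iv = GenomicInterval("chr1", start, end, "+")
        return CircRNA(id="c", interval=iv, exons=[iv])

    def test_long_circle(self, toy_genome):
        circ = self._circ_seq(toy_genome, 0, 200)
        ref = build_junction_reference(circ, toy_genome)
        s = toy_genome["chr1"][0:200]
        assert ref.seq == s[150:200] + s[0:50]
        assert ref.junction_offset == 50
        assert len(ref.seq) == 100

    def test_short_circle_cap(self, toy_genome):
        circ = self._circ_seq(toy_genome, 0, 60)
        ref = build_junction_reference(circ, toy_genome)
        assert ref.junction_offset == 30
        assert len(ref.seq) == 60

    def test_periodicity_oracle(self, toy_genome, rng):
        for _ in range(20):
            start = int(rng.integers(0, 1000))
            length = int(rng.integers(40, 400))
            circ = self._circ_seq(toy_genome, start, start + length)
            s = toy_genome["chr1"][start : start + length]
            ref = build_junction_reference(circ, toy_genome)
            f = ref.junction_offset
            # read across the junction == periodic extension of the circle
            assert ref.seq == periodic_slice(s, len(s) - f, 2 * f)


class TestJunctionMapping:
    @pytest.fixture
    def ref(self, toy_genome):
        s = toy_genome["chr1"][0:200]
        return JunctionReference("c1", s[150:200] + s[0:50], 50)

    def test_spanning_read_hit(self, ref):
        read = SequenceRecord("r1", ref.seq[45:65])
        (hit,) = map_junction_spanning_reads([read], [ref])
        assert (hit.overhang_left, hit.overhang_right) == (5, 15)
        assert hit.start == 45
        assert hit.mismatches == 0

    def test_one_sided_read_no_hit(self, ref):
        read = SequenceRecord("r1", ref.seq[0:30])
        assert map_junction_spanning_reads([read], [ref]) == []

    def test_two_mismatches_rejected(self, ref):
        s = list(ref.seq[40:70])
        s[5] = "A" if s[5] != "A" else "C"
        s[20] = "A" if s[20] != "A" else "C"
        read = SequenceRecord("r1", "".join(s))
        assert map_junction_spanning_reads([read], [ref], max_mismatch=1) == []
        hits = map_junction_spanning_reads([read], [ref], max_mismatch=2)
        assert hits and hits[0].mismatches == 2

    def test_read_too_short(self, ref):
        with pytest.raises(ReadTooShort):
            map_junction_spanning_reads(
                [SequenceRecord("r1", "ACGTACG")], [ref], min_overhang=5
            )

    def test_leftmost_on_ties(self):
        ref = JunctionReference("c", "ACGT" * 10, 20)
        read = SequenceRecord("r", "ACGTACGTACGT")
        (hit,) = map_junction_spanning_reads([read], [ref], min_overhang=4)
        # earliest offset satisfying both overhangs
        assert hit.start == 12

    def test_recall_on_simulated_reads(self, toy_genome, rng):
        s = toy_genome["chr1"][300:520]
        ref = JunctionReference("c", s[-50:] + s[:50], 50)
        reads = []
        for i in range(30):
            start = int(rng.integers(35, 46))
            reads.append(SequenceRecord(f"jx{i}", ref.seq[start : start + 20]))
        hits = map_junction_spanning_reads(reads, [ref])
        assert {h.read_id for h in hits} == {f"jx{i}" for i in range(30)}
        # reads straight from the linear sequence across the same locus: no hits
        linear = [
            SequenceRecord(f"lin{i}", toy_genome["chr1"][500 + i : 520 + i])
            for i in range(10)
        ]
        assert map_junction_spanning_reads(linear, [ref]) == []
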