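"""Degradome analysis: weighted 5'-end pileups, windowed cleavage-peak
calling with binomial significance, peak localization relative to circRNA
bodies, and back-splice-junction-spanning decay-read detection.

A mapped read contributes 1/n_hits of weight at its 5'-end position, keeping
strands separate. A position is a cleavage peak when it holds at least
``min_fraction`` of the weight in the centered 21-nt window (10 nt each
side, truncated at reference ends) and its rounded count passes an exact
upper-tail binomial test at ``alpha``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .circ_model import CircRNA
from .errors import (
    ChromMismatch,
    EmptyPileup,
    InvalidParameters,
    PositionOutOfRange,
    ReadTooShort,
    SequenceUnavailable,
)
from .io_formats import AlignedRead, SequenceRecord

log = logging.getLogger(__name__)


@dataclass
class FivePrimePileup:
    ref: str
    strand: str
    length: int
    weights: np.ndarray

    @property
    def total(self) -> float:
        return float(self.weights.sum())


@dataclass
class CleavagePeak:
    ref: str
    position: int
    weight: float
    window_total: float
    fraction: float
    p_value: float
    strand: str = "+"
    location_class: str = "NA"


@dataclass(frozen=True)
class JunctionReference:
    circ_id: str
    seq: str
    junction_offset: int


@dataclass(frozen=True)
class JunctionHit:
    read_id: str
    circ_id: str
    start: int
    overhang_left: int
    overhang_right: int
    mismatches: int


# ---------------------------------------------------------------------------
# Pileups
# ---------------------------------------------------------------------------

def build_5p_pileup(
    reads: Iterable[AlignedRead], ref_lengths: Mapping[str, int]
) -> dict[tuple[str, str], FivePrimePileup]:
    """Accumulate 1/n_hits weight at each read's 5'-end position.

    Returns one pileup per (reference, strand). Total weight over all pileups
    equals the number of distinct contributing reads when every locus of each
    multi-mapper is present.
    """
    piles: dict[tuple[str, str], np.ndarray] = {}
    for read in reads:
        ref = read.interval.chrom
        if ref not in ref_lengths:
            raise PositionOutOfRange(f"unknown reference {ref!r}")
        length = ref_lengths[ref]
        pos = read.five_prime
        if not 0 <= pos < length:
            raise PositionOutOfRange(
                f"5' end {pos} outside {ref} (length {length})"
            )
        key = (ref, read.interval.strand)
        if key not in piles:
            piles[key] = np.zeros(length)
        piles[key][pos] += 1.0 / read.n_hits
    return {
        key: FivePrimePileup(key[0], key[1], len(w), w) for key, w in piles.items()
    }


# ---------------------------------------------------------------------------
# Binomial significance
# ---------------------------------------------------------------------------

def binomial_peak_pvalue(k: int, n: int, p0: float) -> float:
    """Exact upper-tail probability P(X >= k) for X ~ Binomial(n, p0)."""
    if n < 1 or not 0 <= k <= n or not 0.0 < p0 < 1.0:
        raise InvalidParameters(f"k={k}, n={n}, p0={p0}")
    return float(stats.binom.sf(k - 1, n, p0))


def _round_half_up(x: float) -> int:
    # the 1e-9 guard keeps exact-half weights (e.g. sums of 1/3) from
    # rounding differently depending on float summation order
    return int(math.floor(x + 0.5 + 1e-9))


# ---------------------------------------------------------------------------
# Peak calling
# ---------------------------------------------------------------------------

def call_degradome_peaks(
    pileup: FivePrimePileup,
    half_window: int = 10,
    min_fraction: float = 0.5,
    alpha: float = 0.05,
    null_mode: str = "transcript",
    bh_correct: bool = False,
) -> list[CleavagePeak]:
    """Call cleavage peaks on one pileup.

    Position i is emitted iff w_i / (window sum over [i-hw, i+hw], truncated
    at the reference ends) >= min_fraction, and the exact binomial upper tail
    of the rounded counts is <= alpha. The null is uniform decay over the
    transcript (p0 = 1/L, N = rounded total) by default, or uniform within
    the window (p0 = 1/(2*hw+1), N = rounded window total) in window mode.
    Peak p-values are left uncorrected unless ``bh_correct`` is set.
    """
    w = pileup.weights
    total = float(w.sum())
    if total <= 0:
        raise EmptyPileup(f"pileup {pileup.ref}/{pileup.strand} has no weight")
    if null_mode not in ("transcript", "window"):
        raise InvalidParameters(f"null_mode {null_mode!r}")
    L = pileup.length
    win = np.convolve(w, np.ones(2 * half_window + 1), mode="same")
    n_total = _round_half_up(total)

    candidates: list[CleavagePeak] = []
    for i in np.nonzero(w > 0)[0]:
        frac = float(w[i]) / float(win[i])
        if frac < min_fraction - 1e-12:
            continue
        k = _round_half_up(float(w[i]))
        if null_mode == "transcript":
            n, p0 = n_total, 1.0 / L
        else:
            n, p0 = _round_half_up(float(win[i])), 1.0 / (2 * half_window + 1)
        if k < 1 or n < 1:
            continue
        k = min(k, n)  # rounding can put k one above n at window edges
        p = binomial_peak_pvalue(k, n, p0)
        candidates.append(
            CleavagePeak(
                ref=pileup.ref,
                position=int(i),
                weight=float(w[i]),
                window_total=float(win[i]),
                fraction=frac,
                p_value=p,
                strand=pileup.strand,
            )
        )
    if bh_correct and candidates:
        from .circ_model import bh_fdr

        adj = bh_fdr([c.p_value for c in candidates])
        for c, q in zip(candidates, adj):
            c.p_value = q
    return [c for c in candidates if c.p_value <= alpha]


def locate_peak_vs_circ(peak: CleavagePeak, circ: CircRNA) -> str:
    """Classify a peak as upstream/within/downstream of a circRNA body in
    transcription direction (on -, genomic positions beyond the end are
    upstream)."""
    iv = circ.interval
    if peak.ref != iv.chrom:
        raise ChromMismatch(f"{peak.ref} vs {iv.chrom}")
    pos = peak.position
    if iv.start <= pos < iv.end:
        return "within"
    if pos < iv.start:
        return "upstream" if iv.strand == "+" else "downstream"
    return "downstream" if iv.strand == "+" else "upstream"


# ---------------------------------------------------------------------------
# Back-splice junction references and spanning reads
# ---------------------------------------------------------------------------

def build_junction_reference(
    circ: CircRNA, genome: Mapping[str, str], flank: int = 50
) -> JunctionReference:
    """Concatenate the circle's terminal and initial sequence across the
    back-splice point: last f nt + first f nt of the spliced circle, with
    f = min(flank, floor(L/2)) so short circles never duplicate content."""
    try:
        s = circ.spliced_sequence(genome)
    except KeyError as exc:
        raise SequenceUnavailable(f"no sequence for {circ.interval.chrom}") from exc
    if not s:
        raise SequenceUnavailable(f"empty spliced sequence for {circ.id}")
    f = min(flank, len(s) // 2)
    if f == 0:
        raise SequenceUnavailable(f"circle {circ.id} too short for a junction")
    return JunctionReference(circ.id, s[-f:] + s[:f], f)


def map_junction_spanning_reads(
    reads: Sequence[SequenceRecord],
    refs: Sequence[JunctionReference],
    max_mismatch: int = 1,
    min_overhang: int = 5,
) -> list[JunctionHit]:
    """Ungapped scan of sense reads against junction references.

    A hit requires <= max_mismatch mismatches over the full read and at
    least ``min_overhang`` bases on each side of the junction. A read that
    matches a reference equally well at several offsets reports the leftmost.
    """
    hits = []
    for read in reads:
        if len(read.seq) < 2 * min_overhang:
            raise ReadTooShort(
                f"read {read.id} shorter than 2 x min_overhang"
            )
        for ref in refs:
            best = None  # (mismatches, start)
            rlen = len(read.seq)
            for start in range(0, len(ref.seq) - rlen + 1):
                left = ref.junction_offset - start
                right = start + rlen - ref.junction_offset
                if left < min_overhang or right < min_overhang:
                    continue
                mm = _count_mismatches(read.seq, ref.seq, start, max_mismatch)
                if mm <= max_mismatch and (best is None or mm < best[0]):
                    best = (mm, start)
            if best is not None:
                mm, start = best
                hits.append(
                    JunctionHit(
                        read_id=read.id,
                        circ_id=ref.circ_id,
                        start=start,
                        overhang_left=ref.junction_offset - start,
                        overhang_right=start + rlen - ref.junction_offset,
                        mismatches=mm,
                    )
                )
    return hits


def _count_mismatches(read: str, ref: str, start: int, cap: int) -> int:
    mm = 0
    for i, base in enumerate(read):
        if base != ref[start + i]:
            mm += 1
            if mm > cap:
                break
    return mm
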