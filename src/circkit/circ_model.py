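"""circRNA typing, alternative back-splicing classification, quantification,
differential expression, and expression-profile correlation.

Conventions
-----------
The circle's donor boundary (its 3' end in transcript orientation) is the
genomic end on the + strand and the genomic start on the - strand; the
acceptor boundary is the opposite bound. Alternative back-splicing labels
are assigned per unordered pair with A5BS/A3BS taking precedence over MIC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import (
    BoundaryMismatch,
    ConstantVector,
    StrandMismatch,
    ZeroLibrary,
)
from .io_formats import GenomicInterval, TranscriptModel

log = logging.getLogger(__name__)

ECIRC = "ecircRNA"
CIRNA = "ciRNA"
INTERGENIC = "intergenic"


@dataclass
class CircRNA:
    id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    host_gene_id: Optional[str] = None
    circ_type: Optional[str] = None
    junction_reads: float = 0.0

    def __post_init__(self):
        for e in self.exons:
            if not self.interval.contains(e):
                from .errors import BlockSumMismatch

                raise BlockSumMismatch(f"exon {e} outside circle {self.id}")

    @property
    def donor(self) -> int:
        """Genomic coordinate of the back-splice donor boundary (circle 3')."""
        return self.interval.end if self.interval.strand == "+" else self.interval.start

    @property
    def acceptor(self) -> int:
        """Genomic coordinate of the back-splice acceptor boundary (circle 5')."""
        return self.interval.start if self.interval.strand == "+" else self.interval.end

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        from .sequtil import revcomp

        chrom_seq = genome[self.interval.chrom]
        s = "".join(chrom_seq[e.start : e.end] for e in self.exons)
        return revcomp(s) if self.interval.strand == "-" else s


@dataclass
class DEResult:
    id: str
    fold_change: float
    p_value: float
    fdr: float
    direction: str  # up / down / ns


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_circ_type(circ: CircRNA, models: Sequence[TranscriptModel]) -> str:
    """ecircRNA if the circle overlaps any same-strand annotated exon;
    otherwise ciRNA if it lies fully inside a single same-strand intron;
    otherwise intergenic."""
    iv = circ.interval
    in_intron = False
    for m in models:
        if m.interval.chrom != iv.chrom or m.strand != iv.strand:
            continue
        for e in m.exons:
            if e.overlaps(iv):
                return ECIRC
        if not in_intron:
            for intr in m.introns():
                if intr.contains(iv):
                    in_intron = True
                    break
    return CIRNA if in_intron else INTERGENIC


def classify_alt_backsplicing(
    circs: Sequence[CircRNA],
) -> list[tuple[tuple[str, str], str]]:
    """Label each unordered pair of same-gene circRNAs as A5BS, A3BS, or MIC.

    A5BS: shared donor, differing acceptor. A3BS: shared acceptor, differing
    donor. MIC: partial interval overlap (neither contains the other) with at
    least one mutually exclusive exon on each side. At most one label per
    pair; A5BS/A3BS take precedence over MIC.
    """
    strands = {c.interval.strand for c in circs}
    if len(strands) > 1:
        raise StrandMismatch(f"mixed strands in gene group: {strands}")
    out = []
    for i in range(len(circs)):
        for j in range(i + 1, len(circs)):
            a, b = circs[i], circs[j]
            if a.interval.chrom != b.interval.chrom:
                continue
            label = None
            if a.donor == b.donor and a.acceptor != b.acceptor:
                label = "A5BS"
            elif a.acceptor == b.acceptor and a.donor != b.donor:
                label = "A3BS"
            elif (
                a.interval.overlaps(b.interval)
                and not a.interval.contains(b.interval)
                and not b.interval.contains(a.interval)
                and _has_exclusive_exon(a, b)
                and _has_exclusive_exon(b, a)
            ):
                label = "MIC"
            if label:
                out.append(((a.id, b.id), label))
    return out


def _has_exclusive_exon(a: CircRNA, b: CircRNA) -> bool:
    """True if some exon of ``a`` overlaps no exon of ``b``."""
    return any(not any(ea.overlaps(eb) for eb in b.exons) for ea in a.exons)


def classify_internal_as(
    chains: Sequence[Sequence[GenomicInterval]], strand: str = "+"
) -> list[str]:
    """Classify internal AS differences between isoform exon chains sharing
    both back-splice sites.

    Returns accumulated labels from {A3SS, A5SS, ExonS, IntronR} over all
    chain pairs. Which shifted boundary counts as acceptor (A3SS) vs donor
    (A5SS) side is strand-aware: on + the exon start is the acceptor.
    """
    chains = [sorted(c, key=lambda e: e.start) for c in chains]
    outer = {(c[0].start, c[-1].end) for c in chains}
    if len(outer) > 1:
        raise BoundaryMismatch(f"outer boundaries differ: {outer}")
    labels: list[str] = []
    for i in range(len(chains)):
        for j in range(i + 1, len(chains)):
            labels.extend(_compare_chains(chains[i], chains[j], strand))
    return labels


def _compare_chains(a, b, strand) -> set[str]:
    labels: set[str] = set()
    for first, second in ((a, b), (b, a)):
        for e in first:
            partners = [x for x in second if x.overlaps(e)]
            if not partners:
                labels.add("ExonS")
            elif len(partners) > 1:
                # one exon continuous across an intron spliced in the other
                labels.add("IntronR")
            else:
                p = partners[0]
                if sum(1 for y in first if y.overlaps(p)) > 1:
                    continue  # p retains an intron; labeled from the other side
                if e.start != p.start:
                    labels.add("A3SS" if strand == "+" else "A5SS")
                if e.end != p.end:
                    labels.add("A5SS" if strand == "+" else "A3SS")
    return labels


# ---------------------------------------------------------------------------
# Quantification / differential expression
# ---------------------------------------------------------------------------

def rpm_normalize(
    counts: Mapping[str, Mapping[str, float]] | "np.ndarray",
    mapped_totals: Mapping[str, float] | Sequence[float],
):
    """Normalize junction read counts to reads per million mapped reads.

    ``counts`` maps row id -> {sample -> count}; ``mapped_totals`` maps
    sample -> library size. value = count / (total / 1e6).
    """
    if isinstance(counts, np.ndarray):
        totals = np.asarray(mapped_totals, dtype=float)
        if np.any(totals <= 0):
            raise ZeroLibrary("mapped total <= 0")
        return counts / (totals / 1e6)
    out: dict[str, dict[str, float]] = {}
    for rid, row in counts.items():
        out[rid] = {}
        for sample, count in row.items():
            total = mapped_totals[sample]
            if total <= 0:
                raise ZeroLibrary(f"mapped total <= 0 for sample {sample}")
            out[rid][sample] = count / (total / 1e6)
    return out


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out.tolist()


def fold_change(rpm_treatment: float, rpm_control: float, pseudocount: float = 0.5) -> float:
    """Treatment/control RPM ratio. The pseudocount is applied to both sides
    only when one side is zero, so non-degenerate ratios stay exact and
    reciprocity holds either way."""
    if rpm_treatment < 0 or rpm_control < 0:
        raise ValueError("negative RPM")
    if min(rpm_treatment, rpm_control) == 0.0:
        return (rpm_treatment + pseudocount) / (rpm_control + pseudocount)
    return rpm_treatment / rpm_control


def two_proportion_binomial_p(k1: int, k2: int, n1: float, n2: float) -> float:
    """Exact two-sided binomial test of k1 successes out of k1+k2 trials with
    success probability n1/(n1+n2). Deliberate stand-in for the original
    count-based DE test; documented as a substitution."""
    if n1 <= 0 or n2 <= 0:
        raise ZeroLibrary("library size <= 0")
    n = k1 + k2
    if n == 0:
        return 1.0
    p0 = n1 / (n1 + n2)
    return stats.binomtest(k1, n=n, p=p0, alternative="two-sided").pvalue


def differential_circrnas(
    counts_treatment: Mapping[str, float],
    counts_control: Mapping[str, float],
    total_treatment: float,
    total_control: float,
    fc_cutoff: float = 2.0,
    p_cutoff: float = 0.01,
    fdr_cutoff: float = 0.01,
) -> list[DEResult]:
    """Two-condition differential expression on pooled junction counts.

    Fold change is computed on RPM (treatment/control); p-values come from
    the exact two-proportion binomial comparison; FDR is Benjamini-Hochberg.
    direction is 'up'/'down' only under the triple cutoff
    (FC >= cutoff or <= 1/cutoff, p < p_cutoff, FDR <= fdr_cutoff).
    """
    if total_treatment <= 0 or total_control <= 0:
        raise ZeroLibrary("mapped total <= 0")
    ids = sorted(set(counts_treatment) | set(counts_control))
    fcs, ps = [], []
    for rid in ids:
        kt = counts_treatment.get(rid, 0)
        kc = counts_control.get(rid, 0)
        rpm_t = kt / (total_treatment / 1e6)
        rpm_c = kc / (total_control / 1e6)
        fcs.append(fold_change(rpm_t, rpm_c))
        ps.append(
            two_proportion_binomial_p(
                int(round(kt)), int(round(kc)), total_treatment, total_control
            )
        )
    fdrs = bh_fdr(ps)
    out = []
    for rid, fc, p, q in zip(ids, fcs, ps, fdrs):
        direction = "ns"
        if p < p_cutoff and q <= fdr_cutoff:
            if fc >= fc_cutoff:
                direction = "up"
            elif fc <= 1.0 / fc_cutoff:
                direction = "down"
        out.append(DEResult(rid, fc, p, q, direction))
    return out


def pearson_profile(
    x: Sequence[float], y: Sequence[float], threshold: float = 0.5
) -> tuple[float, bool]:
    """Sample Pearson r plus a high-correlation flag (|r| >= threshold)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("vectors must share a length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVector("Pearson r undefined for constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    return r, abs(r) >= threshold
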