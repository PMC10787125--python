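"""Readers/writers for external formats and the shared coordinate types.

All internal coordinates are 0-based half-open. GFF3/GTF (1-based inclusive)
and SAM (1-based) are converted at the boundary; BED is already half-open.
Sequence input is normalized to uppercase DNA with U mapped to T.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pysam

from .errors import (
    BlockSumMismatch,
    CoordinateError,
    EmptySequence,
    InconsistentHitCount,
    MalformedFasta,
    MissingHeader,
    OrphanExon,
    StrandMissing,
)
from .sequtil import normalize_seq, revcomp

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise MalformedFasta("empty record id")
        if len(self.seq) < 1:
            raise EmptySequence(f"record {self.id!r} has no sequence")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0:
            raise CoordinateError(f"negative start: {self}")
        if self.end <= self.start:
            raise CoordinateError(f"end <= start: {self}")
        if self.strand not in ("+", "-"):
            raise StrandMissing(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    gene_id: str
    transcript_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval]
    cds: Optional[tuple[int, int]] = None  # transcript coordinates, half-open

    def __post_init__(self):
        exons = sorted(self.exons, key=lambda e: e.start)
        prev_end = None
        for e in exons:
            if e.chrom != self.interval.chrom or e.strand != self.interval.strand:
                raise CoordinateError(
                    f"exon {e} off-transcript for {self.transcript_id}"
                )
            if e.start < self.interval.start or e.end > self.interval.end:
                raise CoordinateError(
                    f"exon {e} outside transcript interval for {self.transcript_id}"
                )
            if prev_end is not None and e.start < prev_end:
                raise CoordinateError(
                    f"overlapping exons in {self.transcript_id}"
                )
            prev_end = e.end
        self.exons = exons
        if self.cds is not None:
            cs, ce = self.cds
            if not (0 <= cs < ce <= self.exonic_length):
                raise CoordinateError(
                    f"CDS {self.cds} outside transcript {self.transcript_id}"
                )

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.interval.chrom, a.end, b.start, self.strand)
                )
        return out

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position (0-based, must be exonic) to a transcript
        coordinate counted from the transcript 5' end."""
        off = 0
        for e in self.exons:
            if e.start <= gpos < e.end:
                t_plus = off + (gpos - e.start)
                if self.strand == "+":
                    return t_plus
                return self.exonic_length - 1 - t_plus
            off += e.length
        raise CoordinateError(f"{gpos} is not exonic in {self.transcript_id}")

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.exonic_length:
            raise CoordinateError(f"transcript position {tpos} out of range")
        t_plus = tpos if self.strand == "+" else self.exonic_length - 1 - tpos
        off = 0
        for e in self.exons:
            if t_plus < off + e.length:
                return e.start + (t_plus - off)
            off += e.length
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.interval.chrom]
        s = "".join(chrom_seq[e.start : e.end] for e in self.exons)
        return revcomp(s) if self.strand == "-" else s


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    interval: GenomicInterval
    n_hits: int = 1
    mismatches: int = 0

    def __post_init__(self):
        if self.n_hits < 1:
            raise InconsistentHitCount(f"n_hits < 1 for {self.read_id}")

    @property
    def five_prime(self) -> int:
        """Mapped 5'-end position: leftmost base on +, rightmost base on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized SequenceRecords (U->T, uppercase)."""
    records: list[SequenceRecord] = []
    header = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise EmptySequence(f"record {header!r} has no sequence")
        try:
            records.append(SequenceRecord(header, normalize_seq(seq)))
        except ValueError as exc:
            raise MalformedFasta(f"record {header!r}: {exc}") from exc

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                if not header:
                    raise MalformedFasta("empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise MalformedFasta("sequence data before any header")
                chunks.append(line)
        flush()
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 70,
                descriptions: Optional[Mapping[str, str]] = None) -> None:
    with open(path, "w") as fh:
        for rec in records:
            desc = f" {descriptions[rec.id]}" if descriptions and rec.id in descriptions else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path) -> list[SequenceRecord]:
    records = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 4 != 0:
        raise MalformedFasta("FASTQ record count not a multiple of 4")
    for i in range(0, len(lines), 4):
        if not lines[i].startswith("@"):
            raise MalformedFasta(f"bad FASTQ header line: {lines[i]!r}")
        records.append(SequenceRecord(lines[i][1:].split()[0], normalize_seq(lines[i + 1])))
    return records


def read_reads(path) -> list[SequenceRecord]:
    """Read FASTA or FASTQ, sniffing the first character."""
    with open(path) as fh:
        first = fh.read(1)
    return read_fastq(path) if first == "@" else read_fasta(path)


# ---------------------------------------------------------------------------
# GFF3 / GTF gene models
# ---------------------------------------------------------------------------

def _parse_attrs(raw: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    if "=" in raw and '"' not in raw:  # GFF3 style
        for part in raw.strip().split(";"):
            part = part.strip()
            if part and "=" in part:
                k, v = part.split("=", 1)
                attrs[k.strip()] = v.strip()
    else:  # GTF style
        for part in raw.strip().split(";"):
            part = part.strip()
            if not part:
                continue
            bits = part.split(None, 1)
            if len(bits) == 2:
                attrs[bits[0]] = bits[1].strip().strip('"')
    return attrs


_TRANSCRIPT_TYPES = {"mrna", "transcript"}


def read_gene_models(path, strict: bool = False) -> list[TranscriptModel]:
    """Parse gene models from GFF3 or GTF into TranscriptModels.

    File coordinates (1-based inclusive) are converted to internal 0-based
    half-open. CDS features are mapped to transcript coordinates. ``strict``
    additionally enforces that the CDS length is a codon multiple.
    """
    tx_meta: "OrderedDict[str, dict]" = OrderedDict()
    exons: dict[str, list[GenomicInterval]] = {}
    cds_parts: dict[str, list[GenomicInterval]] = {}
    id_to_gene: dict[str, str] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise CoordinateError(f"{path}:{lineno}: fewer than 9 columns")
            chrom, _src, ftype, start_s, end_s, _score, strand, _frame, raw = cols[:9]
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise CoordinateError(f"{path}:{lineno}: end < start")
            start, end = start1 - 1, end1
            attrs = _parse_attrs(raw)
            ftl = ftype.lower()
            if ftl == "gene":
                gid = attrs.get("ID") or attrs.get("gene_id")
                if gid:
                    id_to_gene[gid] = gid
            elif ftl in _TRANSCRIPT_TYPES:
                tid = attrs.get("ID") or attrs.get("transcript_id")
                gid = attrs.get("Parent") or attrs.get("gene_id") or tid
                if tid is None:
                    raise OrphanExon(f"{path}:{lineno}: transcript without an id")
                tx_meta[tid] = {
                    "gene": gid,
                    "interval": GenomicInterval(chrom, start, end, strand),
                }
            elif ftl in ("exon", "cds"):
                parent = attrs.get("Parent") or attrs.get("transcript_id")
                if parent is None:
                    raise OrphanExon(f"{path}:{lineno}: {ftype} without a parent")
                iv = GenomicInterval(chrom, start, end, strand)
                target = exons if ftl == "exon" else cds_parts
                for pid in parent.split(","):
                    target.setdefault(pid, []).append(iv)
                    if pid not in tx_meta:
                        gid = attrs.get("gene_id")
                        tx_meta[pid] = {"gene": gid or pid, "interval": None}

    models: list[TranscriptModel] = []
    for tid, meta in tx_meta.items():
        ex = sorted(exons.get(tid, []), key=lambda e: e.start)
        interval = meta["interval"]
        if not ex:
            if interval is None:
                continue
            ex = [interval]
        if interval is None:
            interval = GenomicInterval(
                ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand
            )
        model = TranscriptModel(meta["gene"], tid, interval, ex)
        parts = cds_parts.get(tid)
        if parts:
            tpos = []
            for p in parts:
                tpos.append(model.genomic_to_transcript(p.start))
                tpos.append(model.genomic_to_transcript(p.end - 1))
            cs, ce = min(tpos), max(tpos) + 1
            if strict and (ce - cs) % 3 != 0:
                raise CoordinateError(
                    f"CDS length of {tid} not divisible by 3"
                )
            model.cds = (cs, ce)
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# circRNA tables (BED6 / BED12 dialect)
# ---------------------------------------------------------------------------

def read_circ_table(path) -> list:
    """Read a BED6/BED12-dialect circRNA table.

    Column 5 (score) carries the back-splice junction read count. 12-column
    rows define the exon chain from blockSizes/blockStarts; 6-column rows get
    a single-exon chain spanning the interval.
    """
    from .circ_model import CircRNA

    circs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise StrandMissing(f"{path}:{lineno}: fewer than 6 columns")
            chrom, start_s, end_s, name, score_s, strand = cols[:6]
            if strand not in ("+", "-"):
                raise StrandMissing(f"{path}:{lineno}: strand {strand!r}")
            start, end = int(start_s), int(end_s)
            interval = GenomicInterval(chrom, start, end, strand)
            reads = float(score_s) if score_s not in (".", "") else 0.0
            if len(cols) >= 12:
                n_blocks = int(cols[9])
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                starts = [int(x) for x in cols[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise BlockSumMismatch(
                        f"{path}:{lineno}: block count disagrees with fields"
                    )
                chain = []
                for bs, sz in zip(starts, sizes):
                    if bs + sz > end - start:
                        raise BlockSumMismatch(
                            f"{path}:{lineno}: block exceeds interval"
                        )
                    chain.append(
                        GenomicInterval(chrom, start + bs, start + bs + sz, strand)
                    )
            else:
                chain = [interval]
            circs.append(
                CircRNA(
                    id=name,
                    interval=interval,
                    exons=chain,
                    junction_reads=reads,
                )
            )
    return circs


def write_circ_table(path, circs) -> None:
    """Write circRNAs as BED12 (score column = junction read count)."""
    with open(path, "w") as fh:
        for c in circs:
            iv = c.interval
            sizes = ",".join(str(e.length) for e in c.exons)
            starts = ",".join(str(e.start - iv.start) for e in c.exons)
            score = c.junction_reads
            score_s = str(int(score)) if float(score) == int(score) else repr(score)
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        c.id,
                        score_s,
                        iv.strand,
                        str(iv.start),
                        str(iv.end),
                        "0",
                        str(len(c.exons)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# SAM alignments -> 5' ends
# ---------------------------------------------------------------------------

def read_alignments_5p(path, strict: bool = False) -> list[AlignedRead]:
    """Read SAM alignments as AlignedReads carrying hit counts.

    The mapped span excludes soft clips (pysam reference coordinates).
    ``n_hits`` comes from the NH tag when present, otherwise it defaults to
    the number of mapped records sharing the read id. Unmapped records are
    skipped with a logged count.
    """
    path = str(path)
    with open(path) as fh:
        first = fh.read(1)
    if first != "@":
        raise MissingHeader(f"{path}: SAM file does not start with a header")

    raw: list[tuple[str, str, int, int, str, Optional[int], int]] = []
    n_unmapped = 0
    with pysam.AlignmentFile(path, "r") as sam:
        for rec in sam:
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            nh = rec.get_tag("NH") if rec.has_tag("NH") else None
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            raw.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                    nh,
                    int(nm),
                )
            )
    if n_unmapped:
        log.info("skipped %d unmapped records", n_unmapped)

    per_read: dict[str, int] = {}
    for name, *_ in raw:
        per_read[name] = per_read.get(name, 0) + 1

    reads = []
    for name, chrom, start, end, strand, nh, nm in raw:
        observed = per_read[name]
        if nh is not None and strict and nh != observed:
            raise InconsistentHitCount(
                f"read {name}: NH={nh} but {observed} records"
            )
        reads.append(
            AlignedRead(
                read_id=name,
                interval=GenomicInterval(chrom, start, end, strand),
                n_hits=int(nh) if nh is not None else observed,
                mismatches=nm,
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Coordinate conversion helpers (GFF boundary)
# ---------------------------------------------------------------------------

def to_gff_coords(interval: GenomicInterval) -> tuple[int, int]:
    """Internal half-open -> GFF 1-based inclusive."""
    return interval.start + 1, interval.end


def from_gff_coords(chrom: str, start1: int, end1: int, strand: str) -> GenomicInterval:
    """GFF 1-based inclusive -> internal half-open."""
    if end1 < start1:
        raise CoordinateError(f"end < start: {start1}..{end1}")
    return GenomicInterval(chrom, start1 - 1, end1, strand)
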