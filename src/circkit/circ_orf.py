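"""Rolling-circle ORF prediction from circRNAs, uORF/dORF/pORF annotation on
linear transcripts, and unique-peptide support filtering.

circRNA ORFs are found by scanning the 4x-concatenated spliced sequence on
the sense strand in all three frames; an ORF whose periodic reading frame
never reaches a stop codon is a rolling ORF, reported once with its peptide
truncated at four copies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import CircleTooShort, EmptySequence, InvalidCDS
from .sequtil import CODON_TABLE, STOP_CODONS, translate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OpenReadingFrame:
    source_id: str
    kind: str  # cORF / uORF / dORF / pORF
    frame: int
    start: int  # nucleotide start in source coordinates (mod circle length for cORFs)
    aa_length: int
    peptide: str
    spans_junction: bool = False
    rolling: bool = False

    @property
    def orf_id(self) -> str:
        return f"{self.source_id}:{self.kind}:{self.start}"


@dataclass
class PeptideRecord:
    sequence: str
    matched_orf_ids: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Rolling-circle ORFs
# ---------------------------------------------------------------------------

def rolling_circle_seq(circ_spliced_seq: str, copies: int = 4) -> str:
    """Exact ``copies``-fold concatenation of the spliced circle sequence."""
    if not circ_spliced_seq:
        raise EmptySequence("empty circle sequence")
    return circ_spliced_seq * copies


def find_corfs(
    circ_spliced_seq: str, min_aa: int = 10, source_id: str = "circ"
) -> list[OpenReadingFrame]:
    """ATG->stop ORFs of the circular sequence, read over 4 concatenated
    copies on the sense strand.

    Each circular start position (< L) is scanned once, so ORFs repeated
    across copies are reported a single time. ``min_aa`` is a strict
    threshold (aa_length > min_aa). An ORF with no stop codon anywhere in
    its periodic frame is emitted once with ``rolling=True`` and its peptide
    truncated at the 4-copy boundary.
    """
    s = circ_spliced_seq
    L = len(s)
    if L < 3:
        raise CircleTooShort(f"circle of {L} nt")
    # Two extra bases let a stop codon that straddles the 4L boundary be seen:
    # any stop reachable from a start < L begins no later than 4L - 4.
    scan = s * 4 + s[:2]
    four_l = 4 * L
    orfs: list[OpenReadingFrame] = []
    for start in range(L):
        if scan[start : start + 3] != "ATG":
            continue
        aas = []
        pos = start
        stopped = False
        while pos + 3 <= len(scan):
            codon = scan[pos : pos + 3]
            if codon in STOP_CODONS:
                stopped = True
                break
            aas.append(CODON_TABLE.get(codon, "X"))
            pos += 3
        if stopped:
            peptide = "".join(aas)
            end = pos + 3
            if len(peptide) > min_aa:
                orfs.append(
                    OpenReadingFrame(
                        source_id=source_id,
                        kind="cORF",
                        frame=start % 3,
                        start=start,
                        aa_length=len(peptide),
                        peptide=peptide,
                        spans_junction=end > L,
                        rolling=False,
                    )
                )
        else:
            # no stop in the periodic frame: rolling ORF, truncate at 4 copies
            n_codons = (four_l - start) // 3
            peptide = "".join(aas[:n_codons])
            if len(peptide) > min_aa:
                orfs.append(
                    OpenReadingFrame(
                        source_id=source_id,
                        kind="cORF",
                        frame=start % 3,
                        start=start,
                        aa_length=len(peptide),
                        peptide=peptide,
                        spans_junction=True,
                        rolling=True,
                    )
                )
    return orfs


# ---------------------------------------------------------------------------
# uORF / dORF / pORF on linear transcripts
# ---------------------------------------------------------------------------

def find_uorfs_dorfs(
    transcript_seq: str,
    cds_start: int,
    cds_end: int,
    min_aa: int = 10,
    source_id: str = "tx",
) -> list[OpenReadingFrame]:
    """uORFs fully inside [0, cds_start), dORFs fully inside [cds_end, L),
    plus the annotated CDS itself as pORF. ORFs overlapping the CDS are
    excluded and counted in the log."""
    L = len(transcript_seq)
    if not 0 <= cds_start < cds_end <= L:
        raise InvalidCDS(f"CDS {cds_start}..{cds_end} outside transcript of {L} nt")
    if (cds_end - cds_start) % 3 != 0:
        raise InvalidCDS("CDS length not divisible by 3")

    orfs: list[OpenReadingFrame] = []
    pep, _ = translate(transcript_seq[cds_start:cds_end])
    orfs.append(
        OpenReadingFrame(
            source_id=source_id,
            kind="pORF",
            frame=cds_start % 3,
            start=cds_start,
            aa_length=len(pep),
            peptide=pep,
        )
    )

    n_excluded = 0
    for start in range(L - 2):
        if transcript_seq[start : start + 3] != "ATG":
            continue
        pep, stopped = translate(transcript_seq[start:])
        if not stopped:
            continue
        end = start + 3 * len(pep) + 3
        if len(pep) <= min_aa:
            continue
        if start == cds_start and end == cds_end:
            continue  # the annotated CDS itself, already emitted as pORF
        if end <= cds_start:
            kind = "uORF"
        elif start >= cds_end:
            kind = "dORF"
        else:
            n_excluded += 1
            continue
        orfs.append(
            OpenReadingFrame(
                source_id=source_id,
                kind=kind,
                frame=start % 3,
                start=start,
                aa_length=len(pep),
                peptide=pep,
            )
        )
    if n_excluded:
        log.info("%s: %d ORFs overlapping the CDS excluded", source_id, n_excluded)
    return orfs


# ---------------------------------------------------------------------------
# Unique-peptide support
# ---------------------------------------------------------------------------

def match_peptides(
    peptides: Iterable[PeptideRecord], orfs: Sequence[OpenReadingFrame]
) -> None:
    """Fill each peptide's matched ORF ids by exact substring search."""
    for pep in peptides:
        pep.matched_orf_ids = [
            orf.orf_id for orf in orfs if pep.sequence in orf.peptide
        ]


def unique_peptide_filter(
    peptides: Sequence[PeptideRecord], orfs: Sequence[OpenReadingFrame]
) -> tuple[list[OpenReadingFrame], list[PeptideRecord]]:
    """Drop peptides matching != 1 ORF; retain ORFs with >= 1 surviving
    unique peptide. Returns (supported ORFs, dropped peptides)."""
    for pep in peptides:
        if not pep.matched_orf_ids:
            match_peptides([pep], orfs)
    dropped = [p for p in peptides if len(p.matched_orf_ids) != 1]
    surviving = [p for p in peptides if len(p.matched_orf_ids) == 1]
    supported_ids = {p.matched_orf_ids[0] for p in surviving}
    supported = [o for o in orfs if o.orf_id in supported_ids]
    return supported, dropped
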