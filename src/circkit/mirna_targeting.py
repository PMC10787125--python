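"""miRNA-mediated cleavage calling at degradome peaks.

The duplex engine is a declared simplified nearest-pair energy model, not a
full thermodynamic re-implementation: pair energies G:C = -3, A:T = -2,
G:T = -1 (wobble), +2 per bulged base inside the duplex, +1 per opposed
mismatch, dangling ends free. The decision rule of the pipeline is the
ratio of the duplex minimum energy to the energy of the miRNA bound to its
exact complement; a duplex passes when that ratio clears the threshold and
the predicted slice position (the target base opposite miRNA position 10)
lands within +/-1 of the degradome peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .degradome import CleavagePeak
from .errors import (
    LengthOutOfRange,
    Position10Unpaired,
    SiteOutOfRange,
    WindowTooShort,
)
from .sequtil import periodic_slice

log = logging.getLogger(__name__)

_INF = float("inf")


@dataclass(frozen=True)
class MiRNA:
    id: str
    seq: str  # 5'->3', DNA alphabet (U already mapped to T)
    family: Optional[str] = None

    def __post_init__(self):
        if len(self.seq) < 15:
            raise LengthOutOfRange(f"miRNA {self.id} shorter than 15 nt")


@dataclass(frozen=True)
class DuplexParams:
    gc: float = -3.0
    at: float = -2.0
    gt: float = -1.0
    bulge: float = 2.0
    mismatch: float = 1.0

    def pair_energy(self, a: str, b: str) -> Optional[float]:
        pair = a + b
        if pair in ("GC", "CG"):
            return self.gc
        if pair in ("AT", "TA"):
            return self.at
        if pair in ("GT", "TG"):
            return self.gt
        return None

    def perfect_energy(self, mirna_seq: str) -> float:
        return sum(
            self.gc if base in "GC" else self.at for base in mirna_seq
        )


DEFAULT_PARAMS = DuplexParams()


@dataclass
class TargetWindow:
    transcript_id: str
    center: int  # peak/site position in transcript coordinates
    seq: str
    start: int  # transcript coordinate of seq[0] (may be negative if circular)
    center_index: int
    circular: bool = False
    transcript_length: int = 0
    left_truncated: bool = False
    right_truncated: bool = False

    def coord(self, index: int) -> int:
        """Transcript coordinate of window position ``index``."""
        pos = self.start + index
        if self.circular:
            return pos % self.transcript_length
        return pos


@dataclass
class DuplexAlignment:
    mirna_id: str
    pairs: list[tuple[int, int]]  # (miRNA index, window index), miRNA 5'->3'
    energy: float
    perfect_energy: float

    @property
    def mfe_ratio(self) -> float:
        if self.energy >= 0 or not self.pairs:
            return 0.0
        return self.energy / self.perfect_energy


@dataclass
class CleavageCall:
    peak: CleavagePeak
    mirna_id: str
    transcript_id: str
    mfe_ratio: float
    slice_position: int
    slice_offset: int
    is_circ: bool = False


# ---------------------------------------------------------------------------
# Target context extraction
# ---------------------------------------------------------------------------

def extract_cleavage_context(
    transcript_seq: str,
    site: int,
    flank: int = 25,
    circular: bool = False,
    transcript_id: str = "",
) -> TargetWindow:
    """Cut the up-to-51-nt window around a cleavage site.

    Linear transcripts truncate at their ends (flags set); circular
    transcripts wrap across the back-splice junction using the periodic
    extension of the spliced sequence and never truncate.
    """
    L = len(transcript_seq)
    if not 0 <= site < L:
        raise SiteOutOfRange(f"site {site} outside transcript of length {L}")
    if circular:
        start = site - flank
        return TargetWindow(
            transcript_id=transcript_id,
            center=site,
            seq=periodic_slice(transcript_seq, start, 2 * flank + 1),
            start=start,
            center_index=flank,
            circular=True,
            transcript_length=L,
        )
    lo = max(0, site - flank)
    hi = min(L, site + flank + 1)
    return TargetWindow(
        transcript_id=transcript_id,
        center=site,
        seq=transcript_seq[lo:hi],
        start=lo,
        center_index=site - lo,
        circular=False,
        transcript_length=L,
        left_truncated=site - flank < 0,
        right_truncated=site + flank + 1 > L,
    )


# ---------------------------------------------------------------------------
# Duplex alignment (global on miRNA with free dangling ends, local on window)
# ---------------------------------------------------------------------------

def duplex_energy(
    mirna_seq: str, window_seq: str, params: DuplexParams = DEFAULT_PARAMS
) -> tuple[float, list[tuple[int, int]]]:
    """Minimum duplex energy and its pair list for raw sequences.

    A duplex is a strictly increasing set of base pairs between the miRNA
    (5'->3') and the reversed window; bases between consecutive pairs cost
    ``mismatch`` when opposed and ``bulge`` when unopposed, bases outside
    the outermost pairs are free. Returns the minimum over all non-empty
    duplexes, or (0.0, []) when nothing can pair. Pairs are reported as
    (miRNA index, window index).
    """
    m = mirna_seq
    rw = window_seq[::-1]
    M, W = len(m), len(rw)

    best = [[_INF] * W for _ in range(M)]
    inner = [[_INF] * W for _ in range(M)]
    best_prev: list[list[Optional[tuple[int, int]]]] = [[None] * W for _ in range(M)]
    inner_ptr: list[list[Optional[tuple[int, int]]]] = [[None] * W for _ in range(M)]

    for i in range(M):
        for j in range(W):
            e = params.pair_energy(m[i], rw[j])
            if e is not None:
                if i > 0 and j > 0 and inner[i - 1][j - 1] < 0:
                    best[i][j] = e + inner[i - 1][j - 1]
                    best_prev[i][j] = inner_ptr[i - 1][j - 1]
                else:
                    best[i][j] = e
            cands: list[tuple[float, Optional[tuple[int, int]]]] = []
            if best[i][j] < _INF:
                cands.append((best[i][j], (i, j)))
            if i > 0 and j > 0 and inner[i - 1][j - 1] < _INF:
                cands.append(
                    (inner[i - 1][j - 1] + params.mismatch, inner_ptr[i - 1][j - 1])
                )
            if i > 0 and inner[i - 1][j] < _INF:
                cands.append((inner[i - 1][j] + params.bulge, inner_ptr[i - 1][j]))
            if j > 0 and inner[i][j - 1] < _INF:
                cands.append((inner[i][j - 1] + params.bulge, inner_ptr[i][j - 1]))
            if cands:
                val, ptr = min(cands, key=lambda c: c[0])
                inner[i][j] = val
                inner_ptr[i][j] = ptr

    e_min, argmin = _INF, None
    for i in range(M):
        for j in range(W):
            if best[i][j] < e_min:
                e_min, argmin = best[i][j], (i, j)

    if argmin is None or e_min >= 0:
        return 0.0, []

    pairs_rev = []
    node: Optional[tuple[int, int]] = argmin
    while node is not None:
        pairs_rev.append(node)
        node = best_prev[node[0]][node[1]]
    pairs = [(i, W - 1 - j) for i, j in reversed(pairs_rev)]
    return e_min, pairs


def duplex_align(
    mirna: MiRNA, window: TargetWindow, params: DuplexParams = DEFAULT_PARAMS
) -> DuplexAlignment:
    """Minimum-energy antiparallel co-alignment of a miRNA against a target
    window (see :func:`duplex_energy` for the model)."""
    if len(window.seq) < len(mirna.seq) * 0.5:
        raise WindowTooShort(
            f"window of {len(window.seq)} nt for miRNA of {len(mirna.seq)} nt"
        )
    energy, pairs = duplex_energy(mirna.seq, window.seq, params)
    return DuplexAlignment(mirna.id, pairs, energy, params.perfect_energy(mirna.seq))


def predicted_slice_position(duplex: DuplexAlignment, window: TargetWindow) -> int:
    """Transcript coordinate of the target base opposite miRNA position 10
    (1-based from the miRNA 5' end)."""
    for mi, wi in duplex.pairs:
        if mi == 9:
            return window.coord(wi)
    raise Position10Unpaired(
        f"miRNA {duplex.mirna_id}: position 10 not paired"
    )


def render_duplex(mirna: MiRNA, window: TargetWindow, duplex: DuplexAlignment) -> str:
    """Compact text rendering: target 5'->3' over miRNA 3'->5'."""
    if not duplex.pairs:
        return "(no duplex)"
    # Walk pairs in target order (ascending window index = descending miRNA index)
    pairs = sorted(duplex.pairs, key=lambda p: p[1])
    top, mid, bot = [], [], []
    prev_w, prev_m = None, None
    for mi, wi in pairs:
        if prev_w is not None:
            gw = wi - prev_w - 1
            gm = prev_m - mi - 1
            shared = min(gw, gm)
            for k in range(shared):
                top.append(window.seq[prev_w + 1 + k])
                bot.append(mirna.seq[prev_m - 1 - k])
                mid.append(".")
            for k in range(shared, gw):
                top.append(window.seq[prev_w + 1 + k])
                bot.append("-")
                mid.append(" ")
            for k in range(shared, gm):
                top.append("-")
                bot.append(mirna.seq[prev_m - 1 - k])
                mid.append(" ")
        top.append(window.seq[wi])
        bot.append(mirna.seq[mi])
        mid.append("|")
        prev_w, prev_m = wi, mi
    return (
        f"target 5' {''.join(top)} 3'\n"
        f"          {''.join(mid)}\n"
        f"miRNA  3' {''.join(bot)} 5'"
    )


# ---------------------------------------------------------------------------
# Cleavage calling
# ---------------------------------------------------------------------------

def call_mirna_cleavage(
    peaks: Sequence[CleavagePeak],
    seqs: Mapping[str, str],
    mirnas: Sequence[MiRNA],
    circular_ids: frozenset | set = frozenset(),
    min_ratio: float = 0.7,
    max_offset: int = 1,
    flank: int = 25,
    ratio_sense: str = "ge",
    params: DuplexParams = DEFAULT_PARAMS,
) -> list[CleavageCall]:
    """For each (peak, miRNA): extract the cleavage context, align, and emit
    a call when the MFE ratio clears ``min_ratio`` and the predicted slice
    lands within ``max_offset`` of the peak.

    ``ratio_sense='ge'`` keeps duplexes at least min_ratio as stable as the
    perfect duplex (conventional reading); 'le' flips the comparison.
    """
    if ratio_sense not in ("ge", "le"):
        raise ValueError("ratio_sense must be 'ge' or 'le'")
    calls = []
    for peak in peaks:
        seq = seqs.get(peak.ref)
        if seq is None:
            continue
        circular = peak.ref in circular_ids
        window = extract_cleavage_context(
            seq, peak.position, flank=flank, circular=circular,
            transcript_id=peak.ref,
        )
        for mirna in mirnas:
            try:
                duplex = duplex_align(mirna, window, params)
            except WindowTooShort:
                continue
            ratio = duplex.mfe_ratio
            passes = ratio >= min_ratio if ratio_sense == "ge" else ratio <= min_ratio
            if not passes or not duplex.pairs:
                continue
            try:
                slice_pos = predicted_slice_position(duplex, window)
            except Position10Unpaired:
                continue
            d = abs(slice_pos - peak.position)
            if circular:
                d = min(d, len(seq) - d)
            if d <= max_offset:
                calls.append(
                    CleavageCall(
                        peak=peak,
                        mirna_id=mirna.id,
                        transcript_id=peak.ref,
                        mfe_ratio=ratio,
                        slice_position=slice_pos,
                        slice_offset=d,
                        is_circ=circular,
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# Conserved / variant small-RNA matching
# ---------------------------------------------------------------------------

def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance (substitutions + gaps)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]


def classify_mirna_read(
    read_seq: str, known: Sequence[MiRNA], max_edits: int = 3
) -> tuple[str, Optional[str], Optional[int]]:
    """Classify a small-RNA read against known miRNAs.

    Returns (class, best-match id, distance): 'conserved' on an exact match,
    'variant' within ``max_edits`` substitutions+gaps, else 'none'. Ties go
    to the first miRNA in input order.
    """
    if not 18 <= len(read_seq) <= 26:
        raise LengthOutOfRange(f"read length {len(read_seq)} outside 18-26")
    best_id, best_d = None, None
    for m in known:
        if read_seq == m.seq:
            return "conserved", m.id, 0
        d = edit_distance(read_seq, m.seq)
        if best_d is None or d < best_d:
            best_id, best_d = m.id, d
    if best_d is not None and best_d <= max_edits:
        return "variant", best_id, best_d
    return "none", best_id, best_d
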