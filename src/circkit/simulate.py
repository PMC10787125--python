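"""Deterministic synthetic fixtures: toy genomes, gene models, planted
circRNAs, degradome reads with planted slice sites, junction-spanning reads,
and peptide tables. Every generator is a pure function of a seeded
numpy Generator, so identical configs give byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .circ_model import CircRNA, classify_circ_type
from .circ_orf import OpenReadingFrame, PeptideRecord, find_corfs
from .degradome import JunctionReference, build_junction_reference
from .errors import ConfigInvalid
from .io_formats import (
    GenomicInterval,
    SequenceRecord,
    TranscriptModel,
    write_circ_table,
    write_fasta,
)
from .mirna_targeting import MiRNA
from .sequtil import revcomp

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    seed: int = 1
    n_genes: int = 12
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (60, 200)
    intergenic_len: tuple[int, int] = (100, 300)
    n_circ_exonic: int = 4
    n_circ_intronic: int = 2
    include_short_circle: bool = False
    n_mirna: int = 8
    mirna_len: int = 21
    planted_sites: int = 8
    signal_reads_per_site: int = 50
    background_rate: float = 0.02
    read_len: int = 20
    multimap_fraction: float = 0.1
    n_junction_reads: int = 5
    junction_flank: int = 50
    min_overhang: int = 5
    n_supported_orfs: int = 3
    n_shared_peptides: int = 2

    def __post_init__(self):
        counts = (
            self.n_genes,
            self.n_circ_exonic,
            self.n_circ_intronic,
            self.n_mirna,
            self.planted_sites,
            self.signal_reads_per_site,
            self.read_len,
            self.n_junction_reads,
        )
        if any(c < 0 for c in counts):
            raise ConfigInvalid("negative count in configuration")
        if self.background_rate < 0 or not 0 <= self.multimap_fraction <= 1:
            raise ConfigInvalid("bad rate/fraction")
        for lo, hi in (
            self.exons_per_gene,
            self.exon_len,
            self.intron_len,
            self.intergenic_len,
        ):
            if lo < 1 or hi < lo:
                raise ConfigInvalid("bad range")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigInvalid(f"unknown config keys: {sorted(unknown)}")
        for key in ("exons_per_gene", "exon_len", "intron_len", "intergenic_len"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class PlantedSite:
    transcript_id: str
    position: int
    mirna_id: str
    is_circ: bool


@dataclass
class TruthSet:
    cleavage: list[PlantedSite] = field(default_factory=list)
    circrnas: list[CircRNA] = field(default_factory=list)
    junction_read_ids: dict[str, str] = field(default_factory=dict)  # read -> circ
    negative_read_ids: list[str] = field(default_factory=list)
    supported_orf_ids: list[str] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


# ---------------------------------------------------------------------------
# Toy genome and gene models
# ---------------------------------------------------------------------------

def make_toy_genome(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """One chromosome carrying ``n_genes`` single-transcript genes with
    alternating strands and random exon/intron structure."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chrom = "chr1"
    pieces: list[str] = []
    cursor = 0
    models: list[TranscriptModel] = []
    for g in range(cfg.n_genes):
        gap = int(rng.integers(cfg.intergenic_len[0], cfg.intergenic_len[1] + 1))
        pieces.append(_random_seq(rng, gap))
        cursor += gap
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        strand = "+" if g % 2 == 0 else "-"
        exons = []
        for e in range(n_ex):
            if e > 0:
                ilen = int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                pieces.append(_random_seq(rng, ilen))
                cursor += ilen
            elen = int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
            pieces.append(_random_seq(rng, elen))
            exons.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
            cursor += elen
        interval = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
        models.append(
            TranscriptModel(f"gene{g}", f"tx{g}", interval, exons)
        )
    pieces.append(_random_seq(rng, 200))
    genome = {chrom: "".join(pieces)}
    return genome, models


def write_gff3(path, models: Sequence[TranscriptModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            iv = m.interval
            fh.write(
                f"{iv.chrom}\tcirckit\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={m.gene_id}\n"
            )
            fh.write(
                f"{iv.chrom}\tcirckit\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={m.transcript_id};Parent={m.gene_id}\n"
            )
            for e in m.exons:
                fh.write(
                    f"{e.chrom}\tcirckit\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tParent={m.transcript_id}\n"
                )


# ---------------------------------------------------------------------------
# Planted circRNAs
# ---------------------------------------------------------------------------

def plant_circrnas(
    genome: Mapping[str, str],
    models: Sequence[TranscriptModel],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> list[CircRNA]:
    """ecircRNAs from random consecutive exon runs and ciRNAs from random
    intron interiors, BED12-consistent."""
    circs: list[CircRNA] = []
    multi_exon = [m for m in models if len(m.exons) >= 2]
    intronic = [m for m in models if m.introns()]
    for i in range(cfg.n_circ_exonic):
        m = multi_exon[int(rng.integers(len(multi_exon)))]
        a = int(rng.integers(0, len(m.exons) - 1))
        b = int(rng.integers(a + 1, len(m.exons))) + 1
        chain = m.exons[a:b]
        interval = GenomicInterval(
            m.interval.chrom, chain[0].start, chain[-1].end, m.strand
        )
        circs.append(
            CircRNA(
                id=f"ecirc{i}",
                interval=interval,
                exons=list(chain),
                host_gene_id=m.gene_id,
                junction_reads=float(rng.integers(5, 100)),
            )
        )
    for i in range(cfg.n_circ_intronic):
        m = intronic[int(rng.integers(len(intronic)))]
        intr = m.introns()[int(rng.integers(len(m.introns())))]
        pad = min(5, (intr.length - 20) // 2) if intr.length > 30 else 1
        iv = GenomicInterval(intr.chrom, intr.start + pad, intr.end - pad, intr.strand)
        circs.append(
            CircRNA(
                id=f"icirc{i}",
                interval=iv,
                exons=[iv],
                host_gene_id=m.gene_id,
                junction_reads=float(rng.integers(5, 100)),
            )
        )
    if cfg.include_short_circle:
        m = models[0]
        e = m.exons[0]
        length = min(80, e.length)
        iv = GenomicInterval(e.chrom, e.start, e.start + length, e.strand)
        circs.append(
            CircRNA(
                id="shortcirc0",
                interval=iv,
                exons=[iv],
                host_gene_id=m.gene_id,
                junction_reads=5.0,
            )
        )
    for c in circs:
        c.circ_type = classify_circ_type(c, models)
    return circs


# ---------------------------------------------------------------------------
# miRNAs
# ---------------------------------------------------------------------------

def make_mirnas(cfg: SimulationConfig, rng: np.random.Generator) -> list[MiRNA]:
    return [
        MiRNA(f"mir{i}", _random_seq(rng, cfg.mirna_len))
        for i in range(cfg.n_mirna)
    ]


def shuffle_mirnas(mirnas: Sequence[MiRNA], rng: np.random.Generator) -> list[MiRNA]:
    """Negative control: per-miRNA letter shuffles."""
    out = []
    for m in mirnas:
        letters = list(m.seq)
        rng.shuffle(letters)
        out.append(MiRNA(f"shuf_{m.id}", "".join(letters)))
    return out


# ---------------------------------------------------------------------------
# Degradome simulation
# ---------------------------------------------------------------------------

def simulate_degradome(
    seqs: Mapping[str, str],
    mirnas: Sequence[MiRNA],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    circular_ids: frozenset | set = frozenset(),
) -> tuple[dict[str, str], str, list[PlantedSite]]:
    """Plant miRNA complements so each planted position is the slice site
    (opposite miRNA base 10), then emit signal reads starting exactly there
    plus uniform background, as an aligned SAM against the transcript set.

    Returns (edited sequences, SAM text, planted-site truth).
    """
    edited = dict(seqs)
    order = sorted(edited)
    flank = 25
    min_len = 2 * flank + cfg.read_len + 10
    eligible = [t for t in order if len(edited[t]) >= min_len]
    if not eligible and cfg.planted_sites > 0:
        raise ConfigInvalid("no transcript long enough to plant a site")

    truth: list[PlantedSite] = []
    used: dict[str, list[int]] = {t: [] for t in eligible}
    for s_idx in range(cfg.planted_sites):
        mirna = mirnas[s_idx % len(mirnas)]
        m_len = len(mirna.seq)
        placed = False
        for _ in range(200):
            t = eligible[int(rng.integers(len(eligible)))]
            L = len(edited[t])
            lo = max(flank, m_len)
            hi = L - max(flank + 1, cfg.read_len)
            if hi <= lo:
                continue
            p = int(rng.integers(lo, hi))
            if any(abs(p - q) < 60 for q in used[t]):
                continue
            start = p - m_len + 10
            if start < 0 or start + m_len > L:
                continue
            edited[t] = (
                edited[t][:start] + revcomp(mirna.seq) + edited[t][start + m_len :]
            )
            used[t].append(p)
            truth.append(PlantedSite(t, p, mirna.id, t in circular_ids))
            placed = True
            break
        if not placed:
            raise ConfigInvalid("could not place all planted sites")

    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for t in order:
        lines.append(f"@SQ\tSN:{t}\tLN:{len(edited[t])}")

    def sam_record(qname, ref, pos0, seq, nh):
        return (
            f"{qname}\t0\t{ref}\t{pos0 + 1}\t255\t{len(seq)}M\t*\t0\t0\t"
            f"{seq}\t*\tNH:i:{nh}"
        )

    records: list[str] = []
    for idx, site in enumerate(truth):
        seq_t = edited[site.transcript_id]
        for r in range(cfg.signal_reads_per_site):
            rseq = seq_t[site.position : site.position + cfg.read_len]
            records.append(
                sam_record(f"sig{idx}_{r}", site.transcript_id, site.position, rseq, 1)
            )
    # Background 5' ends are uniform but drawn without replacement per
    # transcript, so background alone never stacks weight on one position
    # (coincident ends are the signal being modeled, not library noise).
    bg_pool: dict[str, list[int]] = {}
    for t in order:
        L = len(edited[t])
        if L > cfg.read_len:
            bg_pool[t] = list(rng.permutation(L - cfg.read_len + 1))

    def next_pos(t: str) -> Optional[int]:
        pool = bg_pool.get(t)
        return int(pool.pop()) if pool else None

    bg_counter = 0
    for t in order:
        if t not in bg_pool:
            continue
        n_bg = int(np.floor(cfg.background_rate * len(edited[t])))
        for _ in range(n_bg):
            pos = next_pos(t)
            if pos is None:
                break
            rseq = edited[t][pos : pos + cfg.read_len]
            qname = f"bg{bg_counter}"
            bg_counter += 1
            if rng.random() < cfg.multimap_fraction and len(bg_pool) > 1:
                n = int(rng.integers(2, 5))
                records.append(sam_record(qname, t, pos, rseq, n))
                for _h in range(n - 1):
                    candidates = sorted(bg_pool)
                    t2 = candidates[int(rng.integers(len(candidates)))]
                    pos2 = next_pos(t2)
                    if pos2 is None:
                        pos2, t2 = pos, t
                    records.append(sam_record(qname, t2, pos2, rseq, n))
            else:
                records.append(sam_record(qname, t, pos, rseq, 1))
    sam_text = "\n".join(lines + records) + "\n"
    return edited, sam_text, truth


# ---------------------------------------------------------------------------
# Junction-spanning reads
# ---------------------------------------------------------------------------

def make_junction_reads(
    ref: JunctionReference,
    n_reads: int,
    read_len: int,
    min_overhang: int,
    rng: np.random.Generator,
) -> list[SequenceRecord]:
    """Error-free reads from a junction reference, each covering at least
    ``min_overhang`` bases on both sides of the junction."""
    f = ref.junction_offset
    lo = max(0, f - read_len + min_overhang)
    hi = min(f - min_overhang, len(ref.seq) - read_len)
    if hi < lo:
        return []
    reads = []
    for r in range(n_reads):
        start = int(rng.integers(lo, hi + 1))
        reads.append(
            SequenceRecord(
                f"jx_{ref.circ_id}_{r}", ref.seq[start : start + read_len]
            )
        )
    return reads


def make_linear_boundary_reads(
    linear_seq: str,
    boundary: int,
    n_reads: int,
    read_len: int,
    min_overhang: int,
    rng: np.random.Generator,
    prefix: str = "lin",
) -> list[SequenceRecord]:
    """Reads from a linear sequence crossing ``boundary`` — negative controls
    for junction mapping (they continue into downstream linear sequence
    instead of wrapping to the circle start)."""
    lo = max(0, boundary - read_len + min_overhang)
    hi = min(boundary - min_overhang, len(linear_seq) - read_len)
    if hi < lo:
        return []
    reads = []
    for r in range(n_reads):
        start = int(rng.integers(lo, hi + 1))
        reads.append(
            SequenceRecord(f"{prefix}_{r}", linear_seq[start : start + read_len])
        )
    return reads


# ---------------------------------------------------------------------------
# Peptide tables
# ---------------------------------------------------------------------------

def simulate_peptides(
    orfs: Sequence[OpenReadingFrame],
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[list[PeptideRecord], list[str]]:
    """Unique peptides drawn from designated ORFs plus shared decoys.

    Returns (peptide records, supported ORF ids). Peptides are substrings of
    ORF peptides, verified unique (or deliberately shared) across the full
    ORF set by substring search.
    """
    usable = [o for o in orfs if o.aa_length >= 8]
    n_sup = min(cfg.n_supported_orfs, len(usable))
    peptides: list[PeptideRecord] = []
    supported: list[str] = []
    for o in usable[:n_sup]:
        found = False
        for _ in range(100):
            plen = int(rng.integers(7, min(12, o.aa_length) + 1))
            start = int(rng.integers(0, o.aa_length - plen + 1))
            cand = o.peptide[start : start + plen]
            owners = [x for x in orfs if cand in x.peptide]
            if len(owners) == 1 and owners[0].orf_id == o.orf_id:
                peptides.append(PeptideRecord(cand))
                supported.append(o.orf_id)
                found = True
                break
        if not found:
            log.info("no unique peptide found for %s", o.orf_id)
    n_shared = 0
    for a_idx in range(len(usable)):
        if n_shared >= cfg.n_shared_peptides:
            break
        a = usable[a_idx]
        for plen in (6, 5, 4):
            done = False
            for start in range(0, a.aa_length - plen + 1):
                cand = a.peptide[start : start + plen]
                owners = [x for x in orfs if cand in x.peptide]
                if len(owners) > 1:
                    peptides.append(PeptideRecord(cand))
                    n_shared += 1
                    done = True
                    break
            if done:
                break
    return peptides, supported


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_all(cfg: SimulationConfig, outdir) -> TruthSet:
    """Run every generator and write all files (text formats only) into
    ``outdir``. Deterministic per seed: two runs produce byte-identical
    trees."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    truth = TruthSet()

    genome, models = make_toy_genome(cfg, rng)
    write_fasta(outdir / "genome.fa", [SequenceRecord(c, s) for c, s in genome.items()])
    write_gff3(outdir / "genes.gff3", models)

    circs = plant_circrnas(genome, models, cfg, rng)
    truth.circrnas = circs
    write_circ_table(outdir / "circles.bed", circs)
    with open(outdir / "truth_circ_types.tsv", "w") as fh:
        fh.write("circ_id\tcirc_type\thost_gene\n")
        for c in circs:
            fh.write(f"{c.id}\t{c.circ_type}\t{c.host_gene_id}\n")

    mirnas = make_mirnas(cfg, rng)
    write_fasta(outdir / "mirnas.fa", [SequenceRecord(m.id, m.seq) for m in mirnas])

    seqs: dict[str, str] = {m.transcript_id: m.spliced_sequence(genome) for m in models}
    circ_seqs = {c.id: c.spliced_sequence(genome) for c in circs}
    seqs.update(circ_seqs)
    circular_ids = frozenset(circ_seqs)

    edited, sam_text, planted = simulate_degradome(
        seqs, mirnas, cfg, rng, circular_ids=circular_ids
    )
    truth.cleavage = planted
    (outdir / "degradome.sam").write_text(sam_text)
    write_fasta(
        outdir / "transcripts.fa",
        [SequenceRecord(t, edited[t]) for t in sorted(edited) if t not in circular_ids],
    )
    circ_records = [SequenceRecord(c, edited[c]) for c in sorted(circular_ids)]
    write_fasta(outdir / "circles.fa", circ_records)
    with open(outdir / "truth_cleavage.tsv", "w") as fh:
        fh.write("transcript_id\tposition\tmirna_id\tis_circ\n")
        for site in planted:
            fh.write(
                f"{site.transcript_id}\t{site.position}\t{site.mirna_id}\t"
                f"{int(site.is_circ)}\n"
            )

    # Junction references + spanning reads (with linear negative controls)
    refs = []
    jx_reads: list[SequenceRecord] = []
    for c in circs:
        cseq = edited[c.id]
        if len(cseq) < 2 * cfg.min_overhang:
            continue
        ref = JunctionReference(
            c.id,
            cseq[-min(cfg.junction_flank, len(cseq) // 2) :]
            + cseq[: min(cfg.junction_flank, len(cseq) // 2)],
            min(cfg.junction_flank, len(cseq) // 2),
        )
        refs.append(ref)
        for rec in make_junction_reads(
            ref, cfg.n_junction_reads, cfg.read_len, cfg.min_overhang, rng
        ):
            jx_reads.append(rec)
            truth.junction_read_ids[rec.id] = c.id
    write_fasta(
        outdir / "junction_refs.fa",
        [SequenceRecord(r.circ_id, r.seq) for r in refs],
        descriptions={r.circ_id: f"offset={r.junction_offset}" for r in refs},
    )
    neg_reads: list[SequenceRecord] = []
    for c in circs:
        host = next((m for m in models if m.gene_id == c.host_gene_id), None)
        if host is None:
            continue
        hseq = host.spliced_sequence(genome)
        donor_base = c.donor - 1 if c.interval.strand == "+" else c.donor
        try:
            boundary = host.genomic_to_transcript(donor_base) + 1
        except Exception:
            continue  # intronic circles have no exonic donor base
        recs = make_linear_boundary_reads(
            hseq, boundary, cfg.n_junction_reads, cfg.read_len,
            cfg.min_overhang, rng, prefix=f"lin_{c.id}",
        )
        neg_reads.extend(recs)
        truth.negative_read_ids.extend(r.id for r in recs)
    write_fasta(outdir / "junction_reads.fa", jx_reads + neg_reads)
    with open(outdir / "truth_junction_reads.tsv", "w") as fh:
        fh.write("read_id\tcirc_id\n")
        for rid in sorted(truth.junction_read_ids):
            fh.write(f"{rid}\t{truth.junction_read_ids[rid]}\n")

    # ORFs and peptides
    orfs: list[OpenReadingFrame] = []
    for c in sorted(circular_ids):
        if len(edited[c]) >= 3:
            orfs.extend(find_corfs(edited[c], source_id=c))
    peptides, supported = simulate_peptides(orfs, cfg, rng)
    truth.supported_orf_ids = supported
    with open(outdir / "peptides.tsv", "w") as fh:
        fh.write("peptide\n")
        for p in peptides:
            fh.write(p.sequence + "\n")
    with open(outdir / "orfs.tsv", "w") as fh:
        fh.write(
            "orf_id\tsource\tkind\tframe\tstart\taa_length\tspans_junction\t"
            "rolling\tpeptide\n"
        )
        for o in orfs:
            fh.write(
                f"{o.orf_id}\t{o.source_id}\t{o.kind}\t{o.frame}\t{o.start}\t"
                f"{o.aa_length}\t{int(o.spans_junction)}\t{int(o.rolling)}\t"
                f"{o.peptide}\n"
            )
    with open(outdir / "truth_supported_orfs.tsv", "w") as fh:
        fh.write("orf_id\n")
        for oid in supported:
            fh.write(oid + "\n")
    return truth
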