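"""Random-segment permutation enrichment: is a feature class enriched within
target regions versus equal-count random transcript segments?

Each permutation draws as many segments as there are target regions from
transcripts that overlap no excluded region, matching the observed region
lengths (sampled with replacement from the target length pool), and
recounts the overlap statistic. The empirical p-value uses the add-one
estimator (1 + #{perm >= obs}) / (n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import UniverseExhausted
from .io_formats import GenomicInterval, TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class RegionSet:
    intervals: list[GenomicInterval]
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class EnrichmentResult:
    observed: int
    perm_mean: float
    perm_sd: float
    z: float
    empirical_p: float
    n_perm: int
    seed: int
    mode: str
    degenerate: bool = False
    perm_counts: list[int] = field(default_factory=list)


class _ChromIndex:
    """Per-chromosome sorted starts plus running max of ends, for O(log n)
    any-overlap queries."""

    def __init__(self, intervals: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in grouped.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs])
            ends = np.maximum.accumulate(np.array([p[1] for p in pairs]))
            self.by_chrom[chrom] = (starts, ends)

    def overlaps_any(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized: does [start, end) overlap any indexed interval?"""
        if chrom not in self.by_chrom:
            return np.zeros(len(starts), dtype=bool)
        idx_starts, cummax_ends = self.by_chrom[chrom]
        idx = np.searchsorted(idx_starts, ends, side="left") - 1
        ok = idx >= 0
        out = np.zeros(len(starts), dtype=bool)
        out[ok] = cummax_ends[idx[ok]] > starts[ok]
        return out


def overlap_count(features: RegionSet, regions: RegionSet, mode: str = "events") -> int:
    """Count features overlapping >= 1 region (mode='events', each feature
    once) or regions containing >= 1 feature (mode='regions')."""
    if mode == "events":
        query, index_set = features, regions
    elif mode == "regions":
        query, index_set = regions, features
    else:
        raise ValueError(f"mode {mode!r}")
    index = _ChromIndex(index_set.intervals)
    count = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in query.intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    for chrom, pairs in by_chrom.items():
        starts = np.array([p[0] for p in pairs])
        ends = np.array([p[1] for p in pairs])
        count += int(index.overlaps_any(chrom, starts, ends).sum())
    return count


def eligible_transcripts(
    universe: Sequence[TranscriptModel], exclude: Optional[RegionSet]
) -> list[TranscriptModel]:
    """Transcripts overlapping no excluded region."""
    if exclude is None or not exclude.intervals:
        return list(universe)
    index = _ChromIndex(exclude.intervals)
    out = []
    for t in universe:
        hit = index.overlaps_any(
            t.interval.chrom,
            np.array([t.interval.start]),
            np.array([t.interval.end]),
        )[0]
        if not hit:
            out.append(t)
    return out


def draw_random_segments(
    universe: Sequence[TranscriptModel],
    exclude: Optional[RegionSet],
    k: int,
    length_pool: Sequence[int],
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> RegionSet:
    """Draw ``k`` segments from eligible transcripts, each with a length
    sampled with replacement from ``length_pool`` and placed uniformly
    within a uniformly chosen transcript. Deterministic given the
    generator's state."""
    if k == 0:
        return RegionSet([], "random")
    eligible = eligible_transcripts(universe, exclude)
    if not eligible:
        raise UniverseExhausted("no eligible transcripts")
    pool = np.asarray(length_pool, dtype=int)
    if len(pool) == 0:
        raise UniverseExhausted("empty length pool")
    spans = np.array([t.interval.length for t in eligible])
    segments: list[GenomicInterval] = []
    for _ in range(k):
        placed = False
        for _attempt in range(max_retries):
            ti = int(rng.integers(len(eligible)))
            length = int(pool[int(rng.integers(len(pool)))])
            if length > spans[ti] or length < 1:
                continue
            t = eligible[ti]
            start = t.interval.start + int(
                rng.integers(spans[ti] - length + 1)
            )
            segments.append(
                GenomicInterval(t.interval.chrom, start, start + length, t.strand)
            )
            placed = True
            break
        if not placed:
            raise UniverseExhausted(
                f"could not place a segment after {max_retries} retries"
            )
    return RegionSet(segments, "random")


def enrichment_test(
    features: RegionSet,
    target_regions: RegionSet,
    universe: Sequence[TranscriptModel],
    n_perm: int = 1000,
    seed: int = 0,
    mode: str = "events",
    exclude: Optional[RegionSet] = None,
    fixed_length: Optional[int] = None,
) -> EnrichmentResult:
    """Permutation enrichment of ``features`` in ``target_regions``.

    ``exclude`` defaults to the target regions themselves (random segments
    come from transcripts not producing the targets). ``fixed_length``
    replaces the observed length pool with a constant, reproducing a literal
    equal-count-only scheme.
    """
    observed = overlap_count(features, target_regions, mode=mode)
    if exclude is None:
        exclude = target_regions
    if fixed_length is not None:
        pool: Sequence[int] = [fixed_length]
    else:
        pool = [iv.length for iv in target_regions.intervals]
    rng = np.random.default_rng(seed)
    eligible = eligible_transcripts(universe, exclude)
    counts = []
    for _ in range(n_perm):
        perm = draw_random_segments(
            eligible, None, len(target_regions), pool, rng
        )
        counts.append(overlap_count(features, perm, mode=mode))
    counts_arr = np.array(counts, dtype=float)
    mean = float(counts_arr.mean())
    sd = float(counts_arr.std(ddof=0))
    degenerate = sd == 0.0
    z = 0.0 if degenerate else (observed - mean) / sd
    p = (1 + int((counts_arr >= observed).sum())) / (n_perm + 1)
    if degenerate and observed <= mean:
        p = 1.0
    return EnrichmentResult(
        observed=observed,
        perm_mean=mean,
        perm_sd=sd,
        z=z,
        empirical_p=p,
        n_perm=n_perm,
        seed=seed,
        mode=mode,
        degenerate=degenerate,
        perm_counts=counts,
    )
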