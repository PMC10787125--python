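"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive expected values by enumeration/summation along
code paths disjoint from the package implementations they check.
"""

from __future__ import annotations

import math
from math import comb, gcd

from circkit.mirna_targeting import DuplexParams
from circkit.sequtil import CODON_TABLE, STOP_CODONS, periodic_slice


# ---------------------------------------------------------------------------
# Binomial upper tail by explicit summation
# ---------------------------------------------------------------------------

def binomial_tail_sum(k: int, n: int, p0: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p0), summed term by term from the top
    (smallest terms first) for stability."""
    total = 0.0
    for i in range(n, k - 1, -1):
        total += comb(n, i) * (p0 ** i) * ((1.0 - p0) ** (n - i))
    return min(total, 1.0)


def binomial_tail_table(n: int, p0: float) -> list[float]:
    """P(X >= k) for every k in 0..n, via pmf suffix sums."""
    pmf = [comb(n, i) * (p0 ** i) * ((1.0 - p0) ** (n - i)) for i in range(n + 1)]
    out = [0.0] * (n + 1)
    acc = 0.0
    for k in range(n, -1, -1):
        acc += pmf[k]
        out[k] = min(acc, 1.0)
    return out


# ---------------------------------------------------------------------------
# Per-position brute-force peak evaluation
# ---------------------------------------------------------------------------

def brute_force_peaks(
    weights,
    half_window: int = 10,
    min_fraction: float = 0.5,
    alpha: float = 0.05,
    null_mode: str = "transcript",
) -> list[int]:
    """Positions passing the fraction and binomial cutoffs, evaluated one by
    one with python slicing and the summation oracle."""
    from circkit.degradome import binomial_peak_pvalue

    def round_half_up(x):
        # same epsilon-stabilized rounding rule as the caller's contract
        return int(math.floor(x + 0.5 + 1e-9))

    L = len(weights)
    total = float(sum(weights))
    n_total = round_half_up(total)
    out = []
    for i in range(L):
        w = float(weights[i])
        if w <= 0:
            continue
        lo = max(0, i - half_window)
        hi = min(L, i + half_window + 1)
        window = float(sum(weights[lo:hi]))
        if w / window < min_fraction - 1e-12:
            continue
        k = round_half_up(w)
        if null_mode == "transcript":
            n, p0 = n_total, 1.0 / L
        else:
            n, p0 = round_half_up(window), 1.0 / (2 * half_window + 1)
        if k < 1 or n < 1:
            continue
        k = min(k, n)
        if binomial_peak_pvalue(k, n, p0) <= alpha:
            out.append(i)
    return out


# ---------------------------------------------------------------------------
# Duplex energy oracles
# ---------------------------------------------------------------------------

def _gap_cost(a: int, b: int, params: DuplexParams) -> float:
    """Optimal cost of the inter-pair region with ``a`` and ``b`` leftover
    bases: oppose as mismatches while cheaper than two bulges."""
    return min(a, b) * min(params.mismatch, 2 * params.bulge) + abs(a - b) * params.bulge


def quadratic_duplex_energy(mseq: str, wseq: str, params: DuplexParams) -> float:
    """O(M^2 W^2) evaluation over last-pair decompositions with the
    closed-form gap cost."""
    rw = wseq[::-1]
    M, W = len(mseq), len(rw)
    best: dict[tuple[int, int], float] = {}
    e_min = math.inf
    for i in range(M):
        for j in range(W):
            e = params.pair_energy(mseq[i], rw[j])
            if e is None:
                continue
            b = e
            for (pi, pj), val in best.items():
                if pi < i and pj < j:
                    b = min(b, val + _gap_cost(i - pi - 1, j - pj - 1, params) + e)
            best[(i, j)] = b
            e_min = min(e_min, b)
    if e_min is math.inf or e_min >= 0:
        return 0.0
    return e_min


def enumerate_duplex_energy(mseq: str, wseq: str, params: DuplexParams) -> float:
    """Exhaustive enumeration over all monotone pair sets (tiny inputs)."""
    rw = wseq[::-1]
    M, W = len(mseq), len(rw)
    best = math.inf

    def rec(i: int, j: int, last, energy: float):
        nonlocal best
        for ni in range(i, M):
            for nj in range(j, W):
                e = params.pair_energy(mseq[ni], rw[nj])
                if e is None:
                    continue
                cost = 0.0 if last is None else _gap_cost(
                    ni - last[0] - 1, nj - last[1] - 1, params
                )
                ne = energy + cost + e
                if ne < best:
                    best = ne
                rec(ni + 1, nj + 1, (ni, nj), ne)

    rec(0, 0, None, 0.0)
    if best is math.inf or best >= 0:
        return 0.0
    return best


# ---------------------------------------------------------------------------
# Periodic-sequence ORF oracle
# ---------------------------------------------------------------------------

def periodic_orfs(seq: str, min_aa: int = 10) -> set[tuple[int, str, bool, bool]]:
    """ORFs of the infinite periodic circle, truncated at 4 copies:
    set of (start, peptide, spans_junction, rolling)."""
    L = len(seq)
    out = set()
    for start in range(L):
        if periodic_slice(seq, start, 3) != "ATG":
            continue
        orbit = L // gcd(3, L)
        stop_k = None
        for k in range(orbit):
            if periodic_slice(seq, start + 3 * k, 3) in STOP_CODONS:
                stop_k = k
                break
        if stop_k is not None:
            pep = "".join(
                CODON_TABLE.get(periodic_slice(seq, start + 3 * k, 3), "X")
                for k in range(stop_k)
            )
            end = start + 3 * stop_k + 3
            rec = (start, pep, end > L, False)
        else:
            n = (4 * L - start) // 3
            pep = "".join(
                CODON_TABLE.get(periodic_slice(seq, start + 3 * k, 3), "X")
                for k in range(n)
            )
            rec = (start, pep, True, True)
        if len(rec[1]) > min_aa:
            out.add(rec)
    return out


# ---------------------------------------------------------------------------
# BH and overlap oracles
# ---------------------------------------------------------------------------

def bh_oracle(pvalues) -> list[float]:
    """Quadratic-time Benjamini-Hochberg: adj_i = min over p_j >= p_i of
    n * p_j / rank(p_j), capped at 1."""
    n = len(pvalues)
    ranked = sorted(pvalues)
    out = []
    for p in pvalues:
        best = 1.0
        for j, q in enumerate(ranked, 1):
            if q >= p:
                best = min(best, n * q / j)
        out.append(min(best, 1.0))
    return out


def overlap_count_quadratic(features, regions, mode: str = "events") -> int:
    def hits(query, others):
        n = 0
        for q in query:
            if any(
                q.chrom == o.chrom and q.start < o.end and o.start < q.end
                for o in others
            ):
                n += 1
        return n

    if mode == "events":
        return hits(features, regions)
    return hits(regions, features)
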