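"""Small nucleotide/peptide helpers shared across modules."""

from __future__ import annotations

from Bio.Data import CodonTable

_STANDARD = CodonTable.standard_dna_table
CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_ALPHABET = frozenset("ACGTN")


def normalize_seq(seq: str) -> str:
    """Uppercase and map U->T. Raises ValueError on non-nucleotide letters."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - VALID_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> tuple[str, bool]:
    """Translate full codons of ``nt``; stop at the first stop codon.

    Returns ``(peptide, stopped)`` where ``stopped`` is True when a stop
    codon terminated translation within the string.
    """
    aas = []
    for i in range(0, len(nt) - 2, 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            return "".join(aas), True
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas), False


def periodic_slice(seq: str, start: int, length: int) -> str:
    """Slice ``length`` characters from the periodic extension of ``seq``.

    ``start`` may be negative or exceed ``len(seq)``; indices wrap modulo
    the sequence length.
    """
    L = len(seq)
    return "".join(seq[(start + i) % L] for i in range(length))
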