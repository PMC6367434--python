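"""Small DNA sequence utilities: complementing, IUPAC matching, mismatch counts."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC degenerate nucleotide codes -> the set of bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

BASES = "ACGT"


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters other than ACGTN not supported)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_match(pattern: str, seq: str) -> bool:
    """True if ``seq`` matches the equally long degenerate ``pattern``."""
    if len(pattern) != len(seq):
        return False
    return all(b in IUPAC[p] for p, b in zip(pattern.upper(), seq.upper()))


def find_motif(seq: str, pattern: str) -> list[int]:
    """All 0-based start positions where the degenerate pattern occurs on the given strand."""
    k = len(pattern)
    return [i for i in range(len(seq) - k + 1) if iupac_match(pattern, seq[i : i + k])]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random ACGT string."""
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
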