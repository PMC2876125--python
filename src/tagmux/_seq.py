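"""Small sequence helpers shared across modules.

IUPAC handling is deliberately explicit: degenerate codes appear only in
primers (e.g. the Y in JS2), never in tags or reads, and primer matching must
be exact over the degeneracy sets.
"""

from __future__ import annotations

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an (IUPAC) DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_strict_dna(seq: str) -> bool:
    return bool(seq) and all(b in "ACGT" for b in seq)


def is_iupac_dna(seq: str) -> bool:
    return bool(seq) and all(b in IUPAC for b in seq)


def iupac_match(pattern: str, window: str) -> bool:
    """True iff `window` matches `pattern` base-for-base, with IUPAC
    degeneracy resolved on the pattern side only (reads carry ACGTN; an N in
    a read matches nothing but an N-degenerate pattern position)."""
    if len(pattern) != len(window):
        return False
    for p, w in zip(pattern, window):
        if w not in IUPAC.get(p, ""):
            return False
    return True


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
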