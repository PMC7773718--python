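"""Small shared DNA helpers: alphabets, reverse complement, encoding."""

from __future__ import annotations

import numpy as np

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)

# Watson-Crick pairing for hairpin/dimer screens (unambiguous bases only).
WC_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC DNA string, preserving case."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, *, unambiguous: bool = False, name: str = "sequence") -> str:
    """Uppercase *seq* and check its alphabet; return the normalized string."""
    if not seq:
        raise ValueError(f"{name} is empty")
    up = seq.upper()
    allowed = UNAMBIGUOUS if unambiguous else IUPAC_DNA
    bad = set(up) - allowed
    if bad:
        kind = "unambiguous ACGT" if unambiguous else "IUPAC DNA"
        raise ValueError(f"{name} contains non-{kind} characters: {sorted(bad)!r}")
    return up


def encode(seq: str) -> np.ndarray:
    """Byte-encode a DNA string as a uint8 array (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))
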