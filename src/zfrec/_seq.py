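"""Small nucleotide-sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base -> 0..3 code; anything else (incl. N) -> 4
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(DNA):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters beyond ACGTN untouched)."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    return bool(seq) and all(c in "ACGT" for c in seq.upper())


def check_dna(seq: str, what: str = "sequence") -> str:
    """Uppercase and validate a strict-ACGT sequence; raise ValueError otherwise."""
    s = seq.upper()
    bad = set(s) - set(DNA)
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return s


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to int8 codes A=0 C=1 G=2 T=3, other=4."""
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def pad_fill(length: int, cycle: str = "TCGA", phase: int = 0) -> str:
    """Deterministic filler of a given length cycling through `cycle`.

    Used for the spacer/pad bases between a lox site and its flanking ZF
    motifs: the screen only constrains their *length*, so any fixed sequence
    works; a cycle avoids homopolymer artifacts in simulated reads.
    """
    if length < 0:
        raise ValueError("pad length must be non-negative")
    if not cycle:
        raise ValueError("pad cycle must be non-empty")
    reps = (length + phase) // len(cycle) + 1
    return (cycle * reps)[phase : phase + length]
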