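"""Small DNA-string helpers shared across modules.

Sequences are plain upper-case A/C/G/T strings on the genomic top strand;
coordinates are 0-based half-open everywhere inside the package.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# uint8 complement table for vectorised work on byte-encoded sequences
COMP_U8 = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    COMP_U8[_a] = _b


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    """Byte view of a DNA string (uint8 ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    """Random sequence with expected G+C fraction ``gc``."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    p = [(1.0 - gc) / 2, gc / 2, gc / 2, (1.0 - gc) / 2]
    arr = rng.choice(seq_to_u8(BASES), size=n, p=p)
    return arr.tobytes().decode("ascii")


def base_composition(seq: str) -> np.ndarray:
    """Fractions of A, C, G, T (in that order)."""
    u8 = seq_to_u8(seq)
    counts = np.array([(u8 == ord(b)).sum() for b in BASES], dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty sequence")
    return counts / total
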