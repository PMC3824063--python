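"""Shared nucleotide-sequence helpers."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

# Encoding: A=0 C=1 G=2 T/U=3, N in a reference = 4, N in a read = 5.
# The two N codes are distinct so N never silently matches N: an N on
# either side is a mismatch at that position.
_REF_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}
_READ_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 5}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returns DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_ref(seq: str) -> np.ndarray:
    return np.frombuffer(
        bytes(_REF_CODE[c] for c in seq), dtype=np.uint8
    ).copy()


def encode_read(seq: str) -> np.ndarray:
    return np.frombuffer(
        bytes(_READ_CODE[c] for c in seq), dtype=np.uint8
    ).copy()
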