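"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

DNA_ALPHABET = "ACGT"

_COMP_STR = bytes.maketrans(b"ACGTacgtNn", b"TGCAtgcaNn")

# uint8 ASCII complement lookup (identity outside ACGTN)
COMP_U8 = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTacgtNn", b"TGCAtgcaNn"):
    COMP_U8[_a] = _b


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP_STR)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 ASCII array (copy)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
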