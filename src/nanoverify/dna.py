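"""Small DNA sequence helpers shared across the package."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
#: Symbol alphabet used by pileups and the caller; deletion is a fifth symbol.
SYMBOLS = "ACGT-"
SYMBOL_INDEX = {s: i for i, s in enumerate(SYMBOLS)}
DEL = "-"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_VALID = frozenset(BASES)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def validate_dna(seq: str, name: str = "sequence") -> str:
    """Return ``seq`` uppercased, raising ValueError on non-ACGT characters."""
    up = seq.upper()
    if not set(up) <= _VALID:
        bad = sorted(set(up) - _VALID)
        raise ValueError(f"{name} contains non-ACGT characters: {bad}")
    return up


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def seq_to_array(seq: str) -> np.ndarray:
    """Encode ACGT as uint8 codes 0..3 (anything else becomes 255)."""
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))
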