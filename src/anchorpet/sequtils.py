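"""Small DNA helpers shared across modules.

All genomic coordinates in this package are 1-based inclusive; conversion to
BED/bedGraph 0-based half-open happens only at file boundaries (see `io`).
"""

from __future__ import annotations

import math

import numpy as np

DNA_ALPHABET = frozenset("ACGT")
DNA_ALPHABET_N = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    """Uniform random DNA sequence of `length` bases."""
    if length <= 0:
        raise ValueError(f"sequence length must be positive, got {length}")
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def check_dna(seq: str, *, allow_n: bool = False, context: str = "sequence") -> None:
    alphabet = DNA_ALPHABET_N if allow_n else DNA_ALPHABET
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"{context} contains non-DNA characters: {sorted(bad)!r}")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal rounding with ties away from zero (table-style rounding).

    Python's builtin round() uses banker's rounding, which disagrees with how
    percentages are conventionally printed (2.45 -> 2.5, not 2.4).
    """
    scale = 10.0**ndigits
    rounded = math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)
    return rounded if ndigits > 0 else int(rounded)
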