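"""Low-level DNA string helpers shared across the package.

Sequences are plain upper-case A/C/G/T strings; coordinates are 0-based
half-open everywhere inside the library.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.40) -> str:
    """Random sequence with the requested GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(BASES[i] for i in idx)


def mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """Substitute each base independently with probability ``rate``.

    Substitutions always change the base (no silent identities), so the
    realised divergence from ``seq`` equals ``rate`` in expectation.
    """
    if rate <= 0:
        return seq
    n = len(seq)
    hits = np.flatnonzero(rng.random(n) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings, with early exit."""
    d = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                d += 1
        return d
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d
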