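"""Small nucleotide-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement (DNA space; U treated as T)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(rng: np.random.Generator, length: int) -> str:
    """Uniform i.i.d. DNA string of the given length."""
    return "".join(rng.choice(list(BASES), size=length))


def mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    """Apply i.i.d. substitution errors at the given per-base rate."""
    if error_rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    for i in hits:
        choices = [b for b in BASES if b != out[i]]
        out[i] = choices[rng.integers(3)]
    return "".join(out)
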