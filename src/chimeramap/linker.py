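"""Ungapped detection of the ligation linker inside a read or insert.

The linker is a 24-nt biotinylated RNA oligo ligated between the two RNA
fragments of a chimera; in DNA space (as sequenced) it reads
``CTAGTAGCCCATGCAATGCGAGGA``.  Because the linker is short and indels are
rare on Illumina instruments, matching is ungapped with a mismatch budget
proportional to the matched length.

Three placements are searched: the full linker anywhere inside the
sequence, a linker *prefix* hanging off the 3' end of the sequence, and a
linker *suffix* hanging off the 5' end (the latter two occur when a read
covers only part of the junction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

#: DNA-space sequence of the biotinylated RNA linker.
DEFAULT_LINKER = "CTAGTAGCCCATGCAATGCGAGGA"

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4,
              "a": 0, "c": 1, "g": 2, "t": 3, "u": 3, "n": 4}


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (N -> its own code)."""
    try:
        return np.frombuffer(bytes(_BASE_CODE[c] for c in seq), dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class LinkerMatch:
    """One ungapped linker occurrence within a sequence.

    ``start``/``end`` are 0-based half-open offsets in the searched sequence;
    ``kind`` records the placement: ``internal``/``full`` for the whole
    linker inside the read, ``prefix`` for a linker prefix at the read 3'
    end, ``suffix`` for a linker suffix at the read 5' end.
    """

    start: int
    end: int
    mismatches: int
    kind: str

    @property
    def length(self) -> int:
        return self.end - self.start


def find_linker(
    seq: str,
    linker: str = DEFAULT_LINKER,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
) -> Optional[LinkerMatch]:
    """Best-scoring ungapped linker occurrence in ``seq``, or ``None``.

    Candidates must satisfy ``mismatches <= floor(rate * matched_length)``.
    Ties are broken by longer matched length, then smaller start offset.
    """
    if not linker:
        raise ValueError("linker must be non-empty")
    if min_overlap < 4:
        raise ValueError("min_overlap must be >= 4")
    s = encode(seq)
    lk = encode(linker)
    n, m = len(s), len(lk)
    candidates = []  # (mismatches - is tested per candidate; rank by len desc, start asc)

    if n >= m:
        windows = np.lib.stride_tricks.sliding_window_view(s, m)
        mis = (windows != lk).sum(axis=1)
        budget = int(np.floor(max_mismatch_rate * m))
        ok = np.nonzero(mis <= budget)[0]
        for start in ok:
            kind = "full" if m == n else "internal"
            candidates.append(LinkerMatch(int(start), int(start) + m, int(mis[start]), kind))

    # linker prefix at the 3' end of the read (junction ran off the read end)
    max_hang = min(m - 1, n)
    for olen in range(max_hang, min_overlap - 1, -1):
        budget = int(np.floor(max_mismatch_rate * olen))
        d = int((s[n - olen:] != lk[:olen]).sum())
        if d <= budget:
            candidates.append(LinkerMatch(n - olen, n, d, "prefix"))
            break  # longer overlaps dominate shorter ones at the same end

    # linker suffix at the 5' end of the read
    for olen in range(max_hang, min_overlap - 1, -1):
        budget = int(np.floor(max_mismatch_rate * olen))
        d = int((s[:olen] != lk[m - olen:]).sum())
        if d <= budget:
            candidates.append(LinkerMatch(0, olen, d, "suffix"))
            break

    if not candidates:
        return None
    return min(candidates, key=lambda c: (-(c.length), c.start, c.mismatches))


def find_all_linkers(
    seq: str,
    linker: str = DEFAULT_LINKER,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
):
    """All non-overlapping full-length linker occurrences, greedy left-to-right.

    Used to detect reads carrying two disjoint linker copies (ambiguous
    chimeras, e.g. linker concatemers).
    """
    s = encode(seq)
    lk = encode(linker)
    n, m = len(s), len(lk)
    out = []
    if n < m:
        return out
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mis = (windows != lk).sum(axis=1)
    budget = int(np.floor(max_mismatch_rate * m))
    last_end = 0
    for start in np.nonzero(mis <= budget)[0]:
        if start >= last_end:
            out.append(LinkerMatch(int(start), int(start) + m, int(mis[start]), "internal"))
            last_end = int(start) + m
    return out
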