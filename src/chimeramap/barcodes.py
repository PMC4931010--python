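"""Sample demultiplexing and random-barcode (UMI) extraction.

Read 1 of each pair starts with a combined barcode block described by a
configuration string over the alphabet ``{N, X}`` read 5'->3': ``N``
positions hold random nucleotides used for PCR-duplicate removal (the UMI)
and ``X`` positions hold a fixed per-sample barcode used for multiplexed
sequencing.  The default configuration is ``NNNNXXXXNN`` (six random
nucleotides around a 4-nt sample barcode).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_LAYOUT_CONFIG = "NNNNXXXXNN"

#: Sample barcodes used in the mouse embryonic stem cell libraries.
DEFAULT_SAMPLE_BARCODES = {
    "ES-1": "AGGT",
    "ES-2": "CGCC",
    "ES-indirect": "CATT",
}

UNDETERMINED = "undetermined"


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming distance requires equal lengths ({len(a)} != {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_barcode_distance(sample_barcodes) -> int:
    """Minimum Hamming distance over all unordered pairs of distinct barcodes.

    A well-designed barcode set keeps this distance large so that single
    sequencing errors cannot flip one sample into another.

    Parameters
    ----------
    sample_barcodes
        Mapping ``sample_id -> barcode`` or an iterable of barcode strings.
    """
    if hasattr(sample_barcodes, "values"):
        codes = list(sample_barcodes.values())
    else:
        codes = list(sample_barcodes)
    distinct = sorted(set(codes))
    if len(distinct) < 2:
        raise ValueError("need at least 2 distinct barcodes")
    lengths = {len(c) for c in distinct}
    if len(lengths) != 1:
        raise ValueError(f"barcodes have unequal lengths: {sorted(lengths)}")
    return min(
        hamming(distinct[i], distinct[j])
        for i in range(len(distinct))
        for j in range(i + 1, len(distinct))
    )


@dataclass(frozen=True)
class BarcodeLayout:
    """Barcode block layout on read 1 plus the sample barcode table.

    ``config_string`` is a pattern over ``{N, X}``; every sample barcode must
    have length equal to the number of ``X`` positions.
    """

    config_string: str = DEFAULT_LAYOUT_CONFIG
    sample_barcodes: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLE_BARCODES))

    def __post_init__(self):
        bad = set(self.config_string) - {"N", "X"}
        if bad:
            raise ValueError(f"layout config may only contain N and X, got {sorted(bad)}")
        if not self.sample_barcodes:
            raise ValueError("at least one sample barcode is required")
        n_x = self.n_x_positions
        for sid, code in self.sample_barcodes.items():
            if len(code) != n_x:
                raise ValueError(
                    f"barcode {code!r} for sample {sid!r} does not match "
                    f"{n_x} X positions in {self.config_string!r}"
                )

    @property
    def length(self) -> int:
        return len(self.config_string)

    @property
    def n_positions(self) -> tuple:
        return tuple(i for i, c in enumerate(self.config_string) if c == "N")

    @property
    def x_positions(self) -> tuple:
        return tuple(i for i, c in enumerate(self.config_string) if c == "X")

    @property
    def n_x_positions(self) -> int:
        return self.config_string.count("X")

    @property
    def umi_length(self) -> int:
        return self.config_string.count("N")

    def min_distance(self) -> int:
        return min_pairwise_barcode_distance(self.sample_barcodes)


def demultiplex(read1_seq: str, layout: BarcodeLayout, max_mismatch: int = 1):
    """Assign a read to a sample and extract its UMI.

    Returns ``(sample_id, umi, payload_offset)``.  ``sample_id`` is
    :data:`UNDETERMINED` when no barcode lies within ``max_mismatch`` of the
    observed X positions, or when two barcodes tie at the minimum distance;
    unassignable reads are routed, not raised.
    """
    if len(read1_seq) <= layout.length:
        raise ValueError(
            f"read of length {len(read1_seq)} does not extend past the "
            f"{layout.length}-nt barcode block"
        )
    block = read1_seq[: layout.length]
    umi = "".join(block[i] for i in layout.n_positions)
    observed = "".join(block[i] for i in layout.x_positions)

    best_id, best_d, tie = None, None, False
    for sid, code in layout.sample_barcodes.items():
        d = hamming(observed, code)
        if best_d is None or d < best_d:
            best_id, best_d, tie = sid, d, False
        elif d == best_d:
            tie = True
    if best_d is None or best_d > max_mismatch or tie:
        return UNDETERMINED, umi, layout.length
    return best_id, umi, layout.length
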