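"""Chimeric read parsing: dedup, mate merging, linker splitting.

A proximity-ligation library yields inserts of the form
RNA1 + linker + RNA2 (the informative chimeras) together with
non-informative species: linker + RNA2 (no RNA1 was ligated), a bare
continuous fragment (no linker) and bare linker.  This module turns a
paired-end read stream into :class:`ParsedChimera` records carrying the two
fragment sequences and a category label, after exact-duplicate removal and
sample demultiplexing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .barcodes import UNDETERMINED, BarcodeLayout, demultiplex
from .dna import revcomp
from .linker import DEFAULT_LINKER, LinkerMatch, encode, find_all_linkers, find_linker

# chimera categories
CHIMERIC = "chimeric"
LINKER_RNA2 = "linker_rna2"
RNA1_LINKER = "rna1_linker"
LINKER_ONLY = "linker_only"
NO_LINKER = "no_linker"
AMBIGUOUS = "ambiguous"

CATEGORIES = (CHIMERIC, LINKER_RNA2, RNA1_LINKER, LINKER_ONLY, NO_LINKER, AMBIGUOUS)


@dataclass(frozen=True)
class ParsedChimera:
    """One read pair decomposed into its chimera components."""

    read_id: str
    sample_id: str
    umi: str
    rna1_seq: str
    rna2_seq: str
    category: str
    linker: Optional[LinkerMatch] = None

    def __post_init__(self):
        if (self.category == CHIMERIC) != (bool(self.rna1_seq) and bool(self.rna2_seq)):
            raise ValueError(
                "category 'chimeric' requires exactly the case of both "
                "rna1_seq and rna2_seq non-empty"
            )


@dataclass
class ParseOptions:
    linker: str = DEFAULT_LINKER
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    merge_min: int = 10
    merge_max_mismatch_rate: float = 0.1
    min_frag: int = 15
    demux_max_mismatch: int = 1


def dedup(read_pairs: Iterable[tuple]):
    """Collapse read pairs identical in both mate sequences.

    The random barcode is part of read 1, so true PCR duplicates (identical
    molecule, identical UMI) collapse while identical inserts tagged with
    different UMIs survive as distinct molecules.

    Accepts ``(read1_seq, read2_seq)`` or ``(read_id, read1_seq, read2_seq)``
    tuples; keeps the first occurrence of each pair, preserving order.
    Returns ``(unique_pairs, n_duplicates_removed)``.
    """
    seen = set()
    unique = []
    n_dup = 0
    for rec in read_pairs:
        key = (rec[-2], rec[-1])
        if key in seen:
            n_dup += 1
        else:
            seen.add(key)
            unique.append(rec)
    return unique, n_dup


def merge_mates(
    payload: str,
    read2_seq: str,
    merge_min: int = 10,
    max_mismatch_rate: float = 0.1,
) -> Optional[str]:
    """Reconstruct the insert from the read-1 payload and read 2.

    Read 2 sequences the opposite end of the same insert, so its reverse
    complement should overlap the 3' end of the read-1 payload.  Candidate
    offsets are seeded from an exact 16-mer, falling back to a full scan;
    an overlap of >= ``merge_min`` bases with at most
    ``max_mismatch_rate`` mismatches is accepted.  Returns the merged
    insert, or ``None`` when the two mates do not overlap.
    """
    rc2 = revcomp(read2_seq)
    if not payload:
        return rc2 or None
    p = encode(payload)
    q = encode(rc2)
    np_, nq = len(p), len(q)

    offsets = []
    seed_len = min(16, nq)
    if seed_len >= merge_min:
        pos = payload.find(rc2[:seed_len])
        while pos != -1:
            offsets.append(pos)
            pos = payload.find(rc2[:seed_len], pos + 1)
    if not offsets:
        offsets = range(0, np_ - merge_min + 1)

    best = None  # (mismatch_rate, -overlap, offset)
    for o in offsets:
        ov = min(np_ - o, nq)
        if ov < merge_min:
            continue
        mism = int((p[o:o + ov] != q[:ov]).sum())
        if mism > int(np.floor(max_mismatch_rate * ov)):
            continue
        cand = (mism / ov, -ov, o)
        if best is None or cand < best:
            best = cand
    if best is None:
        return None
    o = best[2]
    if o + nq >= np_:
        return payload[:o] + rc2
    return payload  # read 2 nested inside read 1 (degenerate short insert)


def _clip(frag: str, min_frag: int) -> str:
    return frag if len(frag) >= min_frag else ""


def _categorize(rna1: str, rna2: str, has_linker: bool) -> str:
    if not has_linker:
        return NO_LINKER
    if rna1 and rna2:
        return CHIMERIC
    if rna2:
        return LINKER_RNA2
    if rna1:
        return RNA1_LINKER
    return LINKER_ONLY


def split_read_pair(
    read_id: str,
    read1_seq: str,
    read2_seq: str,
    layout: BarcodeLayout,
    options: ParseOptions = None,
) -> ParsedChimera:
    """Demultiplex one pair and split its insert around the linker.

    When the mates overlap they are merged into a single insert; otherwise
    the linker is sought independently in each mate (it sits in one end of
    the pair) and the far mate supplies the other fragment.  Two disjoint
    full linker copies, or a linker found in inconsistent orientation in
    both mates, produce the ``ambiguous`` category.
    """
    opt = options or ParseOptions()
    sample_id, umi, off = demultiplex(read1_seq, layout, opt.demux_max_mismatch)
    payload = read1_seq[off:]

    short_dropped = 0

    def finish(rna1, rna2, match, has_linker):
        nonlocal short_dropped
        c1, c2 = _clip(rna1, opt.min_frag), _clip(rna2, opt.min_frag)
        short_dropped += int(bool(rna1) and not c1) + int(bool(rna2) and not c2)
        cat = _categorize(c1, c2, has_linker)
        return ParsedChimera(read_id, sample_id, umi, c1, c2, cat, match)

    merged = merge_mates(payload, read2_seq, opt.merge_min, opt.merge_max_mismatch_rate)
    if merged is not None:
        full_hits = find_all_linkers(merged, opt.linker, opt.min_overlap, opt.max_mismatch_rate)
        if len(full_hits) >= 2:
            return ParsedChimera(read_id, sample_id, umi, "", "", AMBIGUOUS, None)
        m = find_linker(merged, opt.linker, opt.min_overlap, opt.max_mismatch_rate)
        if m is None:
            return finish(merged, "", None, False)
        return finish(merged[: m.start], merged[m.end:], m, True)

    # unmerged: the linker can sit in either mate; the other mate is the
    # distal end of the opposite fragment
    rc2 = revcomp(read2_seq)
    m1 = find_linker(payload, opt.linker, opt.min_overlap, opt.max_mismatch_rate)
    m2 = find_linker(rc2, opt.linker, opt.min_overlap, opt.max_mismatch_rate)
    if m1 is not None and m2 is not None:
        # consistent only if read1 sees the linker 3' part and read2 its 5' part
        consistent = m1.kind == "prefix" and m2.kind == "suffix"
        if not consistent:
            return ParsedChimera(read_id, sample_id, umi, "", "", AMBIGUOUS, None)
        return finish(payload[: m1.start], rc2[m2.end:], m1, True)
    if m1 is not None:
        return finish(payload[: m1.start], rc2, m1, True)
    if m2 is not None:
        return finish(payload, rc2[m2.end:], m2, True)
    return finish(payload, "", None, False)


@dataclass
class ParseStats:
    n_input: int = 0
    n_duplicates: int = 0
    n_undetermined: int = 0
    category_counts: dict = field(default_factory=dict)
    per_sample: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "input_pairs": self.n_input,
            "duplicates_removed": self.n_duplicates,
            "undetermined": self.n_undetermined,
            "category_counts": dict(self.category_counts),
            "per_sample": dict(self.per_sample),
        }


def parse_read_pairs(
    read_pairs: Iterable[tuple],
    layout: BarcodeLayout,
    options: ParseOptions = None,
):
    """Full read-level pipeline: dedup -> demultiplex -> linker split.

    ``read_pairs`` yields ``(read_id, read1_seq, read2_seq)``.  Returns
    ``(chimeras, stats)`` where undetermined-sample reads are excluded from
    ``chimeras`` but counted in ``stats``.
    """
    opt = options or ParseOptions()
    records = list(read_pairs)
    unique, n_dup = dedup(records)
    stats = ParseStats(n_input=len(records), n_duplicates=n_dup)
    out = []
    for read_id, r1, r2 in unique:
        pc = split_read_pair(read_id, r1, r2, layout, opt)
        if pc.sample_id == UNDETERMINED:
            stats.n_undetermined += 1
            continue
        stats.category_counts[pc.category] = stats.category_counts.get(pc.category, 0) + 1
        stats.per_sample[pc.sample_id] = stats.per_sample.get(pc.sample_id, 0) + 1
        out.append(pc)
    return out, stats
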