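"""Intramolecular (cut-and-ligated) structure evidence.

A chimera whose two fragments map to the *same* gene records a cut followed
by a proximity ligation within one folded molecule.  After filtering out
read pairs that are geometrically indistinguishable from an intact
continuous fragment, each event contributes:

* two junction coordinates (the 3' end of fragment 1, ligated to the
  linker 5' end, and the 5' end of fragment 2, ligated to the linker 3'
  end) marking two transcript positions that were spatially close;
* fragment termini, each a candidate endonuclease (RNase I) cut site,
  accumulating into a single-strandedness footprint;
* one count in a symmetric binned contact map of ligation frequencies.

Clusters of three or more events with overlapping junction positions are
called proximal site pairs.  All coordinates here are transcript-space,
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

CLASS_I = "I"
CLASS_II = "II"


@dataclass(frozen=True)
class ChimeraAlignment:
    """Genomic view of one linker-containing read pair, pre-filtering.

    ``fwd_start``/``rev_start`` describe the genomic placements of the two
    mates (for the continuous-fragment geometry test); ``frag1``/``frag2``
    are the transcript-space fragment intervals once the pair is accepted.
    """

    read_id: str
    gene1: Optional[str]
    gene2: Optional[str]
    has_linker: bool
    frag1_strand: str
    frag2_strand: str
    frag1_genomic: Tuple[int, int]
    frag2_genomic: Tuple[int, int]
    frag1_transcript: Optional[Tuple[int, int]] = None
    frag2_transcript: Optional[Tuple[int, int]] = None


@dataclass(frozen=True)
class IntraPair:
    """One accepted intramolecular cut-and-ligation event."""

    read_id: str
    gene_id: str
    frag1: Tuple[int, int]  # transcript coordinates, half-open
    frag2: Tuple[int, int]
    structural_class: str = ""

    @property
    def junction1(self) -> int:
        """3' terminus of fragment 1 (last covered base) — ligated end."""
        return self.frag1[1] - 1

    @property
    def junction2(self) -> int:
        """5' terminus of fragment 2 — ligated end."""
        return self.frag2[0]


@dataclass
class FilterReport:
    n_input: int = 0
    n_kept: int = 0
    dropped: Dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str):
        self.dropped[reason] = self.dropped.get(reason, 0) + 1


def filter_intramolecular(
    alignments: Iterable[ChimeraAlignment],
    max_continuous_span: int = 2000,
) -> Tuple[List[IntraPair], FilterReport]:
    """Select same-gene, linker-containing pairs with chimeric geometry.

    Dropped, with per-reason counts: pairs spanning two genes; pairs
    without any fraction of the linker; and pairs whose mates form the
    *continuous fragment* geometry — opposite strands within
    ``max_continuous_span`` bp with the plus-strand mate upstream of the
    minus-strand mate — which is exactly what an ordinary un-cut insert
    looks like in paired-end sequencing.
    """
    kept: List[IntraPair] = []
    report = FilterReport()
    for al in alignments:
        report.n_input += 1
        if al.gene1 is None or al.gene2 is None or al.gene1 != al.gene2:
            report.drop("different_genes")
            continue
        if not al.has_linker:
            report.drop("no_linker")
            continue
        if al.frag1_strand != al.frag2_strand:
            # opposite-strand mates: continuous-fragment geometry when the
            # plus-strand mate starts upstream of the minus-strand mate
            if al.frag1_strand == "+":
                plus, minus = al.frag1_genomic, al.frag2_genomic
            else:
                plus, minus = al.frag2_genomic, al.frag1_genomic
            span = max(plus[1], minus[1]) - min(plus[0], minus[0])
            if plus[0] < minus[0] and span <= max_continuous_span:
                report.drop("continuous_fragment_geometry")
                continue
        if al.frag1_transcript is None or al.frag2_transcript is None:
            report.drop("no_transcript_projection")
            continue
        report.n_kept += 1
        kept.append(IntraPair(al.read_id, al.gene1,
                              al.frag1_transcript, al.frag2_transcript))
    return kept, report


def classify_structure(ip: IntraPair) -> Optional[str]:
    """Assign an event to one of the two structural classes.

    Class I: fragment 1 (the linker-upstream fragment in the read) lies 5'
    of fragment 2 on the transcript — the cut simply interrupted the
    molecule and its ends re-ligated in order.  Class II: fragment 1 lies
    3' of fragment 2 — the circularized geometry in which the transcript's
    downstream segment appears first in the read.  Overlapping fragments
    are classified by junction order; identical junctions are ambiguous
    and return ``None``.
    """
    if ip.junction1 == ip.junction2:
        return None
    return CLASS_I if ip.junction1 < ip.junction2 else CLASS_II


def classify_all(intra_pairs: Iterable[IntraPair]):
    """Classify a batch; returns ``(classified_pairs, n_ambiguous)``."""
    out, n_amb = [], 0
    for ip in intra_pairs:
        cls = classify_structure(ip)
        if cls is None:
            n_amb += 1
            continue
        out.append(IntraPair(ip.read_id, ip.gene_id, ip.frag1, ip.frag2, cls))
    return out, n_amb


# ---------------------------------------------------------------------------
# cut-density footprint

@dataclass(frozen=True)
class CutDensityTrack:
    gene_id: str
    counts: np.ndarray  # per transcript position: number of fragment termini

    def smoothed(self, window: int = 5) -> np.ndarray:
        """Moving-mean smoothing for reporting (does not alter counts)."""
        kernel = np.ones(window) / window
        return np.convolve(self.counts, kernel, mode="same")


def cut_density(
    gene_id: str,
    fragments: Iterable[Tuple[int, int]],
    transcript_length: int,
) -> CutDensityTrack:
    """Count fragment termini per transcript position.

    Every fragment terminus (5' start and 3' last covered base) is a
    candidate RNase I cut; single-stranded regions accumulate high
    terminus density.
    """
    counts = np.zeros(transcript_length, dtype=np.int64)
    for s, e in fragments:
        if not (0 <= s < e <= transcript_length):
            raise ValueError(f"fragment [{s}, {e}) outside transcript")
        counts[s] += 1
        counts[e - 1] += 1
    return CutDensityTrack(gene_id, counts)


# ---------------------------------------------------------------------------
# ligation contact map

@dataclass(frozen=True)
class ContactMap:
    gene_id: str
    matrix: np.ndarray  # symmetric, shape (n_bins, n_bins)
    bin_size: int

    @property
    def n_events(self) -> int:
        m = self.matrix
        return int(np.triu(m).sum())


def contact_map(
    gene_id: str,
    intra_pairs: Iterable[IntraPair],
    transcript_length: int,
    bin_size: int = 5,
) -> ContactMap:
    """Symmetric binned matrix of ligation frequencies between positions.

    Each event increments the (bin(junction1), bin(junction2)) cell and its
    transpose (once when the two bins coincide), so the upper triangle sums
    to the event count.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = int(np.ceil(transcript_length / bin_size))
    m = np.zeros((n_bins, n_bins), dtype=np.int64)
    for ip in intra_pairs:
        j1, j2 = ip.junction1, ip.junction2
        for j in (j1, j2):
            if not (0 <= j < transcript_length):
                raise ValueError(f"junction {j} outside transcript of length "
                                 f"{transcript_length} ({gene_id})")
        b1, b2 = j1 // bin_size, j2 // bin_size
        m[b1, b2] += 1
        if b1 != b2:
            m[b2, b1] += 1
    return ContactMap(gene_id, m, bin_size)


# ---------------------------------------------------------------------------
# proximal site pairs

@dataclass(frozen=True)
class ProximalSitePair:
    gene_id: str
    window1: Tuple[int, int]  # [min, max] of member junction1 positions
    window2: Tuple[int, int]
    support: int


def call_proximal_pairs(
    intra_pairs: List[IntraPair],
    min_support: int = 3,
    tol: int = 10,
) -> List[ProximalSitePair]:
    """Cluster events in (junction1, junction2) space; report clusters.

    Single-linkage: two events join when both junction coordinates differ
    by at most ``tol``.  Clusters supported by >= ``min_support`` events
    become proximal site pairs whose windows span the member junctions.
    Events from different genes never link.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    by_gene: Dict[str, List[IntraPair]] = {}
    for ip in intra_pairs:
        by_gene.setdefault(ip.gene_id, []).append(ip)

    out: List[ProximalSitePair] = []
    for gene_id in sorted(by_gene):
        events = by_gene[gene_id]
        n = len(events)
        # union-find over events
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if (abs(events[i].junction1 - events[j].junction1) <= tol
                        and abs(events[i].junction2 - events[j].junction2) <= tol):
                    parent[find(i)] = find(j)
        clusters: Dict[int, List[IntraPair]] = {}
        for i in range(n):
            clusters.setdefault(find(i), []).append(events[i])
        for members in clusters.values():
            if len(members) < min_support:
                continue
            j1 = [m.junction1 for m in members]
            j2 = [m.junction2 for m in members]
            out.append(ProximalSitePair(gene_id, (min(j1), max(j1)),
                                        (min(j2), max(j2)), len(members)))
    out.sort(key=lambda p: (p.gene_id, p.window1, p.window2))
    return out
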