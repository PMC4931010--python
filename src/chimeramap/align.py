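"""Fragment placement and gene/repeat assignment.

Fragments produced by the parser are placed on the genome either by
ingesting alignments from an external aligner (SAM/BAM, see
:mod:`chimeramap.io`) or by the built-in exact-seed toy aligner, which is
adequate for the fixture-scale genomes used in simulation.  Placed
fragments are then assigned to annotated genes, to repeat families, or to
novel loci built by strand-aware merging of leftover fragments.  A
cross-species mixture (two transcriptomes mixed before ligation) yields an
estimate of the random-ligation rate: chimeras joining the two species can
only arise from ligation of molecules that were never co-complexed.

Coordinates are 0-based half-open on the genome throughout; transcript
coordinates run 5'->3' along the mature transcript.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from intervaltree import IntervalTree
from statsmodels.stats.proportion import proportion_confint

from .dna import revcomp


@dataclass(frozen=True)
class MappedFragment:
    """Genomic placement of one fragment (one side of a chimera)."""

    read_id: str
    side: str  # "rna1" | "rna2"
    reference: str
    start: int
    end: int
    strand: str
    unique: bool = True
    mismatches: int = 0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


BIOTYPES = ("mRNA", "lincRNA", "snoRNA", "snRNA", "tRNA", "miRNA",
            "pseudogene", "antisense", "novel")

REPEAT_FAMILIES = ("L1", "SINE", "ERVK", "MaLR", "ERV1", "LTR", "other")


@dataclass
class GeneModel:
    """A gene with sorted, non-overlapping exon intervals on one reference."""

    gene_id: str
    biotype: str
    reference: str
    strand: str
    intervals: List[Tuple[int, int]]

    def __post_init__(self):
        iv = sorted(self.intervals)
        for (s1, e1), (s2, e2) in zip(iv, iv[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping exons in gene {self.gene_id}")
        self.intervals = iv
        self._starts = [s for s, _ in iv]
        self._offsets = np.cumsum([0] + [e - s for s, e in iv]).tolist()

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def transcript_length(self) -> int:
        return self._offsets[-1]

    def to_transcript(self, genome_pos: int) -> int:
        """Map a genomic position inside an exon to transcript coordinates.

        On the minus strand the transcript runs right-to-left on the genome.
        """
        i = bisect.bisect_right(self._starts, genome_pos) - 1
        if i < 0 or genome_pos >= self.intervals[i][1]:
            raise ValueError(f"position {genome_pos} not exonic in {self.gene_id}")
        fwd = self._offsets[i] + (genome_pos - self.intervals[i][0])
        if self.strand == "+":
            return fwd
        return self.transcript_length - 1 - fwd

    def interval_to_transcript(self, start: int, end: int) -> Tuple[int, int]:
        """Project a genomic half-open interval into transcript coordinates."""
        a = self.to_transcript(start)
        b = self.to_transcript(end - 1)
        lo, hi = (a, b) if a <= b else (b, a)
        return lo, hi + 1

    def overlap(self, start: int, end: int) -> int:
        return sum(max(0, min(e, end) - max(s, start)) for s, e in self.intervals)


@dataclass(frozen=True)
class RepeatElement:
    family: str
    reference: str
    start: int
    end: int
    strand: str

    @property
    def gene_like_id(self) -> str:
        return f"repeat:{self.family}"


@dataclass
class PanGenome:
    """Reference-name -> species tag map for pan-genome (mixed) mapping."""

    species_of: Dict[str, str]

    def species(self, reference: str) -> str:
        try:
            return self.species_of[reference]
        except KeyError:
            raise KeyError(f"reference {reference!r} has no species tag") from None


# ---------------------------------------------------------------------------
# toy aligner

UNMAPPED = "unmapped"
AMBIGUOUS_LOCUS = "ambiguous"


class KmerIndex:
    """Exact k-mer seed table over a small genome (both strands via query rc).

    This is deliberately a fixture-scale aligner: ungapped, at most
    ``max_mismatches`` substitutions, intended for toy genomes of at most a
    few megabases.  Real libraries are aligned externally and ingested as
    SAM/BAM.
    """

    def __init__(self, sequences: Dict[str, str], k: int = 15):
        self.k = k
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.table: Dict[str, list] = {}
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self.table.setdefault(seq[i:i + k], []).append((name, i))

    def reference_length(self, name: str) -> int:
        return len(self.sequences[name])


def _count_mismatches(a: str, b: str, limit: int) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def toy_align(
    fragment_seq: str,
    index: KmerIndex,
    read_id: str = "",
    side: str = "rna1",
    max_mismatches: int = 2,
) -> Tuple[str, Optional[MappedFragment]]:
    """Place one fragment; returns ``(status, MappedFragment | None)``.

    ``status`` is ``"unique"``, ``"ambiguous"`` (several equally good loci;
    the best one is still returned with ``unique=False``) or ``"unmapped"``.
    """
    frag = fragment_seq.upper()
    L = len(frag)
    k = index.k
    if L < k:
        return UNMAPPED, None

    hits = {}  # (ref, start, strand) -> mismatches
    for strand, query in (("+", frag), ("-", revcomp(frag))):
        seed_offsets = sorted({0, L // 2, L - k}) if L >= k else [0]
        for off in seed_offsets:
            for ref, pos in index.table.get(query[off:off + k], ()):
                start = pos - off
                if start < 0 or start + L > index.reference_length(ref):
                    continue
                key = (ref, start, strand)
                if key in hits:
                    continue
                mism = _count_mismatches(query, index.sequences[ref][start:start + L],
                                         max_mismatches)
                if mism <= max_mismatches:
                    hits[key] = mism
    if not hits:
        return UNMAPPED, None
    best = min(hits.values())
    best_keys = [kk for kk, v in hits.items() if v == best]
    ref, start, strand = min(best_keys)
    unique = len(best_keys) == 1
    frag_obj = MappedFragment(read_id, side, ref, start, start + L, strand,
                              unique=unique, mismatches=best)
    return ("unique" if unique else AMBIGUOUS_LOCUS), frag_obj


# ---------------------------------------------------------------------------
# gene / repeat / novel-locus assignment

AMBIGUOUS_GENE = "ambiguous"


class GeneAnnotation:
    """Strand-aware interval lookup over a set of :class:`GeneModel`."""

    def __init__(self, genes: List[GeneModel]):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene ids in annotation")
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for g in genes:
            tree = self._trees.setdefault((g.reference, g.strand), IntervalTree())
            for s, e in g.intervals:
                tree.addi(s, e, g.gene_id)

    def overlapping(self, reference: str, strand: str, start: int, end: int):
        tree = self._trees.get((reference, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})


class RepeatAnnotation:
    def __init__(self, repeats: List[RepeatElement]):
        self.repeats = list(repeats)
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for r in repeats:
            self._trees.setdefault((r.reference, r.strand), IntervalTree()).addi(
                r.start, r.end, r)

    def best_overlap(self, reference, strand, start, end):
        tree = self._trees.get((reference, strand))
        if tree is None:
            return None, 0
        best, best_ov = None, 0
        for iv in tree.overlap(start, end):
            ov = min(iv.end, end) - max(iv.begin, start)
            if ov > best_ov:
                best, best_ov = iv.data, ov
        return best, best_ov


def assign_gene(
    frag: MappedFragment,
    annotation: GeneAnnotation,
    repeats: Optional[RepeatAnnotation] = None,
    min_overlap_frac: float = 0.5,
) -> Optional[str]:
    """Assign a uniquely mapped fragment to a same-strand feature.

    Priority: annotated gene covering >= ``min_overlap_frac`` of the
    fragment (two qualifying genes -> ``"ambiguous"``), then repeat family
    (as ``"repeat:<family>"``), then ``None`` (novel-locus candidate).
    """
    if not frag.unique:
        raise ValueError("assign_gene requires a uniquely mapped fragment")
    need = min_overlap_frac * frag.length
    qualifying = []
    for gid in annotation.overlapping(frag.reference, frag.strand, frag.start, frag.end):
        ov = annotation.genes[gid].overlap(frag.start, frag.end)
        if ov >= need:
            qualifying.append(gid)
    if len(qualifying) > 1:
        return AMBIGUOUS_GENE
    if len(qualifying) == 1:
        return qualifying[0]
    if repeats is not None:
        rep, ov = repeats.best_overlap(frag.reference, frag.strand, frag.start, frag.end)
        if rep is not None and ov >= need:
            return rep.gene_like_id
    return None


def build_novel_loci(
    fragments: List[MappedFragment],
    max_gap: int = 100,
) -> Tuple[Dict[Tuple[str, str], str], List[GeneModel]]:
    """Merge unassigned fragments into novel loci (strand-aware, gap <= max_gap).

    Returns ``(assignment, loci)`` where ``assignment`` maps
    ``(read_id, side)`` to a stable novel-locus id.  Ids are assigned in
    sorted genomic order, so they are independent of input order.
    """
    frags = sorted(fragments, key=lambda f: (f.reference, f.strand, f.start, f.end,
                                             f.read_id, f.side))
    assignment: Dict[Tuple[str, str], str] = {}
    loci: List[GeneModel] = []
    cluster: List[MappedFragment] = []

    def flush():
        if not cluster:
            return
        gid = f"novel:{len(loci) + 1}"
        g = GeneModel(gid, "novel", cluster[0].reference, cluster[0].strand,
                      [(min(f.start for f in cluster), max(f.end for f in cluster))])
        loci.append(g)
        for f in cluster:
            assignment[(f.read_id, f.side)] = gid

    for f in frags:
        if cluster and (f.reference != cluster[-1].reference
                        or f.strand != cluster[-1].strand
                        or f.start > max(c.end for c in cluster) + max_gap):
            flush()
            cluster = []
        cluster.append(f)
    flush()
    return assignment, loci


# ---------------------------------------------------------------------------
# random-ligation estimate from a cross-species mixture

@dataclass(frozen=True)
class RandomLigationEstimate:
    """Raw inter-species chimera fraction with Wilson CI and mixing correction.

    Only half (for an equal mixture) of random ligations join the two
    species, so the raw fraction underestimates the true random-ligation
    rate by the factor ``2 p (1 - p)`` where ``p`` is the species-1 share
    of molecules; the corrected estimate divides this factor out.  The raw
    fraction is the conservative, reported quantity.
    """

    n_pairs: int
    n_inter: int
    fraction: float
    ci_low: float
    ci_high: float
    species1_share: float
    corrected: float


def estimate_random_ligation(species_pairs, pan: Optional[PanGenome] = None,
                             alpha: float = 0.05) -> RandomLigationEstimate:
    """Estimate the random-ligation rate from species-tagged chimera sides.

    ``species_pairs`` yields ``(tag1, tag2)`` per uniquely mapped chimera;
    when ``pan`` is given the tags are reference names translated through
    the pan genome.
    """
    pairs = list(species_pairs)
    if pan is not None:
        pairs = [(pan.species(a), pan.species(b)) for a, b in pairs]
    if not pairs:
        raise ValueError("no eligible uniquely-mapped chimeric pairs")
    n = len(pairs)
    n_inter = sum(a != b for a, b in pairs)
    frac = n_inter / n
    lo, hi = proportion_confint(n_inter, n, alpha=alpha, method="wilson")
    species = sorted({s for p in pairs for s in p})
    first = species[0]
    p1 = sum((a == first) + (b == first) for a, b in pairs) / (2 * n)
    denom = 2 * p1 * (1 - p1)
    corrected = frac / denom if denom > 0 else float("nan")
    return RandomLigationEstimate(n, n_inter, frac, float(lo), float(hi), p1, corrected)
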