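"""Synthetic proximity-ligation libraries with full ground truth.

The generator emulates the experimental construct: RNA fragments from a
synthetic genome are joined through the linker into
RNA1 + linker + RNA2 inserts, barcoded, read as a paired-end library, and
contaminated with the realistic failure modes of the protocol — random
(non-co-complexed) ligations, non-informative linker-RNA2 and linker-only
molecules, continuous fragments without linker, PCR duplicates and
sequencing errors.  Every emitted read carries a truth record so each
pipeline stage can be scored exactly.

Deliberate simplifications (see docs/methods.md): genes are single-exon,
bases are i.i.d. uniform, fragment lengths are clamped log-normal and kept
short enough that the ligation junction is always covered by the read
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .align import GeneModel, PanGenome
from .barcodes import BarcodeLayout
from .dna import mutate, random_seq, revcomp
from .linker import DEFAULT_LINKER
from .parse import CHIMERIC, LINKER_ONLY, LINKER_RNA2, NO_LINKER

DEFAULT_BIOTYPE_COUNTS = {
    "mRNA": 20, "lincRNA": 20, "snoRNA": 20,
    "snRNA": 20, "tRNA": 20, "pseudogene": 20,
}

DEFAULT_CATEGORY_MIX = {
    CHIMERIC: 0.70, LINKER_RNA2: 0.15, NO_LINKER: 0.10, LINKER_ONLY: 0.05,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic library; defaults are the study conditions."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 60_000
    biotype_counts: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BIOTYPE_COUNTS))
    gene_length_range: Tuple[int, int] = (300, 800)
    intergenic_gap_range: Tuple[int, int] = (100, 400)

    # interactome
    n_edges: int = 200
    edges: Optional[List[Tuple[str, str]]] = None  # explicit edge list overrides
    edge_weight_sigma: float = 1.0  # log-normal spread of per-edge read weights

    # library
    n_read_pairs: int = 50_000
    read_length: int = 100
    random_ligation_rate: float = 0.07
    duplicate_rate: float = 0.20
    error_rate: float = 0.005
    category_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    layout: BarcodeLayout = field(default_factory=BarcodeLayout)
    linker: str = DEFAULT_LINKER
    # log-normal fragment lengths, clamped so the junction is always read
    frag_len_median: int = 60
    frag_len_sigma: float = 0.35
    frag_len_range: Tuple[int, int] = (15, 75)

    # intramolecular structure
    n_structure_genes: int = 5
    proximal_pairs_per_gene: int = 2
    reads_per_proximal_pair: int = 8
    background_intra_per_gene: int = 20
    hotspots_per_gene: int = 2
    hotspot_width: int = 20
    hotspot_weight: float = 10.0
    junction_jitter: int = 2

    # optional second species (cross-species random-ligation control)
    two_species: bool = False

    def validate(self):
        for name in ("random_ligation_rate", "duplicate_rate", "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = sum(self.category_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category mix sums to {total}, not 1")


@dataclass
class StructureTruth:
    gene_id: str
    proximal_pairs: List[Tuple[int, int]]          # (p, q) transcript positions
    hotspots: List[Tuple[int, int]]                # cut-probability-boosted intervals
    reads_per_pair: Dict[Tuple[int, int], int] = field(default_factory=dict)


@dataclass
class ReadTruth:
    category: str
    sample_id: str
    umi: str
    gene1: Optional[str] = None
    gene2: Optional[str] = None
    rna1_seq: str = ""
    rna2_seq: str = ""
    frag1_locus: Optional[Tuple[str, int, int, str]] = None
    frag2_locus: Optional[Tuple[str, int, int, str]] = None
    is_random_ligation: bool = False
    is_intra: bool = False
    junctions: Optional[Tuple[int, int]] = None    # transcript coords (j1, j2)
    duplicate_of: Optional[str] = None


@dataclass
class SimTruth:
    reads: Dict[str, ReadTruth]
    edges: Dict[Tuple[str, str], int]              # planted edge -> emitted reads
    structures: Dict[str, StructureTruth]
    n_string_duplicates: int = 0                   # total - distinct (r1, r2) keys


@dataclass
class Reference:
    sequences: Dict[str, str]
    genes: List[GeneModel]
    biotypes: Dict[str, str]
    pan: Optional[PanGenome] = None

    def __post_init__(self):
        self.gene_by_id = {g.gene_id: g for g in self.genes}

    def transcript_seq(self, gene_id: str) -> str:
        g = self.gene_by_id[gene_id]
        seq = "".join(self.sequences[g.reference][s:e] for s, e in g.intervals)
        return revcomp(seq) if g.strand == "-" else seq


def _place_species(cfg: SimConfig, rng: np.random.Generator, tag: str,
                   genes: List[GeneModel], sequences: Dict[str, str]):
    names = [f"{tag}chr{i + 1}" for i in range(cfg.n_chromosomes)]
    for name in names:
        sequences[name] = random_seq(rng, cfg.chromosome_length)
    biotype_list = [bt for bt, n in sorted(cfg.biotype_counts.items())
                    for _ in range(n)]
    rng.shuffle(biotype_list)
    cursors = {name: int(rng.integers(*cfg.intergenic_gap_range)) for name in names}
    for i, bt in enumerate(biotype_list):
        length = int(rng.integers(*cfg.gene_length_range))
        placed = False
        for name in sorted(cursors, key=lambda n: cursors[n]):
            if cursors[name] + length <= cfg.chromosome_length:
                start = cursors[name]
                strand = "+" if rng.random() < 0.5 else "-"
                gid = f"{tag}gene{i + 1:03d}"
                genes.append(GeneModel(gid, bt, name, strand, [(start, start + length)]))
                cursors[name] = start + length + int(rng.integers(*cfg.intergenic_gap_range))
                placed = True
                break
        if not placed:
            raise ValueError(
                "cannot place genes without overlap; increase chromosome_length "
                "or n_chromosomes")


def make_reference(cfg: SimConfig) -> Reference:
    """Random chromosomes with non-overlapping single-exon genes.

    Deterministic under ``cfg.seed``.  With ``two_species`` a second,
    independent genome is generated and both are tagged in a pan genome.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes: List[GeneModel] = []
    sequences: Dict[str, str] = {}
    tags = ["sp1_", "sp2_"] if cfg.two_species else [""]
    for tag in tags:
        _place_species(cfg, rng, tag, genes, sequences)
    pan = None
    if cfg.two_species:
        pan = PanGenome({name: ("species1" if name.startswith("sp1_") else "species2")
                         for name in sequences})
    return Reference(sequences, genes, {g.gene_id: g.biotype for g in genes}, pan)


# ---------------------------------------------------------------------------
# library simulation

def _frag_length(cfg: SimConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.frag_len_range
    val = int(round(rng.lognormal(np.log(cfg.frag_len_median), cfg.frag_len_sigma)))
    return int(np.clip(val, lo, hi))


def _random_fragment(cfg, rng, ref: Reference, gene_id: str) -> Tuple[str, int, int]:
    """Fragment (sequence, transcript start, transcript end) from one gene."""
    tseq = ref.transcript_seq(gene_id)
    L = len(tseq)
    flen = min(_frag_length(cfg, rng), L)
    start = int(rng.integers(0, L - flen + 1))
    return tseq[start:start + flen], start, start + flen


def _transcript_to_genomic(g: GeneModel, t_start: int, t_end: int):
    """Genomic locus of a transcript interval (single-exon genes)."""
    gs, ge = g.intervals[0]
    if g.strand == "+":
        return (g.reference, gs + t_start, gs + t_end, "+")
    L = g.transcript_length
    return (g.reference, gs + (L - t_end), gs + (L - t_start), "-")


def _pa_edges(rng: np.random.Generator, gene_ids: List[str],
              n_edges: int) -> List[Tuple[str, str]]:
    # preferential attachment: each new gene connects to earlier genes
    # chosen proportionally to current degree
    import networkx as nx
    m = max(1, round(n_edges / max(1, len(gene_ids) - 2)))
    graph = nx.barabasi_albert_graph(len(gene_ids), m,
                                     seed=int(rng.integers(2 ** 31)))
    edges = [tuple(sorted((gene_ids[u], gene_ids[v]))) for u, v in graph.edges()]
    rng.shuffle(edges)
    return edges[:n_edges]


def _sample_edges(cfg: SimConfig, rng: np.random.Generator,
                  gene_ids: List[str]) -> List[Tuple[str, str]]:
    if cfg.edges is not None:
        return [tuple(sorted(e)) for e in cfg.edges]
    if cfg.two_species:
        # genuine interactions only form within a species: the two lysates
        # are mixed after cross-linking, so cross-species pairs can arise
        # solely from random ligation
        out = []
        for tag in ("sp1_", "sp2_"):
            ids = [g for g in gene_ids if g.startswith(tag)]
            out.extend(_pa_edges(rng, ids, cfg.n_edges // 2))
        return out
    return _pa_edges(rng, gene_ids, cfg.n_edges)


@dataclass
class SimLibrary:
    reads: List[Tuple[str, str, str]]  # (read_id, read1_seq, read2_seq)
    truth: SimTruth
    reference: Reference
    config: SimConfig


def simulate_library(cfg: SimConfig, reference: Optional[Reference] = None) -> SimLibrary:
    """Generate a paired-end library plus truth from the planted model.

    Reads are built as ``read1 = barcode block + insert 5' end`` and
    ``read2 = reverse complement of the insert 3' end`` (adapter-trimmed),
    then duplicated and error-mutated per the configured rates.
    """
    cfg.validate()
    ref = reference if reference is not None else make_reference(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    gene_ids = sorted(ref.gene_by_id)
    samples = sorted(cfg.layout.sample_barcodes)
    edges = _sample_edges(cfg, rng, gene_ids)
    weights = rng.lognormal(0.0, cfg.edge_weight_sigma, size=len(edges))
    weights /= weights.sum()

    # plant structures on the first mRNA genes with transcripts long enough
    # to hold two well-separated fragments
    min_struct_len = 3 * cfg.frag_len_range[1] + 100
    struct_genes = [g for g in gene_ids
                    if ref.biotypes[g] == "mRNA"
                    and ref.gene_by_id[g].transcript_length >= min_struct_len
                    ][: cfg.n_structure_genes]
    structures: Dict[str, StructureTruth] = {}
    cut_weights: Dict[str, np.ndarray] = {}
    for gid in struct_genes:
        L = ref.gene_by_id[gid].transcript_length
        w = np.ones(L)
        hotspots = []
        for _ in range(cfg.hotspots_per_gene):
            s = int(rng.integers(0, L - cfg.hotspot_width))
            hotspots.append((s, s + cfg.hotspot_width))
            w[s:s + cfg.hotspot_width] = cfg.hotspot_weight
        pairs = []
        min_sep = 2 * cfg.frag_len_range[1] + 20
        for _ in range(cfg.proximal_pairs_per_gene):
            for _attempt in range(50):
                p = int(rng.integers(cfg.frag_len_range[1], L - cfg.frag_len_range[1] - min_sep))
                q = p + int(rng.integers(min_sep, L - cfg.frag_len_range[1] - p))
                # keep planted contacts far enough apart that their event
                # clouds cannot chain-link at the default clustering tol
                sep = 11 + 2 * cfg.junction_jitter
                if all(abs(p - pp) > sep or abs(q - qq) > sep
                       for pp, qq in pairs):
                    pairs.append((p, q))
                    break
        structures[gid] = StructureTruth(gid, pairs, hotspots)
        cut_weights[gid] = w / w.sum()

    mix = cfg.category_mix
    n = cfg.n_read_pairs
    n_chim = round(mix.get(CHIMERIC, 0) * n)
    n_l2 = round(mix.get(LINKER_RNA2, 0) * n)
    n_only = round(mix.get(LINKER_ONLY, 0) * n)
    n_nl = n - n_chim - n_l2 - n_only

    n_intra_planned = sum(
        cfg.reads_per_proximal_pair * len(st.proximal_pairs)
        + cfg.background_intra_per_gene for st in structures.values())
    n_intra = min(n_intra_planned, n_chim // 5)
    n_random = round(cfg.random_ligation_rate * (n_chim - n_intra))

    reads: List[Tuple[str, str, str]] = []
    truth_reads: Dict[str, ReadTruth] = {}
    edge_counts: Dict[Tuple[str, str], int] = {e: 0 for e in edges}
    counter = 0

    def emit(insert: str, t: ReadTruth):
        nonlocal counter
        counter += 1
        rid = f"sim:{counter:07d}"
        block = list(cfg.layout.config_string)
        bi = 0
        for i, c in enumerate(cfg.layout.config_string):
            if c == "N":
                block[i] = t.umi[bi]
                bi += 1
            else:
                block[i] = cfg.layout.sample_barcodes[t.sample_id][
                    cfg.layout.x_positions.index(i)]
        read1 = ("".join(block) + insert)[: cfg.read_length]
        read2 = revcomp(insert)[: cfg.read_length]
        reads.append((rid, mutate(read1, rng, cfg.error_rate),
                      mutate(read2, rng, cfg.error_rate)))
        truth_reads[rid] = t
        return rid

    def new_tags():
        sample = samples[int(rng.integers(len(samples)))]
        umi = random_seq(rng, cfg.layout.umi_length)
        return sample, umi

    # random-ligation chimeras (uniform random gene pairs)
    for _ in range(n_random):
        ga, gb = rng.choice(gene_ids, size=2, replace=False)
        s1, a1, b1 = _random_fragment(cfg, rng, ref, ga)
        s2, a2, b2 = _random_fragment(cfg, rng, ref, gb)
        sample, umi = new_tags()
        emit(s1 + cfg.linker + s2, ReadTruth(
            CHIMERIC, sample, umi, ga, gb, s1, s2,
            _transcript_to_genomic(ref.gene_by_id[ga], a1, b1),
            _transcript_to_genomic(ref.gene_by_id[gb], a2, b2),
            is_random_ligation=True))

    # intramolecular cut-and-ligated reads
    intra_budget = n_intra
    for gid, st in structures.items():
        if intra_budget <= 0:
            break
        g = ref.gene_by_id[gid]
        tseq = ref.transcript_seq(gid)
        L = len(tseq)
        w = cut_weights[gid]

        def emit_intra(j1: int, j2: int):
            nonlocal intra_budget
            if intra_budget <= 0:
                return
            len1 = min(_frag_length(cfg, rng), j1 + 1)
            len2 = min(_frag_length(cfg, rng), L - j2)
            if len1 < cfg.frag_len_range[0] or len2 < cfg.frag_len_range[0]:
                return
            f1 = (j1 + 1 - len1, j1 + 1)
            f2 = (j2, j2 + len2)
            s1, s2 = tseq[f1[0]:f1[1]], tseq[f2[0]:f2[1]]
            sample, umi = new_tags()
            emit(s1 + cfg.linker + s2, ReadTruth(
                CHIMERIC, sample, umi, gid, gid, s1, s2,
                _transcript_to_genomic(g, *f1), _transcript_to_genomic(g, *f2),
                is_intra=True, junctions=(j1, j2)))
            intra_budget -= 1

        for (p, q) in st.proximal_pairs:
            emitted = 0
            for _ in range(cfg.reads_per_proximal_pair):
                j1 = p + int(rng.integers(-cfg.junction_jitter, cfg.junction_jitter + 1))
                j2 = q + int(rng.integers(-cfg.junction_jitter, cfg.junction_jitter + 1))
                before = intra_budget
                emit_intra(j1, j2)
                emitted += before - intra_budget
            st.reads_per_pair[(p, q)] = emitted
        for _ in range(cfg.background_intra_per_gene):
            # two hotspot-biased cuts; junctions kept well apart so background
            # events do not pile onto each other
            j1, j2 = sorted(rng.choice(L, size=2, replace=False, p=w))
            if j2 - j1 < cfg.frag_len_range[0]:
                continue
            emit_intra(int(j1), int(j2))

    # inter-molecular chimeras from planted edges, topping the chimeric
    # category up to its exact share (some intra events can be skipped when
    # a junction sits too close to a transcript end)
    n_inter = n_chim - n_random - (n_intra - intra_budget)
    chosen = rng.choice(len(edges), size=n_inter, p=weights)
    for ei in chosen:
        ga, gb = edges[ei]
        if rng.random() < 0.5:
            ga, gb = gb, ga
        s1, a1, b1 = _random_fragment(cfg, rng, ref, ga)
        s2, a2, b2 = _random_fragment(cfg, rng, ref, gb)
        sample, umi = new_tags()
        edge_counts[tuple(sorted((ga, gb)))] += 1
        emit(s1 + cfg.linker + s2, ReadTruth(
            CHIMERIC, sample, umi, ga, gb, s1, s2,
            _transcript_to_genomic(ref.gene_by_id[ga], a1, b1),
            _transcript_to_genomic(ref.gene_by_id[gb], a2, b2)))

    # linker-RNA2, no-linker, linker-only molecules
    for _ in range(n_l2):
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        s2, a2, b2 = _random_fragment(cfg, rng, ref, gid)
        sample, umi = new_tags()
        emit(cfg.linker + s2, ReadTruth(
            LINKER_RNA2, sample, umi, None, gid, "", s2, None,
            _transcript_to_genomic(ref.gene_by_id[gid], a2, b2)))
    for _ in range(n_nl):
        gid = gene_ids[int(rng.integers(len(gene_ids)))]
        s1, a1, b1 = _random_fragment(cfg, rng, ref, gid)
        sample, umi = new_tags()
        emit(s1, ReadTruth(
            NO_LINKER, sample, umi, gid, None, s1, "",
            _transcript_to_genomic(ref.gene_by_id[gid], a1, b1), None))
    for _ in range(n_only):
        sample, umi = new_tags()
        emit(cfg.linker, ReadTruth(LINKER_ONLY, sample, umi))

    # PCR duplicates: re-emit reads verbatim at duplicate_rate
    n_unique = len(reads)
    dup_sources = np.nonzero(rng.random(n_unique) < cfg.duplicate_rate)[0]
    for si in dup_sources:
        counter += 1
        rid = f"sim:{counter:07d}"
        src_id, r1, r2 = reads[si]
        reads.append((rid, r1, r2))
        truth_reads[rid] = replace(truth_reads[src_id], duplicate_of=src_id)

    # interleave duplicates with originals
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]

    distinct = len({(r1, r2) for _, r1, r2 in reads})
    truth = SimTruth(truth_reads, edge_counts, structures,
                     n_string_duplicates=len(reads) - distinct)
    return SimLibrary(reads, truth, ref, cfg)


# ---------------------------------------------------------------------------
# evaluation harness

@dataclass(frozen=True)
class EvalMetrics:
    n_planted: int
    n_tested: int
    n_significant: int
    true_positives: int
    false_positives: int
    sensitivity: float
    specificity: float
    precision: float


def evaluate(calls, truth: SimTruth) -> EvalMetrics:
    """Score significant interaction calls against the planted edge list.

    Sensitivity: planted edges (with at least one emitted read) recovered
    as significant.  Specificity: 1 minus the fraction of tested
    non-planted pairs called significant.
    """
    planted = {e for e, cnt in truth.edges.items() if cnt > 0}
    tested = {(c.pair.gene_a, c.pair.gene_b) for c in calls}
    significant = {(c.pair.gene_a, c.pair.gene_b) for c in calls if c.significant}
    tp = len(significant & planted)
    fp = len(significant - planted)
    tested_nonplanted = len(tested - planted)
    sens = tp / len(planted) if planted else float("nan")
    spec = 1.0 - fp / tested_nonplanted if tested_nonplanted else 1.0
    prec = tp / len(significant) if significant else float("nan")
    return EvalMetrics(len(planted), len(tested), len(significant), tp, fp,
                       sens, spec, prec)


def match_proximal_pairs(called, truth: SimTruth, tol: int = 10):
    """Match called proximal site pairs to planted contacts within ``tol``.

    Returns ``(n_recovered, n_eligible, n_spurious)`` where eligible means
    planted contacts that actually received reads.
    """
    planted = [(st.gene_id, p, q, cnt)
               for st in truth.structures.values()
               for (p, q), cnt in st.reads_per_pair.items()]
    recovered = 0
    matched_calls = set()
    n_eligible = 0
    for gene_id, p, q, cnt in planted:
        if cnt == 0:
            continue
        n_eligible += 1
        for idx, c in enumerate(called):
            if (c.gene_id == gene_id
                    and c.window1[0] - tol <= p <= c.window1[1] + tol
                    and c.window2[0] - tol <= q <= c.window2[1] + tol):
                recovered += 1
                matched_calls.add(idx)
                break
    n_spurious = len(called) - len(matched_calls)
    return recovered, n_eligible, n_spurious
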