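"""End-to-end orchestration: parse -> map -> assign -> call -> structure.

The stages follow the analysis order of the underlying protocol: (1)
duplicate removal, (2) demultiplexing, (3) insert recovery, (4) chimera
parsing, (5) genome mapping, (6) interaction calling, (7) interaction
sites, plus the intramolecular structure branch for same-gene chimeras.
Every record dropped anywhere is attributed to exactly one reason in the
run report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from . import structure as structmod
from .align import (AMBIGUOUS_GENE, GeneAnnotation, KmerIndex, MappedFragment,
                    RandomLigationEstimate, RepeatAnnotation, assign_gene,
                    build_novel_loci, estimate_random_ligation, toy_align)
from .barcodes import BarcodeLayout
from .interactome import InteractionCall, InteractionSite, call_interactions, call_sites
from .parse import CHIMERIC, ParseOptions, ParsedChimera, parse_read_pairs
from .simulate import Reference


@dataclass
class PipelineOptions:
    parse: ParseOptions = field(default_factory=ParseOptions)
    min_overlap_frac: float = 0.5
    novel_max_gap: int = 100
    fdr_threshold: float = 0.05
    min_pair_count: int = 2
    min_site_support: int = 5
    site_max_gap: int = 10
    min_site_width: int = 10
    contact_bin_size: int = 5
    proximal_min_support: int = 3
    proximal_tol: int = 10
    aligner_k: int = 15


@dataclass
class GeneStructureResult:
    gene_id: str
    intra_pairs: list
    cut_density: object
    contact_map: object
    proximal_pairs: list
    n_ambiguous_class: int = 0


@dataclass
class PipelineResult:
    chimeras: List[ParsedChimera]
    parse_stats: object
    fragments: Dict[Tuple[str, str], MappedFragment]
    assignments: Dict[Tuple[str, str], Optional[str]]
    inter_pairs: List[Tuple[str, str]]
    calls: List[InteractionCall]
    sites: List[InteractionSite]
    structures: Dict[str, GeneStructureResult]
    random_ligation: Optional[RandomLigationEstimate]
    report: dict


def _project(gene, frag: MappedFragment) -> Optional[Tuple[int, int]]:
    """Transcript-space interval of a fragment, clamped to the gene span."""
    s = max(frag.start, gene.start)
    e = min(frag.end, gene.end)
    if e <= s:
        return None
    return gene.interval_to_transcript(s, e)


def run_pipeline(
    reads,
    reference: Reference,
    layout: Optional[BarcodeLayout] = None,
    options: Optional[PipelineOptions] = None,
) -> PipelineResult:
    """Run the full in-memory pipeline over ``(read_id, r1, r2)`` tuples."""
    opt = options or PipelineOptions()
    layout = layout or BarcodeLayout()

    # stages 1-4: dedup, demultiplex, insert recovery, chimera parsing
    chimeras, pstats = parse_read_pairs(reads, layout, opt.parse)
    chimeric = [c for c in chimeras if c.category == CHIMERIC]

    # stage 5: mapping (built-in fixture aligner)
    index = KmerIndex(reference.sequences, k=opt.aligner_k)
    fragments: Dict[Tuple[str, str], MappedFragment] = {}
    drop = {"unmapped": 0, "multimapped": 0}
    for c in chimeric:
        for side, seq in (("rna1", c.rna1_seq), ("rna2", c.rna2_seq)):
            status, frag = toy_align(seq, index, read_id=c.read_id, side=side)
            if status == "unique":
                fragments[(c.read_id, side)] = frag
            else:
                drop["unmapped" if frag is None else "multimapped"] += 1

    # stage 6 (front half): feature assignment
    annot = GeneAnnotation(reference.genes)
    repann = RepeatAnnotation(getattr(reference, "repeats", []) or [])
    assignments: Dict[Tuple[str, str], Optional[str]] = {}
    unassigned: List[MappedFragment] = []
    n_ambig_gene = 0
    for key, frag in fragments.items():
        a = assign_gene(frag, annot, repann, opt.min_overlap_frac)
        if a == AMBIGUOUS_GENE:
            n_ambig_gene += 1
            assignments[key] = None
        elif a is None:
            unassigned.append(frag)
            assignments[key] = None
        else:
            assignments[key] = a
    novel_assign, novel_loci = build_novel_loci(unassigned, opt.novel_max_gap)
    for key, gid in novel_assign.items():
        assignments[key] = gid
    biotypes = dict(reference.biotypes)
    for g in novel_loci:
        biotypes[g.gene_id] = "novel"
    gene_models = dict(reference.gene_by_id)
    for g in novel_loci:
        gene_models[g.gene_id] = g

    # pair up chimera sides
    inter_pairs: List[Tuple[str, str]] = []
    intra_by_read: Dict[str, ParsedChimera] = {}
    species_pairs = []
    n_side_dropped = 0
    by_id = {c.read_id: c for c in chimeric}
    for c in chimeric:
        f1 = fragments.get((c.read_id, "rna1"))
        f2 = fragments.get((c.read_id, "rna2"))
        g1 = assignments.get((c.read_id, "rna1"))
        g2 = assignments.get((c.read_id, "rna2"))
        if f1 is None or f2 is None or g1 is None or g2 is None:
            n_side_dropped += 1
            continue
        if reference.pan is not None:
            species_pairs.append((reference.pan.species(f1.reference),
                                  reference.pan.species(f2.reference)))
        if g1 == g2:
            intra_by_read[c.read_id] = c
        else:
            inter_pairs.append((g1, g2))

    # stage 6 (back half): interaction calling
    calls = call_interactions(inter_pairs, biotypes,
                              fdr_threshold=opt.fdr_threshold,
                              min_pair_count=opt.min_pair_count)

    # stage 7: interaction sites from inter-chimera fragments per gene
    frags_per_gene: Dict[str, List[Tuple[int, int]]] = {}
    for c in chimeric:
        for side in ("rna1", "rna2"):
            key = (c.read_id, side)
            gid = assignments.get(key)
            frag = fragments.get(key)
            if gid in (None, AMBIGUOUS_GENE) or frag is None or gid not in gene_models:
                continue
            other = "rna2" if side == "rna1" else "rna1"
            if assignments.get((c.read_id, other)) == gid:
                continue  # intra events feed the structure branch instead
            t = _project(gene_models[gid], frag)
            if t is not None:
                frags_per_gene.setdefault(gid, []).append(t)
    sites: List[InteractionSite] = []
    for gid in sorted(frags_per_gene):
        sites.extend(call_sites(gid, frags_per_gene[gid],
                                gene_models[gid].transcript_length,
                                opt.min_site_support, opt.site_max_gap,
                                opt.min_site_width))

    # structure branch: same-gene chimeras
    alignments = []
    for rid, c in sorted(intra_by_read.items()):
        f1 = fragments[(rid, "rna1")]
        f2 = fragments[(rid, "rna2")]
        gid = assignments[(rid, "rna1")]
        gene = gene_models[gid]
        alignments.append(structmod.ChimeraAlignment(
            rid, gid, gid, has_linker=True,
            frag1_strand=f1.strand, frag2_strand=f2.strand,
            frag1_genomic=(f1.start, f1.end), frag2_genomic=(f2.start, f2.end),
            frag1_transcript=_project(gene, f1),
            frag2_transcript=_project(gene, f2)))
    intra_pairs, filt_report = structmod.filter_intramolecular(alignments)
    classified, n_amb_class = structmod.classify_all(intra_pairs)
    structures: Dict[str, GeneStructureResult] = {}
    by_gene: Dict[str, list] = {}
    for ip in classified:
        by_gene.setdefault(ip.gene_id, []).append(ip)
    for gid in sorted(by_gene):
        ips = by_gene[gid]
        L = gene_models[gid].transcript_length
        frag_ivs = [ip.frag1 for ip in ips] + [ip.frag2 for ip in ips]
        structures[gid] = GeneStructureResult(
            gid, ips,
            structmod.cut_density(gid, frag_ivs, L),
            structmod.contact_map(gid, ips, L, opt.contact_bin_size),
            structmod.call_proximal_pairs(ips, opt.proximal_min_support,
                                          opt.proximal_tol))

    rl = None
    if reference.pan is not None and species_pairs:
        rl = estimate_random_ligation(species_pairs)

    report = {
        "parse": pstats.as_dict(),
        "mapping": {"fragments_mapped_unique": len(fragments), **drop},
        "assignment": {
            "ambiguous_gene": n_ambig_gene,
            "novel_loci": len(novel_loci),
            "chimeras_with_both_sides": len(inter_pairs) + len(intra_by_read),
            "chimera_side_dropped": n_side_dropped,
        },
        "interactome": {
            "inter_chimeras": len(inter_pairs),
            "tested_pairs": len(calls),
            "significant_pairs": sum(c.significant for c in calls),
            "sites": len(sites),
        },
        "structure": {
            "intra_chimeras": len(intra_by_read),
            "kept_after_filters": filt_report.n_kept,
            "dropped": filt_report.dropped,
            "ambiguous_class": n_amb_class,
            "proximal_pairs": sum(len(s.proximal_pairs) for s in structures.values()),
        },
    }
    if rl is not None:
        report["random_ligation"] = {
            "n_pairs": rl.n_pairs, "n_inter_species": rl.n_inter,
            "fraction": rl.fraction, "ci": [rl.ci_low, rl.ci_high],
            "corrected": rl.corrected,
        }
    return PipelineResult(chimeras, pstats, fragments, assignments, inter_pairs,
                          calls, sites, structures, rl, report)
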