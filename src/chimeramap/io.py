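"""Format plumbing: FASTQ/FASTA/GTF/BED/bedGraph/BEDPE/SAM round-trips.

Internal coordinates are 0-based half-open; GTF is written/read 1-based
inclusive and BED-family formats 0-based half-open, per each format's
standard.  Gaps in bedGraph tracks are reported as absent (NaN), never as
zero.
"""

from __future__ import annotations

import gzip
import json
import os
import tempfile
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam

from .align import GeneModel, MappedFragment, PanGenome, RepeatElement


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ / FASTA

def read_fastq_pairs(path1, path2) -> Iterable[Tuple[str, str, str]]:
    """Yield ``(read_id, read1_seq, read2_seq)`` from two FASTQ files."""
    with pysam.FastxFile(str(path1)) as f1, pysam.FastxFile(str(path2)) as f2:
        for r1, r2 in zip(f1, f2):
            if r1.name != r2.name:
                raise ValueError(f"mate ids differ: {r1.name!r} vs {r2.name!r}")
            yield r1.name, r1.sequence.upper(), r2.sequence.upper()


def write_fastq_pairs(path1, path2, reads: Iterable[Tuple[str, str, str]]):
    """Write paired reads; constant qualities (simulated data carries none)."""
    with _open_text(path1, "wt") as f1, _open_text(path2, "wt") as f2:
        for rid, s1, s2 in reads:
            f1.write(f"@{rid}\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{rid}\n{s2}\n+\n{'I' * len(s2)}\n")


def write_fasta(path, sequences: Dict[str, str], width: int = 60):
    with _open_text(path, "wt") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> Dict[str, str]:
    out: Dict[str, List[str]] = {}
    name = None
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                out[name] = []
            elif line and name is not None:
                out[name].append(line.upper())
    return {k: "".join(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# gene annotation (GTF) and repeats (BED6)

def write_gtf(path, genes: List[GeneModel], source: str = "chimeramap"):
    with _open_text(path, "wt") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write("\t".join([
                g.reference, source, "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", attrs]) + "\n")
            for s, e in g.intervals:
                fh.write("\t".join([
                    g.reference, source, "exon", str(s + 1), str(e),
                    ".", g.strand, ".", attrs]) + "\n")


def read_gtf(path) -> List[GeneModel]:
    """Read gene models (gene_id + gene_biotype attributes) from GTF."""
    import gffutils

    with tempfile.NamedTemporaryFile(suffix=".db", delete=False) as tmp:
        dbpath = tmp.name
    try:
        db = gffutils.create_db(str(path), dbpath, force=True,
                                disable_infer_genes=True,
                                disable_infer_transcripts=True)
        genes = []
        for feat in db.features_of_type("gene"):
            gid = feat.attributes["gene_id"][0]
            biotype = feat.attributes.get("gene_biotype", ["other"])[0]
            exons = [(e.start - 1, e.end) for e in db.region(
                seqid=feat.seqid, start=feat.start, end=feat.end,
                featuretype="exon")
                if e.attributes["gene_id"][0] == gid]
            if not exons:
                exons = [(feat.start - 1, feat.end)]
            genes.append(GeneModel(gid, biotype, feat.seqid, feat.strand,
                                   sorted(set(exons))))
        return genes
    finally:
        if os.path.exists(dbpath):
            os.unlink(dbpath)


def write_repeats_bed(path, repeats: List[RepeatElement]):
    with _open_text(path, "wt") as fh:
        for r in repeats:
            fh.write(f"{r.reference}\t{r.start}\t{r.end}\t{r.family}\t0\t{r.strand}\n")


def read_repeats_bed(path) -> List[RepeatElement]:
    out = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{ln}: BED6 record needs 6 fields")
            out.append(RepeatElement(parts[3], parts[0], int(parts[1]),
                                     int(parts[2]), parts[5]))
    return out


def write_species_tsv(path, pan: PanGenome):
    pd.DataFrame(sorted(pan.species_of.items()),
                 columns=["reference", "species"]).to_csv(path, sep="\t", index=False)


def read_species_tsv(path) -> PanGenome:
    df = pd.read_csv(path, sep="\t")
    return PanGenome(dict(zip(df["reference"], df["species"])))


def read_barcodes_tsv(path) -> Dict[str, str]:
    """Two-column ``sample_id<TAB>barcode`` table (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["sample_id", "barcode"], dtype=str)
    return dict(zip(df["sample_id"], df["barcode"]))


# ---------------------------------------------------------------------------
# bedGraph score tracks

def write_bedgraph(path, track: Dict[str, np.ndarray]):
    """Write per-base values as merged constant runs; NaN positions omitted."""
    with _open_text(path, "wt") as fh:
        for ref in sorted(track):
            vals = np.asarray(track[ref], dtype=float)
            i = 0
            n = len(vals)
            while i < n:
                if np.isnan(vals[i]):
                    i += 1
                    continue
                j = i + 1
                while j < n and not np.isnan(vals[j]) and vals[j] == vals[i]:
                    j += 1
                fh.write(f"{ref}\t{i}\t{j}\t{vals[i]:g}\n")
                i = j


def read_bedgraph(path, lengths: Optional[Dict[str, int]] = None
                  ) -> Dict[str, np.ndarray]:
    """Read a bedGraph into per-base arrays; uncovered positions are NaN."""
    records = []
    with _open_text(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: bedGraph record needs 4 fields")
            records.append((parts[0], int(parts[1]), int(parts[2]), float(parts[3])))
    sizes = dict(lengths or {})
    for ref, _s, e, _v in records:
        sizes[ref] = max(sizes.get(ref, 0), e)
    out = {ref: np.full(n, np.nan) for ref, n in sizes.items()}
    for ref, s, e, v in records:
        out[ref][s:e] = v
    return out


# ---------------------------------------------------------------------------
# BEDPE (one record per mapped chimera)

BEDPE_COLUMNS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2",
                 "name", "score", "strand1", "strand2", "sample", "umi"]


def write_bedpe(path, records: Iterable[dict]):
    df = pd.DataFrame(list(records), columns=BEDPE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bedpe(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BEDPE_COLUMNS)


def chimera_to_bedpe(read_id: str, sample: str, umi: str,
                     f1: MappedFragment, f2: MappedFragment) -> dict:
    return {
        "chrom1": f1.reference, "start1": f1.start, "end1": f1.end,
        "chrom2": f2.reference, "start2": f2.start, "end2": f2.end,
        "name": read_id, "score": 0, "strand1": f1.strand, "strand2": f2.strand,
        "sample": sample, "umi": umi,
    }


# ---------------------------------------------------------------------------
# SAM ingestion (fragments aligned externally)

def fragment_read_name(read_id: str, umi: str, side: str) -> str:
    """Naming convention tying SAM records back to parsed chimeras."""
    return f"{read_id}|{umi}|{side}"


def parse_fragment_read_name(name: str) -> Tuple[str, str, str]:
    read_id, umi, side = name.rsplit("|", 2)
    if side not in ("rna1", "rna2"):
        raise ValueError(f"unrecognized fragment side in read name {name!r}")
    return read_id, umi, side


def read_sam_fragments(path, min_mapq: int = 1) -> List[MappedFragment]:
    """Ingest primary fragment alignments from SAM/BAM.

    Records named per :func:`fragment_read_name`; primary alignments with
    MAPQ >= ``min_mapq`` are treated as unique, lower MAPQ as multi-mapped.
    """
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            read_id, _umi, side = parse_fragment_read_name(rec.query_name)
            out.append(MappedFragment(
                read_id, side, rec.reference_name, rec.reference_start,
                rec.reference_end, "-" if rec.is_reverse else "+",
                unique=rec.mapping_quality >= min_mapq))
    return out


# ---------------------------------------------------------------------------
# atomic JSON / TSV outputs

def write_json(path, obj):
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    os.replace(tmp, path)


def write_tsv(path, df: pd.DataFrame):
    tmp = f"{path}.tmp"
    df.to_csv(tmp, sep="\t", index=False)
    os.replace(tmp, path)


def interactions_to_frame(calls) -> pd.DataFrame:
    rows = [{
        "gene_a": c.pair.gene_a, "gene_b": c.pair.gene_b,
        "n_ab": c.pair.n_ab, "n_a": c.pair.n_a, "n_b": c.pair.n_b,
        "N": c.pair.N, "p_value": c.p_value, "q_value": c.q_value,
        "type_label": c.type_label, "significant": c.significant,
    } for c in calls]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "n_ab", "n_a", "n_b",
                                       "N", "p_value", "q_value", "type_label",
                                       "significant"])


def sites_to_frame(sites) -> pd.DataFrame:
    rows = [{"gene_id": s.gene_id, "start": s.start, "end": s.end,
             "support": s.support} for s in sites]
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "support"])
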