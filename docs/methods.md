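# Methods

`chimeramap` analyses proximity-ligation RNA–RNA interactome libraries.
In such an experiment, RNAs cross-linked to a shared protein are
fragmented by RNase I, a 24-nt biotinylated RNA linker
(`CTAGTAGCCCATGCAATGCGAGGA` in sequenced DNA space) is ligated between
the fragment ends, and the resulting RNA1–linker–RNA2 chimeras are
sequenced paired-end. Each chimera is one item of evidence that its two
fragments were spatially close in vivo: between two molecules (an
interaction) or within one folded molecule (structure).

## Read-level model and parsing

Read 1 begins with a combined barcode block described by a configuration
string over `{N, X}`, default `NNNNXXXXNN`: six random nucleotides (the
UMI, used for PCR-duplicate removal) around a fixed 4-nt sample barcode.
The three default sample barcodes (`AGGT`, `CGCC`, `CATT`) pairwise
differ at three of four positions, so the default demultiplexing budget
of 1 mismatch can never convert one sample into another (assignment is
refused on ties or when no barcode is within budget).

Parsing proceeds in the order of the underlying protocol:

1. **Duplicate removal** collapses read pairs identical in both mate
   sequences. Because the UMI is part of read 1, identical inserts with
   different UMIs survive as distinct molecules. Note that two distinct
   molecules can still be byte-identical (e.g. two linker-only circles
   sharing a 6-nt UMI and sample barcode); sequence-level deduplication
   is therefore defined on strings, exactly as stated.
2. **Demultiplexing and UMI extraction** per the layout above.
3. **Insert recovery** merges the read-1 payload with the
   reverse-complemented read 2 when they overlap by ≥ 10 nt with ≤ 10%
   mismatches (candidate offsets are seeded from an exact 16-mer with a
   full-scan fallback). Unmerged pairs are processed as the two ends of
   one insert.
4. **Linker splitting** finds the best ungapped linker occurrence —
   the full linker internally, or a linker prefix/suffix hanging off a
   read end with ≥ 6 nt overlap — with a mismatch budget of
   `floor(0.1 × matched length)`. Ties prefer longer matches, then
   smaller offsets. Bases 5' of the linker are RNA1, bases 3' are RNA2;
   flanks shorter than `min_frag = 15` nt are cleared (too short to map).
   The category follows from which fragments survive: `chimeric`
   (both), `linker_rna2` / `rna1_linker` (one), `linker_only`,
   `no_linker`, or `ambiguous` (two disjoint linker copies, or
   inconsistent linker orientation between unmerged mates). Matching is
   ungapped because the linker is short and indels are rare on Illumina
   instruments; no quality-aware correction is attempted.

## Mapping and feature assignment

Fragments are placed on the genome either by ingesting primary SAM/BAM
alignments (records named `<read_id>|<umi>|<side>`; MAPQ ≥ 1 treated as
unique) or by the built-in toy aligner — an exact k-mer seed table
(k = 15) with ungapped extension allowing ≤ 2 mismatches, adequate only
for the fixture-scale genomes used in simulation. A fragment is unique
only when a single locus attains the best score; multi-mapped fragments
are discarded, and only chimeras with both fragments uniquely mapped
enter any downstream analysis.

A unique fragment is assigned to the same-strand gene covering ≥ 50% of
it (`min_overlap_frac`, a documented choice — two qualifying genes are
ambiguous and dropped with a counter), else to a same-strand repeat
family (as a `repeat:<family>` unit), else pooled into novel loci built
by strand-aware merging of leftover fragments with gaps ≤ 100 nt (novel
ids assigned in sorted genomic order, hence input-order independent).
Coordinates are 0-based half-open internally; GTF is 1-based inclusive
and BED-family formats 0-based half-open at the file boundary only.

## Interaction calling

Chimeras whose sides land on two different genes are aggregated into
unordered pair counts. For a pair (a, b) with pair count `n_ab`,
per-gene endpoint margins `n_a`, `n_b` and total assigned chimeras `N`,
the 2×2 table is

```
a = n_ab          b = n_a − n_ab
c = n_b − n_ab    d = N − a − b − c
```

and the one-sided (enrichment) Fisher exact p-value is the
hypergeometric upper tail P(X ≥ a). This marginal construction and the
`greater` alternative are this package's documented definition. Only
pairs with `n_ab ≥ 2` are tested (interactions should be supported by
multiple read pairs), the Benjamini–Hochberg step-up runs over the
tested pairs, and `q < 0.05` defines significance. Libraries from
replicate samples are merged at the chimera level before testing.
Interaction type labels order the two biotypes alphabetically with
`mRNA` forced last (`lincRNA-mRNA`, `snoRNA-mRNA`, ...); repeat families
collapse to `transposonRNA`.

**Interaction sites** are peaks of overlapping fragment coverage on a
transcript: positions with coverage ≥ 5 fragments, merged across gaps
≤ 10 nt, reported when ≥ 10 nt wide (all three thresholds are package
defaults — the method's description names no values).

**Network topology.** The significant-interaction graph's degree
histogram is fit by least squares on (log₁₀ k, log₁₀ node count). By
default only degrees populated by ≥ 3 nodes enter the fit: the sparse
high-degree tail consists mostly of single-node degrees whose
log-counts are sampling noise, and including them makes the r² of a
genuine preferential-attachment network fluctuate between ~0.54 and
~0.88 across random seeds. With the ≥ 3-node filter the fit is stable
(r² ≈ 0.95–0.99 for preferential attachment at 1,000 nodes, m = 2,
versus r² ≈ 0.55–0.71 for an artificial network of 100 sources each
wired to 300–1,000 of 20,000 targets, whose degree histogram is a
non-monotone Poisson bulk plus a flat far tail). `min_count=1` restores
the unfiltered fit. A fit is refused below 3 distinct degrees.

## Intramolecular structure

Chimeras whose two fragments map to one gene record a cut-and-ligation
within a single folded molecule. Before analysis, read pairs that are
geometrically indistinguishable from an intact (continuous) fragment
are removed: same-gene pairs lacking any fraction of the linker, and
pairs whose mates map to opposite strands within 2,000 bp with the
plus-strand mate upstream of the minus-strand mate — precisely the
signature of an ordinary un-cut insert in paired-end sequencing. Each
dropped record is attributed to exactly one filter.

Junctions are defined by the ligation chemistry: `junction1` is the
last base of fragment 1 (its 3'-OH ligated to the linker 5' end) and
`junction2` the first base of fragment 2 (its 5' end ligated to the
linker 3' end). Events are assigned to one of two structural classes in
transcript orientation — class I when fragment 1 lies 5' of fragment 2
(the molecule was cut and re-ligated in order), class II when fragment 1
lies 3' of fragment 2 (the circularized geometry). Overlapping
fragments classify by junction order; identical junctions are ambiguous
and dropped with a counter. All structure outputs are in transcript
coordinates (minus-strand genes are projected by reversal); the
simulator's single-exon genes keep this projection trivial.

Three summaries are produced per gene:

* **Cut-density footprint** — +1 at every fragment terminus (each is a
  candidate RNase I cut); single-stranded regions accumulate high
  density. An optional 5-nt moving mean is applied only for reporting.
* **Contact map** — a symmetric matrix over 5-nt bins incremented at
  (bin(junction1), bin(junction2)) and its transpose; the upper
  triangle sums to the event count (mass conservation, asserted in
  tests).
* **Proximal site pairs** — single-linkage clusters in (junction1,
  junction2) space, linking events whose junctions both differ by
  ≤ 10 nt ("overlapping ligation positions" is not quantified in the
  method's description; 10 nt is this package's choice), reported at
  ≥ 3 supporting events with windows spanning the member junctions.

## Sequence-level statistics

**Duplex hybridization energy.** An authored, simplified
nearest-neighbour model rather than a wrapper around an external folding
program: the two strands hybridize antiparallel with Watson–Crick and
G·U pairs; adjacent pairs contribute stacking ΔG37 values (the ten
Watson–Crick nearest-neighbour parameters of Xia et al. 1998,
Biochemistry 37:14719, mirrored for strand symmetry); any
wobble-containing stack scores a flat −0.5 kcal/mol; interior unpaired
bases cost +0.5 kcal/mol each; dangling ends are free; no intramolecular
pairing. The minimum-energy alignment is found by a dynamic program
over "best duplex ending at pair (i, j)" with an O(nm) running 2-D
prefix minimum for the loop transition; ΔG ≤ 0 always (an empty duplex
scores 0). Correctness is established against an exhaustive enumeration
of duplex alignments under the identical scoring (≤ 8-nt sequences),
plus symmetry, T/U-spelling invariance, and the monotonicity property
that a sequence's reverse complement is its most stable partner. The
model is deliberately not calibrated against any external program.

**Shuffled controls and the energy test.** Controls are uniform
mononucleotide permutations (seeded Fisher–Yates; a
dinucleotide-preserving mode is intentionally out of scope for the
default since the control design specifies base shuffling). Observed
per-interaction mean ΔG is compared to the control by a one-sided
*paired* Wilcoxon signed-rank test. The pairing matters: each control
value is computed from shuffles of the very fragments behind its
observed value, so the two samples share per-pair composition and are
not independent — an unpaired rank-sum test is miscalibrated under the
null (its p-values fail a Kolmogorov–Smirnov uniformity check), while
the signed-rank test is calibrated (verified over 500 null replicates).
Degenerate inputs (no duplex anywhere) report p = 1 with a diagnostic
flag.

**Conservation metaprofile.** Mean per-base conservation score (e.g. a
PhyloP track, consumed as bedGraph) in W = 1,000-nt windows centred at
each RNA1–linker and linker–RNA2 junction, against an equal number of
seeded random genomic windows of the same width. Track gaps are
excluded from the means (never zero-filled) and counted.

## Random-ligation estimate

In a two-species mixture combined after cross-linking, genuine
interactions are intra-species, so inter-species chimeras measure
random ligation. The raw estimate is the inter-species fraction of
uniquely mapped chimeras with a Wilson 95% CI — conservative by
construction, because random ligation between two molecules of an
equal mixture joins the species only half the time. The corrected
estimate divides by `2·p·(1−p)` (p = species-1 molecule share); the raw
fraction is the default reported quantity.

## The simulator

The generator emulates the library construct end to end: random
i.i.d.-uniform chromosomes; non-overlapping single-exon genes over six
biotypes (default 20 genes each); a preferential-attachment interactome
(default 200 edges, log-normal per-edge read weights); chimeric inserts
`RNA1 + linker + RNA2` drawn from planted edges, from planted
within-gene proximal contacts (fragment termini biased 10× inside
planted single-stranded hotspots, junctions jittered ±2 nt), or from
uniformly random gene pairs at the 7% random-ligation rate; plus
non-informative categories at the documented mix (70% chimeric / 15%
linker–RNA2 / 10% linker-free / 5% linker-only). Reads are
`barcode block + insert 5' end` (read 1) and the reverse complement of
the insert 3' end (read 2, adapter-trimmed), with i.i.d. substitution
errors (default 0.5%) and verbatim re-emission of reads at the 20%
duplicate rate, shuffled into the stream. Everything is deterministic
under the seed, and every read carries a truth record (category,
sample, UMI, fragment loci, junctions, contamination/duplicate flags).

Fragment lengths are clamped log-normal (median 60 nt, range
15–75 nt). The clamp is chosen so that, with 100-nt paired reads, the
ligation junction always falls within the sequenced insert — a
precondition for the round-trip guarantee that zero-error libraries
parse back to their planted truth exactly. Real libraries contain
longer inserts whose junctions escape the reads; such molecules are
simply invisible to any parser and are not modelled.

What passing tests on these simulations do **not** show: performance
under structured (non-uniform) genomic sequence, spliced transcripts,
coverage biases, quality-score-dependent errors, or indels. The
simulator is a correctness harness for the pipeline's logic, not an
error-model of a sequencer.

Default problem sizes (50,000 read pairs for the end-to-end regression,
20,000 chimeras for the two-species control, 10,000 pairs for structure
recovery) were chosen as the package's standard small-study scale;
they complete in well under a minute each on one CPU. At these
conditions the end-to-end run typically recovers ≥ 90% of planted edges
at FDR 0.05 with specificity ≥ 0.97, and 100% of planted proximal
contacts with ≥ 5 supporting reads at a cluster support threshold of 3.

## Known limitations

* Gene-level only: no isoform resolution, no spliced alignment; the
  toy aligner is for fixtures, real data must be aligned externally.
* Antisense calls require an annotated antisense biotype; no de-novo
  antisense inference (the library is strand-aware by construction).
* The duplex energy model omits sequence-dependent wobble stacks,
  loop-size-dependent penalties, and intramolecular competition; its
  ΔG values are comparable within this package only.
* Novel-locus ids are stable for a fixed input set but not across
  datasets.
* The exact read-1/read-2 orientation of the final construct is a
  documented dialect (read 1 = barcode + insert sense strand) shared
  between the simulator and the parser.
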