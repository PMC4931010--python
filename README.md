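# chimeramap

Proximity-ligation RNA–RNA interactome mapping: parse chimeric
(RNA1–linker–RNA2) paired-end reads, call statistically enriched RNA–RNA
interactions and interaction sites, and extract intramolecular RNA
structure evidence from cut-and-ligated reads — with a fully
ground-truthed simulator so every stage is testable offline.

**Who it is for.** Computational biologists analysing proximity-ligation
interactome libraries (chimeras of two RNA fragments joined through a
known 24-nt linker), and anyone who needs a transparent, testable
re-implementation of that analysis: barcode demultiplexing and UMI
deduplication, linker splitting, genome assignment, enrichment testing,
network topology, RNA-structure readouts and duplex energetics.

## The statistics at the core

For each unordered gene pair (a, b) with chimera count
*n<sub>ab</sub>*, per-gene endpoint margins *n<sub>a</sub>*,
*n<sub>b</sub>* and total assigned chimeras *N*, the 2×2 table

| | on b | not on b |
|---|---|---|
| **on a** | *n<sub>ab</sub>* | *n<sub>a</sub> − n<sub>ab</sub>* |
| **not on a** | *n<sub>b</sub> − n<sub>ab</sub>* | *N − rest* |

is scored by a one-sided Fisher exact test (hypergeometric upper tail
P(X ≥ n<sub>ab</sub>)) and corrected across tested pairs by
Benjamini–Hochberg; q < 0.05 defines the interactome. Same-gene chimeras
instead feed the structure branch: each cut-and-ligated read contributes
two junction coordinates (spatially proximal transcript positions), a
cut-density footprint of single-stranded regions, a symmetric binned
contact map of ligation frequencies, and — for clusters of ≥ 3 events
with overlapping junctions — proximal site pairs. Sequence-level
evidence comes from a nearest-neighbour duplex hybridization energy
(ΔG37, kcal/mol) compared against base-shuffled controls with a paired
Wilcoxon signed-rank test, and from conservation metaprofiles around
ligation junctions. Full model details and parameter defaults are in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a small library under the default study conditions (70%
chimeric reads, 7% random-ligation contamination, 20% PCR duplicates,
0.5% sequencing errors) and run the full pipeline:

```python
from chimeramap import SimConfig, simulate_library, run_pipeline, evaluate

cfg = SimConfig(seed=7, n_read_pairs=10_000)
lib = simulate_library(cfg)
result = run_pipeline(lib.reads, lib.reference, cfg.layout)

parse = result.report["parse"]
print(f"read pairs in:        {parse['input_pairs']}")
print(f"PCR duplicates:       {parse['duplicates_removed']}")
print(f"chimeric pairs:       {parse['category_counts']['chimeric']}")
print(f"tested gene pairs:    {result.report['interactome']['tested_pairs']}")
print(f"significant (q<0.05): {result.report['interactome']['significant_pairs']}")
print(f"interaction sites:    {result.report['interactome']['sites']}")
print(f"intramolecular reads: {result.report['structure']['intra_chimeras']}")
print(f"proximal site pairs:  {result.report['structure']['proximal_pairs']}")

m = evaluate(result.calls, lib.truth)
print(f"sensitivity={m.sensitivity:.2f} specificity={m.specificity:.2f}")
```

prints

```
read pairs in:        12007
PCR duplicates:       2014
chimeric pairs:       6989
tested gene pairs:    216
significant (q<0.05): 178
interaction sites:    220
intramolecular reads: 161
proximal site pairs:  10
sensitivity=0.87 specificity=0.78
```

Reading it: 10,000 planted molecules became 12,007 read pairs after 20%
duplication; parsing recovered the planted 70% chimeric share; 216 gene
pairs had ≥ 2 supporting chimeras and were tested, 178 were significant
at FDR 0.05; the structure branch kept 161 same-gene cut-and-ligated
reads and called all 10 planted proximal site pairs. `evaluate` scores
the calls against the simulator's truth — at this small scale a handful
of random-ligation coincidences between low-coverage genes survive the
FDR cut (specificity 0.78); at the default 50,000-pair scale specificity
is ≥ 0.97 (see the acceptance report below).

The same stages are available as a CLI for file-based work:

```sh
chimeramap simulate --seed 7 --n-read-pairs 10000 --out sim/
chimeramap run --fastq1 sim/reads_1.fastq.gz --fastq2 sim/reads_2.fastq.gz \
               --genome sim/genome.fa --gtf sim/genes.gtf --out out/
chimeramap network --interactions out/interactions.tsv --out out/net/
```

`out/` then holds `interactions.tsv`, `sites.tsv`, `proximal_pairs.tsv`,
per-gene cut-density bedGraphs and a machine-readable `run_report.json`
in which every dropped record is attributed to exactly one reason.

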