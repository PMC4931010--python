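"""Interaction calling and network analysis.

Chimeras whose two fragments land on two different genes are evidence of
an inter-molecular interaction.  For each unordered gene pair a 2x2 table
is formed from the pair's chimera count against the two genes' marginal
endpoint counts, scored with a one-sided Fisher exact test (enrichment)
and corrected across tested pairs by Benjamini-Hochberg; pairs with
q < 0.05 constitute the interactome.  Interaction *sites* are peaks of
overlapping fragments on a transcript.  The degree distribution of the
significant-interaction graph is fit by least squares in log-log space to
test the scale-free (power-law) property.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

# canonical biotype ordering for interaction type labels: mRNA sorts last,
# everything else alphabetically (so e.g. "lincRNA-mRNA", "snoRNA-mRNA")
_LABEL_ALIASES = {
    "L1": "transposonRNA", "SINE": "transposonRNA", "ERVK": "transposonRNA",
    "MaLR": "transposonRNA", "ERV1": "transposonRNA", "LTR": "transposonRNA",
    "pseudogene": "pseudogeneRNA",
}
_KNOWN_BIOTYPES = {"mRNA", "lincRNA", "snoRNA", "snRNA", "tRNA", "miRNA",
                   "pseudogene", "antisense", "novel", "transposonRNA",
                   "pseudogeneRNA"} | set(_LABEL_ALIASES)


@dataclass(frozen=True)
class PairCount:
    """Counts underlying one gene pair's 2x2 enrichment table."""

    gene_a: str
    gene_b: str
    n_ab: int   # chimeras joining a and b
    n_a: int    # chimera endpoints on a (any partner)
    n_b: int
    N: int      # all assigned chimeras in the sample

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort strictly before gene_b")
        if self.n_ab > min(self.n_a, self.n_b):
            raise ValueError("pair count exceeds a marginal count")
        if self.N < self.n_a + self.n_b - self.n_ab:
            raise ValueError("total N inconsistent with marginals")

    @property
    def table(self) -> Tuple[int, int, int, int]:
        a = self.n_ab
        b = self.n_a - self.n_ab
        c = self.n_b - self.n_ab
        d = self.N - a - b - c
        return a, b, c, d


@dataclass(frozen=True)
class InteractionCall:
    pair: PairCount
    p_value: float
    q_value: float
    type_label: str
    significant: bool


def count_pairs(assignments: Iterable[Tuple[str, str]]):
    """Aggregate per-chimera gene assignments into unordered pair counts.

    ``assignments`` yields ``(gene1, gene2)`` for chimeras whose two sides
    are both unambiguously assigned; same-gene chimeras belong to the
    structure analysis and must be excluded upstream.  Returns
    ``(pair_counts, margins, N)``.
    """
    pair_n: Counter = Counter()
    margins: Counter = Counter()
    N = 0
    for g1, g2 in assignments:
        if g1 == g2:
            raise ValueError(f"same-gene chimera ({g1}) passed to count_pairs")
        a, b = sorted((g1, g2))
        pair_n[(a, b)] += 1
        margins[a] += 1
        margins[b] += 1
        N += 1
    counts = [PairCount(a, b, n, margins[a], margins[b], N)
              for (a, b), n in sorted(pair_n.items())]
    return counts, dict(margins), N


def fisher_enrichment(pc: PairCount) -> float:
    """One-sided Fisher exact p-value for enrichment of the pair count.

    With the margins fixed, the pair count follows a hypergeometric
    distribution; the p-value is the upper tail P(X >= n_ab).
    """
    a, b, c, d = pc.table
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative cell in 2x2 table {pc.table}")
    # X ~ Hypergeom(population N, successes n_a, draws n_b)
    return float(hypergeom.sf(a - 1, pc.N, pc.n_a, pc.n_b))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order of input preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_interaction(biotype_a: str, biotype_b: str) -> str:
    """Canonical interaction type label, e.g. ``lincRNA-mRNA``.

    Repeat families collapse to ``transposonRNA``; unknown biotypes map to
    ``other``.  The two labels are ordered alphabetically with ``mRNA``
    forced last, so one documented ordering is used everywhere.
    """
    def norm(bt):
        bt = bt.split(":", 1)[1] if bt.startswith("repeat:") else bt
        if bt not in _KNOWN_BIOTYPES:
            return "other"
        return _LABEL_ALIASES.get(bt, bt)

    x, y = norm(biotype_a), norm(biotype_b)
    key = lambda t: (t == "mRNA", t)  # noqa: E731
    x, y = sorted((x, y), key=key)
    return f"{x}-{y}"


def call_interactions(
    assignments: Iterable[Tuple[str, str]],
    biotypes: Dict[str, str],
    fdr_threshold: float = 0.05,
    min_pair_count: int = 2,
) -> List[InteractionCall]:
    """Full calling pass: count, test, correct, label, threshold.

    Only pairs supported by at least ``min_pair_count`` chimeras are
    tested; the BH correction uses the number of tested pairs as m.
    """
    counts, _, _ = count_pairs(assignments)
    tested = [pc for pc in counts if pc.n_ab >= min_pair_count]
    if not tested:
        return []
    p = np.array([fisher_enrichment(pc) for pc in tested])
    q = bh_fdr(p)
    def bt(g):
        if g in biotypes:
            return biotypes[g]
        if g.startswith("repeat:"):
            return g.split(":", 1)[1]
        if g.startswith("novel:"):
            return "novel"
        return "other"
    return [
        InteractionCall(pc, float(pi), float(qi),
                        classify_interaction(bt(pc.gene_a), bt(pc.gene_b)),
                        bool(qi < fdr_threshold))
        for pc, pi, qi in zip(tested, p, q)
    ]


# ---------------------------------------------------------------------------
# interaction sites

@dataclass(frozen=True)
class InteractionSite:
    """A peak of overlapping chimeric fragments on one transcript."""

    gene_id: str
    start: int
    end: int
    support: int  # max fragment coverage inside the site

    @property
    def width(self) -> int:
        return self.end - self.start


def call_sites(
    gene_id: str,
    fragments: Iterable[Tuple[int, int]],
    transcript_length: int,
    min_site_support: int = 5,
    max_gap: int = 10,
    min_site_width: int = 10,
) -> List[InteractionSite]:
    """Call interaction sites from fragment intervals in transcript coordinates.

    Positions covered by >= ``min_site_support`` fragments are kept,
    runs separated by gaps <= ``max_gap`` are merged, and sites narrower
    than ``min_site_width`` are dropped.
    """
    cov = np.zeros(transcript_length + 1, dtype=np.int64)
    n = 0
    for s, e in fragments:
        if not (0 <= s < e <= transcript_length):
            raise ValueError(f"fragment [{s}, {e}) outside transcript of "
                             f"length {transcript_length}")
        cov[s] += 1
        cov[e] -= 1
        n += 1
    if n == 0:
        return []
    cov = np.cumsum(cov)[:transcript_length]
    above = np.nonzero(cov >= min_site_support)[0]
    if above.size == 0:
        return []
    sites = []
    run_start = prev = above[0]
    for pos in above[1:]:
        if pos - prev - 1 > max_gap:
            sites.append((run_start, prev + 1))
            run_start = pos
        prev = pos
    sites.append((run_start, prev + 1))
    return [
        InteractionSite(gene_id, int(s), int(e), int(cov[s:e].max()))
        for s, e in sites
        if e - s >= min_site_width
    ]


# ---------------------------------------------------------------------------
# degree distribution / scale-free diagnostics

@dataclass(frozen=True)
class DegreeDistribution:
    counts: Dict[int, int]  # degree k -> number of nodes

    @property
    def n_nodes(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    intercept: float
    r2: float
    n_points: int


def degree_distribution(edges: Iterable[Tuple[str, str]]) -> DegreeDistribution:
    """Node-degree histogram of the undirected simple graph on ``edges``."""
    deg: Counter = Counter()
    seen = set()
    for u, v in edges:
        e = tuple(sorted((u, v)))
        if e in seen or u == v:
            continue
        seen.add(e)
        deg[u] += 1
        deg[v] += 1
    return DegreeDistribution(dict(Counter(deg.values())))


def fit_power_law(dd: DegreeDistribution, min_count: int = 3) -> PowerLawFit:
    """Least-squares line on (log10 k, log10 node count) over degrees k > 0.

    A scale-free network shows a negative slope with high r2; a flat
    (random promiscuous) topology does not.  By default only degrees
    populated by at least ``min_count`` nodes enter the fit: the sparse
    high-degree tail of an empirical histogram is dominated by sampling
    noise (mostly single-node degrees) and would swamp the regression;
    pass ``min_count=1`` to fit every populated degree.  Refuses to fit
    fewer than 3 distinct degrees.
    """
    ks = sorted(k for k, c in dd.counts.items() if k > 0 and c >= min_count)
    if len(ks) < 3:
        ks = sorted(k for k, c in dd.counts.items() if k > 0 and c > 0)
    if len(ks) < 3:
        raise ValueError(f"need >= 3 distinct degrees to fit, got {len(ks)}")
    x = np.log10(ks)
    y = np.log10([dd.counts[k] for k in ks])
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PowerLawFit(float(slope), float(intercept), float(r2), len(ks))
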