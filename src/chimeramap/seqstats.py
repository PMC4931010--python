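"""Sequence-level statistics of interacting fragments.

Two lines of evidence that called interactions are sequence-driven:

* **Duplex hybridization energy.** The minimum free energy of the
  intermolecular duplex formed by two fragments, from a simplified
  nearest-neighbour model: Watson-Crick and G.U wobble pairs, stacking
  free energies (dG37, kcal/mol) for adjacent pairs, and a flat
  per-nucleotide penalty for interior unpaired bases.  Observed fragment
  pairs are compared against base-shuffled controls with a one-sided
  paired Wilcoxon signed-rank test (each control shares its fragment
  composition with its observed partner, so the design is matched).
  Stacking parameters are the standard
  Watson-Crick nearest-neighbour dG37 set (Xia et al. 1998, Biochemistry
  37:14719); wobble-containing stacks use one flat documented value.

* **Conservation metaprofile.** Mean per-base conservation score (e.g.
  PhyloP) in fixed-width windows centred at ligation junctions, against
  equally many random genomic windows of the same width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import wilcoxon

RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

# 5'-x1 x2-3' stacked on 3'-y1 y2-5'; x1:y1 and x2:y2 are the two pairs.
_WC_STACKS = {
    ("A", "A", "U", "U"): -0.93,
    ("A", "U", "U", "A"): -1.10,
    ("U", "A", "A", "U"): -1.33,
    ("C", "U", "G", "A"): -2.08,
    ("C", "A", "G", "U"): -2.11,
    ("G", "U", "C", "A"): -2.24,
    ("G", "A", "C", "U"): -2.35,
    ("C", "G", "G", "C"): -2.36,
    ("G", "G", "C", "C"): -3.26,
    ("G", "C", "C", "G"): -3.42,
}
# physical symmetry: reading the duplex from the other strand
STACK_DG37 = dict(_WC_STACKS)
for (x1, x2, y1, y2), e in _WC_STACKS.items():
    STACK_DG37[(y2, y1, x2, x1)] = e

#: flat dG37 for any stack containing a G.U wobble pair (simplification)
WOBBLE_STACK_DG37 = -0.5

#: free-energy cost per interior unpaired nucleotide, kcal/mol
LOOP_PENALTY_PER_NT = 0.5

_INF = float("inf")


def _to_rna(seq: str) -> str:
    out = seq.upper().replace("T", "U")
    bad = set(out) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide characters {sorted(bad)} in sequence")
    return out


def stack_energy(x1: str, x2: str, y1: str, y2: str) -> float:
    """dG37 of the stack 5'-x1 x2-3' / 3'-y1 y2-5' (both steps must pair)."""
    e = STACK_DG37.get((x1, x2, y1, y2))
    if e is not None:
        return e
    return WOBBLE_STACK_DG37


@dataclass(frozen=True)
class DuplexEnergy:
    delta_g: float  # kcal/mol; 0 means no duplex formed


def duplex_energy(seq1: str, seq2: str,
                  loop_penalty: float = LOOP_PENALTY_PER_NT) -> DuplexEnergy:
    """Minimum free energy of the intermolecular duplex of two RNAs.

    The two strands hybridize antiparallel: paired positions
    ``(i_1, j_1), ..., (i_k, j_k)`` satisfy ``i`` ascending in ``seq1`` and
    ``j`` descending in ``seq2``, every pair Watson-Crick or G.U.  Adjacent
    pairs contribute their stacking dG37; interior unpaired bases cost
    ``loop_penalty`` each; dangling ends are free; no intramolecular
    structure.  Dynamic program over best-energy-ending-at-pair with an
    O(nm) running 2-D prefix minimum for the loop transition.
    """
    s = _to_rna(seq1)
    t = _to_rna(seq2)
    n, m = len(s), len(t)
    if n < 2 or m < 2:
        return DuplexEnergy(0.0)

    # D[i][j]: best energy of a duplex whose last (3'-most in s) pair is (i, j)
    D = np.full((n, m), _INF)
    # A[i][j] = D[i][j] + 0.5*loop*(j - i); M[i][j] = min A over i' < i, j' > j
    M_prev = np.full(m, _INF)   # M[i][.] maintained incrementally
    half = loop_penalty
    best_global = 0.0

    A_row_prev = np.full(m, _INF)
    for i in range(n):
        if i > 0:
            # fold row i-1 of A into the prefix minimum (suffix-min over j)
            suf = np.minimum.accumulate(A_row_prev[::-1])[::-1]
            # M_new[j] = min(M_prev[j], min_{j' > j} A[i-1][j'])
            shifted = np.full(m, _INF)
            shifted[:-1] = suf[1:]
            M_prev = np.minimum(M_prev, shifted)
        A_row = np.full(m, _INF)
        for j in range(m - 1, -1, -1):
            if (s[i], t[j]) not in RNA_PAIRS:
                continue
            best = 0.0  # open a new duplex at this pair
            if i > 0 and j < m - 1 and D[i - 1, j + 1] < _INF:
                best = min(best, D[i - 1, j + 1] + stack_energy(s[i - 1], s[i], t[j + 1], t[j]))
            if M_prev[j] < _INF:
                # D[i'][j'] + loop*((i - i' - 1) + (j' - j - 1))
                best = min(best, M_prev[j] + half * (i - j - 2))
            D[i, j] = best
            A_row[j] = best + half * (j - i)
            if best < best_global:
                best_global = best
        A_row_prev = A_row
    return DuplexEnergy(float(best_global))


def duplex_energy_bruteforce(seq1: str, seq2: str,
                             loop_penalty: float = LOOP_PENALTY_PER_NT) -> float:
    """Exhaustive enumeration of duplex alignments under the same scoring.

    Exponential; intended as an independent oracle for short sequences
    (<= ~8 nt) in tests.
    """
    s = _to_rna(seq1)
    t = _to_rna(seq2)
    n, m = len(s), len(t)
    best = [0.0]

    def extend(i, j, energy):
        # current duplex ends with pair (i, j); try to add a next pair
        if energy < best[0]:
            best[0] = energy
        for i2 in range(i + 1, n):
            for j2 in range(j - 1, -1, -1):
                if (s[i2], t[j2]) not in RNA_PAIRS:
                    continue
                if i2 == i + 1 and j2 == j - 1:
                    step = stack_energy(s[i], s[i2], t[j], t[j2])
                else:
                    step = loop_penalty * ((i2 - i - 1) + (j - j2 - 1))
                extend(i2, j2, energy + step)

    for i in range(n):
        for j in range(m):
            if (s[i], t[j]) in RNA_PAIRS:
                extend(i, j, 0.0)
    return best[0]


def shuffle_control(seq: str, seed=None) -> str:
    """Uniform mononucleotide permutation of ``seq`` (composition preserved)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = np.array(list(seq))
    return "".join(rng.permutation(arr))


@dataclass(frozen=True)
class EnergyComparison:
    observed: np.ndarray   # per-interaction mean dG
    control: np.ndarray    # same on shuffled fragments
    statistic: float
    p_value: float
    n_shuffles: int
    seed: Optional[int]
    degenerate: bool = False


def compare_energy(
    fragment_pairs: Sequence,
    n_shuffles: int = 1,
    seed: Optional[int] = None,
) -> EnergyComparison:
    """Test whether observed fragment pairs hybridize more stably than chance.

    ``fragment_pairs`` is a sequence of interactions, each either one
    ``(seq1, seq2)`` tuple or a list of such tuples (all ligated fragment
    pairs supporting one interaction).  The observed sample holds one mean
    dG per interaction; the control repeats the computation on
    base-shuffled fragments (``n_shuffles`` per pair, averaged).  One-sided
    paired Wilcoxon signed-rank test of *observed more negative than
    control*; the pairing reflects that each control is a shuffle of the
    very fragments behind its observed value.
    """
    groups: List[List[Tuple[str, str]]] = []
    for item in fragment_pairs:
        if isinstance(item, tuple) and len(item) == 2 and isinstance(item[0], str):
            groups.append([item])
        else:
            groups.append(list(item))
    if len(groups) < 10:
        raise ValueError(f"need >= 10 fragment pairs, got {len(groups)}")

    rng = np.random.default_rng(seed)
    observed = np.array([
        np.mean([duplex_energy(a, b).delta_g for a, b in grp]) for grp in groups
    ])
    control = np.array([
        np.mean([
            duplex_energy(shuffle_control(a, rng), shuffle_control(b, rng)).delta_g
            for a, b in grp for _ in range(n_shuffles)
        ])
        for grp in groups
    ])
    if np.allclose(observed - control, 0.0):
        return EnergyComparison(observed, control, float("nan"), 1.0,
                                n_shuffles, seed, degenerate=True)
    stat, p = wilcoxon(observed, control, alternative="less",
                       zero_method="wilcox")
    return EnergyComparison(observed, control, float(stat), float(p),
                            n_shuffles, seed)


# ---------------------------------------------------------------------------
# conservation metaprofile

@dataclass(frozen=True)
class ConservationProfile:
    positions: np.ndarray       # relative positions -W/2 .. W/2-1
    observed_mean: np.ndarray   # mean score per relative position
    control_mean: np.ndarray
    n_junctions: int
    n_missing: int              # score-less (position, junction) cells skipped

    @property
    def width(self) -> int:
        return len(self.positions)


def _collect(windows, track: Dict[str, np.ndarray], W: int) -> np.ndarray:
    rows = np.full((len(windows), W), np.nan)
    for r, (ref, center) in enumerate(windows):
        scores = track.get(ref)
        if scores is None:
            continue
        lo = center - W // 2
        src_lo = max(0, lo)
        src_hi = min(len(scores), lo + W)
        if src_hi <= src_lo:
            continue
        rows[r, src_lo - lo:src_hi - lo] = scores[src_lo:src_hi]
    return rows


def conservation_profile(
    junction_loci: Sequence[Tuple[str, int]],
    score_track: Dict[str, np.ndarray],
    W: int = 1000,
    n_controls: Optional[int] = None,
    seed: Optional[int] = None,
) -> ConservationProfile:
    """Mean conservation score around ligation junctions vs random windows.

    ``junction_loci`` are ``(reference, genomic_position)`` centres (one per
    RNA1-linker or linker-RNA2 junction); ``score_track`` maps reference to
    a per-base float array with NaN where the track has no value.  The
    control averages ``n_controls`` (default: as many as there are
    junctions) random windows of the same width drawn uniformly from the
    track.  Missing scores are excluded from the means, not zero-filled.
    """
    if not junction_loci:
        raise ValueError("no junction loci supplied")
    rng = np.random.default_rng(seed)
    obs_rows = _collect(list(junction_loci), score_track, W)

    refs = sorted(score_track)
    lengths = np.array([len(score_track[r]) for r in refs], dtype=float)
    k = n_controls if n_controls is not None else len(junction_loci)
    ctrl = []
    for _ in range(k):
        ref = refs[rng.choice(len(refs), p=lengths / lengths.sum())]
        L = len(score_track[ref])
        center = int(rng.integers(W // 2, max(W // 2 + 1, L - W // 2)))
        ctrl.append((ref, center))
    ctrl_rows = _collect(ctrl, score_track, W)

    import warnings
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # a column with no covered position anywhere is legitimately NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        obs_mean = np.nanmean(obs_rows, axis=0)
        ctrl_mean = np.nanmean(ctrl_rows, axis=0)
    n_missing = int(np.isnan(obs_rows).sum())
    positions = np.arange(-(W // 2), W - W // 2)
    return ConservationProfile(positions, obs_mean, ctrl_mean,
                               len(junction_loci), n_missing)
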