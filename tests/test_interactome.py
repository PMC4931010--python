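"""Interaction calling: Fisher enrichment, BH, sites, network topology."""

import math

import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chimeramap.interactome import (DegreeDistribution, PairCount, bh_fdr,
                                    call_interactions, call_sites,
                                    classify_interaction, count_pairs,
                                    degree_distribution, fisher_enrichment,
                                    fit_power_law)


def fisher_oracle(a, b, c, d):
    """P(X >= a) by direct hypergeometric enumeration with exact rationals."""
    N, n_a, n_b = a + b + c + d, a + b, a + c
    total = math.comb(N, n_b)
    acc = 0
    for k in range(a, min(n_a, n_b) + 1):
        if n_b - k <= N - n_a:
            acc += math.comb(n_a, k) * math.comb(N - n_a, n_b - k)
    return acc / total


def bh_oracle(p):
    """Independent step-up implementation (sort, cummin from the right)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestCountPairs:
    def test_unordered_merge_with_margins(self):
        counts, margins, N = count_pairs([("g1", "g2"), ("g2", "g1"), ("g1", "g3")])
        by_pair = {(c.gene_a, c.gene_b): c for c in counts}
        assert by_pair[("g1", "g2")].n_ab == 2
        assert by_pair[("g1", "g3")].n_ab == 1
        assert margins == {"g1": 3, "g2": 2, "g3": 1}
        assert N == 3

    def test_same_gene_chimeras_are_rejected(self):
        with pytest.raises(ValueError, match="same-gene"):
            count_pairs([("g1", "g1")])

    def test_simulator_counts_match_truth(self, clean_library):
        lib = clean_library
        pairs = [(t.gene1, t.gene2) for t in lib.truth.reads.values()
                 if t.category == "chimeric" and not t.is_intra
                 and t.duplicate_of is None]
        counts, _, N = count_pairs(pairs)
        assert N == len(pairs)
        planted = {e: n for e, n in lib.truth.edges.items() if n > 0}
        from collections import Counter
        want = Counter(tuple(sorted(p)) for p in pairs)
        for c in counts:
            assert want[(c.gene_a, c.gene_b)] == c.n_ab


class TestFisher:
    def test_corner_table_closed_form(self):
        # all 5 chimeras of gene a meet all 5 of gene b and nothing else
        pc = PairCount("a", "b", 5, 5, 5, 100)
        assert fisher_enrichment(pc) == pytest.approx(1 / math.comb(100, 5))

    def test_saturated_table_is_uninformative(self):
        pc = PairCount("a", "b", 7, 7, 7, 7)
        assert fisher_enrichment(pc) == pytest.approx(1.0)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(1, 8))
    def test_matches_enumeration_oracle(self, a, b, c, d):
        pc = PairCount("a", "b", a, a + b, a + c, a + b + c + d)
        assert fisher_enrichment(pc) == pytest.approx(fisher_oracle(a, b, c, d),
                                                      rel=1e-10, abs=1e-12)


class TestBH:
    def test_hand_stepped_example(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_uniform_p_maps_to_itself(self):
        assert bh_fdr([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_matches_independent_step_up_oracle(self, rng):
        for _ in range(50):
            p = rng.random(int(rng.integers(1, 60)))
            assert bh_fdr(p) == pytest.approx(bh_oracle(p))

    def test_rejection_set_equals_classical_rule(self, rng):
        alpha = 0.05
        p = np.sort(rng.random(40)) ** 2
        q = bh_fdr(p)
        k = max([i + 1 for i in range(len(p)) if p[i] <= alpha * (i + 1) / len(p)],
                default=0)
        classical = np.zeros(len(p), dtype=bool)
        classical[:k] = True
        assert ((q < alpha) == classical).all()
        assert (np.diff(q) >= -1e-12).all()  # monotone on sorted input


class TestClassify:
    @pytest.mark.parametrize("a,b,label", [
        ("snoRNA", "mRNA", "snoRNA-mRNA"),
        ("mRNA", "snoRNA", "snoRNA-mRNA"),
        ("L1", "mRNA", "transposonRNA-mRNA"),
        ("mRNA", "mRNA", "mRNA-mRNA"),
        ("lincRNA", "mRNA", "lincRNA-mRNA"),
        ("weird", "mRNA", "other-mRNA"),
    ])
    def test_canonical_type_labels(self, a, b, label):
        assert classify_interaction(a, b) == label


class TestSites:
    def test_below_threshold_yields_nothing(self):
        assert call_sites("g", [(0, 30)] * 4, 200, min_site_support=5) == []

    def test_single_stack_is_one_site(self):
        sites = call_sites("g", [(100, 160)] * 6, 400)
        assert len(sites) == 1
        s = sites[0]
        assert (s.start, s.end, s.support) == (100, 160, 6)

    def test_distant_stacks_are_separate_sites(self):
        frags = [(50, 80)] * 5 + [(130, 170)] * 5
        sites = call_sites("g", frags, 400, max_gap=10)
        assert [(s.start, s.end) for s in sites] == [(50, 80), (130, 170)]

    def test_narrow_peaks_are_dropped(self):
        sites = call_sites("g", [(50, 58)] * 6, 200, min_site_width=10)
        assert sites == []


class TestNetwork:
    def test_star_graph_refuses_fit(self):
        dd = degree_distribution([("hub", f"leaf{i}") for i in range(50)])
        assert dd.counts == {50: 1, 1: 50}
        with pytest.raises(ValueError, match="3 distinct"):
            fit_power_law(dd)

    def test_preferential_attachment_is_scale_free(self):
        g = nx.barabasi_albert_graph(1000, 2, seed=0)
        fit = fit_power_law(degree_distribution(
            (str(u), str(v)) for u, v in g.edges()))
        assert fit.slope < 0 and fit.r2 >= 0.8

    def test_promiscuous_network_fails_log_linearity(self):
        rng = np.random.default_rng(0)
        edges = []
        for i in range(100):
            k = int(rng.integers(300, 1001))
            edges.extend((f"mi{i}", f"m{t}")
                         for t in rng.choice(20_000, size=k, replace=False))
        fit = fit_power_law(degree_distribution(edges))
        assert fit.r2 < 0.8

    def test_random_edge_removal_preserves_scale_free_signature(self):
        g = nx.barabasi_albert_graph(1000, 2, seed=3)
        edges = [(str(u), str(v)) for u, v in g.edges()]
        rng = np.random.default_rng(3)
        for retain in (1.0, 0.75, 0.5):
            keep = rng.random(len(edges)) < retain
            sub = [e for e, k in zip(edges, keep) if k]
            fit = fit_power_law(degree_distribution(sub))
            assert fit.slope < 0 and fit.r2 >= 0.8

    def test_degree_sum_equals_node_count(self):
        dd = degree_distribution([("a", "b"), ("b", "c"), ("a", "c"), ("a", "b")])
        assert dd.n_nodes == 3
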