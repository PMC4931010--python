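"""Intramolecular structure evidence: filters, classes, maps, clusters."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chimeramap.structure import (CLASS_I, CLASS_II, ChimeraAlignment,
                                  IntraPair, call_proximal_pairs, classify_all,
                                  classify_structure, contact_map, cut_density,
                                  filter_intramolecular)


def alignment(gene1="g", gene2="g", has_linker=True, strands=("+", "-"),
              frag1=(1000, 1060), frag2=(1500, 1560), t1=(0, 60), t2=(500, 560)):
    return ChimeraAlignment("r", gene1, gene2, has_linker, strands[0], strands[1],
                            frag1, frag2, t1, t2)


class TestFilters:
    def test_pairs_on_two_genes_are_dropped(self):
        kept, rep = filter_intramolecular([alignment(gene2="other")])
        assert kept == [] and rep.dropped == {"different_genes": 1}

    def test_linkerless_pairs_are_dropped(self):
        kept, rep = filter_intramolecular([alignment(has_linker=False)])
        assert kept == [] and rep.dropped == {"no_linker": 1}

    def test_geometry_truth_table(self):
        """Only geometries incompatible with one continuous fragment survive."""
        cases = {
            # convergent (+ upstream of -) within 2 kb: looks like an intact
            # insert -> dropped
            "convergent_near": (alignment(strands=("+", "-"),
                                          frag1=(1000, 1060), frag2=(1500, 1560)), False),
            # same shape but 5 kb apart: cannot be one continuous fragment
            "convergent_far": (alignment(strands=("+", "-"),
                                         frag1=(1000, 1060), frag2=(6000, 6060)), True),
            # divergent orientation (- upstream of +)
            "divergent": (alignment(strands=("-", "+"),
                                    frag1=(1000, 1060), frag2=(1500, 1560)), True),
            # both mates on the same strand
            "same_strand": (alignment(strands=("+", "+"),
                                      frag1=(1000, 1060), frag2=(1500, 1560)), True),
            # plus-strand mate downstream of the minus-strand mate
            "plus_after_minus": (alignment(strands=("+", "-"),
                                           frag1=(1500, 1560), frag2=(1000, 1060)), True),
            "linkerless": (alignment(has_linker=False), False),
        }
        for name, (al, should_survive) in cases.items():
            kept, _ = filter_intramolecular([al])
            assert bool(kept) == should_survive, name

    def test_drop_reasons_partition_the_input(self):
        als = [alignment(), alignment(gene2="x"), alignment(has_linker=False)]
        kept, rep = filter_intramolecular(als)
        assert rep.n_input == 3
        assert rep.n_kept + sum(rep.dropped.values()) == rep.n_input


class TestClassify:
    def test_ordered_fragments_are_class_one(self):
        ip = IntraPair("r", "g", (10, 40), (100, 130))
        assert classify_structure(ip) == CLASS_I

    def test_reversed_fragments_are_class_two(self):
        ip = IntraPair("r", "g", (100, 130), (10, 40))
        assert classify_structure(ip) == CLASS_II

    def test_identical_junctions_are_ambiguous(self):
        ip = IntraPair("r", "g", (10, 40), (39, 70))  # junction1 == junction2 == 39
        assert classify_structure(ip) is None
        kept, n_amb = classify_all([ip])
        assert kept == [] and n_amb == 1

    def test_exhaustive_placements_yield_exactly_two_classes(self):
        """Every non-degenerate placement on a toy transcript maps to I or II."""
        classes = set()
        L, flen = 300, 20
        for s1, s2 in itertools.product(range(0, L - flen, 7), repeat=2):
            ip = IntraPair("r", "g", (s1, s1 + flen), (s2, s2 + flen))
            cls = classify_structure(ip)
            if ip.junction1 != ip.junction2:
                classes.add(cls)
        assert classes == {CLASS_I, CLASS_II}


class TestCutDensity:
    def test_single_fragment_marks_both_termini(self):
        track = cut_density("g", [(50, 120)], 200)
        assert track.counts[50] == 1 and track.counts[119] == 1
        assert track.counts.sum() == 2

    def test_shared_terminus_piles_up(self):
        frags = [(50, 50 + 20 + i) for i in range(10)]
        track = cut_density("g", frags, 200)
        assert track.counts[50] == 10
        assert track.counts.sum() == 20

    def test_hotspot_bias_surfaces_as_track_maxima(self):
        rng = np.random.default_rng(2)
        L = 600
        w = np.ones(L)
        hot = [(100, 120), (400, 420)]
        for s, e in hot:
            w[s:e] = 10.0
        w /= w.sum()
        frags = []
        for _ in range(400):
            a, b = sorted(rng.choice(L, size=2, replace=False, p=w))
            if b - a >= 10:
                frags.append((int(a), int(b) + 1))
        track = cut_density("g", frags, L)
        hot_mask = np.zeros(L, dtype=bool)
        for s, e in hot:
            hot_mask[s:e] = True
        assert track.counts[hot_mask].mean() > 3 * track.counts[~hot_mask].mean()


class TestContactMap:
    def test_single_event_fills_symmetric_cells(self):
        ip = IntraPair("r", "g", (5, 13), (85, 95))  # junctions 12 and 85
        cm = contact_map("g", [ip], 100, bin_size=5)
        assert cm.matrix[2, 17] == 1 and cm.matrix[17, 2] == 1
        assert cm.matrix.sum() == 2

    def test_junction_outside_transcript_raises(self):
        ip = IntraPair("r", "g", (5, 13), (120, 130))
        with pytest.raises(ValueError, match="outside transcript"):
            contact_map("g", [ip], 100, bin_size=5)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 180), st.integers(0, 180)),
                    max_size=40), st.integers(1, 25))
    def test_mass_conservation(self, junctions, bin_size):
        pairs = [IntraPair(f"r{i}", "g", (j1, j1 + 10), (j2, j2 + 10))
                 for i, (j1, j2) in enumerate(junctions)]
        cm = contact_map("g", pairs, 200, bin_size=bin_size)
        assert np.triu(cm.matrix).sum() == len(pairs)
        assert (cm.matrix == cm.matrix.T).all()

    def test_planted_hairpin_dominates_argmax(self):
        p, q = 37, 163
        pairs = [IntraPair(f"r{i}", "g", (p - 20, p + 1), (q, q + 20))
                 for i in range(20)]
        cm = contact_map("g", pairs, 200, bin_size=5)
        b1, b2 = np.unravel_index(np.argmax(cm.matrix), cm.matrix.shape)
        assert {b1, b2} == {p // 5, q // 5}


class TestProximalPairs:
    def events(self, coords):
        return [IntraPair(f"r{i}", "g", (j1 - 10, j1 + 1), (j2, j2 + 10))
                for i, (j1, j2) in enumerate(coords)]

    def test_two_events_fall_below_min_support(self):
        assert call_proximal_pairs(self.events([(50, 120), (52, 121)])) == []

    def test_three_overlapping_events_form_one_pair(self):
        called = call_proximal_pairs(self.events([(50, 120), (52, 121), (47, 117)]))
        assert len(called) == 1
        assert called[0].support == 3
        assert called[0].window1 == (47, 52) and called[0].window2 == (117, 121)

    def test_single_linkage_chains_transitive_neighbours(self):
        # junction1 spaced 0, 8, 16: adjacent links within tol=10 chain all 3
        called = call_proximal_pairs(self.events([(50, 200), (58, 200), (66, 200)]),
                                     min_support=3, tol=10)
        assert len(called) == 1 and called[0].support == 3

    def test_agrees_with_bruteforce_connected_components(self, rng):
        for _ in range(30):
            coords = [(int(rng.integers(20, 400)), int(rng.integers(420, 800)))
                      for _ in range(int(rng.integers(2, 25)))]
            events = self.events(coords)
            called = call_proximal_pairs(events, min_support=3, tol=10)
            # oracle: graph connected components via repeated expansion
            n = len(coords)
            adj = {i: set() for i in range(n)}
            for i in range(n):
                for j in range(i + 1, n):
                    if (abs(coords[i][0] - coords[j][0]) <= 10
                            and abs(coords[i][1] - coords[j][1]) <= 10):
                        adj[i].add(j)
                        adj[j].add(i)
            comps = []
            seen = set()
            for i in range(n):
                if i in seen:
                    continue
                stack, comp = [i], set()
                while stack:
                    k = stack.pop()
                    if k in comp:
                        continue
                    comp.add(k)
                    stack.extend(adj[k] - comp)
                seen |= comp
                comps.append(comp)
            want = sorted(len(c) for c in comps if len(c) >= 3)
            assert sorted(c.support for c in called) == want

    def test_recovery_without_spurious_calls_at_sparse_background(self):
        """>=5 planted events per contact are always recovered; sparse
        background (about one event per 10 x 10-nt cells) never clusters."""
        recovered, spurious = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            planted = [(100 + int(rng.integers(-2, 3)), 500 + int(rng.integers(-2, 3)))
                       for _ in range(5)]
            # background: 8 events scattered over an 800-nt transcript, kept
            # away from the planted cloud
            background = []
            while len(background) < 8:
                j1 = int(rng.integers(20, 780))
                j2 = int(rng.integers(20, 780))
                if abs(j1 - 100) > 40 or abs(j2 - 500) > 40:
                    background.append((j1, j2))
            called = call_proximal_pairs(self.events(planted + background),
                                         min_support=3, tol=10)
            hit = [c for c in called
                   if c.window1[0] <= 100 <= c.window1[1] + 10
                   and c.window2[0] <= 500 <= c.window2[1] + 10]
            recovered += bool(hit)
            spurious += len(called) - len(hit)
        assert recovered == 50
        assert spurious == 0
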