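"""Toy aligner, feature assignment and the cross-species ligation estimate."""

import numpy as np
import pytest

from chimeramap.align import (AMBIGUOUS_GENE, GeneAnnotation, GeneModel,
                              KmerIndex, MappedFragment, PanGenome,
                              RepeatAnnotation, RepeatElement, assign_gene,
                              build_novel_loci, estimate_random_ligation,
                              toy_align)
from chimeramap.dna import random_seq, revcomp
from chimeramap.parse import CHIMERIC, parse_read_pairs


@pytest.fixture(scope="module")
def toy_genome():
    rng = np.random.default_rng(7)
    return {"chrT": random_seq(rng, 5000)}


@pytest.fixture(scope="module")
def toy_index(toy_genome):
    return KmerIndex(toy_genome, k=15)


class TestToyAlign:
    def test_planted_substring_maps_uniquely(self, toy_genome, toy_index):
        frag = toy_genome["chrT"][1000:1060]
        status, m = toy_align(frag, toy_index)
        assert status == "unique"
        assert (m.reference, m.start, m.end, m.strand) == ("chrT", 1000, 1060, "+")

    def test_reverse_strand_fragment(self, toy_genome, toy_index):
        frag = revcomp(toy_genome["chrT"][2000:2050])
        status, m = toy_align(frag, toy_index)
        assert status == "unique" and m.strand == "-" and m.start == 2000

    def test_duplicated_sequence_is_ambiguous(self):
        rng = np.random.default_rng(8)
        unit = random_seq(rng, 80)
        genome = {"chrD": random_seq(rng, 500) + unit + random_seq(rng, 500) + unit}
        idx = KmerIndex(genome, k=15)
        status, m = toy_align(unit[10:50], idx)
        assert status == "ambiguous" and m is not None and not m.unique

    def test_short_fragment_is_unmapped(self, toy_index):
        assert toy_align("ACGTACGT", toy_index) == ("unmapped", None)

    def test_never_unique_when_fragment_occurs_twice(self):
        """Exhaustive substring check on a genome with a planted duplication."""
        rng = np.random.default_rng(9)
        unit = random_seq(rng, 40)
        genome = {"c": unit + random_seq(rng, 200) + unit}
        idx = KmerIndex(genome, k=15)
        for start in range(0, 21, 5):
            frag = unit[start:start + 20]
            n_occ = genome["c"].count(frag) + genome["c"].count(revcomp(frag))
            status, m = toy_align(frag, idx)
            if n_occ >= 2:
                assert status != "unique"

    def test_simulator_fragments_map_to_planted_loci(self, clean_library):
        lib = clean_library
        idx = KmerIndex(lib.reference.sequences, k=15)
        chims, _ = parse_read_pairs(lib.reads, lib.config.layout)
        n, ok = 0, 0
        for pc in chims:
            if pc.category != CHIMERIC:
                continue
            t = lib.truth.reads[pc.read_id]
            for seq, locus in ((pc.rna1_seq, t.frag1_locus),
                               (pc.rna2_seq, t.frag2_locus)):
                status, m = toy_align(seq, idx)
                n += 1
                if status == "unique" and (m.reference, m.start, m.end, m.strand) == locus:
                    ok += 1
            if n >= 500:
                break
        assert n >= 500 and ok == n


GENES = [
    GeneModel("sno1", "snoRNA", "chr1", "+", [(1000, 1200)]),
    GeneModel("geneA", "mRNA", "chr1", "+", [(2000, 3000)]),
    GeneModel("geneB", "mRNA", "chr1", "+", [(3000, 4000)]),
]
REPEATS = [RepeatElement("L1", "chr1", 5000, 5600, "+")]


class TestAssignGene:
    ANNOT = GeneAnnotation(GENES)
    REPS = RepeatAnnotation(REPEATS)

    def frag(self, start, end, strand="+"):
        return MappedFragment("r", "rna1", "chr1", start, end, strand)

    def test_containment_assigns_the_gene(self):
        assert assign_gene(self.frag(1050, 1100), self.ANNOT, self.REPS) == "sno1"

    def test_strand_is_respected(self):
        assert assign_gene(self.frag(1050, 1100, "-"), self.ANNOT, self.REPS) is None

    def test_repeat_only_overlap_becomes_repeat_unit(self):
        assert assign_gene(self.frag(5100, 5160), self.ANNOT, self.REPS) == "repeat:L1"

    def test_majority_overlap_wins_and_even_split_is_ambiguous(self):
        # 60/40 split across the geneA|geneB boundary -> geneA
        assert assign_gene(self.frag(2970, 3020), self.ANNOT, self.REPS) == "geneA"
        # 50/50 -> tie -> ambiguous
        assert assign_gene(self.frag(2975, 3025), self.ANNOT, self.REPS) == AMBIGUOUS_GENE

    def test_multimapped_fragment_is_rejected(self):
        bad = MappedFragment("r", "rna1", "chr1", 0, 50, "+", unique=False)
        with pytest.raises(ValueError, match="uniquely mapped"):
            assign_gene(bad, self.ANNOT, self.REPS)


class TestNovelLoci:
    def test_strand_aware_gap_merge_and_order_independence(self):
        frags = [
            MappedFragment("a", "rna1", "chr1", 100, 150, "+"),
            MappedFragment("b", "rna1", "chr1", 200, 260, "+"),   # gap 50 -> merge
            MappedFragment("c", "rna1", "chr1", 400, 450, "+"),   # gap 140 -> new
            MappedFragment("d", "rna1", "chr1", 120, 170, "-"),   # other strand
        ]
        fwd, loci = build_novel_loci(frags, max_gap=100)
        rev, loci2 = build_novel_loci(frags[::-1], max_gap=100)
        assert fwd == rev
        assert len(loci) == len(loci2) == 3
        assert fwd[("a", "rna1")] == fwd[("b", "rna1")]
        assert fwd[("c", "rna1")] != fwd[("a", "rna1")]
        assert fwd[("d", "rna1")] not in (fwd[("a", "rna1")], fwd[("c", "rna1")])


class TestRandomLigation:
    def test_all_intra_species_is_zero(self):
        est = estimate_random_ligation([("mm", "mm")] * 10)
        assert est.fraction == 0.0

    def test_hand_counted_fraction(self):
        pairs = [("mm", "dm")] * 3 + [("mm", "mm")] * 7
        est = estimate_random_ligation(pairs)
        assert est.fraction == pytest.approx(0.3)
        assert est.ci_low < 0.3 < est.ci_high

    def test_pan_genome_translates_references(self):
        pan = PanGenome({"chr1": "mouse", "chrX": "fly"})
        est = estimate_random_ligation([("chr1", "chrX"), ("chr1", "chr1")], pan=pan)
        assert est.fraction == pytest.approx(0.5)

    def test_zero_eligible_pairs_is_an_error(self):
        with pytest.raises(ValueError, match="no eligible"):
            estimate_random_ligation([])

    def test_wilson_interval_covers_the_planted_rate(self, rng):
        """95% CI covers the true inter-species fraction in >=90% of draws."""
        p, n, covered = 0.035, 4000, 0
        for _ in range(200):
            k = rng.binomial(n, p)
            pairs = [("mm", "dm")] * k + [("mm", "mm")] * (n - k)
            est = estimate_random_ligation(pairs)
            covered += est.ci_low <= p <= est.ci_high
        assert covered >= 180

    def test_mixing_correction_doubles_equal_mixture_fraction(self):
        pairs = [("mm", "dm")] * 35 + [("mm", "mm")] * 482 + [("dm", "dm")] * 483
        est = estimate_random_ligation(pairs)
        assert est.corrected == pytest.approx(est.fraction / (2 * est.species1_share
                                                              * (1 - est.species1_share)))
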