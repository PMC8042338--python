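"""Flank conservation, substitution classes, cross-species re-scoring."""

import itertools

import numpy as np
import pytest

from mirsite.duplex_core import reverse_complement
from mirsite.errors import ContractError, CoordinateError
from mirsite.io_formats import MiRNA, OrthologSet
from mirsite.ortholog_conservation import (
    AlignmentParams,
    SubstitutionCounts,
    align_global,
    classify_substitutions,
    cluster_shrinkage,
    conserved_flanks,
    rescore_across_species,
    translate_segment,
)
from mirsite.synthetic_data import random_sequence


def oracle_best_score(a, b, params=AlignmentParams()):
    """Exhaustive global-alignment DP written independently (plain recursion)."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == 0 and j == 0:
            return 0
        best = -(10 ** 9)
        if i > 0 and j > 0:
            sub = params.match if a[i - 1] == b[j - 1] else params.mismatch
            best = max(best, f(i - 1, j - 1) + sub)
        if i > 0:
            best = max(best, f(i - 1, j) + params.gap)
        if j > 0:
            best = max(best, f(i, j - 1) + params.gap)
        return best

    return f(len(a), len(b))


class TestClassifySubstitutions:
    @pytest.mark.parametrize(
        "ref,other,expected",
        [
            ("ACGU", "ACGC", SubstitutionCounts(pyrimidine_transition=1)),
            ("AGGG", "GGGG", SubstitutionCounts(purine_transition=1)),
            ("ACGU", "AAGU", SubstitutionCounts(transversion=1)),
            ("ACGU", "ACGU", SubstitutionCounts()),
        ],
    )
    def test_single_changes(self, ref, other, expected):
        assert classify_substitutions(ref, other) == expected

    def test_symmetric_under_swap(self, rng):
        for _ in range(20):
            a = random_sequence(40, 0.5, rng)
            b = random_sequence(40, 0.5, rng)
            ca, cb = classify_substitutions(a, b), classify_substitutions(b, a)
            assert (ca.purine_transition, ca.pyrimidine_transition, ca.transversion) == (
                cb.purine_transition, cb.pyrimidine_transition, cb.transversion
            )

    def test_empty_rejected(self):
        with pytest.raises(ContractError):
            classify_substitutions("", "ACGU")

    def test_alignment_optimal_vs_oracle(self, rng):
        for _ in range(40):
            a = random_sequence(int(rng.integers(3, 13)), 0.5, rng)
            b = random_sequence(int(rng.integers(3, 13)), 0.5, rng)
            _, _, score = align_global(a, b)
            assert score == oracle_best_score(a, b)


class TestConservedFlanks:
    def make_set(self, core_by_species, flank5="UGCGGG", flank3="CCGAG", pad="AAUU"):
        segments = {
            sp: pad + flank5 + core + flank3 + pad for sp, core in core_by_species.items()
        }
        return OrthologSet("L", segments, "hsa"), (
            len(pad) + len(flank5) + 1,
            len(pad) + len(flank5) + len(core_by_species["hsa"]),
        )

    def test_planted_flanks_recovered(self):
        oset, cluster = self.make_set(
            {"hsa": "ACGUACGUACGU", "ptr": "GCGUACGUACGU", "mmu": "ACGUACGUACGC"}
        )
        f5, f3 = conserved_flanks(oset, cluster, max_len=6)
        assert f5 == "UGCGGG"
        assert f3.startswith("CCGAG")

    def test_identical_segments_reach_max_len(self):
        oset, cluster = self.make_set({"hsa": "ACGUACGU", "ptr": "ACGUACGU"})
        f5, f3 = conserved_flanks(oset, cluster, max_len=4)
        assert len(f5) == 4 and len(f3) == 4

    def test_divergent_flank_empty(self):
        # ptr carries no A at all, so no upstream flank oligo is shared
        segments = {"hsa": "AAAACGUCCGU", "ptr": "GGGGCGUCCGU"}
        oset = OrthologSet("L", segments, "hsa")
        f5, _ = conserved_flanks(oset, (5, 11), max_len=4)
        assert f5 == ""

    def test_coordinate_error(self):
        oset, _ = self.make_set({"hsa": "ACGU", "ptr": "ACGU"})
        with pytest.raises(CoordinateError):
            conserved_flanks(oset, (1, 999))


class TestRescore:
    def test_reference_reproduced(self, rng):
        mirna = MiRNA("m", "".join(rng.choice(list("ACGU"), 22)))
        ref = random_sequence(30, 0.5, rng) + reverse_complement(mirna.sequence) + random_sequence(30, 0.5, rng)
        oset = OrthologSet("L", {"hsa": ref, "ptr": ref}, "hsa")
        res = rescore_across_species(mirna, oset)
        assert res["hsa"]["ratio"] == 100.0 and res["hsa"]["band"] == ">=90"
        assert res["ptr"] == res["hsa"]

    def test_transition_drops_two_bonds(self):
        """G→A inside a G-C paired position: 3-bond pair becomes 1-bond A-C."""
        mirna = MiRNA("m", "C" * 10 + "A" * 12)
        window = reverse_complement(mirna.sequence)  # U*12 + G*10
        mutated = window[:12] + "A" + window[13:]  # one G→A, pairs C via A-C
        ref_ratio = rescore_across_species(
            mirna, OrthologSet("L", {"hsa": window, "ptr": mutated}, "hsa")
        )
        mb = 10 * 3 + 12 * 2
        assert ref_ratio["hsa"]["ratio"] == 100.0
        assert ref_ratio["ptr"]["ratio"] == pytest.approx(100.0 * (mb - 2) / mb)

    def test_deleted_site_weak_band(self, rng):
        mirna = MiRNA("m", "".join(rng.choice(list("ACGU"), 22)))
        ref = random_sequence(40, 0.5, rng) + reverse_complement(mirna.sequence) + random_sequence(40, 0.5, rng)
        gone = random_sequence(102, 0.5, rng)  # site replaced entirely
        res = rescore_across_species(mirna, OrthologSet("L", {"hsa": ref, "ptr": gone}, "hsa"))
        assert res["ptr"]["band"] == "<80"

    def test_short_segment_not_evaluable(self):
        mirna = MiRNA("m", "A" * 22)
        oset = OrthologSet("L", {"hsa": "U" * 30, "ptr": "U" * 10}, "hsa")
        assert rescore_across_species(mirna, oset)["ptr"]["band"] == "not_evaluable"


class TestTranslate:
    def test_alanine_repeat(self):
        assert translate_segment("GCUGCU") == "AA"

    def test_ala_val_cluster_peptide(self):
        # GC-repeat cluster with one GUx codon: A...V...A pattern
        seq = "GCU" * 3 + "GUA" + "GCC" * 8
        assert translate_segment(seq) == "AAAVAAAAAAAA"

    def test_stop(self):
        assert translate_segment("AUGUAA") == "M*"

    @pytest.mark.parametrize("frame", [0, 1, 2])
    def test_length_law(self, frame, rng):
        seq = random_sequence(25, 0.5, rng)
        assert len(translate_segment(seq, frame)) == (25 - frame) // 3

    def test_too_short(self):
        with pytest.raises(ContractError):
            translate_segment("AC")


class TestClusterShrinkage:
    def test_identical_lengths_equal(self):
        seg = "AA" + "UGCGGG" + "ACGUACGUACGU" + "CCGAG" + "UU"
        oset = OrthologSet("L", {"hsa": seg, "ptr": seg, "mmu": seg}, "hsa")
        lengths = cluster_shrinkage(oset, (9, 20), max_flank=6)
        assert set(lengths.values()) == {12}

    def test_planted_deletion(self):
        core = "ACGUACGUACGUACGUACGUACGUACGUACGUA"  # 33 nt
        seg = "AA" + "UGCGGG" + core + "CCGAG" + "UU"
        short = "AA" + "UGCGGG" + core[11:] + "CCGAG" + "UU"
        oset = OrthologSet("L", {"hsa": seg, "ptr": short}, "hsa")
        lengths = cluster_shrinkage(oset, (9, 41), max_flank=6)
        assert lengths["hsa"] == 33 and lengths["ptr"] == 22
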