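"""Generator determinism, planting contracts and round-trips."""

import json

import numpy as np
import pytest

from mirsite.cluster_analysis import build_clusters, offset_patterns
from mirsite.duplex_core import max_bonds, reverse_complement, score_window
from mirsite.errors import GenerationError
from mirsite.io_formats import MiRNA
from mirsite.site_scanner import find_sites, group_polysites
from mirsite.synthetic_data import (
    SimConfig,
    degrade_window,
    gen_cohort,
    gen_mirna,
    gen_ortholog_set,
    random_sequence,
    truth_sites,
    write_cohort,
)
from mirsite.ortholog_conservation import classify_substitutions, conserved_flanks


class TestGenMirna:
    def test_gc_rich(self):
        rng = np.random.default_rng(1)
        m = gen_mirna(20, 0.95, rng)
        assert max_bonds(m) >= 56  # >= 18 of 20 bases G/C in expectation

    def test_au_only(self):
        rng = np.random.default_rng(1)
        assert max_bonds(gen_mirna(22, 0.0, rng)) == 44

    def test_deterministic(self):
        a = gen_mirna(22, 0.5, np.random.default_rng(7))
        b = gen_mirna(22, 0.5, np.random.default_rng(7))
        assert a.sequence == b.sequence

    def test_out_of_range(self):
        rng = np.random.default_rng(1)
        with pytest.raises(GenerationError):
            gen_mirna(10, 0.5, rng)
        with pytest.raises(GenerationError):
            gen_mirna(22, 1.5, rng)


class TestDegradeWindow:
    def test_target_100_untouched(self):
        rng = np.random.default_rng(2)
        m = gen_mirna(22, 0.5, rng)
        window, achieved = degrade_window(m, 100.0, rng)
        assert window == reverse_complement(m.sequence) and achieved == 100.0

    @pytest.mark.parametrize("target", [85.0, 88.0, 90.0, 93.0, 97.0])
    def test_targets_hit_within_tolerance(self, target):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = gen_mirna(22, 0.5, rng)
            window, achieved = degrade_window(m, target, rng)
            rescored = score_window(m, window).ratio
            assert rescored == pytest.approx(achieved)
            assert abs(rescored - target) <= 1.5


class TestGenOrthologSet:
    def test_zero_rate_identical(self):
        rng = np.random.default_rng(4)
        ref = random_sequence(80, 0.5, rng)
        oset = gen_ortholog_set(ref, 4, 0.0, 0.8, rng=rng)
        assert set(oset.segments.values()) == {ref}

    def test_transition_only_divergence(self):
        rng = np.random.default_rng(5)
        ref = random_sequence(120, 0.5, rng)
        oset = gen_ortholog_set(ref, 5, 0.1, 1.0, rng=rng)
        for sp, seg in oset.segments.items():
            counts = classify_substitutions(ref, seg)
            assert counts.transversion == 0 and counts.indel == 0

    def test_flanks_never_mutated(self):
        rng = np.random.default_rng(6)
        ref = "AAA" + "UGCGGG" + random_sequence(40, 0.5, rng) + "CCGAG" + "UUU"
        oset = gen_ortholog_set(ref, 6, 0.5, 0.8, ("UGCGGG", "CCGAG"), rng)
        for seg in oset.segments.values():
            assert "UGCGGG" in seg and "CCGAG" in seg

    def test_missing_flank_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(GenerationError):
            gen_ortholog_set("ACGUACGU", 3, 0.1, 0.8, ("GGGGGG", ""), rng)


class TestGenCohort:
    def test_deterministic_byte_identical(self, tmp_path):
        paths_a = write_cohort(gen_cohort(SimConfig(seed=11)), tmp_path / "a")
        paths_b = write_cohort(gen_cohort(SimConfig(seed=11)), tmp_path / "b")
        for name in paths_a:
            assert paths_a[name].read_bytes() == paths_b[name].read_bytes()

    def test_different_seed_differs(self):
        a = gen_cohort(SimConfig(seed=1))
        b = gen_cohort(SimConfig(seed=2))
        assert [m.sequence for m in a.mirnas] != [m.sequence for m in b.mirnas]

    def test_planted_sites_recovered_by_scanner(self, default_cohort):
        c = default_cohort
        by_id = {t.transcript_id: t for t in c.transcripts}
        mir = {m.id: m for m in c.mirnas}
        for rec in c.ground_truth["planted_sites"]:
            sites = find_sites(mir[rec["mirna_id"]], by_id[rec["transcript_id"]])
            hit = [s for s in sites if s.start == rec["start"]]
            assert hit, f"missing planting {rec}"
            assert hit[0].ratio == pytest.approx(rec["achieved_ratio"])
            assert hit[0].region == rec["region"]

    def test_ground_truth_clusters_match_build_clusters(self, default_cohort):
        c = default_cohort
        planted = truth_sites(default_cohort)
        for truth in c.ground_truth["clusters"]:
            members = [
                s for s in planted
                if s.transcript_id == truth["transcript_id"]
                and any(m["mirna_id"] == s.mirna_id and m["start"] == s.start
                        for m in truth["members"])
            ]
            (cluster,) = build_clusters(members)
            assert [cluster.span_start, cluster.span_end] == truth["span"]

    def test_offset_round_trip(self, default_cohort):
        c = default_cohort
        planted = truth_sites(c)
        for rec in c.ground_truth["offset_pairs"]:
            (p,) = offset_patterns(planted, [(rec["mirna_a"], rec["mirna_b"])])
            assert p.constant and p.offset == rec["offset"]
            assert set(p.per_gene) == set(rec["genes"])

    def test_polysite_round_trip(self, default_cohort):
        c = default_cohort
        by_id = {t.transcript_id: t for t in c.transcripts}
        mir = {m.id: m for m in c.mirnas}
        for rec in c.ground_truth["polysites"]:
            sites = find_sites(mir[rec["mirna_id"]], by_id[rec["transcript_id"]])
            perfect = [s for s in sites if s.ratio == 100.0]
            (run,) = group_polysites(perfect, max_gap=3)
            assert list(run.starts) == rec["starts"]
            assert run.count == len(rec["starts"])

    def test_rpkm_range_and_high_band(self, default_cohort):
        values = list(default_cohort.ground_truth["rpkm"].values())
        assert all(0.1 <= v <= 322.5 for v in values)
        assert any(v >= 43.1 for v in values)

    def test_empty_cohort_valid(self, tmp_path):
        cfg = SimConfig(seed=0, n_genes=0, planted_sites=[], clusters=[],
                        offset_pairs=[], ortholog=None)
        cohort = gen_cohort(cfg)
        assert cohort.mirnas == [] and cohort.transcripts == []
        paths = write_cohort(cohort, tmp_path)
        truth = json.loads(paths["ground_truth"].read_text())
        assert truth["planted_sites"] == []

    def test_cluster_compaction_of_close_plantings(self, default_cohort):
        """Overlapping cluster plantings yield compaction > 1."""
        planted = truth_sites(default_cohort)
        truth = default_cohort.ground_truth["clusters"][0]
        members = [
            s for s in planted
            if s.transcript_id == truth["transcript_id"]
            and any(m["mirna_id"] == s.mirna_id and m["start"] == s.start
                    for m in truth["members"])
        ]
        (cluster,) = build_clusters(members)
        assert cluster.compaction > 1.5
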