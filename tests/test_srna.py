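import numpy as np
import pandas as pd
import pytest

from methylpath.srna import (
    CleavageRecord,
    cleavage_dependency,
    competence,
    dependency_table,
    filter_sites,
    normalize_profile,
    secondary_fraction,
    site_retention,
)


class TestNormalizeProfile:
    def test_hand_arithmetic(self):
        prof = normalize_profile({24: 250}, library_total=1_000_000,
                                 region_length=500)
        assert prof.rpm[24] == pytest.approx(250.0)
        assert prof.rpkm[24] == pytest.approx(500.0)

    def test_zero_counts(self):
        prof = normalize_profile({s: 0 for s in range(18, 29)},
                                 library_total=10_000, region_length=100)
        assert all(v == 0 for v in prof.rpm.values())

    def test_doubling_total_halves_rpm(self):
        a = normalize_profile({21: 40, 24: 10}, 1_000_000, 200)
        b = normalize_profile({21: 40, 24: 10}, 2_000_000, 200)
        for s in (21, 24):
            assert b.rpm[s] == pytest.approx(a.rpm[s] / 2)

    def test_rpm_sum_conservation(self):
        rng = np.random.default_rng(0)
        counts = {s: int(rng.integers(0, 500)) for s in range(18, 29)}
        prof = normalize_profile(counts, 3_456_789, 700)
        assert sum(prof.rpm.values()) == pytest.approx(
            sum(counts.values()) * 1e6 / 3_456_789)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile({24: 1}, 0, 100)


class TestFilterSites:
    def rec(self, p, lib="L", functional=True):
        return CleavageRecord("T1", 100, p, lib, "active", functional)

    def test_below_alpha_kept(self):
        assert len(filter_sites([self.rec(0.01)])) == 1

    def test_boundary_dropped(self):
        assert filter_sites([self.rec(0.05)]) == []

    def test_empty(self):
        assert filter_sites([]) == []


class TestCleavageDependency:
    def rec(self, site, functional, p=0.001):
        lib = "ddm1" if functional else "ddm1_rdr6"
        return CleavageRecord("T1", site, p, lib, "active", functional)

    def test_site_in_both_libraries_is_primary(self):
        label, sites = cleavage_dependency(
            [self.rec(100, True), self.rec(100, False)], "active")
        assert label == "PRIMARY_ONLY"
        assert sites["primary"] == {100} and not sites["rdr6_dependent"]

    def test_site_lost_without_rdr6_is_secondary(self):
        label, sites = cleavage_dependency(
            [self.rec(100, True), self.rec(500, False, p=1.0)], "active")
        assert label == "SECONDARY_INVOLVED"
        assert sites["rdr6_dependent"] == {100}

    def test_no_surviving_site_uncleaved(self):
        label, _ = cleavage_dependency(
            [self.rec(100, True, p=0.9), self.rec(100, False, p=0.9)], "active")
        assert label == "UNCLEAVED"

    def test_missing_library_class_rejected(self):
        with pytest.raises(ValueError):
            cleavage_dependency([self.rec(100, True)], "active")

    def test_adding_mutant_site_never_creates_dependency(self):
        base = [self.rec(100, True), self.rec(900, False, p=1.0)]
        label0, s0 = cleavage_dependency(base, "active")
        label1, s1 = cleavage_dependency(base + [self.rec(200, False)], "active")
        assert s1["rdr6_dependent"] <= s0["rdr6_dependent"]


class TestSiteRetention:
    def test_retained_and_gained(self):
        assert site_retention({100}, {100, 250}) == ("RETAINED_AND_GAINED", (1, 2))

    def test_distinct_sites(self):
        assert site_retention({100}, {250}) == ("NOT_RETAINED_DISTINCT", (1, 1))

    def test_none(self):
        assert site_retention(set(), set()) == ("NONE", (0, 0))

    def test_one_sided(self):
        assert site_retention({100}, set())[0] == "SILENT_ONLY"
        assert site_retention(set(), {100})[0] == "ACTIVE_ONLY"

    def test_tolerance_window(self):
        assert site_retention({100}, {103}, tolerance=5)[0] == "RETAINED_AND_GAINED"
        assert site_retention({100}, {110}, tolerance=5)[0] == "NOT_RETAINED_DISTINCT"

    def test_matches_set_comparison_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            silent = set(rng.integers(0, 40, rng.integers(0, 5)).tolist())
            active = set(rng.integers(0, 40, rng.integers(0, 5)).tolist())
            label, trans = site_retention(silent, active, tolerance=0)
            if not silent and not active:
                expected = "NONE"
            elif silent and not active:
                expected = "SILENT_ONLY"
            elif active and not silent:
                expected = "ACTIVE_ONLY"
            elif silent & active:
                expected = "RETAINED_AND_GAINED"
            else:
                expected = "NOT_RETAINED_DISTINCT"
            assert label == expected
            assert trans == (len(silent), len(active))


class TestCompetence:
    def test_rnaseq_threshold_inclusive(self):
        call = competence("T", rnaseq_rpm=1.0, sirna_2122_rpm=0,
                          cleavage_evidence=False)
        assert call.competent and call.evidence == {"rnaseq"}

    def test_sirna_below_ten_not_competent(self):
        call = competence("T", rnaseq_rpm=0, sirna_2122_rpm=9.99,
                          cleavage_evidence=False)
        assert not call.competent

    def test_sirna_at_ten_competent(self):
        call = competence("T", 0, 10.0, False)
        assert call.evidence == {"sirna2122"}

    def test_cleavage_alone_suffices(self):
        call = competence("T", 0, 0, True)
        assert call.competent and call.evidence == {"cleavage"}

    def test_rnaseq_just_below_one(self):
        assert not competence("T", 0.999, 0, False).competent


class TestDependencyTableAndGroups:
    def test_synthetic_truth_recovered_exactly(self, small_dataset):
        """At zero site noise the SECONDARY_INVOLVED set equals the planted
        RDR6-dependent-cleavage set."""
        from methylpath.srna import read_pare_table
        records = [
            CleavageRecord(r.feature_id, int(r.site), float(r.p_value),
                           r.library_id, r.background, bool(r.rdr6_functional))
            for r in small_dataset.pare.itertuples(index=False)]
        te_ids = [f.id for f in small_dataset.tes]
        dep = dependency_table(records, "active", te_ids)
        observed = set(dep.index[dep["dependency"] == "SECONDARY_INVOLVED"])
        truth = small_dataset.truth_cleavage
        planted = set(truth[(truth["background"] == "active")
                            & truth["rdr6_dependent"]]["te_id"])
        assert observed == planted

    def test_group_separation_by_construction(self):
        """Cleaved TEs carrying 21-22 nt mass and uncleaved TEs carrying
        24 nt mass split cleanly into group profiles."""
        profs = []
        for i in range(6):
            cleaved = i < 3
            counts = {21: 200, 22: 220} if cleaved else {24: 300}
            profs.append(normalize_profile(counts, 1_000_000, 500,
                                           feature_id=f"T{i}", library_id="L"))
        dep = {f"T{i}": ("SECONDARY_INVOLVED" if i < 3 else "UNCLEAVED")
               for i in range(6)}
        table = secondary_fraction(profs, dep)
        assert table.loc[("L", "CLEAVED"), "share_21_22"] == pytest.approx(1.0)
        assert table.loc[("L", "UNCLEAVED"), "share_21_22"] == pytest.approx(0.0)

    def test_all_uncleaved_single_group(self):
        profs = [normalize_profile({24: 10}, 1_000_000, 100,
                                   feature_id="T0", library_id="L")]
        table = secondary_fraction(profs, {})
        assert list(table.index) == [("L", "UNCLEAVED")]

    def test_empty_profiles_empty_table(self):
        assert secondary_fraction([], {}).empty
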