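import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

from methylpath.io import Feature
from methylpath.methylome import (
    DMS,
    build_matrix,
    call_dms,
    feature_levels,
    merge_dms,
    weighted_level,
)

from conftest import make_calls


def expand_oracle(pairs):
    """Brute-force weighted level: expand every read into a 0/1 observation
    and average."""
    obs = []
    for n_meth, n_total in pairs:
        obs.extend([1] * n_meth + [0] * (n_total - n_meth))
    return sum(obs) / len(obs) if obs else None


class TestWeightedLevel:
    def test_hand_sum(self):
        calls = make_calls([("chr1", p, "+", "CHH", m, t) for p, (m, t) in
                            enumerate([(5, 10), (0, 10), (15, 20)], start=1)])
        lvl = weighted_level(calls, "CHH")
        assert lvl.level == pytest.approx(0.5)
        assert lvl.n_cytosines == 3 and lvl.n_reads == 40

    def test_fully_unmethylated_is_zero_not_undefined(self):
        calls = make_calls([("chr1", 1, "+", "CHH", 0, 8),
                            ("chr1", 2, "-", "CHH", 0, 4)])
        lvl = weighted_level(calls, "CHH")
        assert lvl.level == 0.0 and lvl.n_cytosines == 2

    def test_no_coverage_is_undefined(self):
        calls = make_calls([("chr1", 1, "+", "CG", 3, 5),
                            ("chr1", 2, "+", "CHH", 0, 0)])
        lvl = weighted_level(calls, "CHH")
        assert lvl.level is None and lvl.n_cytosines == 0

    def test_matches_read_expansion_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = rng.integers(1, 30)
            totals = rng.integers(0, 25, n)
            meths = rng.integers(0, totals + 1)
            calls = make_calls([("chr1", i + 1, "+", "CHH", int(m), int(t))
                                for i, (m, t) in enumerate(zip(meths, totals))])
            lvl = weighted_level(calls, "CHH")
            oracle = expand_oracle([(m, t) for m, t in zip(meths, totals) if t > 0])
            if oracle is None:
                assert lvl.level is None
            else:
                assert lvl.level == oracle  # exact: same integer division

    def test_permutation_invariance(self):
        rows = [("chr1", p, "+", "CHH", p % 3, 5) for p in range(1, 20)]
        a = weighted_level(make_calls(rows), "CHH")
        b = weighted_level(make_calls(rows[::-1]), "CHH")
        assert a.level == b.level


class TestBuildMatrix:
    def feature(self):
        return [Feature("T1", "chr1", 0, 100), Feature("T2", "chr1", 200, 300)]

    def test_all_covered(self):
        calls = make_calls([("chr1", p, "+", "CHH", 1, 4)
                            for p in (10, 50, 250, 260)])
        m = build_matrix({"ref": calls, "polV": calls}, self.feature(), "CHH")
        assert m.covered_all.all()
        assert m.levels.notna().all().all()
        assert m.levels.loc["T1", "ref"] == pytest.approx(0.25)

    def test_uncovered_in_one_role_flagged(self):
        full = make_calls([("chr1", p, "+", "CHH", 1, 4) for p in (10, 250)])
        partial = make_calls([("chr1", 10, "+", "CHH", 1, 4)])
        m = build_matrix({"ref": full, "polV": partial}, self.feature(), "CHH")
        assert bool(m.covered_all["T1"]) is True
        assert bool(m.covered_all["T2"]) is False

    def test_empty_feature_list(self):
        calls = make_calls([("chr1", 10, "+", "CHH", 1, 4)])
        m = build_matrix({"ref": calls}, [], "CHH")
        assert m.levels.empty

    def test_boundary_cytosines(self):
        # feature [100, 200): 1-based pos 101 is the first base, 200 the last
        calls = make_calls([("chr1", 100, "+", "CHH", 4, 4),
                            ("chr1", 101, "+", "CHH", 0, 4),
                            ("chr1", 200, "+", "CHH", 0, 4),
                            ("chr1", 201, "+", "CHH", 4, 4)])
        per = feature_levels(calls, [Feature("T", "chr1", 100, 200)], "CHH")
        assert per.loc["T", "n_cytosines"] == 2
        assert per.loc["T", "level"] == pytest.approx(0.0)


class TestCallDMS:
    def test_extreme_site_called(self):
        a = make_calls([("chr1", 100, "+", "CHH", 20, 20)])
        b = make_calls([("chr1", 100, "+", "CHH", 0, 20)])
        (d,) = call_dms(a, b, alpha=0.05)
        assert d.direction == "hypo" and d.pos == 99
        assert d.p_value == pytest.approx(
            fisher_exact([[20, 0], [0, 20]])[1])

    def test_identical_tables_yield_nothing(self):
        rng = np.random.default_rng(1)
        rows = [("chr1", p, "+", "CHH", int(rng.integers(0, 10)), 10)
                for p in range(1, 200)]
        a = make_calls(rows)
        assert call_dms(a, a.copy(), alpha=0.5) == []

    def test_position_covered_in_one_genotype_not_tested(self):
        a = make_calls([("chr1", 100, "+", "CHH", 20, 20),
                        ("chr1", 200, "+", "CHH", 20, 20)])
        b = make_calls([("chr1", 200, "+", "CHH", 0, 20)])
        calls = call_dms(a, b, alpha=0.05)
        assert [d.pos for d in calls] == [199]

    def test_unsorted_input_rejected(self):
        df = pd.DataFrame([("chr1", 5, "+", "CHH", 0, 5),
                           ("chr1", 2, "+", "CHH", 0, 5)],
                          columns=["chrom", "pos", "strand", "context",
                                   "n_meth", "n_total"])
        with pytest.raises(ValueError, match="sorted"):
            call_dms(df, df)


def brute_force_clusters(positions, max_gap):
    """O(n^2) transitive closure on |pos_i - pos_j| <= max_gap adjacency."""
    positions = sorted(set(positions))
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                parent[find(i)] = find(j)
    clusters = {}
    for i, p in enumerate(positions):
        clusters.setdefault(find(i), []).append(p)
    return sorted(sorted(c) for c in clusters.values())


class TestMergeDMS:
    def dms(self, positions, chrom="chr1"):
        return [DMS(chrom, p, "CHH", 0.001, "hypo") for p in positions]

    def test_four_sites_one_region(self):
        (r,) = merge_dms(self.dms([100, 200, 400, 600]))
        assert (r.start, r.end, r.n_dms) == (100, 601, 4)

    def test_large_gaps_no_region(self):
        assert merge_dms(self.dms([100, 400, 700, 1000])) == []

    def test_empty_input(self):
        assert merge_dms([]) == []

    def test_boundary_gap_exactly_250_joins(self):
        (r,) = merge_dms(self.dms([0, 250, 500, 750]))
        assert r.n_dms == 4

    def test_chromosomes_never_chain(self):
        dms = self.dms([0, 100, 200]) + self.dms([300, 400, 500], chrom="chr2")
        regions = merge_dms(dms, min_dms=3)
        assert [(r.chrom, r.start, r.end, r.n_dms) for r in regions] == \
               [("chr1", 0, 201, 3), ("chr2", 300, 501, 3)]

    def test_matches_transitive_closure_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(0, 200))
            positions = np.cumsum(rng.integers(1, 600, n)).tolist()
            regions = merge_dms(self.dms(positions), max_gap=250, min_dms=4)
            # single-linkage on sorted positions == transitive closure
            expected = [c for c in brute_force_clusters(positions, 250)
                        if len(c) >= 4]
            assert [(r.start, r.end, r.n_dms) for r in regions] == \
                   [(c[0], c[-1] + 1, len(c)) for c in expected]

    def test_duplicate_sites_do_not_inflate_counts(self):
        dup = self.dms([100, 100, 200, 200, 300])
        assert merge_dms(dup, min_dms=4) == []
        (r,) = merge_dms(dup, min_dms=3)
        assert r.n_dms == 3
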