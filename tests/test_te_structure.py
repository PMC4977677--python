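import numpy as np
import pandas as pd
import pytest

from methylpath.io import Feature
from methylpath.te_structure import (
    ConsensusCoverage,
    GenomeMappability,
    accept_domain_hit,
    accept_ltr,
    domain_enrichment,
    landmark_likelihood_map,
    landmark_presence,
    length_class,
    profiles_from_hits,
    size_category_table,
    split_peptides,
)


class TestLengthClass:
    @pytest.mark.parametrize("te_len,cons_len,expected", [
        (11_000, 11_600, "FULL_LENGTH"),   # 0.948 of an 11.6 kb consensus
        (219, 11_600, "FRAGMENT"),         # a short fragment
        (5_800, 11_600, "INTERMEDIATE"),   # exactly half
        (9_280, 11_600, "INTERMEDIATE"),   # exactly 0.80: strict boundary
        (2_320, 11_600, "INTERMEDIATE"),   # exactly 0.20: strict boundary
    ])
    def test_thresholds(self, te_len, cons_len, expected):
        assert length_class(te_len, cons_len) == expected

    def test_zero_consensus_rejected(self):
        with pytest.raises(ValueError):
            length_class(100, 0)


class TestLandmarks:
    def cov(self, intervals, L=12_000):
        return ConsensusCoverage.from_intervals("T", "ATHILA", L, intervals)

    def test_full_coverage_contains_landmark(self):
        assert landmark_presence(self.cov([(0, 12_000)]), (500, 900))

    def test_gap_overlapping_landmark(self):
        cov = self.cov([(0, 400), (1000, 2000)])
        assert not landmark_presence(cov, (300, 1100))

    def test_empty_coverage(self):
        assert not landmark_presence(self.cov([]), (300, 400))

    def test_likelihood_fractions(self):
        covs = {f"T{i}": self.cov([(0, 12_000)] if i < 3 else [(6000, 12_000)])
                for i in range(4)}
        calls = pd.DataFrame({"category": ["POLIV_RDDM"] * 4},
                             index=[f"T{i}" for i in range(4)])
        table = landmark_likelihood_map(covs, {"LTR5": (0, 500)}, calls)
        assert table.loc["POLIV_RDDM", "LTR5"] == pytest.approx(0.75)

    def test_full_coverage_family_row_is_one(self):
        covs = {f"T{i}": self.cov([(0, 12_000)]) for i in range(5)}
        calls = pd.DataFrame({"category": ["RDR6_RDDM"] * 5},
                             index=list(covs))
        marks = {"LTR5": (0, 500), "GAG": (1000, 2500), "LTR3": (11_000, 12_000)}
        table = landmark_likelihood_map(covs, marks, calls)
        assert (table.loc["RDR6_RDDM"] == 1.0).all()


class TestSplitPeptides:
    def test_hand_translation_with_stop_split(self):
        frags = [f for f in split_peptides("ATGAAATAGATGCCC") if f.frame == 1]
        assert [f.peptide for f in frags] == ["MK", "MP"]
        assert [(f.nt_start, f.nt_end) for f in frags] == [(0, 6), (9, 15)]

    def test_all_stop_frame_empty(self):
        frags = [f for f in split_peptides("TAGTAGTAG") if f.frame == 1]
        assert frags == []

    def test_revcomp_symmetry(self):
        from Bio.Seq import Seq
        rng = np.random.default_rng(2)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        rc = str(Seq(seq).reverse_complement())
        fwd_of_rc = sorted(f.peptide for f in split_peptides(rc) if f.frame > 0)
        rev_of_seq = sorted(f.peptide for f in split_peptides(seq) if f.frame < 0)
        assert fwd_of_rc == rev_of_seq

    def test_fragments_tile_each_frame(self):
        """Per frame, fragments plus stop codons account for every complete
        codon."""
        rng = np.random.default_rng(4)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 301)])
        frags = split_peptides(seq)
        for frame in (1, 2, 3, -1, -2, -3):
            shift = abs(frame) - 1
            n_codons = (len(seq) - shift) // 3
            ours = [f for f in frags if f.frame == frame]
            n_res = sum(len(f.peptide) for f in ours)
            # residues + stops == total codons (trailing stops included)
            from Bio.Seq import Seq
            s = seq if frame > 0 else str(Seq(seq).reverse_complement())
            aa = str(Seq(s[shift:shift + 3 * n_codons]).translate())
            assert n_res == n_codons - aa.count("*")
            # no fragment overlaps another and all lie within the sequence
            spans = sorted((f.nt_start, f.nt_end) for f in ours)
            assert all(0 <= a < b <= len(seq) for a, b in spans)
            assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))

    def test_n_codons_become_x(self):
        frags = [f for f in split_peptides("ATGANA") if f.frame == 1]
        assert frags[0].peptide == "MX"


class TestDomainRules:
    def test_domain_hit_threshold_strict(self):
        assert accept_domain_hit(0.95) is True
        assert accept_domain_hit(0.90) is False
        assert accept_domain_hit(0.0) is False

    def test_ltr_edge_rules(self):
        assert accept_ltr((1000, 1200), (1000, 9000)) == (True, "LTR5")
        assert accept_ltr((8800, 9000), (1000, 9000)) == (True, "LTR3")
        assert accept_ltr((4000, 4200), (1000, 9000)) == (False, None)

    def test_ltr_outside_te_rejected(self):
        with pytest.raises(ValueError):
            accept_ltr((900, 1200), (1000, 9000))

    def test_profiles_from_hits_applies_both_rules(self):
        hits = pd.DataFrame({"te_id": ["T1", "T1", "T2"],
                             "domain": ["GAG", "RT", "GAG"],
                             "covered_fraction": [0.99, 0.5, 0.92]})
        ltrs = pd.DataFrame({"te_id": ["T1"], "ltr_start": [0], "ltr_end": [200],
                             "te_start": [0], "te_end": [5000]})
        prof = profiles_from_hits(hits, ltr_table=ltrs)
        assert prof["T1"].domains == {"GAG", "LTR5"}
        assert prof["T2"].domains == {"GAG"}


class TestDomainEnrichment:
    def build(self, n=40, seed=0):
        from methylpath.te_structure import DomainProfile
        rng = np.random.default_rng(seed)
        ids = [f"T{i}" for i in range(n)]
        profiles = {t: DomainProfile(t, frozenset(
            d for d in ("GAG", "RT") if rng.random() < 0.4)) for t in ids}
        cats = rng.choice(["A", "B"], n)
        calls = pd.DataFrame({"category": cats}, index=ids)
        return profiles, calls

    def test_hand_ratio(self):
        from methylpath.te_structure import DomainProfile
        ids = [f"T{i}" for i in range(10)]
        profiles = {t: DomainProfile(t, frozenset(["GAG"] if i < 4 else []))
                    for i, t in enumerate(ids)}
        calls = pd.DataFrame(
            {"category": ["A"] * 5 + ["B"] * 5}, index=ids)
        table = domain_enrichment(profiles, calls, domains=("GAG",))
        assert table.loc["A", "GAG"] == pytest.approx((4 / 5) / (4 / 10))

    def test_all_te_pseudocategory_is_identically_one(self):
        profiles, calls = self.build()
        calls_all = calls.copy()
        calls_all["category"] = "ALL"
        table = domain_enrichment(profiles, calls_all, domains=("GAG", "RT"))
        present = table.dropna(axis=1, how="all")
        assert np.allclose(present.to_numpy(dtype=float), 1.0)

    def test_domain_absent_genome_wide_undefined(self):
        profiles, calls = self.build()
        table = domain_enrichment(profiles, calls, domains=("INT",))
        assert table["INT"].isna().all()


class TestSizeCategoryTable:
    def test_closed_form_chi2(self):
        lengths = {f"A{i}": 300 for i in range(10)}
        lengths |= {f"B{i}": 300 for i in range(20)}
        lengths |= {f"C{i}": 3000 for i in range(20)}
        lengths |= {f"D{i}": 3000 for i in range(10)}
        calls = pd.DataFrame(
            {"category": ["X"] * 10 + ["Y"] * 20 + ["X"] * 20 + ["Y"] * 10},
            index=list(lengths))
        counts, chi2, _ = size_category_table(calls, lengths)
        assert chi2.statistic == pytest.approx(20 / 3, abs=5e-4)
        assert chi2.df == 1

    def test_degenerate_table_skips_test(self):
        lengths = {f"T{i}": 300 for i in range(6)}
        calls = pd.DataFrame({"category": ["X"] * 3 + ["Y"] * 3},
                             index=list(lengths))
        with pytest.warns(UserWarning, match="degenerate"):
            counts, chi2, contrasts = size_category_table(calls, lengths)
        assert chi2 is None and contrasts == []

    def test_proportional_counts_not_significant(self):
        lengths = {}
        cats = {}
        i = 0
        for cat in ("X", "Y"):
            for L, n in ((300, 12), (3000, 12)):
                for _ in range(n):
                    lengths[f"T{i}"] = L
                    cats[f"T{i}"] = cat
                    i += 1
        calls = pd.DataFrame({"category": pd.Series(cats)})
        _, chi2, contrasts = size_category_table(calls, lengths)
        assert chi2.p_value == pytest.approx(1.0)
        assert contrasts == []


def brute_force_mappability(genome, te, k):
    """Hash every k-mer of the genome (both strands) and score windows."""
    from collections import Counter
    comp = str.maketrans("ACGTN", "TGCAN")
    counts = Counter()
    for seq in genome.values():
        for i in range(len(seq) - k + 1):
            counts[seq[i:i + k]] += 1
            counts[seq[i:i + k].translate(comp)[::-1]] += 1
    seq = genome[te.chrom]
    if te.length >= k:
        starts = range(te.start, min(te.end, len(seq) - k + 1))
    else:
        starts = range(max(0, te.start - k + 1), min(te.end, len(seq) - k + 1))
    scores = [counts[seq[s:s + k]] == 1 for s in starts]
    return sum(scores) / len(scores) if scores else 0.0


class TestMappability:
    def random_genome(self, rng, n=3000):
        return {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])}

    def test_unique_sequence_is_perfect(self):
        rng = np.random.default_rng(0)
        genome = self.random_genome(rng)
        te = Feature("T", "chr1", 500, 900)
        frac, cls = GenomeMappability(genome, 150).te_mappability(te)
        assert (frac, cls) == (1.0, "perfect")

    def test_buried_duplicate_is_non_mappable(self):
        rng = np.random.default_rng(1)
        base = self.random_genome(rng)["chr1"]
        unit = base[500:900 + 149]  # TE plus a shared right flank
        genome = {"chr1": base[:2000] + unit + base[2000:]}
        te_a = Feature("A", "chr1", 500, 900)
        frac, cls = GenomeMappability(genome, 150).te_mappability(te_a)
        assert (frac, cls) == (0.0, "non")

    def test_tandem_duplicate_with_unique_flank_is_semi(self):
        rng = np.random.default_rng(2)
        base = self.random_genome(rng)["chr1"]
        unit = base[500:900]  # TE body only; flanks remain unique
        genome = {"chr1": base[:2000] + unit + base[2000:]}
        frac, cls = GenomeMappability(genome, 150).te_mappability(
            Feature("A", "chr1", 500, 900))
        assert cls == "semi"
        assert 0 < frac < 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        base = self.random_genome(rng, 5000)["chr1"]
        # plant a duplication and a short TE
        genome = {"chr1": base + base[1000:1400], "chr2": base[2000:2600]}
        idx = GenomeMappability(genome, 150)
        tes = [Feature("A", "chr1", 1000, 1400),
               Feature("B", "chr1", 4000, 4090),   # shorter than a read
               Feature("C", "chr2", 100, 500),
               Feature("D", "chr1", 4900, 5100)]   # spans the junction
        for te in tes:
            frac, _ = idx.te_mappability(te)
            assert frac == pytest.approx(
                brute_force_mappability(genome, te, 150))

    def test_planted_duplicates_recovered_in_simulation(self, small_dataset):
        truth = small_dataset.truth
        idx = GenomeMappability(small_dataset.genome, 150)
        flagged = truth[truth["duplicate_of"] != ""]
        assert len(flagged) >= 2
        by_te = {f.id: f for f in small_dataset.tes}
        for row in flagged.itertuples(index=False):
            frac, cls = idx.te_mappability(by_te[row.te_id])
            kind = row.duplicate_of.split(":")[0]
            if kind == "buried":
                assert cls == "non"
            else:
                # identical bodies, unique flanks: interior windows repeat,
                # edge windows reach unique sequence
                assert cls == "semi"
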