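"""TE length and structure analyses.

Covers: full-length vs fragment calls against a family consensus, presence of
consensus landmarks (LTRs, ORFs, promoters) per pathway category, six-frame
peptide splitting for domain searches, LTR-domain acceptance rules and
observed/expected enrichment per category, TE size-class contingency tests,
and exact-k-mer TE mappability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import Feature, PipelineConfig
from .stats import Chi2Result, ProportionContrast, chi2_homogeneity, pairwise_proportions

LENGTH_CLASSES = ("FULL_LENGTH", "INTERMEDIATE", "FRAGMENT")

#: the seven domains an autonomous LTR retrotransposon needs
ESSENTIAL_DOMAINS = ("LTR5", "GAG", "AP", "RT", "RNaseH", "INT", "LTR3")

#: Fig-style domain-count buckets (0-domain TEs are excluded from buckets)
DOMAIN_BUCKETS = ((1, 1), (2, 3), (4, 5), (6, 7))

#: TE size bins in bp: <0.5 kb, 0.5-2 kb, 2-5 kb, >5 kb
SIZE_BIN_EDGES = (500, 2000, 5000)
SIZE_BIN_LABELS = ("<0.5kb", "0.5-2kb", "2-5kb", ">5kb")


@dataclass(frozen=True)
class ConsensusCoverage:
    """Which parts of a family consensus one genomic TE copy aligns to.

    ``covered`` holds sorted, non-overlapping 0-based half-open intervals on
    the consensus.
    """

    te_id: str
    consensus_id: str
    consensus_length: int
    covered: tuple

    def __post_init__(self) -> None:
        prev_end = -1
        for start, end in self.covered:
            if not (0 <= start < end <= self.consensus_length):
                raise ValueError(
                    f"{self.te_id}: interval ({start},{end}) outside consensus")
            if start <= prev_end:
                raise ValueError(f"{self.te_id}: intervals overlap or are unsorted")
            prev_end = end

    @classmethod
    def from_intervals(cls, te_id: str, consensus_id: str, consensus_length: int,
                       intervals: Sequence[tuple]) -> "ConsensusCoverage":
        """Normalize arbitrary intervals (sort + merge touching/overlapping)."""
        merged: list[list[int]] = []
        for start, end in sorted(intervals):
            if merged and start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        return cls(te_id, consensus_id, consensus_length,
                   tuple((s, e) for s, e in merged))

    @property
    def fraction(self) -> float:
        return sum(e - s for s, e in self.covered) / self.consensus_length


def length_class(te_length: int, consensus_length: int,
                 config: Optional[PipelineConfig] = None) -> str:
    """FULL_LENGTH (> 80 % of consensus), FRAGMENT (< 20 %) or INTERMEDIATE."""
    config = config or PipelineConfig()
    if consensus_length <= 0:
        raise ValueError("consensus_length must be positive")
    ratio = te_length / consensus_length
    if ratio > config.full_length_min:
        return "FULL_LENGTH"
    if ratio < config.fragment_max:
        return "FRAGMENT"
    return "INTERMEDIATE"


def landmark_presence(coverage: ConsensusCoverage, landmark: tuple) -> bool:
    """True iff the landmark interval is fully contained in the covered union."""
    start, end = landmark
    if not (0 <= start < end <= coverage.consensus_length):
        raise ValueError(f"landmark ({start},{end}) outside consensus")
    return any(s <= start and end <= e for s, e in coverage.covered)


def landmark_fraction(coverage: ConsensusCoverage, landmark: tuple) -> float:
    """Fraction of the landmark covered (reported alongside strict presence)."""
    start, end = landmark
    covered = sum(max(0, min(e, end) - max(s, start)) for s, e in coverage.covered)
    return covered / (end - start)


def landmark_likelihood_map(coverages: Mapping[str, ConsensusCoverage],
                            landmarks: Mapping[str, tuple],
                            calls: pd.DataFrame) -> pd.DataFrame:
    """Per pathway category, the fraction of TEs carrying each landmark.

    ``calls`` is a categorize_genome table restricted to the family of
    interest; TEs without a coverage record count as landmark-absent.
    Categories with no TEs yield NaN cells.
    """
    cats = sorted(calls["category"].unique())
    out = pd.DataFrame(index=cats, columns=list(landmarks), dtype=float)
    for cat in cats:
        ids = calls.index[calls["category"] == cat]
        if len(ids) == 0:
            continue
        for name, interval in landmarks.items():
            present = sum(
                1 for tid in ids
                if tid in coverages and landmark_presence(coverages[tid], interval))
            out.loc[cat, name] = present / len(ids)
    return out


class PeptideFragment(NamedTuple):
    """A maximal stop-free peptide from one reading frame.

    ``frame`` is +1/+2/+3 (forward) or -1/-2/-3 (reverse complement);
    ``nt_start``/``nt_end`` are 0-based half-open coordinates of the encoding
    codons on the forward strand of the input sequence.
    """

    frame: int
    nt_start: int
    nt_end: int
    peptide: str


def split_peptides(sequence: str, min_length: int = 1) -> list[PeptideFragment]:
    """All possible peptides: translate all six frames and split at stops.

    Codons containing N translate to X. Fragments shorter than ``min_length``
    residues are dropped.
    """
    seq = str(sequence).upper()
    n = len(seq)
    out: list[PeptideFragment] = []
    for strand in (+1, -1):
        s = seq if strand == 1 else str(Seq(seq).reverse_complement())
        for shift in range(3):
            usable = (n - shift) // 3 * 3
            if usable <= 0:
                continue
            aa = str(Seq(s[shift:shift + usable]).translate())
            frame = strand * (shift + 1)
            start_codon = 0
            for part in aa.split("*"):
                if len(part) >= min_length:
                    c0, c1 = start_codon, start_codon + len(part)
                    if strand == 1:
                        nt_start, nt_end = shift + 3 * c0, shift + 3 * c1
                    else:
                        nt_start = n - (shift + 3 * c1)
                        nt_end = n - (shift + 3 * c0)
                    out.append(PeptideFragment(frame, nt_start, nt_end, part))
                start_codon += len(part) + 1  # +1 skips the stop codon
    return out


def accept_domain_hit(covered_fraction: float,
                      config: Optional[PipelineConfig] = None) -> bool:
    """Keep a domain hit only if it covers >90 % of the reference HMM model."""
    config = config or PipelineConfig()
    if not 0.0 <= covered_fraction <= 1.0:
        raise ValueError("covered_fraction must be in [0, 1]")
    return covered_fraction > config.domain_min_coverage


def accept_ltr(ltr: tuple, te: tuple,
               config: Optional[PipelineConfig] = None) -> tuple[bool, Optional[str]]:
    """Accept an LTR only at a TE edge (within 50 bp of either end).

    Returns (accepted, side) with side LTR5/LTR3 assigned by the nearer end
    (None when discarded as internal).
    """
    config = config or PipelineConfig()
    (ls, le), (ts, te_end) = ltr, te
    if ls < ts or le > te_end:
        raise ValueError("LTR interval must lie within the TE span")
    d5 = ls - ts
    d3 = te_end - le
    if min(d5, d3) > config.ltr_edge_max_dist:
        return False, None
    return True, "LTR5" if d5 <= d3 else "LTR3"


@dataclass(frozen=True)
class DomainProfile:
    """Which essential retrotransposition domains one TE carries."""

    te_id: str
    domains: frozenset

    def __post_init__(self) -> None:
        bad = set(self.domains) - set(ESSENTIAL_DOMAINS)
        if bad:
            raise ValueError(f"{self.te_id}: unknown domain(s) {sorted(bad)}")

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def bucket(self) -> Optional[str]:
        for lo, hi in DOMAIN_BUCKETS:
            if lo <= self.n_domains <= hi:
                return f"{lo}" if lo == hi else f"{lo}-{hi}"
        return None  # zero domains: excluded from buckets


def profiles_from_hits(hits: pd.DataFrame,
                       config: Optional[PipelineConfig] = None,
                       ltr_table: Optional[pd.DataFrame] = None
                       ) -> dict[str, DomainProfile]:
    """Build domain profiles from an HMM hit table and optional LTR table.

    ``hits`` columns: te_id, domain, covered_fraction (of the domain model);
    only hits passing :func:`accept_domain_hit` count. ``ltr_table`` columns:
    te_id, ltr_start, ltr_end, te_start, te_end — accepted LTRs add
    LTR5/LTR3.
    """
    config = config or PipelineConfig()
    domains: dict[str, set] = {}
    for row in hits.itertuples(index=False):
        if row.domain not in ESSENTIAL_DOMAINS:
            raise ValueError(f"unknown domain {row.domain!r}")
        if accept_domain_hit(float(row.covered_fraction), config):
            domains.setdefault(row.te_id, set()).add(row.domain)
    if ltr_table is not None:
        for row in ltr_table.itertuples(index=False):
            ok, side = accept_ltr((row.ltr_start, row.ltr_end),
                                  (row.te_start, row.te_end), config)
            if ok:
                domains.setdefault(row.te_id, set()).add(side)
    return {tid: DomainProfile(tid, frozenset(doms))
            for tid, doms in domains.items()}


def domain_enrichment(profiles: Mapping[str, DomainProfile],
                      calls: pd.DataFrame,
                      domains: Sequence[str] = ESSENTIAL_DOMAINS) -> pd.DataFrame:
    """Observed/expected frequency of each domain per pathway category.

    expected = frequency of the domain over all TEs in ``calls``; observed =
    frequency within a category; cell = observed / expected (NaN when the
    domain is absent genome-wide). TEs without a profile have zero domains.
    """
    all_ids = list(calls.index)
    if not all_ids:
        raise ValueError("no TEs to analyse")

    def freq(ids, domain) -> float:
        return sum(1 for t in ids
                   if t in profiles and domain in profiles[t].domains) / len(ids)

    expected = {d: freq(all_ids, d) for d in domains}
    cats = sorted(calls["category"].unique())
    out = pd.DataFrame(index=cats, columns=list(domains), dtype=float)
    for cat in cats:
        ids = list(calls.index[calls["category"] == cat])
        for d in domains:
            out.loc[cat, d] = freq(ids, d) / expected[d] if expected[d] > 0 else np.nan
    return out


def size_category_table(calls: pd.DataFrame, te_lengths: Mapping[str, int],
                        edges: Sequence[int] = SIZE_BIN_EDGES,
                        alpha: float = 0.001
                        ) -> tuple[pd.DataFrame, Optional[Chi2Result],
                                   list[ProportionContrast]]:
    """Category x size-bin contingency table with a homogeneity test.

    Returns (counts, chi2 result, significant pairwise contrasts). When the
    table is degenerate (a single populated size bin or category) the test is
    skipped and (counts, None, []) returned.
    """
    labels = SIZE_BIN_LABELS if tuple(edges) == SIZE_BIN_EDGES else [
        f"bin{i}" for i in range(len(edges) + 1)]
    lengths = pd.Series({t: te_lengths[t] for t in calls.index})
    bins = pd.cut(lengths, [0, *edges, np.inf], labels=labels, right=True)
    counts = pd.crosstab(calls["category"], bins)
    populated = counts.loc[(counts.sum(axis=1) > 0), counts.sum(axis=0) > 0]
    if populated.shape[0] < 2 or populated.shape[1] < 2:
        import warnings
        warnings.warn("degenerate size/category table; homogeneity test skipped")
        return counts, None, []
    result = chi2_homogeneity(populated.to_numpy())
    contrasts = pairwise_proportions(populated.to_numpy(), alpha=alpha)
    return counts, result, contrasts


# ---------------------------------------------------------------------------
# mappability
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


class GenomeMappability:
    """Exact k-mer uniqueness of read-length windows over a genome.

    A window is unique when its sequence occurs exactly once in the genome
    counting both strands (the window itself contributes one occurrence).
    Suited to compact genomes; the index is a plain hash of every k-mer.
    """

    def __init__(self, genome: Mapping[str, str], read_length: int = 150):
        self.k = read_length
        self.genome = {c: str(s).upper() for c, s in genome.items()}
        counts: dict[str, int] = {}
        for seq in self.genome.values():
            for i in range(len(seq) - self.k + 1):
                kmer = seq[i:i + self.k]
                counts[kmer] = counts.get(kmer, 0) + 1
        self._counts = counts

    def occurrences(self, window: str) -> int:
        return (self._counts.get(window, 0)
                + self._counts.get(_revcomp(window), 0))

    def te_mappability(self, te: Feature) -> tuple[float, str]:
        """Fraction of read-length windows over the TE that map uniquely.

        Windows start at every position within the TE; a TE shorter than the
        read length instead uses every window overlapping it. Windows running
        past the chromosome end are skipped. Returns (fraction, class) with
        class perfect (fraction 1), non (0) or semi.
        """
        seq = self.genome[te.chrom]
        if te.length >= self.k:
            starts = range(te.start, min(te.end, len(seq) - self.k + 1))
        else:
            starts = range(max(0, te.start - self.k + 1),
                           min(te.end, len(seq) - self.k + 1))
        total = unique = 0
        for s in starts:
            total += 1
            if self.occurrences(seq[s:s + self.k]) == 1:
                unique += 1
        if total == 0:
            return 0.0, "non"
        frac = unique / total
        cls = "perfect" if frac == 1.0 else ("non" if frac == 0.0 else "semi")
        return frac, cls


def mappability_summary(genome: Mapping[str, str], tes: Sequence[Feature],
                        read_length: int = 150) -> pd.DataFrame:
    """Per-TE mappability fractions and classes plus implicit genome summary."""
    idx = GenomeMappability(genome, read_length)
    rows = [(te.id, *idx.te_mappability(te)) for te in tes]
    return pd.DataFrame(rows, columns=["te_id", "fraction", "class"]
                        ).set_index("te_id")
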