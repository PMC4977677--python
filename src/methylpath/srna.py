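"""Small-RNA quantification and degradome (PARE) cleavage analysis.

Raw per-size read counts are normalized to reads per million genome-matched
18-28 nt reads (RPM) and per kilobase of region (RPKM). Cleavage sites are
kept at p < 0.05; comparing libraries with and without functional RDR6
separates primary-small-RNA cleavage from RDR6-dependent secondary events,
and comparing contexts (TE-silent vs TE-active) classifies site retention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import PipelineConfig

DEPENDENCY_LABELS = ("PRIMARY_ONLY", "SECONDARY_INVOLVED", "UNCLEAVED")
RETENTION_LABELS = ("RETAINED_AND_GAINED", "NOT_RETAINED_DISTINCT",
                    "SILENT_ONLY", "ACTIVE_ONLY", "NONE")


@dataclass(frozen=True)
class SizeProfile:
    """Per-size-class small-RNA abundance of one feature in one library."""

    feature_id: str
    library_id: str
    counts: dict            # size (nt) -> raw count
    library_total: int      # genome-matched 18-28 nt reads in the library
    region_length: int      # bp

    def __post_init__(self) -> None:
        if self.library_total <= 0:
            raise ValueError("library_total must be positive")
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative read count")

    @property
    def rpm(self) -> dict:
        return {s: c / self.library_total * 1e6 for s, c in self.counts.items()}

    @property
    def rpkm(self) -> dict:
        kb = self.region_length / 1000
        return {s: v / kb for s, v in self.rpm.items()}

    def rpm_in(self, sizes: Iterable[int]) -> float:
        rpm = self.rpm
        return sum(rpm.get(s, 0.0) for s in sizes)


def normalize_profile(raw_counts: Mapping[int, int], library_total: int,
                      region_length: int, feature_id: str = "",
                      library_id: str = "") -> SizeProfile:
    """Wrap raw per-size counts with their RPM/RPKM normalization."""
    return SizeProfile(feature_id=feature_id, library_id=library_id,
                       counts=dict(raw_counts), library_total=library_total,
                       region_length=region_length)


@dataclass(frozen=True)
class CleavageRecord:
    """One PARE cleavage site on a TE mRNA."""

    feature_id: str
    site: int
    p_value: float
    library_id: str
    background: str        # "silent" | "active"
    rdr6_functional: bool  # does the library's genotype carry functional RDR6

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")


def filter_sites(records: Sequence[CleavageRecord],
                 alpha: float = 0.05) -> list[CleavageRecord]:
    """Keep only sites with p strictly below alpha."""
    return [r for r in records if r.p_value < alpha]


def cleavage_dependency(records: Sequence[CleavageRecord], background: str,
                        config: Optional[PipelineConfig] = None
                        ) -> tuple[str, dict]:
    """Classify one TE's cleavage as primary-only vs RDR6-dependent.

    Sites observed in an rdr6-mutant library are primary (no RDR6 needed);
    sites seen only when RDR6 is functional are RDR6-dependent secondary
    events. The TE is SECONDARY_INVOLVED if any RDR6-dependent site exists,
    PRIMARY_ONLY if cleaved at primary sites only, UNCLEAVED with no
    surviving site. Requires records (possibly empty per library, but the
    library classes must both exist) from an RDR6-functional and an
    rdr6-mutant library of the background.

    Returns (label, {"primary": sites, "rdr6_dependent": sites}).
    """
    config = config or PipelineConfig()
    recs = [r for r in records if r.background == background]
    libs_functional = {r.library_id for r in recs if r.rdr6_functional}
    libs_mutant = {r.library_id for r in recs if not r.rdr6_functional}
    if not libs_functional or not libs_mutant:
        raise ValueError(
            f"need sites from both an RDR6-functional and an rdr6-mutant "
            f"library for background {background!r} (use sentinel records "
            f"with p_value 1 for site-free libraries)")
    kept = filter_sites(recs, config.cleavage_alpha)
    sites_functional = {r.site for r in kept if r.rdr6_functional}
    sites_mutant = {r.site for r in kept if not r.rdr6_functional}
    primary = sites_mutant
    dependent = sites_functional - sites_mutant
    if not sites_functional and not sites_mutant:
        return "UNCLEAVED", {"primary": set(), "rdr6_dependent": set()}
    label = "SECONDARY_INVOLVED" if dependent else "PRIMARY_ONLY"
    return label, {"primary": primary, "rdr6_dependent": dependent}


def site_retention(silent_sites: Iterable[int], active_sites: Iterable[int],
                   tolerance: int = 0) -> tuple[str, tuple]:
    """Compare one TE's cleavage sites between the silent and active contexts.

    A silent site is retained when an active site lies within ``tolerance``
    bp. Categories when both contexts are cleaved: RETAINED_AND_GAINED if any
    silent site is retained (same sites persist, possibly with new ones),
    NOT_RETAINED_DISTINCT if the active sites are entirely different ones.
    Otherwise SILENT_ONLY, ACTIVE_ONLY or NONE. Also returns the site-count
    transition (n_silent, n_active).

    With tolerance 0 "retained" means the exact coordinate reappears.
    """
    s = sorted(set(silent_sites))
    a = sorted(set(active_sites))
    transition = (len(s), len(a))
    if not s and not a:
        return "NONE", transition
    if s and not a:
        return "SILENT_ONLY", transition
    if a and not s:
        return "ACTIVE_ONLY", transition

    def matched(site: int, others: Sequence[int]) -> bool:
        i = int(np.searchsorted(others, site))
        for j in (i - 1, i):
            if 0 <= j < len(others) and abs(others[j] - site) <= tolerance:
                return True
        return False

    if any(matched(x, a) for x in s):
        return "RETAINED_AND_GAINED", transition
    return "NOT_RETAINED_DISTINCT", transition


@dataclass(frozen=True)
class CompetenceCall:
    """Whether a TE shows any sign of being transcribable when derepressed."""

    feature_id: str
    competent: bool
    evidence: frozenset  # subset of {"rnaseq", "sirna2122", "cleavage"}

    def __post_init__(self) -> None:
        if self.competent != bool(self.evidence):
            raise ValueError("competent must mirror non-empty evidence")


def competence(feature_id: str, rnaseq_rpm: float, sirna_2122_rpm: float,
               cleavage_evidence: bool,
               config: Optional[PipelineConfig] = None) -> CompetenceCall:
    """Transcriptional-competence call for one TE.

    Evidence: >=1 uniquely matching RPM in derepressed (ddm1) RNA-seq, >=10
    RPM of 21-22 nt siRNAs in ddm1, or any surviving mRNA cleavage site.
    """
    config = config or PipelineConfig()
    if rnaseq_rpm < 0 or sirna_2122_rpm < 0:
        raise ValueError("RPM values must be non-negative")
    evidence = set()
    if rnaseq_rpm >= config.competence_rna_rpm:
        evidence.add("rnaseq")
    if sirna_2122_rpm >= config.competence_sirna_rpm:
        evidence.add("sirna2122")
    if cleavage_evidence:
        evidence.add("cleavage")
    return CompetenceCall(feature_id=feature_id, competent=bool(evidence),
                          evidence=frozenset(evidence))


# ---------------------------------------------------------------------------
# table-level helpers
# ---------------------------------------------------------------------------

def read_srna_counts(path) -> pd.DataFrame:
    """Read a long-format sRNA count table: feature_id, library_id, size, count."""
    df = pd.read_csv(path, sep="\t")
    required = {"feature_id", "library_id", "size", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_pare_table(path) -> list[CleavageRecord]:
    """Read a PARE site table: feature_id, site, p_value, library_id,
    background, rdr6_functional."""
    df = pd.read_csv(path, sep="\t")
    return [CleavageRecord(feature_id=r.feature_id, site=int(r.site),
                           p_value=float(r.p_value), library_id=r.library_id,
                           background=r.background,
                           rdr6_functional=bool(r.rdr6_functional))
            for r in df.itertuples(index=False)]


def profiles_from_table(counts: pd.DataFrame, library_totals: Mapping[str, int],
                        region_lengths: Mapping[str, int]) -> list[SizeProfile]:
    """Build per-(feature, library) SizeProfiles from a long count table."""
    out = []
    for (fid, lib), grp in counts.groupby(["feature_id", "library_id"], sort=True):
        out.append(SizeProfile(
            feature_id=fid, library_id=lib,
            counts=dict(zip(grp["size"].astype(int), grp["count"].astype(int))),
            library_total=int(library_totals[lib]),
            region_length=int(region_lengths[fid])))
    return out


def dependency_table(records: Sequence[CleavageRecord], background: str,
                     feature_ids: Sequence[str],
                     config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """cleavage_dependency over many TEs.

    TEs with no record at all are UNCLEAVED (the library pair is assumed
    assayed genome-wide).
    """
    config = config or PipelineConfig()
    by_feature: dict[str, list[CleavageRecord]] = {}
    libs = [r for r in records if r.background == background]
    has_functional = any(r.rdr6_functional for r in libs)
    has_mutant = any(not r.rdr6_functional for r in libs)
    if not (has_functional and has_mutant):
        raise ValueError(f"background {background!r}: need both an "
                         "RDR6-functional and an rdr6-mutant library")
    sentinel_libs = [next(r for r in libs if r.rdr6_functional).library_id,
                     next(r for r in libs if not r.rdr6_functional).library_id]
    for r in libs:
        by_feature.setdefault(r.feature_id, []).append(r)
    rows = []
    for fid in feature_ids:
        recs = by_feature.get(fid, [])
        if not recs:
            rows.append((fid, "UNCLEAVED", 0, 0))
            continue
        # pad so both library classes exist for the per-TE call
        recs = recs + [
            CleavageRecord(fid, -1, 1.0, sentinel_libs[0], background, True),
            CleavageRecord(fid, -1, 1.0, sentinel_libs[1], background, False)]
        label, sites = cleavage_dependency(recs, background, config)
        rows.append((fid, label, len(sites["primary"]),
                     len(sites["rdr6_dependent"])))
    return pd.DataFrame(rows, columns=["feature_id", "dependency", "n_primary",
                                       "n_rdr6_dependent"]).set_index("feature_id")


def secondary_fraction(profiles: Sequence[SizeProfile],
                       dependency: Mapping[str, str],
                       config: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Mean RPM per size class for cleaved vs uncleaved TEs, per library.

    Rows are (library_id, group) with group CLEAVED (PRIMARY_ONLY or
    SECONDARY_INVOLVED) or UNCLEAVED; columns are size classes 18-28 nt plus
    the share of 21-22 nt RPM in the 18-28 nt total.
    """
    config = config or PipelineConfig()
    sizes = list(range(config.sirna_size_min, config.sirna_size_max + 1))
    if not profiles:
        return pd.DataFrame(columns=[*sizes, "share_21_22"])
    rows = []
    for p in profiles:
        group = "UNCLEAVED" if dependency.get(p.feature_id, "UNCLEAVED") == \
            "UNCLEAVED" else "CLEAVED"
        rpm = p.rpm
        rows.append((p.library_id, group, *[rpm.get(s, 0.0) for s in sizes]))
    df = pd.DataFrame(rows, columns=["library_id", "group", *sizes])
    means = df.groupby(["library_id", "group"]).mean()
    total = means[sizes].sum(axis=1)
    sec = means[list(config.secondary_sizes)].sum(axis=1)
    means["share_21_22"] = np.where(total > 0, sec / total, np.nan)
    return means
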