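"""Weighted methylation levels per feature/genotype/context, differential
methylation site (DMS) calling and DMS merging into regions (DMRs).

The weighted methylation level of a feature is the coverage-weighted average

    level = sum(n_meth) / sum(n_total)

over all covered cytosines of one context inside the feature, which weights
each cytosine by its read depth rather than averaging per-site fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .io import CONTEXTS, Feature, PipelineConfig
from .stats import bh_adjust


@dataclass(frozen=True)
class MethylationLevel:
    """Weighted methylation of one feature in one genotype and context.

    ``level`` is None when no cytosine of the context is covered
    (n_cytosines == 0); a covered but fully unmethylated feature has
    level 0.0, which is a different statement.
    """

    feature_id: str
    genotype_role: str
    context: str
    level: Optional[float]
    n_cytosines: int
    n_reads: int

    def __post_init__(self) -> None:
        if (self.level is None) != (self.n_cytosines == 0):
            raise ValueError("level must be defined iff n_cytosines >= 1")
        if self.level is not None and not (0.0 <= self.level <= 1.0):
            raise ValueError(f"level {self.level} outside [0, 1]")


@dataclass(frozen=True)
class DMS:
    """A differentially methylated site between two genotypes.

    ``pos`` is 0-based. ``direction`` is hyper/hypo in the second genotype
    relative to the first.
    """

    chrom: str
    pos: int
    context: str
    p_value: float
    direction: str  # "hyper" | "hypo"


@dataclass(frozen=True)
class DMRegion:
    """A differentially methylated region spanning its member DMSs
    (0-based half-open, end = last DMS position + 1)."""

    chrom: str
    start: int
    end: int
    n_dms: int


def weighted_level(calls: pd.DataFrame, context: Optional[str] = None,
                   feature_id: str = "", genotype_role: str = "") -> MethylationLevel:
    """Weighted methylation level of one feature from its overlapping calls.

    Only calls of the requested context with n_total > 0 contribute. With no
    such call the level is undefined (None), never coerced to 0.
    """
    df = calls
    if context is not None:
        df = df[df["context"] == context]
    df = df[df["n_total"] > 0]
    n_cyt = int(len(df))
    n_reads = int(df["n_total"].sum())
    level = float(df["n_meth"].sum() / n_reads) if n_cyt else None
    return MethylationLevel(feature_id=feature_id, genotype_role=genotype_role,
                            context=context or "all", level=level,
                            n_cytosines=n_cyt, n_reads=n_reads)


def calls_in_span(calls: pd.DataFrame, chrom: str, start: int, end: int) -> pd.DataFrame:
    """Calls whose cytosine lies in [start, end) on chrom (any strand).

    ``calls`` must be sorted by (chrom, pos); positions are 1-based so the
    0-based cytosine coordinate is pos - 1.
    """
    sub = calls[calls["chrom"] == chrom]
    pos = sub["pos"].to_numpy()
    lo = np.searchsorted(pos, start + 1, side="left")
    hi = np.searchsorted(pos, end, side="right")
    return sub.iloc[lo:hi]


class _ChromIndex:
    """Per-chromosome cumulative sums for O(log n) feature-level queries."""

    def __init__(self, calls: pd.DataFrame, context: str):
        sub = calls[(calls["context"] == context) & (calls["n_total"] > 0)]
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in sub.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy(dtype=np.int64)
            order = np.argsort(pos, kind="mergesort")
            pos = pos[order]
            cmeth = np.concatenate([[0], np.cumsum(grp["n_meth"].to_numpy()[order])])
            ctot = np.concatenate([[0], np.cumsum(grp["n_total"].to_numpy()[order])])
            self.by_chrom[chrom] = (pos, cmeth, ctot)

    def query(self, chrom: str, start: int, end: int) -> tuple[int, int, int]:
        """(n_cytosines, sum n_meth, sum n_total) over [start, end)."""
        if chrom not in self.by_chrom:
            return 0, 0, 0
        pos, cmeth, ctot = self.by_chrom[chrom]
        lo = int(np.searchsorted(pos, start + 1, side="left"))
        hi = int(np.searchsorted(pos, end, side="right"))
        return hi - lo, int(cmeth[hi] - cmeth[lo]), int(ctot[hi] - ctot[lo])


def feature_levels(calls: pd.DataFrame, features: Sequence[Feature],
                   context: str, genotype_role: str = "") -> pd.DataFrame:
    """Weighted levels of many features from one genotype's call table.

    Returns a DataFrame indexed by feature id with columns level (NaN when
    uncovered), n_cytosines and n_reads.
    """
    index = _ChromIndex(calls, context)
    rows = []
    for f in features:
        n_cyt, meth, tot = index.query(f.chrom, f.start, f.end)
        rows.append((f.id, meth / tot if n_cyt else np.nan, n_cyt, tot))
    out = pd.DataFrame(rows, columns=["feature_id", "level", "n_cytosines", "n_reads"])
    return out.set_index("feature_id")


@dataclass
class MethylationMatrix:
    """Feature x genotype-role methylation levels for one context."""

    context: str
    levels: pd.DataFrame        # feature x role, NaN = undefined
    n_cytosines: pd.DataFrame   # feature x role
    covered_all: pd.Series      # bool per feature (over the given roles)

    @property
    def feature_ids(self) -> pd.Index:
        return self.levels.index

    def to_tsv(self, path) -> None:
        out = self.levels.copy()
        out["covered_all"] = self.covered_all
        out.to_csv(path, sep="\t", na_rep="NA")


def build_matrix(tables: dict[str, pd.DataFrame], features: Sequence[Feature],
                 context: str, config: PipelineConfig | None = None) -> MethylationMatrix:
    """Per-feature weighted levels across genotype roles.

    ``tables`` maps role name -> cytosine call table. A feature counts as
    covered_all when it has at least ``config.min_covered_cytosines`` covered
    cytosines of the context in every role.
    """
    config = config or PipelineConfig()
    levels, ncyt = {}, {}
    for role, calls in tables.items():
        per = feature_levels(calls, features, context, genotype_role=role)
        levels[role] = per["level"]
        ncyt[role] = per["n_cytosines"]
    idx = pd.Index([f.id for f in features], name="feature_id")
    lv = pd.DataFrame(levels, index=idx)
    nc = pd.DataFrame(ncyt, index=idx).fillna(0).astype(int)
    covered = (nc >= config.min_covered_cytosines).all(axis=1) if len(tables) else \
        pd.Series(False, index=idx)
    return MethylationMatrix(context=context, levels=lv, n_cytosines=nc,
                             covered_all=covered)


@lru_cache(maxsize=1_000_000)
def _fisher_p(ma: int, ua: int, mb: int, ub: int) -> float:
    return float(fisher_exact([[ma, ua], [mb, ub]], alternative="two-sided")[1])


def call_dms(calls_a: pd.DataFrame, calls_b: pd.DataFrame,
             alpha: float = 0.01, context: Optional[str] = None) -> list[DMS]:
    """Differentially methylated sites between two genotypes.

    At every position covered in both genotypes a two-sided Fisher exact test
    compares (n_meth, n_total - n_meth); p-values are Benjamini-Hochberg
    adjusted and sites with adjusted p < alpha are returned with their
    direction in the second genotype relative to the first.
    """
    for name, df in (("calls_a", calls_a), ("calls_b", calls_b)):
        key = df[["chrom", "pos"]]
        if not key.equals(key.sort_values(["chrom", "pos"], kind="mergesort")):
            raise ValueError(f"{name} is not sorted by (chrom, pos)")
    a, b = calls_a, calls_b
    if context is not None:
        a = a[a["context"] == context]
        b = b[b["context"] == context]
    merged = a.merge(b, on=["chrom", "pos", "strand", "context"],
                     suffixes=("_a", "_b"))
    merged = merged[(merged["n_total_a"] > 0) & (merged["n_total_b"] > 0)]
    if merged.empty:
        return []
    ma = merged["n_meth_a"].to_numpy()
    ta = merged["n_total_a"].to_numpy()
    mb = merged["n_meth_b"].to_numpy()
    tb = merged["n_total_b"].to_numpy()
    pvals = np.fromiter(
        (_fisher_p(int(x), int(u - x), int(y), int(v - y))
         for x, u, y, v in zip(ma, ta, mb, tb)),
        dtype=float, count=len(merged))
    padj = bh_adjust(np.clip(pvals, np.nextafter(0, 1), 1.0))
    keep = padj < alpha
    frac_a = ma / ta
    frac_b = mb / tb
    out = [
        DMS(chrom=row.chrom, pos=int(row.pos) - 1, context=row.context,
            p_value=float(p), direction="hyper" if fb > fa else "hypo")
        for row, p, fa, fb, k in zip(merged.itertuples(index=False), padj,
                                     frac_a, frac_b, keep) if k
    ]
    out.sort(key=lambda d: (d.chrom, d.pos))
    return out


def merge_dms(dms: Sequence[DMS], max_gap: int = 250, min_dms: int = 4) -> list[DMRegion]:
    """Chain DMSs into DMRs by single linkage.

    Consecutive DMSs on the same chromosome at most ``max_gap`` bp apart join
    one cluster; clusters with at least ``min_dms`` members are reported as
    regions spanning the first to last member site. Duplicate positions are
    collapsed first so the result is invariant to repeated input sites.
    """
    seen = sorted({(d.chrom, d.pos) for d in dms})
    regions: list[DMRegion] = []
    cluster: list[tuple[str, int]] = []

    def flush() -> None:
        if len(cluster) >= min_dms:
            regions.append(DMRegion(chrom=cluster[0][0], start=cluster[0][1],
                                    end=cluster[-1][1] + 1, n_dms=len(cluster)))

    for site in seen:
        if cluster and (site[0] != cluster[-1][0]
                        or site[1] - cluster[-1][1] > max_gap):
            flush()
            cluster = []
        cluster.append(site)
    flush()
    return regions


def dmrs_to_features(regions: Sequence[DMRegion]) -> list[Feature]:
    """Represent DMRs as features (for meta-plots and level calculations)."""
    return [Feature(id=f"DMR_{r.chrom}_{r.start}", chrom=r.chrom, start=r.start,
                    end=r.end, strand=".", kind="DMR") for r in regions]


def write_dmrs_bed(regions: Sequence[DMRegion], path) -> None:
    """BED6 plus an n_dms column."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tDMR_{r.chrom}_{r.start}"
                     f"\t0\t.\t{r.n_dms}\n")
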