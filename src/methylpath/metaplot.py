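"""Anchored, binned average methylation profiles (meta-plots).

Each element contributes per-bin weighted methylation levels in fixed-width
windows (default 100 bp) over its body and flanking regions (default 2 kb);
the profile is the unweighted mean across elements per bin with a 95 %
normal-approximation confidence band.

Offset conventions (biological orientation, minus-strand elements flipped):

* ``five_prime`` anchor: offset 0 is the first body base; negative offsets
  are the upstream flank; body bins run to min(length, body cap).
* ``three_prime`` anchor: offset 0 is the first base downstream of the body;
  negative offsets walk back into the body.
* ``dmr_edge``: the left genomic edge, no strand flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import Feature
from .methylome import DMRegion
from .stats import mean_ci95

ANCHORS = ("five_prime", "three_prime", "dmr_edge")


@dataclass
class MetaProfile:
    anchor: str
    bin: int
    flank: int
    table: pd.DataFrame  # columns: offset, mean, ci_low, ci_high, n_elements

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "anchor", self.anchor)
        out.to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, label: Optional[str] = None, color=None):
        """Line with a translucent confidence ribbon."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        ax.plot(t["offset"], t["mean"], label=label, color=color)
        ax.fill_between(t["offset"], t["ci_low"], t["ci_high"], alpha=0.25,
                        color=color, linewidth=0)
        ax.set_xlabel(f"distance from {self.anchor.replace('_', ' ')} (bp)")
        ax.set_ylabel("methylation level")
        return ax


def feature_bins(feature: Feature, calls: pd.DataFrame, bin: int = 100,
                 flank: int = 2000, anchor: str = "five_prime",
                 context: Optional[str] = "CHH",
                 body_cap: int = 3000) -> pd.Series:
    """Per-bin weighted methylation levels for one element.

    Returns a Series indexed by bin-start offset (bp); bins with no covered
    cytosine are NaN. Minus-strand features are flipped so offsets follow the
    biological 5'->3' direction of the annotation.
    """
    if anchor not in ANCHORS:
        raise ValueError(f"anchor must be one of {ANCHORS}")
    length = feature.length
    body_extent = min(length, body_cap)

    sub = calls[calls["chrom"] == feature.chrom]
    if context is not None:
        sub = sub[sub["context"] == context]
    sub = sub[sub["n_total"] > 0]
    pos0 = sub["pos"].to_numpy(dtype=np.int64) - 1  # 0-based cytosine coords

    flip = feature.strand == "-" and anchor != "dmr_edge"
    if flip:
        b = (feature.end - 1) - pos0
    else:
        b = pos0 - feature.start

    if anchor == "three_prime":
        off = b - length
        lo = -int(np.ceil(body_extent / bin)) * bin
        hi = flank
    else:  # five_prime or dmr_edge
        off = b
        lo = -flank
        hi = body_extent
    keep = (off >= lo) & (off < hi)
    # body cap: an element never contributes past its own length
    if anchor == "three_prime":
        keep &= off >= -body_extent
    off = off[keep]
    meth = sub["n_meth"].to_numpy()[keep]
    tot = sub["n_total"].to_numpy()[keep]

    starts = np.arange(lo, hi, bin)
    idx = (off - lo) // bin
    sums_m = np.bincount(idx, weights=meth, minlength=len(starts))
    sums_t = np.bincount(idx, weights=tot, minlength=len(starts))
    with np.errstate(invalid="ignore", divide="ignore"):
        levels = np.where(sums_t > 0, sums_m / np.maximum(sums_t, 1), np.nan)
    return pd.Series(levels, index=pd.Index(starts, name="offset"))


def aggregate_profile(per_element: Sequence[pd.Series], anchor: str = "five_prime",
                      bin: int = 100, flank: int = 2000) -> MetaProfile:
    """Combine per-element bin series into a mean profile with 95 % CI.

    Per offset, the mean is the unweighted average over elements with a
    defined value there, and the band is mean +/- 1.96 sd/sqrt(n). Offsets
    with no contributing element are dropped.
    """
    if not per_element:
        raise ValueError("aggregate_profile needs at least one element")
    wide = pd.concat(list(per_element), axis=1)
    rows = []
    for offset in sorted(wide.index):
        vals = wide.loc[offset].to_numpy(dtype=float)
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            continue
        mean, lo, hi = mean_ci95(vals)
        rows.append((offset, mean, lo, hi, vals.size))
    table = pd.DataFrame(rows, columns=["offset", "mean", "ci_low", "ci_high",
                                        "n_elements"])
    return MetaProfile(anchor=anchor, bin=bin, flank=flank, table=table)


def profile_features(features: Sequence[Feature], calls: pd.DataFrame,
                     bin: int = 100, flank: int = 2000,
                     anchor: str = "five_prime", context: Optional[str] = "CHH",
                     body_cap: int = 3000) -> MetaProfile:
    """Meta-plot over a feature set (convenience wrapper)."""
    per = [feature_bins(f, calls, bin=bin, flank=flank, anchor=anchor,
                        context=context, body_cap=body_cap) for f in features]
    return aggregate_profile(per, anchor=anchor, bin=bin, flank=flank)


def dmr_profile(dmrs: Sequence[DMRegion], calls: pd.DataFrame, bin: int = 100,
                flank: int = 2000, context: Optional[str] = "CHH",
                body_cap: int = 3000, min_length: int = 0) -> MetaProfile:
    """Meta-plot over DMRs anchored at their single (left) edge, no strand flip.

    ``min_length`` optionally restricts to DMRs longer than that many bp
    before profiling.
    """
    kept = [r for r in dmrs if (r.end - r.start) > min_length]
    if not kept:
        raise ValueError("no DMRs to profile (after length filter)")
    feats = [Feature(id=f"DMR_{r.chrom}_{r.start}", chrom=r.chrom, start=r.start,
                     end=r.end, strand=".", kind="DMR") for r in kept]
    per = [feature_bins(f, calls, bin=bin, flank=flank, anchor="dmr_edge",
                        context=context, body_cap=body_cap) for f in feats]
    return aggregate_profile(per, anchor="dmr_edge", bin=bin, flank=flank)
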