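"""Assign each transposable element to a CHH methylation pathway.

Six categories describe who makes the small RNAs (or whether any are needed)
that keep CHH methylation on a TE:

* ``NO_CHH`` — under 1 % CHH methylation in the background reference, nothing
  to classify.
* ``POLIV_RDDM`` — canonical RdDM: methylation collapses (>2-fold loss) in
  Pol IV and Pol V mutants but not in rdr6, and the pol IV rdr6 double mutant
  loses nothing beyond pol IV alone.
* ``RDR6_RDDM`` — expression-dependent RdDM: loss in rdr6 and Pol V but not
  pol IV, and the double mutant adds nothing beyond rdr6.
* ``DCL3_RDDM`` — DCL3-dependent, Pol IV/RDR6-independent RdDM: loss in dcl3
  and Pol V only.
* ``COREGULATED`` — loss appears only when Pol IV and RDR6 are removed
  together (redundant targeting).
* ``MAINTENANCE`` — methylated but RdDM-independent (no Pol V loss, or no
  pathway rule fits).

In the TE-silent background every mutant is compared to wt Col; in the
TE-active background the ddm1 double mutants are compared to ddm1 itself.
Rules are evaluated in the fixed order above; the first match wins, and
``rule_trace`` records every comparison so any overlap is auditable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CLASSIFIER_ROLES, PipelineConfig
from .methylome import MethylationMatrix

CATEGORIES = ("UNCOVERED", "NO_CHH", "POLIV_RDDM", "RDR6_RDDM", "DCL3_RDDM",
              "COREGULATED", "MAINTENANCE")

#: categories that imply small-RNA-directed methylation (all require Pol V)
RDDM_CATEGORIES = ("POLIV_RDDM", "RDR6_RDDM", "DCL3_RDDM", "COREGULATED")


@dataclass(frozen=True)
class RdDMCall:
    feature_id: str
    background: str  # "silent" | "active"
    category: str
    levels: dict = field(default_factory=dict)
    rule_trace: tuple = ()

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def lost_twofold(ref_level: float, mut_level: float, threshold: float = 2.0) -> bool:
    """True iff the mutant lost more than ``threshold``-fold methylation.

    Strict: exactly threshold-fold does not qualify. A zero reference has
    nothing to lose and returns False; a zero mutant level under a positive
    reference always qualifies.
    """
    for name, v in (("ref_level", ref_level), ("mut_level", mut_level)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"{name} is undefined; gate on coverage before calling")
    return ref_level > 0 and mut_level < ref_level / threshold


def classify(levels: Mapping[str, float], background: str = "silent",
             config: Optional[PipelineConfig] = None,
             feature_id: str = "") -> RdDMCall:
    """Classify one TE from its per-role CHH levels.

    ``levels`` must define the six canonical roles ref, polIV, rdr6, dcl3,
    polV and polIV_rdr6 (in the active background these come from ddm1 and
    its double mutants). Extra roles are carried along but ignored.
    """
    config = config or PipelineConfig()
    for role in CLASSIFIER_ROLES:
        v = levels.get(role)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing or undefined level for role {role!r}")
    thr = config.fold_loss_threshold
    trace: list[str] = []

    def lost(a: str, b: str) -> bool:
        v = lost_twofold(levels[a], levels[b], thr)
        trace.append(f"lost({a}->{b})={v}")
        return v

    ref = levels["ref"]
    trace.append(f"ref={ref:.4g}<{config.no_chh_threshold}"
                 f"={ref < config.no_chh_threshold}")
    category = None
    if ref < config.no_chh_threshold:
        category = "NO_CHH"
    else:
        pol4 = lost("ref", "polIV")
        rdr6 = lost("ref", "rdr6")
        dcl3 = lost("ref", "dcl3")
        pol5 = lost("ref", "polV")
        double_vs_ref = lost("ref", "polIV_rdr6")
        if pol4 and pol5 and not rdr6 and not lost("polIV", "polIV_rdr6"):
            category = "POLIV_RDDM"
        elif rdr6 and pol5 and not pol4 and not lost("rdr6", "polIV_rdr6"):
            category = "RDR6_RDDM"
        elif dcl3 and pol5 and not pol4 and not rdr6 and not double_vs_ref:
            category = "DCL3_RDDM"
        elif double_vs_ref:
            category = "COREGULATED"
        else:
            category = "MAINTENANCE"
    return RdDMCall(feature_id=feature_id, background=background,
                    category=category, levels=dict(levels),
                    rule_trace=tuple(trace))


def categorize_genome(matrix: MethylationMatrix, background: str = "silent",
                      config: Optional[PipelineConfig] = None,
                      role_map: Optional[Mapping[str, str]] = None
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Classify every feature of a methylation matrix.

    ``role_map`` maps canonical classifier roles to the matrix's column names
    (defaults to identity for the six canonical names; use e.g.
    {"ref": "wt", ...} when columns carry manifest role names). Features not
    covered in every role are UNCOVERED.

    Returns (calls table, per-category counts). The calls table is indexed by
    feature id with columns background, category, the six role levels and a
    semicolon-joined rule trace, sorted by category then descending reference
    level (the heat-map row order).
    """
    config = config or PipelineConfig()
    role_map = dict(role_map or {r: r for r in CLASSIFIER_ROLES})
    missing_cols = [c for c in role_map.values() if c not in matrix.levels.columns]
    if missing_cols:
        raise ValueError(f"matrix lacks role column(s): {missing_cols}")
    rows = []
    for fid in matrix.feature_ids:
        if not bool(matrix.covered_all.loc[fid]):
            rows.append((fid, background, "UNCOVERED",
                         *[np.nan] * len(CLASSIFIER_ROLES), ""))
            continue
        levels = {canon: float(matrix.levels.loc[fid, col])
                  for canon, col in role_map.items()}
        call = classify(levels, background=background, config=config,
                        feature_id=fid)
        rows.append((fid, background, call.category,
                     *[levels.get(r, np.nan) for r in CLASSIFIER_ROLES],
                     ";".join(call.rule_trace)))
    calls = pd.DataFrame(
        rows, columns=["feature_id", "background", "category",
                       *CLASSIFIER_ROLES, "rule_trace"]).set_index("feature_id")
    order = {c: i for i, c in enumerate(CATEGORIES)}
    calls = calls.sort_values(
        ["category", "ref"],
        key=lambda s: s.map(order) if s.name == "category" else -s,
        kind="mergesort")
    counts = calls["category"].value_counts().reindex(CATEGORIES, fill_value=0)
    counts.name = "n_te"
    return calls, counts


def category_shift(calls_silent: pd.DataFrame, calls_active: pd.DataFrame,
                   feature_ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Transition matrix of categories between the silent and active contexts.

    Both call tables must cover the same feature universe; ``feature_ids``
    optionally restricts to a subset (e.g. one TE family). Rows are silent
    categories, columns active categories, cells TE counts.
    """
    s_ids, a_ids = set(calls_silent.index), set(calls_active.index)
    if s_ids != a_ids:
        only_s = sorted(s_ids - a_ids)[:5]
        only_a = sorted(a_ids - s_ids)[:5]
        raise ValueError(
            f"feature sets differ: silent-only {only_s}, active-only {only_a}")
    idx = pd.Index(sorted(s_ids))
    if feature_ids is not None:
        idx = idx.intersection(pd.Index(feature_ids))
    table = pd.crosstab(calls_silent.loc[idx, "category"],
                        calls_active.loc[idx, "category"],
                        rownames=["silent"], colnames=["active"])
    return table.reindex(index=CATEGORIES, columns=CATEGORIES, fill_value=0)
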