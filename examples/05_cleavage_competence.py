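"""Degradome analysis: which TE mRNA cleavage events need RDR6, and which
TEs are transcriptionally competent at all.

Sites surviving the p < 0.05 filter are compared between libraries with and
without functional RDR6: sites that vanish in the rdr6 mutant mark
RDR6-dependent secondary small-RNA amplification.
"""

from collections import Counter

from methylpath import SimulationParams, simulate
from methylpath.srna import CleavageRecord, competence, dependency_table

ds = simulate(SimulationParams(seed=4, n_te=60,
                               chrom_sizes={"chr1": 60_000, "chr2": 60_000}))
records = [CleavageRecord(r.feature_id, int(r.site), float(r.p_value),
                          r.library_id, r.background, bool(r.rdr6_functional))
           for r in ds.pare.itertuples(index=False)]
te_ids = [f.id for f in ds.tes]

dep = dependency_table(records, background="active", feature_ids=te_ids)
print("cleavage dependency (TE-active context):",
      dict(Counter(dep["dependency"])))
# SECONDARY_INVOLVED TEs lose at least one cleavage site when RDR6 is gone

rdr6_targets = set(ds.truth.loc[ds.truth["category_active"] == "RDR6_RDDM",
                                "te_id"])
secondary = set(dep.index[dep["dependency"] == "SECONDARY_INVOLVED"])
print(f"RDR6-RdDM targets with secondary cleavage: "
      f"{len(secondary & rdr6_targets)}/{len(rdr6_targets)}")

call = competence("demo", rnaseq_rpm=1.2, sirna_2122_rpm=0.0,
                  cleavage_evidence=False)
print(f"\ncompetence(rnaseq 1.2 RPM): competent={call.competent}, "
      f"evidence={sorted(call.evidence)}")
# one uniquely-matching RPM of ddm1 mRNA is already evidence the TE can
# be transcribed once silencing is released
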