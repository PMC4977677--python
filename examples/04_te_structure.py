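"""TE structure: length classes, domain enrichment and mappability.

Compares each TE's annotated length to its family consensus, counts which
essential retrotransposition domains survive in each copy, and asks whether
pathway categories are enriched for structurally complete elements.
"""

from methylpath import SimulationParams, build_matrix, categorize_genome, simulate
from methylpath.io import canonical_role, required_roles
from methylpath.te_structure import (
    GenomeMappability,
    domain_enrichment,
    length_class,
    profiles_from_hits,
)

ds = simulate(SimulationParams(seed=4, n_te=60,
                               chrom_sizes={"chr1": 60_000, "chr2": 60_000}))

truth = ds.truth.set_index("te_id")
classes = {tid: length_class(int(row["te_length"]), int(row["consensus_length"]))
           for tid, row in truth.iterrows()}
from collections import Counter
print("length classes:", dict(Counter(classes.values())))
# FULL_LENGTH = >80 % of the family consensus, FRAGMENT = <20 %

tables = {canonical_role(r, "active"): df
          for r, df in ds.methylomes["active"].items()
          if r in required_roles("active")}
calls, _ = categorize_genome(build_matrix(tables, ds.tes, "CHH"), "active")
profiles = profiles_from_hits(ds.domain_hits)
enrich = domain_enrichment(profiles, calls[calls["category"] != "UNCOVERED"])
print("\nobserved/expected domain frequency per pathway category:")
print(enrich.round(2).to_string())
# cells > 1 mean the category holds more domain-complete TEs than expected

idx = GenomeMappability(ds.genome, read_length=150)
frac, cls = idx.te_mappability(ds.tes[0])
print(f"\n{ds.tes[0].id}: {frac:.2f} of 150 bp windows map uniquely -> {cls}")
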