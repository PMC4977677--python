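"""Anchored meta-plot: average CHH methylation around TE 5' ends.

Each TE contributes weighted methylation per 100 bp window from 2 kb
upstream into its body; the profile is the mean across TEs with a 95 %
confidence band.
"""

from methylpath import SimulationParams, simulate
from methylpath.metaplot import profile_features

ds = simulate(SimulationParams(seed=4, n_te=60,
                               chrom_sizes={"chr1": 60_000, "chr2": 60_000}))
methylated = set(ds.truth.loc[ds.truth["category_silent"] != "NO_CHH", "te_id"])
tes = [f for f in ds.tes if f.id in methylated]

prof = profile_features(tes, ds.methylomes["silent"]["wt"],
                        bin=100, flank=2000, anchor="five_prime", context="CHH")
print("offset  mean   ci_low ci_high  n")
for _, row in prof.table.iterrows():
    if -300 <= row["offset"] <= 300:
        print(f"{row['offset']:>6.0f}  {row['mean']:.3f}  {row['ci_low']:.3f}"
              f"  {row['ci_high']:.3f}  {row['n_elements']:>3.0f}")
# negative offsets are upstream flank (background methylation), offset 0 is
# the first TE base: methylation steps up sharply at the boundary

# prof.plot() draws the line with a translucent confidence ribbon
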