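"""Call differentially methylated regions between two genotypes.

Per shared cytosine a Fisher exact test compares methylated/unmethylated
read counts; BH-adjusted significant sites (DMSs) within 250 bp of each
other chain into DMRs, reported when they hold at least four DMSs.
"""

from methylpath import SimulationParams, call_dms, merge_dms, simulate

# per-site exact tests need real read depth: at ~20x a single cytosine can
# rarely reach genome-wide significance, so this demo simulates 100x
ds = simulate(SimulationParams(seed=4, n_te=60, depth_mean=100.0,
                               chrom_sizes={"chr1": 60_000, "chr2": 60_000}))
wt = ds.methylomes["silent"]["wt"]
polv = ds.methylomes["silent"]["polV"]

dms = call_dms(wt, polv, alpha=0.01, context="CHH")
regions = merge_dms(dms, max_gap=250, min_dms=4)
print(f"{len(dms)} DMSs between wt and polV -> {len(regions)} DMRs")
# polV is required by every RdDM route, so RdDM-target TEs lose CHH
# methylation and come out as hypo-DMRs

for r in regions[:5]:
    overlapping = [f.id for f in ds.tes
                   if f.chrom == r.chrom and f.start < r.end and r.start < f.end]
    print(f"  {r.chrom}:{r.start}-{r.end}  n_dms={r.n_dms:<4} "
          f"TEs: {','.join(overlapping) or '-'}")
print("  ... (a DMR spans its first to last member site)")
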