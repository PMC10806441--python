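"""Rarefy both markers, convert to percent and fuse them.

Each marker is rarefied to the lower quartile of its per-sample read
totals, converted to percent abundance, and the two markers are
averaged over the samples both retained — OTUs aligned by their full
taxonomy.
"""

import sedna
from sedna.fusion import lower_quartile_depth, marker_overlap_report

ds = sedna.generate_dataset(sedna.default_config(seed=1, n_samples=40, n_taxa=25))
pcts, taxs = {}, {}
for mk in ("V7", "V9"):
    otu, _, _ = sedna.run_marker_filters(ds.markers[mk], ds.taxonomy, ds.sequences[mk])
    depth = lower_quartile_depth(otu)
    rared = sedna.rarefy(otu, depth, seed=1, shallow="keep")
    pcts[mk] = sedna.to_percent(rared)
    taxs[mk] = ds.taxonomy.subset(pcts[mk].index)
    print(f"{mk}: rarefied to {depth:,} reads, {pcts[mk].shape[0]} OTUs")

fused = sedna.fuse_markers(pcts["V7"], pcts["V9"], taxs["V7"], taxs["V9"],
                           rarefaction_depths={}, seed=1)
print(f"\nfused table: {fused.percents.shape[0]} samples x {fused.percents.shape[1]} OTUs")
print("marker overlap:", marker_overlap_report(fused))
print("Every fused value is the mean of the two markers' percents (0 when a")
print("marker missed the OTU), so per-sample percents still sum to 100.")
print("per-sample sums:", fused.percents.sum(axis=1).round(6).unique())
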