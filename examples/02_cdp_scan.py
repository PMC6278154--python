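"""Scan for cluster-determining positions between two clades.

Plants five clade-diagnostic columns (clade A mostly W, clade B mostly D,
purity 0.9) among background columns, weights sequences by identity
clustering, and scans every column for residue-vs-clade mutual information
with a cluster-level permutation test.
"""

from sdpnet import cdp_scan, cluster_weights
from sdpnet.synthetic_data import CdpSpec, SyntheticTruth, generate

planted = [10, 20, 30, 40, 50]
truth = SyntheticTruth(
    seed=21,
    planted_cdps=tuple(
        CdpSpec(column=c, dominant={"A": "W", "B": "D"}, q=0.9) for c in planted
    ),
)
data = generate({"A": 100, "B": 100}, 60, truth)
weights = cluster_weights(data.alignment, 0.62)
print(f"{weights.n_clusters} identity clusters over {data.alignment.n_seqs} sequences")

results = cdp_scan(
    data.alignment, data.groups, weights, n_perm=999, seed=22
)
cdps = [r for r in results if r.is_cdp]
print(f"{len(cdps)} CDPs at BH 0.05 (planted: {planted})")
for r in cdps:
    print(f"  column {r.column:3d}  I = {r.statistic:.3f} nats  "
          f"p_adj = {r.p_adjusted:.4f}  z = {r.z:.1f}")
# The statistic is the weighted mutual information between residue and
# clade label; a fully diagnostic column on equal clades would reach
# ln 2 = 0.693 nats, purity 0.9 lands a bit below that.
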