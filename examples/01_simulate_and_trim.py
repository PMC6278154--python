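"""Generate a two-clade synthetic alignment and trim it.

Builds an alignment with one planted clade-specific insert, then removes
gap-rich / high-entropy columns the way one would before tree building.
The insert block is half-gapped (absent in clade B), so trimming strips
exactly those columns.
"""

from sdpnet import trim_alignment
from sdpnet.synthetic_data import CsiSpec, SyntheticTruth, generate

truth = SyntheticTruth(
    seed=11,
    planted_csis=(CsiSpec(clade="A", col_start=30, col_end=54),),
)
data = generate({"A": 40, "B": 40}, 80, truth)
aln = data.alignment
print(f"alignment: {aln.n_seqs} sequences x {aln.n_cols} columns")

trimmed, kept = trim_alignment(aln, g=0.3, h=0.8)
removed = set(range(1, aln.n_cols + 1)) - set(kept)
insert = set(range(30, 55))
print(f"trimming (g=0.3, h=0.8) kept {len(kept)} columns")
print(f"insert columns removed: {len(insert & removed)}/{len(insert)}")
# The planted insert (columns 30-54) is gapped in clade B, so its gap
# fraction (0.5) exceeds g and the whole block is removed; the remaining
# removed columns are high-entropy background (entropy_norm > h).
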