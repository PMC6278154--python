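# Methods

This note documents the models, statistics and numerical choices behind
`sdpnet`, and what the synthetic validation does and does not show.

## Alignment model and trimming

An alignment is rectangular over the 20 amino acids plus `X` (unknown) and
`-` (gap); rows are upper-cased on ingest and anything else is rejected
with the offending sequence and column. All public coordinates are
1-based alignment columns; positions can additionally be quoted in the
residue numbering of a reference sequence (a crystal-structure chain,
typically) through `ColumnMap`, defined exactly on the reference's
non-gap columns.

Trimming keeps columns with gap fraction ≤ g (default 0.3) and normalised
entropy ≤ h (default 0.8). Entropy is plain Shannon entropy of the
residue frequencies — gaps and `X` excluded — divided by ln 20, so it is 0
for a conserved column and 1 when all twenty residues are equally
frequent. This is a deliberately transparent, BMGE-like criterion, not a
bit-compatible reimplementation of any published trimmer (those smooth
frequencies through a substitution matrix); column counts on real data
therefore differ from other tools and are treated as approximate
everywhere. Columns with no countable residue (all gap/`X`) are always
removed. Trimming is idempotent by construction.

`X` is excluded from every frequency-based statistic (it carries no
residue information) but retained in output rows.

## Clades and sequence weights

Clades come either from an explicit id→label table or from a Newick tree:
each clade is the leaf set of the most recent common ancestor of a few
named exemplar leaves, after optional midpoint rooting. Midpoint rooting
is implemented explicitly: the longest leaf-to-leaf path (ties broken by
sorted leaf labels) is split at its midpoint; when the midpoint falls
exactly on an existing node that node becomes the root. Overlapping clade
leaf sets raise a non-monophyly error rather than being silently merged.

Redundancy weighting follows the common identity-clustering recipe:
greedy single-pass clustering in file order, where a sequence joins the
first cluster whose *founder* it matches at ≥ 62% identity (matches over
columns where both rows are non-gap; no shared columns means identity 0),
else founds a new cluster. Every member of a cluster of size s gets
weight 1/s, so weights sum to the number of clusters. The 0.62 default is
the convention of the weighted-MI literature this pipeline builds on.
Because the clustering is greedy, input order matters; the file order is
always used, making results reproducible. Raising the threshold can only
split clusters, so cluster counts are monotone in the threshold.

## CDP statistic and its null

For two clades the per-column statistic is the weighted mutual
information (nats) between residue and clade label,
I(X;G) = Σ p(a,g) ln[p(a,g)/(p(a)p(g))], with identity-cluster weights,
gaps/`X` excluded and weights renormalised per column. A perfectly
diagnostic column on equal-weight clades reaches ln 2.

Significance is by permutation: clade labels are permuted *over identity
clusters* — whole clusters flip together — because near-duplicate
sequences are not independent observations and flipping them individually
would make the null anti-conservative. Each cluster carries its founder's
observed label into the permutation pool. One permutation per replicate
is applied to all columns, preserving between-column dependence. p-values
use the add-one convention p = (1 + #{null ≥ obs})/(n_perm + 1), so the
minimum attainable p is 1/(n_perm+1); with Benjamini–Hochberg adjustment
(the default; Bonferroni by flag) the permutation count must be generous
enough that 1/(n_perm+1) sits below α·k/m for the expected number of true
hits k among m columns — the tests use 999 permutations for exactly this
reason.

## Covariation: MI, APC, shuffle z-scores

Pair scores are weighted MI over the 20×20 joint table of sequences
non-gap at both columns. A flat pseudocount is spread over the table with
total added mass `pseudocount × n_clusters` (default pseudocount 0.05), a
low-count correction in the spirit of the weighted-MI lineage. The flat
mass inflates raw MI for pairs involving conserved columns (the mass in
low-marginal cells dominates); this inflation is near-constant across
pairs and is removed by the average product correction and by the
z-scoring, which are the quantities the method thresholds. The
pseudocount is an exposed flag; at 0 the raw MI is the exact
plug-in estimate (verified against a brute-force oracle to 1e-12).

APC subtracts the product of the mean pair score of each column over the
overall mean: MI_APC(i,j) = MI(i,j) − m(i)m(j)/m̄. On a system where all
pairs score equally, APC is identically zero; pairs below background go
negative. A zero overall mean returns the input unchanged with a warning.

The null model permutes residues independently within each column among
its non-gap slots — conservation profile and gap structure are preserved,
covariation is destroyed — and recomputes the APC-corrected score;
z = (obs − null mean)/null sd over (default) 100 shuffles. Pairs whose
null has zero variance (e.g. two nearly conserved columns) are flagged
`degenerate` and reported with z = 0 rather than ±∞. Columns below 50%
occupancy are excluded from the pair universe by default.

## Networks, promotion, key SDPs

Only CDP columns enter the graph; an edge joins two CDPs with z ≥ the
threshold (default 6.5 — the conventional cut-off calibrated for datasets
of roughly 400 identity clusters; a warning is emitted when the dataset
exceeds that, since z-scores grow with sequence numbers and the threshold
should then be raised; no automatic rescaling is attempted because no
principled rule exists). Degree ≥ 2 promotes a CDP to SDP, degree 1 to
pSDP, isolated CDPs stay unsupported. Connected components with ≥ 2 nodes
are SDNs, ordered by size. Edges are monotone in the threshold, so
classes only ever move up the unsupported→pSDP→SDP ladder as the
threshold drops; `threshold_sweep_table` reports the sweep.

Key SDPs are the reference positions classified SDP (not pSDP — putative
positions need corroborating evidence before promotion; a flag admits
them for exploration) in the networks of both independently analysed
clades. SDP columns the reference gaps over cannot be compared across
datasets and are returned in a side list, never dropped. The combined
two-clade dataset is analysed and reported too, but key-SDP determination
uses only the single-clade networks: in the combined set the clade label
itself couples all diagnostic columns, producing a dense, less
interpretable network (the examples demonstrate this).

## Insert calling

Per clade, a column is marked when its weighted in-clade occupancy is
≥ θ_in (default 0.5) while every other clade stays ≤ θ_out (default 0.1).
Marked columns merge into maximal runs tolerating ≤ max_gap_run (default
2) unmarked columns; a merge is accepted only when the merged interval
still satisfies the mean occupancy thresholds, so reported intervals
always honour the calling contract. Runs shorter than min_len (default 5)
are dropped. Identity-cluster weights keep a large shallow subclade from
dominating the occupancy. Known limitation: an insert that elongates a
region shared with other clades is called only over its clade-exclusive
portion, where the other clades actually fall below θ_out. Per-sequence
insert lengths (non-gap counts over the interval) feed the tree
annotation table; the logo matrix reports weighted per-column residue
frequencies with gaps as a separate class, rows summing to 1.

## Structure queries

PDB files are parsed with the first model only; alternate locations
resolve to the highest-occupancy conformer; HETATM residues (metal ions,
ligands) are kept with a flag. Distances are minimum pairwise
inter-atomic distances under an atom filter — heavy atoms by default,
since crystal structures usually lack hydrogens; this convention is the
main tolerance when comparing against published Å figures whose atom
convention is unstated. `proximity_report` flags positions within a
cutoff (default 5 Å) of a residue site and lists unresolvable positions
as unmapped rather than dropping them.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, so
every stage is testable by planted-signal recovery without any downloads:

* **background** — per-column profiles from a symmetric Dirichlet
  (concentration 0.5 by default, giving the mix of conserved and variable
  columns typical of a protein family core), identical across clades,
  sequences i.i.d.;
* **diagnostic columns** — per-clade dominant residue with purity q
  (default 0.9), else a background draw;
* **coupled pairs** — within each clade, the residue at column j is a
  fixed bijective image of column i's residue with probability ρ, else an
  independent draw pushed through the same bijection: marginals match
  background, so the coupling is invisible to single-column statistics
  (tested), and CDP and MI stages measure genuinely different signals;
* **coupled diagnostic pairs** — both columns diagnostic and drawn
  jointly: the planted analogue of a co-evolved SDP pair;
* **inserts** — clade-exclusive occupied blocks with per-sequence
  presence probability and tail-length jitter.

Planted features occupy disjoint columns (enforced). Clades are emitted
as caterpillar subtrees on a caterpillar backbone. The main
simplification: no phylogenetic autocorrelation beyond the clade split —
within a clade sequences are exchangeable. On real data that correlation
exists and is exactly what the identity-cluster weighting compensates;
passing the synthetic recovery tests therefore validates the statistics
given the weighting model, not the weighting model itself. Everything is
a pure function of (parameters, seed); identical seeds give byte-identical
alignments.

Validation problem sizes (chosen to exercise the regimes the statistics
target while keeping the suite quick): oracle equivalence on ≤ 10×10
alignments; null calibration on 200 sequences × 100 columns with 100
shuffles and 999 permutations; end-to-end recovery on two clades of 100
with four planted pairs per seed over ten seeds; insert recovery on 60+60
sequences. The same sizes are used by `scripts/acceptance.py`.

## Pipeline determinism

A run is a pure function of (inputs, config, seed); the config is
archived verbatim in the output directory and re-running it reproduces
all outputs. The seed is mandatory — stochastic stages refuse to run
without one. Derived stage seeds are fixed offsets of the run seed so the
three covariation runs are mutually independent but individually
reproducible.
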