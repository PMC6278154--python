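"""Clade partitions and identity-cluster sequence weights.

A :class:`GroupAssignment` partitions alignment sequences into named clades,
either read from an explicit two-column table or derived from a Newick tree
by taking, for each clade, the leaf set of the most recent common ancestor
of a few named exemplar leaves (after optional midpoint rooting).

:func:`cluster_weights` implements the standard redundancy correction used
by alignment statistics: sequences are greedily clustered at a pairwise
identity threshold and each sequence is weighted 1/(cluster size), so a
clade of near-identical sequences counts once rather than many times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

from .alignment_io import Alignment, GAP_CODE


class GroupingError(ValueError):
    pass


@dataclass(frozen=True)
class GroupAssignment:
    """Disjoint, non-empty named groups of sequence ids."""

    groups: dict[str, frozenset[str]]
    focal_pair: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for label, members in self.groups.items():
            if not members:
                raise GroupingError(f"group {label!r} is empty")
            for sid in members:
                if sid in seen:
                    raise GroupingError(
                        f"sequence {sid!r} assigned to both "
                        f"{seen[sid]!r} and {label!r}"
                    )
                seen[sid] = label
        if self.focal_pair is not None:
            for label in self.focal_pair:
                if label not in self.groups:
                    raise GroupingError(f"focal group {label!r} not defined")

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    def label_of(self, sid: str) -> str | None:
        for label, members in self.groups.items():
            if sid in members:
                return label
        return None

    def members(self, label: str) -> frozenset[str]:
        return self.groups[label]

    def assigned_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.groups.values():
            out |= members
        return frozenset(out)


def groups_from_table(path: str | Path) -> GroupAssignment:
    """Read a two-column TSV (sequence id, group label)."""
    assignment: dict[str, str] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GroupingError(
                    f"{path}:{lineno}: expected 2 tab-separated fields, "
                    f"got {len(parts)}"
                )
            sid, label = parts
            if sid in assignment and assignment[sid] != label:
                raise GroupingError(
                    f"sequence {sid!r} assigned to both "
                    f"{assignment[sid]!r} and {label!r}"
                )
            assignment[sid] = label
            n_rows += 1
    if n_rows == 0:
        raise GroupingError(f"empty group table: {path}")
    groups: dict[str, set[str]] = {}
    for sid, label in assignment.items():
        groups.setdefault(label, set()).add(sid)
    return GroupAssignment(groups={k: frozenset(v) for k, v in groups.items()})


def write_group_table(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label in groups.labels:
            for sid in sorted(groups.members(label)):
                fh.write(f"{sid}\t{label}\n")


def _midpoint_reroot(t: dendropy.Tree, eps: float = 1e-9) -> None:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Ties between equally long paths are broken deterministically by sorted
    leaf labels.  When the midpoint coincides with an existing node, that
    node becomes the root; otherwise the spanning edge is split.
    """
    pdm = t.phylogenetic_distance_matrix()
    leaves = sorted(
        (lf.taxon for lf in t.leaf_node_iter() if lf.taxon),
        key=lambda x: x.label,
    )
    best = None
    for i, ta in enumerate(leaves):
        for tb in leaves[i + 1 :]:
            d = pdm.patristic_distance(ta, tb)
            if best is None or d > best[0] + eps:
                best = (d, ta, tb)
    if best is None:
        return
    d, ta, tb = best
    node_a = next(lf for lf in t.leaf_node_iter() if lf.taxon is ta)
    node_b = next(lf for lf in t.leaf_node_iter() if lf.taxon is tb)
    anc_a = [node_a] + list(node_a.ancestor_iter())
    anc_b = [node_b] + list(node_b.ancestor_iter())
    mrca = next(n for n in anc_a if n in set(anc_b))

    def walk(start, target):
        """Find (edge, dist_from_child_end) at ``target`` up from ``start``;
        returns (node, None) when the target lands on a node."""
        node, cum = start, 0.0
        while node is not mrca:
            elen = node.edge.length or 0.0
            if abs(cum + elen - target) <= eps:
                return node.parent_node, None
            if cum + elen > target:
                return node.edge, target - cum
            cum += elen
            node = node.parent_node
        return None

    target = d / 2.0
    hit = walk(node_a, target)
    if hit is None:
        hit = walk(node_b, d - target)
    where, offset = hit
    if offset is None:
        if where is not t.seed_node:
            t.reroot_at_node(where, update_bipartitions=True)
    else:
        elen = where.length or 0.0
        t.reroot_at_edge(
            where,
            length1=elen - offset,  # tail (rootward) side
            length2=offset,  # head (child) side
            update_bipartitions=True,
        )


def groups_from_tree(
    tree: str | Path | dendropy.Tree,
    exemplars: Mapping[str, Iterable[str]],
    root: str = "midpoint",
) -> GroupAssignment:
    """Clades as MRCA leaf sets of exemplar leaves on a (rooted) tree.

    ``root='midpoint'`` reroots at the midpoint of the longest leaf-to-leaf
    path before taking MRCAs; ``root='as-given'`` uses the tree as read.
    Overlapping clades raise a non-monophyly error naming the groups.
    """
    if root not in ("midpoint", "as-given"):
        raise ValueError(f"unknown rooting mode {root!r}")
    if isinstance(tree, dendropy.Tree):
        t = tree.clone(depth=1)
    else:
        text = Path(tree).read_text() if Path(str(tree)).exists() else str(tree)
        # preserve_underscores: leaf labels must match alignment ids verbatim
        t = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    if root == "midpoint":
        _midpoint_reroot(t)
    # treat the (possibly new) seed node as the root for MRCA queries
    t.is_rooted = True
    t.update_bipartitions()
    leaf_names = {lf.taxon.label for lf in t.leaf_node_iter() if lf.taxon}
    groups: dict[str, frozenset[str]] = {}
    for label, ex in exemplars.items():
        ex = list(ex)
        missing = [e for e in ex if e not in leaf_names]
        if missing:
            raise GroupingError(
                f"exemplar leaves not in tree for group {label!r}: {missing}"
            )
        mrca = t.mrca(taxon_labels=ex)
        members = frozenset(
            lf.taxon.label for lf in mrca.leaf_iter() if lf.taxon
        )
        groups[label] = members
    labels = list(groups)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if groups[a] & groups[b]:
                raise GroupingError(
                    f"groups {a!r} and {b!r} are not monophyletic: their "
                    f"MRCA leaf sets overlap"
                )
    return GroupAssignment(groups=groups)


@dataclass(frozen=True)
class SequenceWeights:
    """1/(cluster size) weights from greedy identity clustering.

    ``clusters`` maps each weighted id to its 0-based cluster index; the sum
    of all weights equals ``n_clusters`` exactly (up to float rounding).
    """

    weight: dict[str, float]
    clusters: dict[str, int]
    n_clusters: int
    identity_threshold: float

    def vector(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self.weight[i] for i in ids], dtype=float)


def pairwise_identity(row_a: np.ndarray, row_b: np.ndarray) -> float:
    """Fraction of matching residues over columns non-gap in both rows."""
    both = (row_a != GAP_CODE) & (row_b != GAP_CODE)
    denom = int(both.sum())
    if denom == 0:
        return 0.0
    return float(np.sum(row_a[both] == row_b[both])) / denom


def cluster_weights(
    aln: Alignment,
    identity_threshold: float = 0.62,
    restrict_to: Iterable[str] | None = None,
) -> SequenceWeights:
    """Greedy single-pass identity clustering in input order.

    Each sequence joins the first cluster whose founding representative
    shares pairwise identity >= threshold (identity counted over columns
    where both rows are non-gap), else founds a new cluster.  Weights are
    1/(cluster size); their sum is the number of clusters.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError(f"identity threshold {identity_threshold} outside (0, 1]")
    if restrict_to is not None:
        keep = set(restrict_to)
        sel = [i for i, sid in enumerate(aln.ids) if sid in keep]
        if not sel:
            raise GroupingError("restrict_to shares no ids with the alignment")
    else:
        sel = list(range(aln.n_seqs))
    codes = aln.codes()
    reps: list[int] = []  # row index of each cluster's founder
    assign: dict[str, int] = {}
    sizes: list[int] = []
    for i in sel:
        placed = False
        for k, r in enumerate(reps):
            if pairwise_identity(codes[i], codes[r]) >= identity_threshold:
                assign[aln.ids[i]] = k
                sizes[k] += 1
                placed = True
                break
        if not placed:
            reps.append(i)
            sizes.append(1)
            assign[aln.ids[i]] = len(reps) - 1
    weight = {sid: 1.0 / sizes[k] for sid, k in assign.items()}
    return SequenceWeights(
        weight=weight,
        clusters=assign,
        n_clusters=len(reps),
        identity_threshold=identity_threshold,
    )


def weights_report(weights: SequenceWeights):
    import pandas as pd

    return pd.DataFrame(
        [
            {"id": sid, "cluster": weights.clusters[sid], "weight": w}
            for sid, w in weights.weight.items()
        ]
    )
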