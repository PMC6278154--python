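"""Cluster Determining Positions (CDPs).

A CDP is an alignment column whose residue composition is significantly
associated with membership in one of two sequence clades.  The statistic is
the weighted mutual information (in nats) between the residue observed at
the column and the clade label,

    I(X; G) = sum_{a,g} p(a,g) ln[ p(a,g) / (p(a) p(g)) ],

with frequencies computed from identity-cluster weights, gaps and unknown
residues excluded, and weights renormalised per column.  Significance comes
from a label-permutation null: clade labels are permuted over identity
clusters (whole clusters flip together, which keeps near-duplicate
sequences from making the null anti-conservative), one permutation per
replicate applied to all columns so that between-column dependence is
preserved.  p-values use the add-one permutation convention
p = (1 + #{null >= observed}) / (n_perm + 1) and are adjusted for multiple
testing (Benjamini-Hochberg by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .alignment_io import Alignment, ColumnMap, N_AA
from .grouping import GroupAssignment, SequenceWeights


class CdpError(ValueError):
    pass


@dataclass(frozen=True)
class CdpResult:
    column: int  # 1-based alignment column
    ref_position: int | None
    statistic: float  # weighted MI between residue and group, nats
    p_value: float
    p_adjusted: float
    z: float
    is_cdp: bool


def _weighted_group_mi(
    counts_a: np.ndarray, counts_b: np.ndarray
) -> np.ndarray:
    """Columnwise MI from per-group weighted residue counts.

    ``counts_a``/``counts_b`` have shape (20, n_cols).  Zero cells
    contribute zero; a column with no usable mass in one group scores 0.
    """
    joint = np.stack([counts_a, counts_b])  # (2, 20, C)
    tot = joint.sum(axis=(0, 1))  # (C,)
    safe_tot = np.where(tot > 0, tot, 1.0)
    p = joint / safe_tot
    p_res = p.sum(axis=0)  # (20, C)
    p_grp = p.sum(axis=1)  # (2, C)
    denom = p_grp[:, None, :] * p_res[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(np.where(p > 0, p / np.where(denom > 0, denom, 1.0), 1.0))
    mi = term.sum(axis=(0, 1))
    return np.where(tot > 0, np.maximum(mi, 0.0), 0.0)


class _ColumnGroupMI:
    """Precomputed structures for fast MI evaluation under many labelings."""

    def __init__(self, codes: np.ndarray, w: np.ndarray):
        # residue indicator stacks: (20, n_seqs, n_cols) as float for matvec
        self.n_seqs, self.n_cols = codes.shape
        self.w = w
        self.indicators = [
            (codes == a).astype(float) for a in range(N_AA)
        ]

    def counts_for_mask(self, mask: np.ndarray) -> np.ndarray:
        """Weighted residue counts (20, n_cols) over sequences where mask=1."""
        v = self.w * mask
        return np.stack([v @ B for B in self.indicators])

    def mi_for_labels(self, labels: np.ndarray) -> np.ndarray:
        ca = self.counts_for_mask((labels == 0).astype(float))
        cb = self.counts_for_mask((labels == 1).astype(float))
        return _weighted_group_mi(ca, cb)


def cdp_scan(
    aln: Alignment,
    groups: GroupAssignment,
    weights: SequenceWeights,
    group_a: str | None = None,
    group_b: str | None = None,
    n_perm: int = 999,
    alpha: float = 0.05,
    adjust: str = "bh",
    seed: int | None = None,
    column_map: ColumnMap | None = None,
    columns: list[int] | None = None,
) -> list[CdpResult]:
    """Scan every column for association between residue and clade label.

    ``group_a``/``group_b`` default to the assignment's focal pair or, for a
    two-group assignment, its two labels.  ``columns`` restricts the scan to
    the given 1-based columns (results still report original coordinates).
    A seed is mandatory: the permutation null is part of the result.
    """
    if seed is None:
        raise CdpError("a seed is required for the permutation null")
    if n_perm < 99:
        raise CdpError("n_perm must be at least 99")
    if adjust not in ("bh", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    if group_a is None or group_b is None:
        if groups.focal_pair is not None:
            group_a, group_b = groups.focal_pair
        elif len(groups.labels) == 2:
            group_a, group_b = groups.labels
        else:
            raise CdpError("two group labels required")

    members_a = groups.members(group_a)
    members_b = groups.members(group_b)
    sel_ids = [i for i in aln.ids if i in members_a or i in members_b]
    if not (members_a & set(sel_ids)) or not (members_b & set(sel_ids)):
        raise CdpError("both groups must have sequences in the alignment")

    sub = aln.subset_rows(sel_ids)
    if columns is not None:
        sub = sub.subset_columns(columns)
        col_coords = list(columns)
    else:
        col_coords = list(range(1, aln.n_cols + 1))
    codes = sub.codes()
    w = weights.vector(sub.ids)
    labels = np.array([0 if sid in members_a else 1 for sid in sub.ids])

    usable = codes < N_AA
    for g in (0, 1):
        if not usable[labels == g].any():
            raise CdpError(
                f"group {(group_a, group_b)[g]!r} has no non-gap residues "
                "at any column"
            )

    engine = _ColumnGroupMI(codes, w)
    observed = engine.mi_for_labels(labels)

    # cluster-level permutation: whole identity clusters flip together
    cluster_of = np.array([weights.clusters[sid] for sid in sub.ids])
    uniq, cluster_idx = np.unique(cluster_of, return_inverse=True)
    founder_label = np.empty(len(uniq), dtype=int)
    for k in range(len(uniq)):
        founder_label[k] = labels[cluster_idx == k][0]

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, len(col_coords)))
    for r in range(n_perm):
        perm = rng.permutation(founder_label)
        null[r] = engine.mi_for_labels(perm[cluster_idx])

    ge = (null >= observed[None, :] - 1e-15).sum(axis=0)
    p = (1.0 + ge) / (n_perm + 1.0)
    mu = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    z = np.where(sd > 0, (observed - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    method = "fdr_bh" if adjust == "bh" else "bonferroni"
    _, p_adj, _, _ = multipletests(p, alpha=alpha, method=method)

    results = []
    for i, col in enumerate(col_coords):
        ref = column_map.ref_position(col) if column_map is not None else None
        results.append(
            CdpResult(
                column=col,
                ref_position=ref,
                statistic=float(observed[i]),
                p_value=float(p[i]),
                p_adjusted=float(p_adj[i]),
                z=float(z[i]),
                is_cdp=bool(p_adj[i] <= alpha),
            )
        )
    results.sort(key=lambda r: r.column)
    return results


def cdp_report(results: list[CdpResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "column": r.column,
                "ref_position": r.ref_position,
                "statistic": r.statistic,
                "p": r.p_value,
                "p_adjusted": r.p_adjusted,
                "z": r.z,
                "is_cdp": r.is_cdp,
            }
            for r in results
        ]
    )
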