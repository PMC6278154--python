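"""Cluster Specific Inserts (CSIs).

A CSI is a stretch of alignment columns occupied predominantly by one clade
and gapped in the others — the alignment signature of a clade-specific
insertion.  Detection is per clade: columns whose weighted in-clade
occupancy reaches ``theta_in`` while every other clade stays at or below
``theta_out`` are marked, marked columns are merged into maximal runs
tolerating short unmarked interruptions, and runs of at least ``min_len``
columns are reported with per-sequence insert lengths (non-gap residue
counts over the interval).

A limitation inherent to the occupancy contrast: an insert that merely
elongates a region shared with other clades is called only over its
clade-exclusive portion, where the other clades' occupancy actually drops
below ``theta_out``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_io import Alignment, GAP_CODE
from .grouping import GroupAssignment, SequenceWeights


class CsiError(ValueError):
    pass


@dataclass(frozen=True)
class InsertCall:
    clade: str
    col_start: int  # 1-based inclusive
    col_end: int
    occupancy_in: float
    occupancy_out_max: float
    per_sequence_length: dict[str, int]

    @property
    def length(self) -> int:
        return self.col_end - self.col_start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.col_start, self.col_end)


def _clade_occupancy(
    codes: np.ndarray,
    ids: tuple[str, ...],
    members: frozenset[str],
    weights: SequenceWeights | None,
) -> np.ndarray:
    """Weighted non-gap fraction per column within one clade."""
    idx = [k for k, sid in enumerate(ids) if sid in members]
    sub = codes[idx]
    if weights is not None:
        w = np.array([weights.weight[ids[k]] for k in idx])
    else:
        w = np.ones(len(idx))
    w = w / w.sum()
    return ((sub != GAP_CODE) * w[:, None]).sum(axis=0)


def call_csis(
    aln: Alignment,
    groups: GroupAssignment,
    theta_in: float = 0.5,
    theta_out: float = 0.1,
    min_len: int = 5,
    max_gap_run: int = 2,
    weights: SequenceWeights | None = None,
) -> list[InsertCall]:
    """Detect clade-specific insert intervals for every clade.

    Runs of marked columns separated by at most ``max_gap_run`` unmarked
    columns are merged when the merged interval still satisfies the mean
    occupancy thresholds; calls shorter than ``min_len`` are dropped.
    Identity-cluster weights, when given, keep large shallow subclades from
    dominating the occupancy.
    """
    if len(groups.labels) < 2:
        raise CsiError("insert calling needs at least two clades to contrast")
    if not theta_out < theta_in:
        raise CsiError("theta_out must be strictly below theta_in")
    codes = aln.codes()
    occ = {
        label: _clade_occupancy(codes, aln.ids, groups.members(label), weights)
        for label in groups.labels
    }
    calls: list[InsertCall] = []
    for label in groups.labels:
        others = [l for l in groups.labels if l != label]
        out_max = np.max(np.stack([occ[l] for l in others]), axis=0)
        marked = (occ[label] >= theta_in) & (out_max <= theta_out)

        runs = _merge_runs(marked, occ[label], out_max, theta_in, theta_out, max_gap_run)
        for start0, end0 in runs:
            if end0 - start0 + 1 < min_len:
                continue
            in_mean = float(occ[label][start0 : end0 + 1].mean())
            out_mean_max = float(out_max[start0 : end0 + 1].mean())
            lengths = {}
            for k, sid in enumerate(aln.ids):
                if sid in groups.members(label):
                    lengths[sid] = int(
                        np.sum(codes[k, start0 : end0 + 1] != GAP_CODE)
                    )
            calls.append(
                InsertCall(
                    clade=label,
                    col_start=int(start0) + 1,
                    col_end=int(end0) + 1,
                    occupancy_in=in_mean,
                    occupancy_out_max=out_mean_max,
                    per_sequence_length=lengths,
                )
            )
    calls.sort(key=lambda c: (c.clade, c.col_start))
    return calls


def _merge_runs(
    marked: np.ndarray,
    occ_in: np.ndarray,
    occ_out: np.ndarray,
    theta_in: float,
    theta_out: float,
    max_gap_run: int,
) -> list[tuple[int, int]]:
    """Maximal marked runs, merging across gaps of <= max_gap_run columns.

    A merge is accepted only when the merged interval still has mean
    in-clade occupancy >= theta_in and mean outside occupancy <= theta_out,
    so reported intervals always honour the calling thresholds.
    """
    raw: list[list[int]] = []
    for c in np.flatnonzero(marked):
        if raw and c == raw[-1][1] + 1:
            raw[-1][1] = c
        else:
            raw.append([c, c])
    merged: list[list[int]] = []
    for run in raw:
        if merged and run[0] - merged[-1][1] - 1 <= max_gap_run:
            s, e = merged[-1][0], run[1]
            if (
                occ_in[s : e + 1].mean() >= theta_in
                and occ_out[s : e + 1].mean() <= theta_out
            ):
                merged[-1][1] = e
                continue
        merged.append(list(run))
    return [(s, e) for s, e in merged]


def csi_logo(
    aln: Alignment,
    call: InsertCall,
    groups: GroupAssignment,
    weights: SequenceWeights | None = None,
) -> pd.DataFrame:
    """Weighted per-column residue frequencies of the focal clade.

    Rows are interval columns; columns are the 20 amino acids plus ``gap``
    (X counted as gap for display); every row sums to 1.
    """
    from .alignment_io import AMINO_ACIDS, N_AA

    members = groups.members(call.clade)
    idx = [k for k, sid in enumerate(aln.ids) if sid in members]
    if weights is not None:
        w = np.array([weights.weight[aln.ids[k]] for k in idx])
    else:
        w = np.ones(len(idx))
    w = w / w.sum()
    codes = aln.codes()[idx, call.col_start - 1 : call.col_end]
    rows = []
    for c in range(codes.shape[1]):
        col = codes[:, c]
        freq = {aa: 0.0 for aa in AMINO_ACIDS}
        gap = 0.0
        for wk, code in zip(w, col):
            if code < N_AA:
                freq[AMINO_ACIDS[code]] += wk
            else:
                gap += wk
        freq["gap"] = gap
        freq["column"] = call.col_start + c
        rows.append(freq)
    return pd.DataFrame(rows).set_index("column")


def csi_tree_annotation(
    calls: list[InsertCall],
    leaf_names: list[str],
    alignment_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Per-leaf insert lengths, one column per call.

    Clade members report their measured length, other aligned sequences 0,
    and leaves absent from the alignment NaN (listed, lengths empty).
    ``leaf_names`` typically come from the phylogeny the table will be
    plotted against; ``alignment_ids`` defaults to the union of ids seen by
    any call.
    """
    if alignment_ids is None:
        aligned: set[str] = set()
        for call in calls:
            aligned |= set(call.per_sequence_length)
    else:
        aligned = set(alignment_ids)
    data = {}
    for call in calls:
        name = f"{call.clade}:{call.col_start}-{call.col_end}"
        data[name] = [
            float(call.per_sequence_length.get(leaf, 0))
            if leaf in aligned
            else np.nan
            for leaf in leaf_names
        ]
    return pd.DataFrame(data, index=leaf_names)


def csi_report(calls: list[InsertCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "clade": c.clade,
                "col_start": c.col_start,
                "col_end": c.col_end,
                "length": c.length,
                "occupancy_in": c.occupancy_in,
                "occupancy_out_max": c.occupancy_out_max,
                "median_insert_length": float(
                    np.median(list(c.per_sequence_length.values()))
                ),
            }
            for c in calls
        ]
    )


def itol_simplebar(call: InsertCall, path) -> None:
    """Minimal iTOL simple-bar annotation of per-sequence insert lengths."""
    with open(path, "w") as fh:
        fh.write("DATASET_SIMPLEBAR\nSEPARATOR TAB\n")
        fh.write(f"DATASET_LABEL\tCSI {call.clade} {call.col_start}-{call.col_end}\n")
        fh.write("COLOR\t#cc0000\nDATA\n")
        for sid, length in sorted(call.per_sequence_length.items()):
            fh.write(f"{sid}\t{length}\n")
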