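"""Column-pair covariation: mutual information, APC correction, shuffle z-scores.

For a pair of alignment columns (i, j) the raw score is the weighted mutual
information (nats) of the 20x20 joint residue table built from sequences
that are non-gap at both columns, with a flat pseudocount spread over the
table (total added mass = pseudocount x number of identity clusters, a
low-count correction in the spirit of the weighted-MI literature).

Raw MI mixes covariation with conservation and phylogenetic background;
the average product correction (APC) removes the dominant background
component:

    MI_APC(i, j) = MI(i, j) - mean_i(MI) * mean_j(MI) / mean(MI)

Significance is calibrated by shuffled alignments: residues are permuted
independently within each column (preserving column composition and gap
positions, destroying covariation), the APC-corrected score is recomputed,
and each pair is reported as z = (observed - null mean) / null sd.  Pairs
whose null has zero variance (e.g. both columns nearly conserved) are
flagged degenerate and given z = 0 rather than an infinite score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import Alignment, N_AA
from .grouping import SequenceWeights

Pair = tuple[int, int]


class CovariationError(ValueError):
    pass


@dataclass(frozen=True)
class PairScore:
    mi_raw: float
    mi_apc: float
    z: float = float("nan")
    degenerate: bool = False


@dataclass(frozen=True)
class CovariationResult:
    """APC-corrected MI and shuffle z-scores for all column pairs used."""

    pairs: dict[Pair, PairScore]
    columns_used: tuple[int, ...]  # 1-based original coordinates
    n_shuffles: int
    seed: int | None

    def z_of(self, i: int, j: int) -> float:
        a, b = (i, j) if i < j else (j, i)
        return self.pairs[(a, b)].z


def _usable_columns(
    aln: Alignment, columns: list[int] | None, min_occupancy: float
) -> tuple[np.ndarray, list[int]]:
    codes = aln.codes()
    if columns is None:
        cand = list(range(1, aln.n_cols + 1))
    else:
        cand = list(columns)
    keep = []
    for c in cand:
        occ = float(np.mean(codes[:, c - 1] < N_AA))
        if occ >= min_occupancy:
            keep.append(c)
    if len(keep) < 2:
        raise CovariationError(
            f"fewer than 2 columns with occupancy >= {min_occupancy}"
        )
    return codes[:, [c - 1 for c in keep]], keep


def _mi_matrix(codes_sub: np.ndarray, w: np.ndarray, pc_mass: float) -> np.ndarray:
    """All-pairs weighted MI (nats), shape (C, C); diagonal not meaningful.

    One-hot encoding makes the weighted joint table of every pair a single
    matrix product; sequences gapped (or X) at a column contribute an
    all-zero row there, so pair tables automatically use only sequences
    non-gap at both columns.
    """
    n, C = codes_sub.shape
    onehot = (codes_sub[:, :, None] == np.arange(N_AA)[None, None, :]).astype(
        float
    )
    X = onehot.reshape(n, C * N_AA)
    J = X.T @ (X * w[:, None])
    J = J.reshape(C, N_AA, C, N_AA).transpose(0, 2, 1, 3)  # (C, C, 20, 20)
    if pc_mass > 0:
        J = J + pc_mass / (N_AA * N_AA)
    tot = J.sum(axis=(2, 3))
    safe_tot = np.where(tot > 0, tot, 1.0)
    p = J / safe_tot[:, :, None, None]
    pi = p.sum(axis=3)
    pj = p.sum(axis=2)
    denom = pi[:, :, :, None] * pj[:, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * np.log(
            np.where(p > 0, p / np.where(denom > 0, denom, 1.0), 1.0)
        )
    mi = term.sum(axis=(2, 3))
    mi = np.where(tot > 0, np.maximum(mi, 0.0), 0.0)
    return mi


def _apc_matrix(mi: np.ndarray) -> np.ndarray:
    C = mi.shape[0]
    off = mi.copy()
    np.fill_diagonal(off, 0.0)
    col_mean = off.sum(axis=1) / (C - 1)
    overall = off.sum() / (C * (C - 1))
    if overall == 0:
        return mi.copy()
    return mi - np.outer(col_mean, col_mean) / overall


def pairwise_mi(
    aln: Alignment,
    weights: SequenceWeights,
    columns: list[int] | None = None,
    pseudocount: float = 0.05,
    min_occupancy: float = 0.5,
) -> dict[Pair, float]:
    """Raw weighted MI for every usable column pair (i < j, 1-based)."""
    codes_sub, keep = _usable_columns(aln, columns, min_occupancy)
    w = weights.vector(aln.ids)
    mi = _mi_matrix(codes_sub, w, pseudocount * weights.n_clusters)
    out: dict[Pair, float] = {}
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            out[(keep[a], keep[b])] = float(mi[a, b])
    return out


def apc_correct(mi: dict[Pair, float]) -> dict[Pair, float]:
    """Average product correction of a pairwise MI map.

    Requires scores over at least 3 columns.  When the overall mean is zero
    the input is returned unchanged.
    """
    cols = sorted({c for p in mi for c in p})
    if len(cols) < 3:
        raise CovariationError("APC needs pairs over at least 3 columns")
    idx = {c: k for k, c in enumerate(cols)}
    C = len(cols)
    m = np.zeros((C, C))
    for (i, j), v in mi.items():
        m[idx[i], idx[j]] = v
        m[idx[j], idx[i]] = v
    corrected = _apc_matrix(m)
    return {(i, j): float(corrected[idx[i], idx[j]]) for (i, j) in mi}


def _shuffle_within_columns(
    codes_sub: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Permute residues among the non-gap slots of each column independently."""
    out = codes_sub.copy()
    for c in range(codes_sub.shape[1]):
        idx = np.flatnonzero(codes_sub[:, c] < N_AA)
        out[idx, c] = codes_sub[rng.permutation(idx), c]
    return out


def mi_zscores(
    aln: Alignment,
    weights: SequenceWeights,
    n_shuffles: int = 100,
    seed: int | None = None,
    columns: list[int] | None = None,
    pseudocount: float = 0.05,
    min_occupancy: float = 0.5,
) -> CovariationResult:
    """APC-corrected MI with z-scores against a within-column shuffle null."""
    if seed is None:
        raise CovariationError("a seed is required for the shuffle null")
    if n_shuffles < 50:
        raise CovariationError("n_shuffles must be at least 50")
    codes_sub, keep = _usable_columns(aln, columns, min_occupancy)
    w = weights.vector(aln.ids)
    pc_mass = pseudocount * weights.n_clusters

    obs = _apc_matrix(_mi_matrix(codes_sub, w, pc_mass))

    rng = np.random.default_rng(seed)
    C = len(keep)
    mean = np.zeros((C, C))
    m2 = np.zeros((C, C))
    for r in range(n_shuffles):
        shuffled = _shuffle_within_columns(codes_sub, rng)
        null = _apc_matrix(_mi_matrix(shuffled, w, pc_mass))
        delta = null - mean
        mean += delta / (r + 1)
        m2 += delta * (null - mean)
    sd = np.sqrt(m2 / (n_shuffles - 1))

    pairs: dict[Pair, PairScore] = {}
    mi_raw = _mi_matrix(codes_sub, w, pc_mass)
    for a in range(C):
        for b in range(a + 1, C):
            degenerate = sd[a, b] <= 0
            z = 0.0 if degenerate else float((obs[a, b] - mean[a, b]) / sd[a, b])
            pairs[(keep[a], keep[b])] = PairScore(
                mi_raw=float(mi_raw[a, b]),
                mi_apc=float(obs[a, b]),
                z=z,
                degenerate=bool(degenerate),
            )
    return CovariationResult(
        pairs=pairs,
        columns_used=tuple(keep),
        n_shuffles=n_shuffles,
        seed=seed,
    )


def edge_table(cov: CovariationResult, column_map=None):
    """TSV-ready edge list: col_i, col_j, ref_i, ref_j, mi_raw, mi_apc, z."""
    import pandas as pd

    rows = []
    for (i, j), s in sorted(cov.pairs.items()):
        rows.append(
            {
                "col_i": i,
                "col_j": j,
                "ref_i": column_map.ref_position(i) if column_map else None,
                "ref_j": column_map.ref_position(j) if column_map else None,
                "mi_raw": s.mi_raw,
                "mi_apc": s.mi_apc,
                "z": s.z,
                "degenerate": s.degenerate,
            }
        )
    return pd.DataFrame(rows)
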