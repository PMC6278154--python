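"""Synthetic alignments with planted clade signal, coupling and inserts.

The generator emulates the statistical structure a clade-aware specificity
analysis assumes, so every stage of the pipeline can be validated by
planted-signal recovery:

* background columns — per-column residue profiles drawn from a symmetric
  Dirichlet (low concentration = conserved columns), identical across
  clades, sequences i.i.d.;
* diagnostic (CDP-like) columns — each clade emits its own dominant residue
  with purity ``q``, otherwise a background draw;
* coupled pairs — within each clade the residue at column j is a fixed
  bijective image of the residue at column i with probability ``rho``, else
  an independent draw pushed through the same bijection, so the *marginal*
  of each pair column matches background and the coupling is invisible to
  single-column statistics;
* coupled diagnostic pairs — both columns clade-diagnostic and their
  residues drawn jointly, the planted analogue of an SDP pair;
* clade-specific inserts — blocks occupied only in one clade, with optional
  per-sequence presence and length noise.

Clades are emitted as star-like subtrees on a caterpillar backbone; there
is no further phylogenetic autocorrelation within a clade (the identity
weighting of the analysis is what compensates relatedness on real data).
Everything is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignment_io import AMINO_ACIDS, Alignment, N_AA, alignment_from_records
from .csi import InsertCall
from .grouping import GroupAssignment


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class CdpSpec:
    """A planted clade-diagnostic column: per-clade dominant residue, purity q."""

    column: int  # 1-based
    dominant: dict[str, str]  # clade label -> residue
    q: float = 0.9


@dataclass(frozen=True)
class PairSpec:
    """A planted coupled column pair.

    ``diagnostic=False`` plants pure covariation with background marginals;
    ``diagnostic=True`` additionally makes both columns clade-diagnostic
    with purity ``q`` (dominant residues assigned by the generator).
    """

    col_i: int
    col_j: int
    rho: float = 1.0
    diagnostic: bool = False
    q: float = 0.9


@dataclass(frozen=True)
class CsiSpec:
    """A planted clade-exclusive insert block."""

    clade: str
    col_start: int
    col_end: int
    presence_prob: float = 1.0
    length_jitter: int = 0


@dataclass(frozen=True)
class SyntheticTruth:
    """Full description of the planted signal; with a seed it determines
    the generated alignment byte-for-byte."""

    seed: int
    planted_cdps: tuple[CdpSpec, ...] = ()
    planted_pairs: tuple[PairSpec, ...] = ()
    planted_csis: tuple[CsiSpec, ...] = ()
    background_concentration: float = 0.5

    def cdp_columns(self) -> frozenset[int]:
        cols = {c.column for c in self.planted_cdps}
        for p in self.planted_pairs:
            if p.diagnostic:
                cols |= {p.col_i, p.col_j}
        return frozenset(cols)

    def pair_set(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            (min(p.col_i, p.col_j), max(p.col_i, p.col_j))
            for p in self.planted_pairs
        )

    def reserved_columns(self) -> dict[int, str]:
        """column -> feature kind; raises on overlap."""
        out: dict[int, str] = {}

        def claim(col: int, kind: str) -> None:
            if col in out:
                raise GeneratorError(
                    f"planted features overlap at column {col} "
                    f"({out[col]} and {kind})"
                )
            out[col] = kind

        for c in self.planted_cdps:
            claim(c.column, "cdp")
        for p in self.planted_pairs:
            claim(p.col_i, "pair")
            claim(p.col_j, "pair")
        for s in self.planted_csis:
            for col in range(s.col_start, s.col_end + 1):
                claim(col, "csi")
        return out


@dataclass(frozen=True)
class GeneratedDataset:
    alignment: Alignment
    groups: GroupAssignment
    newick: str
    truth: SyntheticTruth
    # realized internals, useful for property checks
    bijections: dict[tuple[int, int], tuple[int, ...]] = field(default_factory=dict)
    csi_lengths: dict[tuple[str, int, int], dict[str, int]] = field(
        default_factory=dict
    )


def _caterpillar(labels: Sequence[str]) -> str:
    if len(labels) == 1:
        return f"{labels[0]}:1"
    node = f"({labels[0]}:1,{labels[1]}:1):1"
    for name in labels[2:]:
        node = f"({node},{name}:1):1"
    return node


def generate(
    n_per_clade: Mapping[str, int],
    n_cols: int,
    truth: SyntheticTruth,
) -> GeneratedDataset:
    """Generate (alignment, clade assignment, newick tree) with planted truth."""
    reserved = truth.reserved_columns()
    if reserved and max(reserved) > n_cols:
        raise GeneratorError(
            f"planted column {max(reserved)} exceeds n_cols={n_cols}"
        )
    clades = list(n_per_clade)
    for label, n in n_per_clade.items():
        if n < 2:
            raise GeneratorError(f"clade {label!r} needs at least 2 sequences")
    for spec in truth.planted_cdps:
        missing = [c for c in clades if c not in spec.dominant]
        if missing:
            raise GeneratorError(
                f"CDP column {spec.column} lacks dominant residues for {missing}"
            )
    for spec in truth.planted_csis:
        if spec.clade not in clades:
            raise GeneratorError(f"CSI clade {spec.clade!r} not among clades")

    rng = np.random.default_rng(truth.seed)
    ids: list[str] = []
    clade_of: dict[str, str] = {}
    clade_idx: dict[str, list[int]] = {label: [] for label in clades}
    for label in clades:
        for k in range(n_per_clade[label]):
            sid = f"{label}_{k:04d}"
            clade_idx[label].append(len(ids))
            clade_of[sid] = label
            ids.append(sid)
    n_seqs = len(ids)

    alpha = truth.background_concentration
    profiles = rng.dirichlet(np.full(N_AA, alpha), size=n_cols)  # (n_cols, 20)
    mat = np.empty((n_seqs, n_cols), dtype="<U1")

    aa = np.array(list(AMINO_ACIDS))

    def draw_bg(col0: int, size: int) -> np.ndarray:
        return rng.choice(N_AA, size=size, p=profiles[col0])

    # background everywhere first; planted features overwrite
    for c in range(n_cols):
        mat[:, c] = aa[draw_bg(c, n_seqs)]

    # diagnostic columns
    for spec in truth.planted_cdps:
        c0 = spec.column - 1
        for label in clades:
            rows = clade_idx[label]
            use_dom = rng.random(len(rows)) < spec.q
            bg = aa[draw_bg(c0, len(rows))]
            vals = np.where(use_dom, spec.dominant[label].upper(), bg)
            mat[rows, c0] = vals

    # coupled pairs
    bijections: dict[tuple[int, int], tuple[int, ...]] = {}
    for spec in truth.planted_pairs:
        i0, j0 = spec.col_i - 1, spec.col_j - 1
        sigma = rng.permutation(N_AA)
        key = (min(spec.col_i, spec.col_j), max(spec.col_i, spec.col_j))
        bijections[key] = tuple(int(v) for v in sigma)
        if spec.diagnostic:
            dom_i = rng.choice(N_AA, size=len(clades), replace=False)
        for ci, label in enumerate(clades):
            rows = clade_idx[label]
            n = len(rows)
            x = draw_bg(i0, n)
            coupled = rng.random(n) < spec.rho
            x_indep = draw_bg(i0, n)
            y = np.where(coupled, sigma[x], sigma[x_indep])
            if spec.diagnostic:
                dominant = rng.random(n) < spec.q
                x = np.where(dominant, dom_i[ci], x)
                y = np.where(dominant, sigma[dom_i[ci]], y)
            mat[rows, i0] = aa[x]
            mat[rows, j0] = aa[y]

    # clade-specific inserts
    csi_lengths: dict[tuple[str, int, int], dict[str, int]] = {}
    for spec in truth.planted_csis:
        s0, e0 = spec.col_start - 1, spec.col_end - 1
        width = e0 - s0 + 1
        lengths: dict[str, int] = {}
        mat[:, s0 : e0 + 1] = "-"
        for label in clades:
            rows = clade_idx[label]
            if label != spec.clade:
                for r in rows:
                    lengths.setdefault(ids[r], 0)
                continue
            for r in rows:
                if rng.random() >= spec.presence_prob:
                    lengths[ids[r]] = 0
                    continue
                trim = int(rng.integers(0, spec.length_jitter + 1))
                occ = width - trim
                for k in range(occ):
                    c0 = s0 + k
                    mat[r, c0] = aa[draw_bg(c0, 1)[0]]
                lengths[ids[r]] = occ
        csi_lengths[(spec.clade, spec.col_start, spec.col_end)] = {
            sid: n for sid, n in lengths.items() if clade_of[sid] == spec.clade
        }

    aln = alignment_from_records(
        (sid, "".join(mat[i])) for i, sid in enumerate(ids)
    )
    groups = GroupAssignment(
        groups={
            label: frozenset(sid for sid in ids if clade_of[sid] == label)
            for label in clades
        },
        focal_pair=tuple(clades[:2]) if len(clades) >= 2 else None,
    )
    subtrees = [
        f"({_caterpillar([ids[i] for i in clade_idx[label]])}):1"
        for label in clades
    ]
    newick = f"({_caterpillar_join(subtrees)});"
    return GeneratedDataset(
        alignment=aln,
        groups=groups,
        newick=newick,
        truth=truth,
        bijections=bijections,
        csi_lengths=csi_lengths,
    )


def _caterpillar_join(subtrees: list[str]) -> str:
    if len(subtrees) == 1:
        return subtrees[0]
    node = f"({subtrees[0]},{subtrees[1]}):1"
    for s in subtrees[2:]:
        node = f"({node},{s}):1"
    return node


@dataclass(frozen=True)
class RecoveryMetrics:
    """Sensitivity/precision of a stage's output against the planted truth.

    ``precision`` is None when nothing was called (undefined, reported as
    null rather than 0 or 1).  ``boundary_error`` is the largest absolute
    boundary deviation over matched insert intervals, None when no feature
    has boundaries.
    """

    sensitivity: float
    precision: float | None
    boundary_error: float | None = None


def compare_cdp_columns(
    found: set[int] | frozenset[int], truth: SyntheticTruth
) -> RecoveryMetrics:
    planted = truth.cdp_columns()
    tp = len(planted & set(found))
    sens = tp / len(planted) if planted else 1.0
    prec = tp / len(found) if found else None
    return RecoveryMetrics(sensitivity=sens, precision=prec)


def compare_pairs(
    found: set[tuple[int, int]], truth: SyntheticTruth
) -> RecoveryMetrics:
    norm = {(min(i, j), max(i, j)) for i, j in found}
    planted = truth.pair_set()
    tp = len(planted & norm)
    sens = tp / len(planted) if planted else 1.0
    prec = tp / len(norm) if norm else None
    return RecoveryMetrics(sensitivity=sens, precision=prec)


def compare_csis(
    calls: list[InsertCall], truth: SyntheticTruth
) -> RecoveryMetrics:
    planted = [
        (s.clade, s.col_start, s.col_end) for s in truth.planted_csis
    ]
    matched = 0
    boundary_errors = []
    used: set[int] = set()
    for clade, start, end in planted:
        best = None
        for k, call in enumerate(calls):
            if k in used or call.clade != clade:
                continue
            overlap = min(end, call.col_end) - max(start, call.col_start) + 1
            if overlap > 0:
                err = max(abs(call.col_start - start), abs(call.col_end - end))
                if best is None or err < best[1]:
                    best = (k, err)
        if best is not None:
            used.add(best[0])
            matched += 1
            boundary_errors.append(best[1])
    sens = matched / len(planted) if planted else 1.0
    prec = matched / len(calls) if calls else None
    return RecoveryMetrics(
        sensitivity=sens,
        precision=prec,
        boundary_error=float(max(boundary_errors)) if boundary_errors else None,
    )


def truth_compare(result, truth: SyntheticTruth) -> RecoveryMetrics:
    """Dispatch on the result type: CDP column sets, pair sets or CSI calls."""
    if isinstance(result, (set, frozenset)):
        sample = next(iter(result), None)
        if sample is None:
            # empty result: undefined precision against whichever truth is richer
            if truth.planted_csis:
                return compare_csis([], truth)
            if truth.pair_set():
                return compare_pairs(set(), truth)
            return compare_cdp_columns(set(), truth)
        if isinstance(sample, tuple):
            return compare_pairs(result, truth)
        return compare_cdp_columns(result, truth)
    if isinstance(result, list) and all(isinstance(c, InsertCall) for c in result):
        return compare_csis(result, truth)
    raise TypeError(f"cannot compare result of type {type(result)!r} to truth")
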