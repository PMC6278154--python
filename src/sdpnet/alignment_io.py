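"""Aligned-FASTA input/output, reference numbering, column statistics and trimming.

The central container is :class:`Alignment`, a rectangular protein multiple
sequence alignment over the 20 standard amino acids plus ``X`` (unknown
residue) and ``-`` (gap).  Columns are addressed 1-based in every public
structure and report; the internal numpy code matrix is an implementation
detail.

Trimming follows the common gap-fraction / entropy recipe used to strip
poorly aligned regions before tree building: a column is kept when its gap
fraction is at most ``g`` and its normalised Shannon entropy is at most
``h``.  The entropy here is the plain Shannon entropy of the residue
frequencies (gaps and ``X`` excluded) divided by ln 20, so a fully conserved
column scores 0 and a column with all twenty residues equally represented
scores 1.  This is deliberately a transparent, BMGE-like criterion rather
than a bit-compatible reimplementation of any particular trimmer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = AMINO_ACIDS + UNKNOWN + GAP

# integer codes: 0..19 amino acids, 20 = X, 21 = gap
_CODE = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_CODE[UNKNOWN] = 20
_CODE[GAP] = 21
N_AA = 20
X_CODE = 20
GAP_CODE = 21

_DECODE = np.array(list(AMINO_ACIDS + UNKNOWN + GAP))


class AlignmentError(ValueError):
    """Malformed alignment: ragged rows, duplicate ids or illegal characters."""


@dataclass(frozen=True)
class Alignment:
    """A rectangular protein MSA with stable, unique sequence identifiers."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise AlignmentError("alignment has no sequences")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise AlignmentError(f"duplicate sequence id: {i!r}")
                seen.add(i)
        n = len(self.rows[0])
        if n < 1:
            raise AlignmentError("alignment has zero columns")
        for sid, row in zip(self.ids, self.rows):
            if len(row) != n:
                raise AlignmentError(
                    f"ragged alignment: sequence {sid!r} has length "
                    f"{len(row)}, expected {n}"
                )
            for pos, ch in enumerate(row):
                if ch not in _CODE:
                    raise AlignmentError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {pos + 1}"
                    )

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def codes(self) -> np.ndarray:
        """Integer code matrix, shape (n_seqs, n_cols); 0..19 AA, 20 X, 21 gap."""
        flat = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        lut = np.full(128, 255, dtype=np.uint8)
        for ch, c in _CODE.items():
            lut[ord(ch)] = c
        return lut[flat].reshape(self.n_seqs, self.n_cols).astype(np.int64)

    def row(self, sid: str) -> str:
        try:
            return self.rows[self.ids.index(sid)]
        except ValueError:
            raise KeyError(f"no sequence with id {sid!r}") from None

    def subset_rows(self, keep_ids: Iterable[str]) -> "Alignment":
        """Rows restricted to ``keep_ids``, original order preserved."""
        keep = set(keep_ids)
        idx = [i for i, sid in enumerate(self.ids) if sid in keep]
        if not idx:
            raise AlignmentError("no sequences left after row subset")
        return Alignment(
            ids=tuple(self.ids[i] for i in idx),
            rows=tuple(self.rows[i] for i in idx),
        )

    def subset_columns(self, columns_1based: Sequence[int]) -> "Alignment":
        """Columns restricted to the given 1-based indices, in the given order."""
        cols = [c - 1 for c in columns_1based]
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return Alignment(ids=self.ids, rows=rows)


def alignment_from_records(records: Iterable[tuple[str, str]]) -> Alignment:
    """Build an :class:`Alignment` from (id, row) pairs; rows are upper-cased."""
    ids, rows = [], []
    for sid, row in records:
        if not sid:
            raise AlignmentError("empty sequence id")
        ids.append(sid)
        rows.append(row.upper())
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def read_alignment(path: str | Path, dialect: str = "fasta") -> Alignment:
    """Read an aligned FASTA file, preserving sequence order.

    Raises :class:`AlignmentError` on ragged rows, duplicate ids or
    characters outside the 20-amino-acid + ``X`` + ``-`` alphabet.
    """
    if dialect != "fasta":
        raise ValueError(f"unsupported dialect {dialect!r}")
    recs = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not recs:
        raise AlignmentError(f"no sequences parsed from {path}")
    return alignment_from_records(recs)


def write_alignment(aln: Alignment, path: str | Path, width: int = 60) -> None:
    """Write aligned FASTA, wrapping rows at ``width`` characters."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional map between alignment columns and reference numbering.

    Defined exactly on the columns where the reference row is non-gap;
    residue numbers increase strictly with column index.  All columns are
    1-based.
    """

    reference_id: str
    col_to_ref: dict[int, int]
    ref_to_col: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ref_to_col:
            object.__setattr__(
                self, "ref_to_col", {v: k for k, v in self.col_to_ref.items()}
            )

    def ref_position(self, column_1based: int) -> int | None:
        return self.col_to_ref.get(column_1based)

    def column(self, ref_number: int) -> int | None:
        return self.ref_to_col.get(ref_number)


def build_column_map(
    aln: Alignment, reference_id: str, first_residue_number: int = 1
) -> ColumnMap:
    """Number the reference sequence's non-gap columns consecutively.

    Matches the convention of quoting alignment positions in the residue
    numbering of a reference structure.
    """
    row = aln.row(reference_id)  # KeyError if unknown
    col_to_ref: dict[int, int] = {}
    n = first_residue_number
    for c, ch in enumerate(row, start=1):
        if ch != GAP:
            col_to_ref[c] = n
            n += 1
    if not col_to_ref:
        raise AlignmentError(f"reference {reference_id!r} is all gaps")
    return ColumnMap(reference_id=reference_id, col_to_ref=col_to_ref)


@dataclass(frozen=True)
class ColumnStats:
    """Per-column gap fraction and normalised entropy (gaps and X excluded)."""

    column: int  # 1-based
    gap_fraction: float
    entropy_norm: float
    occupancy: float
    all_gap: bool


def column_stats(aln: Alignment) -> list[ColumnStats]:
    codes = aln.codes()
    n_seqs = aln.n_seqs
    out = []
    for c in range(aln.n_cols):
        col = codes[:, c]
        gap_fraction = float(np.mean(col == GAP_CODE))
        residues = col[col < N_AA]  # X excluded from frequencies
        if residues.size == 0:
            out.append(
                ColumnStats(
                    column=c + 1,
                    gap_fraction=gap_fraction,
                    entropy_norm=0.0,
                    occupancy=1.0 - gap_fraction,
                    all_gap=True,
                )
            )
            continue
        counts = np.bincount(residues, minlength=N_AA).astype(float)
        p = counts / counts.sum()
        nz = p[p > 0]
        h = float(-(nz * np.log(nz)).sum()) / np.log(N_AA)
        out.append(
            ColumnStats(
                column=c + 1,
                gap_fraction=gap_fraction,
                entropy_norm=h,
                occupancy=1.0 - gap_fraction,
                all_gap=False,
            )
        )
    return out


def trim_alignment(
    aln: Alignment, g: float = 0.3, h: float = 0.8
) -> tuple[Alignment, list[int]]:
    """Keep columns with gap_fraction <= g and entropy_norm <= h.

    Returns the trimmed alignment and the kept columns in original 1-based
    coordinates.  Columns with no countable residues (all gap or all X) are
    always removed.
    """
    if not (0.0 <= g <= 1.0):
        raise ValueError(f"gap threshold g={g} outside [0, 1]")
    if not (0.0 <= h <= 1.0):
        raise ValueError(f"entropy threshold h={h} outside [0, 1]")
    stats = column_stats(aln)
    kept = [
        s.column
        for s in stats
        if not s.all_gap and s.gap_fraction <= g and s.entropy_norm <= h
    ]
    if not kept:
        raise AlignmentError("trimming removed every column")
    return aln.subset_columns(kept), kept


def column_report(aln: Alignment, g: float = 0.3, h: float = 0.8):
    """Per-column TSV-ready table: column, gap_fraction, entropy_norm, kept."""
    import pandas as pd

    stats = column_stats(aln)
    rows = [
        {
            "column": s.column,
            "gap_fraction": s.gap_fraction,
            "entropy_norm": s.entropy_norm,
            "kept": (not s.all_gap) and s.gap_fraction <= g and s.entropy_norm <= h,
        }
        for s in stats
    ]
    return pd.DataFrame(rows)
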