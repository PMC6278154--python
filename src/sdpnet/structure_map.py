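"""Mapping alignment positions onto a PDB-format structure and distance queries.

The reference structure convention: positions produced by the alignment
analysis are quoted in the residue numbering of a reference crystal
structure, so proximity questions ("is this position within 5 A of the
catalytic site?") reduce to minimum inter-atomic distance queries on the
coordinate file.  Distances default to heavy atoms, since crystal
structures usually lack hydrogens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning
from scipy.spatial.distance import cdist


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass(frozen=True)
class Residue:
    number: int
    insertion_code: str
    name: str
    atoms: tuple[Atom, ...]
    is_hetero: bool = False


@dataclass(frozen=True)
class StructureModel:
    """First model of a PDB file: chains of residues with atom coordinates.

    Alternate locations are resolved to the highest-occupancy conformer;
    HETATM residues (ions, ligands, waters) are retained with a flag.
    """

    chains: dict[str, tuple[Residue, ...]]
    source: str = ""

    def residue(self, chain: str, number: int, icode: str = " ") -> Residue:
        for r in self.chains.get(chain, ()):
            if r.number == number and r.insertion_code == icode:
                return r
        raise StructureError(f"residue {chain}:{number}{icode.strip()} not found")


def read_structure(path: str | Path) -> StructureModel:
    """Parse the first model of a PDB-format file."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        structure = parser.get_structure("s", str(path))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise StructureError(f"no models in {path}") from None
    chains: dict[str, tuple[Residue, ...]] = {}
    n_atoms = 0
    for chain in model:
        residues = []
        for res in chain:
            hetflag, resnum, icode = res.get_id()
            atoms = []
            for atom in res:
                if atom.is_disordered():
                    # keep the highest-occupancy alternate location
                    best = max(
                        atom.disordered_get_list(),
                        key=lambda a: (a.get_occupancy() or 0.0),
                    )
                else:
                    best = atom
                x, y, z = (float(v) for v in best.get_coord())
                if not all(np.isfinite([x, y, z])):
                    raise StructureError(
                        f"non-finite coordinates at {chain.id}:{resnum}"
                    )
                atoms.append(
                    Atom(
                        name=best.get_name(),
                        element=(best.element or "").strip().upper(),
                        coord=(x, y, z),
                    )
                )
            n_atoms += len(atoms)
            residues.append(
                Residue(
                    number=int(resnum),
                    insertion_code=icode if icode.strip() else " ",
                    name=res.get_resname().strip(),
                    atoms=tuple(atoms),
                    is_hetero=hetflag.strip() != "",
                )
            )
        if residues:
            chains[chain.id] = tuple(residues)
    if n_atoms == 0:
        raise StructureError(f"no ATOM records in {path}")
    return StructureModel(chains=chains, source=str(path))


Selection = Iterable[tuple[str, int]]  # (chain id, residue number) pairs


def _coords(
    s: StructureModel, selection: Selection, atoms: str
) -> np.ndarray:
    if atoms not in ("heavy", "all", "CA"):
        raise ValueError(f"unknown atom filter {atoms!r}")
    pts = []
    names = []
    for chain, number in selection:
        res = s.residue(chain, number)
        for a in res.atoms:
            if atoms == "CA" and a.name != "CA":
                continue
            if atoms == "heavy" and a.element == "H":
                continue
            pts.append(a.coord)
        names.append(f"{chain}:{number}")
    if not pts:
        raise StructureError(
            f"selection {names} resolves to no atoms under filter {atoms!r}"
        )
    return np.asarray(pts, dtype=float)


def min_distance(
    s: StructureModel,
    sel_a: Selection,
    sel_b: Selection,
    atoms: str = "heavy",
) -> float:
    """Minimum pairwise inter-atomic distance (A) between two selections."""
    a = _coords(s, list(sel_a), atoms)
    b = _coords(s, list(sel_b), atoms)
    return float(cdist(a, b).min())


def proximity_report(
    s: StructureModel,
    positions: Iterable[int],
    site: Iterable[int],
    chain: str = "A",
    cutoff: float = 5.0,
    atoms: str = "heavy",
) -> pd.DataFrame:
    """Minimum distance of each position to a residue site, with a cutoff flag.

    Positions that do not resolve in the stated chain are listed as
    unmapped (distance NaN) rather than dropped.
    """
    site_sel = [(chain, n) for n in site]
    rows = []
    for pos in positions:
        try:
            d = min_distance(s, [(chain, pos)], site_sel, atoms=atoms)
            rows.append(
                {
                    "position": pos,
                    "min_distance": d,
                    "within_cutoff": d <= cutoff,
                    "unmapped": False,
                }
            )
        except StructureError:
            rows.append(
                {
                    "position": pos,
                    "min_distance": float("nan"),
                    "within_cutoff": False,
                    "unmapped": True,
                }
            )
    return pd.DataFrame(rows)
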