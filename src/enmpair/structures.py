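"""Cα-level structure I/O.

Reads coarse-grained (one node per residue) structures from PDB files,
carrying the experimental B-factor column, and pairs residues between two
conformers of the same protein so per-residue quantities can be compared.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio

logger = logging.getLogger(__name__)

ResidueId = tuple[str, int, str]  # (chain, residue number, insertion code)


class StructureError(ValueError):
    """Base class for structure parsing/pairing failures."""


class NoCalphaError(StructureError):
    """Raised when a file or chain contains no Cα atoms."""


class ChainNotFoundError(StructureError):
    """Raised when the requested chain is absent."""


class EmptyPairingError(StructureError):
    """Raised when two structures share no residue identifiers."""


@dataclass
class CalphaStructure:
    """One Cα node per residue, in file order.

    Attributes
    ----------
    residue_id:
        ``(chain, residue number, insertion code)`` per residue, author
        numbering as deposited.
    residue_name:
        Three-letter residue code per residue.
    coords:
        ``(N, 3)`` Cα positions in Å.
    exp_bfactor:
        Experimental B-factors in Å², or ``None`` if the column is absent.
    source_label:
        Free-text provenance (file name, PDB ID, generator spec).
    """

    residue_id: list[ResidueId]
    residue_name: list[str]
    coords: np.ndarray
    exp_bfactor: np.ndarray | None = None
    source_label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residue_id)
        if n < 1:
            raise StructureError("structure must contain at least one residue")
        if self.coords.shape != (n, 3):
            raise StructureError(
                f"coords shape {self.coords.shape} does not match {n} residues"
            )
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if len(set(self.residue_id)) != n:
            raise StructureError("duplicated residue identifiers")
        if len(self.residue_name) != n:
            raise StructureError("residue_name length mismatch")
        if self.exp_bfactor is not None:
            self.exp_bfactor = np.asarray(self.exp_bfactor, dtype=float)
            if self.exp_bfactor.shape != (n,):
                raise StructureError("exp_bfactor length mismatch")
            if np.any(self.exp_bfactor < 0):
                raise StructureError("negative experimental B-factor")

    @property
    def n_residues(self) -> int:
        return len(self.residue_id)

    def residue_numbers(self) -> np.ndarray:
        """Author residue numbers as an integer array."""
        return np.array([rid[1] for rid in self.residue_id], dtype=int)

    def with_coords(self, coords: np.ndarray, source_label: str | None = None) -> "CalphaStructure":
        """Copy of this structure with replaced coordinates."""
        return CalphaStructure(
            residue_id=list(self.residue_id),
            residue_name=list(self.residue_name),
            coords=np.array(coords, dtype=float),
            exp_bfactor=None if self.exp_bfactor is None else self.exp_bfactor.copy(),
            source_label=self.source_label if source_label is None else source_label,
        )


@dataclass
class ResiduePairing:
    """One-to-one residue correspondence between two structures.

    ``index_pairs`` holds ``(index into A, index into B)`` sorted by A's
    sequence order; ``coverage`` is the fraction of A's residues paired.
    """

    index_pairs: list[tuple[int, int]]
    coverage: float

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([i for i, _ in self.index_pairs], dtype=int)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([j for _, j in self.index_pairs], dtype=int)

    def __len__(self) -> int:
        return len(self.index_pairs)


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def read_calpha(
    path: str | Path,
    chain: str | None = None,
    model: int = 1,
) -> CalphaStructure:
    """Read the Cα trace of one chain/model from a PDB file.

    HETATM records are ignored, so waters and ligands never enter the
    elastic network; non-standard residues with a CA atom are kept.
    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by the alphabetically first altloc code).  When ``chain``
    is ``None`` and the file holds several chains, the first chain with Cα
    atoms is used and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PDB file not found: {path}")
    with _open_maybe_gzip(path) as fh:
        pdb_file = pdbio.PDBFile.read(fh)
    atoms = pdbio.get_structure(
        pdb_file, model=model, altloc="all", extra_fields=["b_factor", "occupancy"]
    )
    atoms = atoms[~atoms.hetero]
    atoms = atoms[atoms.atom_name == "CA"]
    if atoms.array_length() == 0:
        raise NoCalphaError(f"no Cα atoms found in {path} (model {model})")

    chains_present = list(dict.fromkeys(atoms.chain_id.tolist()))
    if chain is None:
        chain = chains_present[0]
        if len(chains_present) > 1:
            logger.warning(
                "%s has chains %s; defaulting to first chain %r",
                path.name, chains_present, chain,
            )
    elif chain not in chains_present:
        raise ChainNotFoundError(
            f"chain {chain!r} not found in {path}; available: {chains_present}"
        )
    atoms = atoms[atoms.chain_id == chain]
    if atoms.array_length() == 0:
        raise NoCalphaError(f"no Cα atoms in chain {chain!r} of {path}")

    # Resolve altlocs per residue: highest occupancy, then lowest altloc code.
    best: dict[ResidueId, tuple[float, str, int]] = {}
    order: list[ResidueId] = []
    for i in range(atoms.array_length()):
        rid: ResidueId = (
            str(atoms.chain_id[i]),
            int(atoms.res_id[i]),
            str(atoms.ins_code[i]).strip(),
        )
        occ = float(atoms.occupancy[i])
        alt = str(atoms.altloc_id[i]).strip()
        if rid not in best:
            order.append(rid)
            best[rid] = (occ, alt, i)
        else:
            occ0, alt0, _ = best[rid]
            if (-occ, alt) < (-occ0, alt0):
                best[rid] = (occ, alt, i)

    idx = [best[rid][2] for rid in order]
    return CalphaStructure(
        residue_id=order,
        residue_name=[str(atoms.res_name[i]) for i in idx],
        coords=atoms.coord[idx].astype(float),
        exp_bfactor=atoms.b_factor[idx].astype(float),
        source_label=path.name,
    )


def pair_residues(a: CalphaStructure, b: CalphaStructure) -> ResiduePairing:
    """Match residues of two conformers by (chain, number, insertion code).

    Unmatched residues are dropped; pairs follow A's sequence order.
    """
    b_lookup = {rid: j for j, rid in enumerate(b.residue_id)}
    pairs = [(i, b_lookup[rid]) for i, rid in enumerate(a.residue_id) if rid in b_lookup]
    if not pairs:
        raise EmptyPairingError(
            f"no common residues between {a.source_label!r} and {b.source_label!r}"
        )
    return ResiduePairing(index_pairs=pairs, coverage=len(pairs) / a.n_residues)


def write_profile_table(
    structure: CalphaStructure,
    columns: dict[str, Sequence[float]],
    path: str | Path,
) -> None:
    """Write labelled per-residue values as a CSV table.

    The table carries (chain, resnum, icode, resname) identifier columns
    followed by one column per quantity; values are written unrounded so a
    round-trip read reproduces them to printed precision.
    """
    n = structure.n_residues
    data: dict[str, list] = {
        "chain": [rid[0] for rid in structure.residue_id],
        "resnum": [rid[1] for rid in structure.residue_id],
        "icode": [rid[2] for rid in structure.residue_id],
        "resname": list(structure.residue_name),
    }
    for name, values in columns.items():
        values = np.asarray(values)
        if values.shape != (n,):
            raise ValueError(f"column {name!r} has length {values.shape}, expected {n}")
        data[name] = values.tolist()
    pd.DataFrame(data).to_csv(path, index=False)


def write_calpha_pdb(structure: CalphaStructure, path: str | Path,
                     bfactor: np.ndarray | None = None) -> None:
    """Write a Cα-only PDB file (ATOM records, occupancy 1.00).

    ``bfactor`` overrides the structure's experimental column; absent both,
    zeros are written.
    """
    n = structure.n_residues
    atoms = struc.AtomArray(n)
    atoms.coord = structure.coords.astype(np.float32)
    atoms.chain_id = np.array([rid[0] or "A" for rid in structure.residue_id])
    atoms.res_id = np.array([rid[1] for rid in structure.residue_id], dtype=int)
    atoms.ins_code = np.array([rid[2] for rid in structure.residue_id])
    atoms.res_name = np.array(structure.residue_name)
    atoms.atom_name = np.array(["CA"] * n)
    atoms.element = np.array(["C"] * n)
    atoms.hetero = np.zeros(n, dtype=bool)
    atoms.set_annotation("occupancy", np.ones(n))
    b = bfactor if bfactor is not None else structure.exp_bfactor
    atoms.set_annotation("b_factor", np.zeros(n) if b is None else np.asarray(b, float))
    pdb_file = pdbio.PDBFile()
    pdbio.set_structure(pdb_file, atoms)
    pdb_file.write(str(path))


def select_residues(
    structure: CalphaStructure,
    selection: Iterable[tuple[int, int]] | Sequence[int] | np.ndarray,
) -> np.ndarray:
    """Resolve a residue selection to positional indices.

    ``selection`` is either a list of inclusive author-number ranges
    ``[(lo, hi), ...]`` or an explicit array of positional indices / boolean
    mask of length N.
    """
    sel = list(selection)
    if sel and isinstance(sel[0], tuple):
        numbers = structure.residue_numbers()
        mask = np.zeros(structure.n_residues, dtype=bool)
        for lo, hi in sel:
            mask |= (numbers >= lo) & (numbers <= hi)
        return np.flatnonzero(mask)
    arr = np.asarray(sel)
    if arr.dtype == bool:
        if arr.shape != (structure.n_residues,):
            raise ValueError("boolean selection mask has wrong length")
        return np.flatnonzero(arr)
    return arr.astype(int)
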