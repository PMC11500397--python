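"""Protein structure parsing, PDB writing and amino-acid composition.

Parsing is backed by Biopython's :class:`Bio.PDB.PDBParser`; the parsed model
is flattened into plain dataclasses so the rest of the pipeline never touches
SMCRA objects.  Only the 20 standard amino acids enter the residue list;
waters and ions encountered in the file are kept on side lists so solvated
systems written by :mod:`parchlab.solvation` round-trip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionException

from .constants import (
    AA_SET,
    FORMAL_CHARGE,
    ION_RESNAMES,
    ONE_TO_THREE,
    THREE_TO_ONE,
    WATER_RESNAMES,
)
from .errors import EmptyStructureError, FormatError

__all__ = [
    "Atom",
    "ResidueRecord",
    "ProteinStructure",
    "CompositionTable",
    "read_structure",
    "write_structure",
    "composition",
    "compare_composition",
]


@dataclass
class Atom:
    """A single atom: label, element and Cartesian coordinates in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be a finite 3-vector")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class ResidueRecord:
    """One standard amino-acid residue with its atoms."""

    chain_id: str
    seq_index: int
    aa_type: str
    atoms: list[Atom] = field(default_factory=list)

    def __post_init__(self):
        if self.aa_type not in AA_SET:
            raise ValueError(f"{self.aa_type!r} is not a standard amino-acid code")

    @property
    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass
class ProteinStructure:
    """An ordered collection of standard residues plus any co-parsed solvent.

    ``solvent`` holds water-oxygen coordinates (n, 3) and ``ions`` a list of
    ``(species, coords)`` pairs; both are populated when reading files written
    by :func:`parchlab.solvation.write_system`.
    """

    id: str
    residues: list[ResidueRecord]
    his_charge: int = 0
    solvent: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    ions: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def __post_init__(self):
        if not self.residues:
            raise EmptyStructureError(f"{self.id}: no standard amino-acid residues")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def net_charge(self) -> int:
        """Formal charge at neutral pH: K,R → +1; D,E → −1; H → ``his_charge``."""
        total = 0
        for res in self.residues:
            if res.aa_type == "H":
                total += self.his_charge
            else:
                total += FORMAL_CHARGE[res.aa_type]
        return total

    @property
    def sequence(self) -> str:
        return "".join(r.aa_type for r in self.residues)


@dataclass
class CompositionTable:
    """Counts and percent abundances of the 20 amino acids."""

    counts: dict[str, int]
    fractions: dict[str, float]


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if stripped[0] in "H123456789" and name[:1].isdigit():
        return "H"
    if stripped[0] == "H":
        return "H"
    return stripped[0]


def read_structure(path, model_index: int = 0, his_charge: int = 0) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Parameters
    ----------
    path : path-like
        PDB file with ATOM/HETATM (and optionally MODEL) records.
    model_index : int
        0-based index into the file's models; multi-conformation files default
        to the first model.
    his_charge : int
        Formal charge assigned to histidine (0 at neutral pH by default).

    Notes
    -----
    Nonstandard residues are skipped with a warning rather than remapped.
    Waters (HOH/WAT/...) go to ``structure.solvent``; recognised monatomic
    ions go to ``structure.ions``.  For altloc disorder Biopython's
    highest-occupancy conformer is kept (ties: first listed).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    try:
        bp = parser.get_structure(path.stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise FormatError(f"{path}: unparseable PDB file ({exc})") from exc

    models = list(bp)
    if not models:
        raise EmptyStructureError(f"{path}: file contains no coordinates")
    if not 0 <= model_index < len(models):
        raise IndexError(
            f"model_index {model_index} out of range: file has {len(models)} model(s)"
        )
    model = models[model_index]

    residues: list[ResidueRecord] = []
    solvent: list[np.ndarray] = []
    ions: list[tuple[str, np.ndarray]] = []
    for chain in model:
        for res in chain:
            resname = res.get_resname().strip()
            if resname in WATER_RESNAMES:
                for atom in res:
                    elem = (atom.element or _guess_element(atom.get_name())).upper()
                    if elem == "O":
                        solvent.append(np.asarray(atom.get_coord(), dtype=float))
                continue
            if resname in ION_RESNAMES and len(res) == 1:
                atom = next(iter(res))
                ions.append((ION_RESNAMES[resname],
                             np.asarray(atom.get_coord(), dtype=float)))
                continue
            if resname not in THREE_TO_ONE:
                warnings.warn(
                    f"{path.name}: skipping nonstandard residue {resname} "
                    f"{chain.id}{res.id[1]}",
                    stacklevel=2,
                )
                continue
            atoms = [
                Atom(
                    name=a.get_name(),
                    element=(a.element or _guess_element(a.get_name())).upper(),
                    coords=np.asarray(a.get_coord(), dtype=float),
                )
                for a in res
            ]
            record = ResidueRecord(
                chain_id=chain.id,
                seq_index=res.id[1],
                aa_type=THREE_TO_ONE[resname],
                atoms=atoms,
            )
            if not record.heavy_atoms:
                warnings.warn(
                    f"{path.name}: residue {resname} {chain.id}{res.id[1]} has no "
                    "heavy atoms; skipped",
                    stacklevel=2,
                )
                continue
            residues.append(record)

    if not residues:
        raise EmptyStructureError(f"{path}: no standard amino-acid residues")
    solvent_arr = np.asarray(solvent) if solvent else np.empty((0, 3))
    return ProteinStructure(
        id=path.stem, residues=residues, his_charge=his_charge,
        solvent=solvent_arr, ions=ions,
    )


# ---------------------------------------------------------------------------
# PDB output
# ---------------------------------------------------------------------------

def _pdb_line(record: str, serial: int, name: str, resname: str, chain: str,
              resseq: int, coords: np.ndarray, element: str) -> str:
    name_field = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial % 100000:>5d} {name_field[:4]} {resname:<3s} "
        f"{chain[:1]}{resseq % 10000:>4d}    "
        f"{coords[0]:8.3f}{coords[1]:8.3f}{coords[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {element:>2s}\n"
    )


def write_structure(structure: ProteinStructure, path, waters=None, ions=None) -> None:
    """Write a structure (optionally with waters/ions) as a PDB file.

    ``waters`` is an iterable of (id, coords) pairs or bare coordinate
    3-vectors; ``ions`` an iterable of (species, coords) pairs.
    """
    path = Path(path)
    serial = 1
    with path.open("w") as fh:
        for res in structure.residues:
            resname = ONE_TO_THREE[res.aa_type]
            for atom in res.atoms:
                fh.write(_pdb_line("ATOM", serial, atom.name, resname,
                                   res.chain_id, res.seq_index, atom.coords,
                                   atom.element))
                serial += 1
        fh.write("TER\n")
        wat_seq = 1
        for entry in (waters if waters is not None else []):
            coords = entry[1] if isinstance(entry, tuple) else getattr(entry, "coords", entry)
            fh.write(_pdb_line("HETATM", serial, "O", "HOH", "W",
                               wat_seq, np.asarray(coords, dtype=float), "O"))
            serial += 1
            wat_seq += 1
        ion_seq = 1
        for entry in (ions if ions is not None else []):
            species = entry[0] if isinstance(entry, tuple) else entry.species
            coords = entry[1] if isinstance(entry, tuple) else entry.coords
            resname = "NA" if species.startswith("Na") else "CL"
            fh.write(_pdb_line("HETATM", serial, resname, resname, "I",
                               ion_seq, np.asarray(coords, dtype=float),
                               resname[:2].strip()))
            serial += 1
            ion_seq += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Composition statistics
# ---------------------------------------------------------------------------

def composition(structure: ProteinStructure) -> CompositionTable:
    """Counts and percent abundances of each amino-acid type (all 20 keys present)."""
    counts = {aa: 0 for aa in sorted(AA_SET)}
    for res in structure.residues:
        counts[res.aa_type] += 1
    total = sum(counts.values())
    fractions = {aa: 100.0 * c / total for aa, c in counts.items()}
    return CompositionTable(counts=counts, fractions=fractions)


def compare_composition(a: CompositionTable, b: CompositionTable) -> dict[str, float]:
    """Signed percent-abundance difference per residue type (a − b).

    Types missing from either table are treated as 0%.  The differences sum
    to zero across the alphabet because each table sums to 100%.
    """
    alphabet = sorted(set(a.fractions) | set(b.fractions))
    return {aa: a.fractions.get(aa, 0.0) - b.fractions.get(aa, 0.0) for aa in alphabet}
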