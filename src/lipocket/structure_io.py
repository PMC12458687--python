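"""Structure parsing, ligand extraction, and curation-time geometric filters.

Heavy-atom geometry throughout: hydrogens (and deuterium) are dropped at
parse time.  Predicted models store per-residue confidence (pLDDT, 0-100)
in the B-factor column, so one ``StructureModel`` type serves both
experimental and predicted inputs; ``model_kind`` records which.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "StructureModel",
    "LigandInstance",
    "StructureError",
    "parse_structure",
    "write_pdb",
    "extract_standalone_ligands",
    "is_buried_ligand",
    "trim_n_terminal",
    "mean_plddt",
    "read_signal_peptide_table",
]

#: heavy-atom distance at or below which a ligand counts as covalently
#: attached to the polymer (longer than any standard covalent bond to a
#: heavy atom, shorter than any van der Waals contact)
COVALENT_CUTOFF = 1.9

WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


class StructureError(ValueError):
    """Raised for unreadable, empty, or contract-violating structures."""


@dataclass(frozen=True)
class AtomRecord:
    """A single heavy atom.

    ``b_factor`` holds the crystallographic B factor for experimental
    structures and the pLDDT confidence (0-100) for predicted models.
    ``residue_index`` is the author's 1-based numbering.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_index: int
    coords: tuple[float, float, float]
    b_factor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError("element symbol must be non-empty")
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError("atom coordinates must be finite")
        if self.b_factor < 0:
            raise ValueError("b_factor must be >= 0")


@dataclass(frozen=True)
class Residue:
    """A residue key plus the indices of its atoms within the parent model."""

    chain_id: str
    residue_index: int
    residue_name: str
    atom_indices: tuple[int, ...]

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class StructureModel:
    """Parsed heavy atoms of one structure model.

    ``polymer_residues`` lists protein residues in chain order; waters and
    hetero compounds are excluded from it but their atoms stay in ``atoms``
    so ligands can be recovered.
    """

    atoms: list[AtomRecord]
    source_id: str = ""
    model_kind: Literal["experimental", "predicted"] = "experimental"
    polymer_residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.polymer_residues:
            self.polymer_residues = _group_polymer_residues(self.atoms)
        for res in self.polymer_residues:
            if not res.atom_indices:
                raise StructureError(f"polymer residue {res.key} owns no atom")

    # -- convenience views -------------------------------------------------

    @property
    def n_residues(self) -> int:
        return len(self.polymer_residues)

    def polymer_coords(self) -> np.ndarray:
        idx = [i for r in self.polymer_residues for i in r.atom_indices]
        return np.array([self.atoms[i].coords for i in idx], dtype=float)

    def polymer_atom_indices(self) -> list[int]:
        return [i for r in self.polymer_residues for i in r.atom_indices]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residue_of_atom(self) -> dict[int, Residue]:
        out: dict[int, Residue] = {}
        for res in self.polymer_residues:
            for i in res.atom_indices:
                out[i] = res
        return out


@dataclass
class LigandInstance:
    """A standalone (non-covalent) hetero compound with its heavy atoms."""

    comp_id: str
    atoms: list[AtomRecord]
    center_of_mass: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("ligand must have at least one heavy atom")
        if self.comp_id != self.comp_id.upper():
            raise ValueError("comp_id must be uppercase")


def _group_polymer_residues(atoms: Sequence[AtomRecord]) -> list[Residue]:
    """Group non-hetero, non-water atoms into residues preserving file order."""
    order: list[tuple[str, int, str]] = []
    members: dict[tuple[str, int, str], list[int]] = {}
    for i, atom in enumerate(atoms):
        if atom.is_hetero or atom.residue_name in WATER_NAMES:
            continue
        key = (atom.chain_id, atom.residue_index, atom.residue_name)
        if key not in members:
            members[key] = []
            order.append(key)
        members[key].append(i)
    return [
        Residue(chain_id=c, residue_index=idx, residue_name=name,
                atom_indices=tuple(members[(c, idx, name)]))
        for (c, idx, name) in order
    ]


# ---------------------------------------------------------------------------
# parsing / writing
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def parse_structure(
    path: str | Path,
    fmt: Literal["pdb", "mmcif", "auto"] = "auto",
    model_kind: Literal["experimental", "predicted"] = "experimental",
) -> StructureModel:
    """Read a PDB or mmCIF file into a heavy-atom :class:`StructureModel`.

    Only the first model of multi-model files is read.  Alternate locations
    are resolved to the highest-occupancy conformer.  Hydrogens are dropped;
    waters are kept as atoms but excluded from the polymer residue list.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such structure file: {path}")
    if fmt == "auto":
        fmt = _detect_format(path)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    st.remove_alternative_conformations()  # keeps highest occupancy
    st.remove_hydrogens()

    if len(st) == 0:
        raise StructureError(f"empty structure: {path}")
    model = st[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            het = res.het_flag == "H"
            for atom in res:
                el = atom.element.name
                if el in ("H", "D"):
                    continue
                atoms.append(AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=el,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_index=res.seqid.num,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    b_factor=max(atom.b_iso, 0.0),
                    is_hetero=het,
                ))
    if not atoms:
        raise StructureError(f"no heavy atoms in {path}")
    return StructureModel(atoms=atoms, source_id=path.stem, model_kind=model_kind)


def write_pdb(structure: StructureModel, path: str | Path) -> None:
    """Write the model back out as minimal PDB text (ATOM/HETATM records)."""
    lines = []
    for i, a in enumerate(structure.atoms, start=1):
        record = "HETATM" if a.is_hetero else "ATOM  "
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        lines.append(
            f"{record}{i:5d} {name:<4.4s} {a.residue_name:>3.3s} "
            f"{a.chain_id[:1]:1s}{a.residue_index:4d}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{1.00:6.2f}{a.b_factor:6.2f}          {a.element:>2.2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ligand extraction and curation filters
# ---------------------------------------------------------------------------

def extract_standalone_ligands(
    structure: StructureModel,
    comp_ids: Iterable[str],
    covalent_cutoff: float = COVALENT_CUTOFF,
    mass_weighted: bool = False,
) -> list[LigandInstance]:
    """Return hetero residues matching ``comp_ids`` that are not covalently
    bound to the polymer.

    A ligand is covalent (and excluded) if any of its heavy atoms sits
    within ``covalent_cutoff`` of a polymer heavy atom.  The center of mass
    is the unweighted heavy-atom centroid unless ``mass_weighted``.
    """
    wanted = {c.upper() for c in comp_ids}
    if not wanted:
        raise ValueError("comp_ids must be non-empty")

    groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
    for atom in structure.atoms:
        if atom.is_hetero and atom.residue_name in wanted:
            groups.setdefault(
                (atom.chain_id, atom.residue_index, atom.residue_name), []
            ).append(atom)
    if not groups:
        return []

    poly = structure.polymer_coords()
    out: list[LigandInstance] = []
    for (chain, idx, comp), lig_atoms in groups.items():
        coords = np.array([a.coords for a in lig_atoms], dtype=float)
        if poly.size:
            dmin = np.min(np.linalg.norm(
                coords[:, None, :] - poly[None, :, :], axis=2))
            if dmin <= covalent_cutoff:
                continue
        if mass_weighted:
            masses = np.array([_atomic_mass(a.element) for a in lig_atoms])
            com = (coords * masses[:, None]).sum(0) / masses.sum()
        else:
            com = coords.mean(axis=0)
        out.append(LigandInstance(
            comp_id=comp, atoms=list(lig_atoms),
            center_of_mass=tuple(float(c) for c in com)))
    return out


_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "P": 30.974}


def _atomic_mass(element: str) -> float:
    return _MASSES.get(element, 12.011)


def is_buried_ligand(
    structure: StructureModel,
    ligand: LigandInstance,
    radius: float = 8.0,
    min_residues: int = 10,
) -> bool:
    """Surface-lipid filter: true iff at least ``min_residues`` distinct
    polymer residues have an atom within ``radius`` (closed interval) of the
    ligand center of mass."""
    com = np.asarray(ligand.center_of_mass, dtype=float)
    count = 0
    for res in structure.polymer_residues:
        coords = np.array(
            [structure.atoms[i].coords for i in res.atom_indices], dtype=float)
        if np.min(np.linalg.norm(coords - com, axis=1)) <= radius:
            count += 1
            if count >= min_residues:
                return True
    return count >= min_residues


def trim_n_terminal(structure: StructureModel, cut_site: int) -> StructureModel:
    """Remove the first ``cut_site`` polymer residues (a cleaved signal
    peptide) together with their atoms; ``cut_site = 0`` is the identity."""
    n = structure.n_residues
    if not 0 <= cut_site < n:
        raise StructureError(
            f"cut_site {cut_site} out of range for {n}-residue model")
    if cut_site == 0:
        return StructureModel(
            atoms=list(structure.atoms), source_id=structure.source_id,
            model_kind=structure.model_kind)
    drop = {
        i for res in structure.polymer_residues[:cut_site]
        for i in res.atom_indices
    }
    kept = [a for i, a in enumerate(structure.atoms) if i not in drop]
    return StructureModel(
        atoms=kept, source_id=structure.source_id,
        model_kind=structure.model_kind)


def mean_plddt(structure: StructureModel) -> float:
    """Mean per-residue pLDDT of a predicted model.

    The representative per-residue value is the CA atom's B-factor (first
    atom as fallback); predicted models carry identical pLDDT on all atoms
    of a residue, so the choice is safe.
    """
    if structure.model_kind != "predicted":
        raise StructureError("mean_plddt applies to predicted models only")
    values = []
    for res in structure.polymer_residues:
        rep = None
        for i in res.atom_indices:
            if structure.atoms[i].name == "CA":
                rep = structure.atoms[i]
                break
        if rep is None:
            rep = structure.atoms[res.atom_indices[0]]
        values.append(rep.b_factor)
    if not values:
        raise StructureError("no polymer residues for pLDDT")
    return float(np.mean(values))


def read_signal_peptide_table(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV ``protein_id<TAB>cut_site`` of signal-peptide
    cleavage sites (last residue of the signal peptide, 1-based)."""
    out: dict[str, int] = {}
    lines = Path(path).read_text().splitlines()
    for ln, line in enumerate(lines):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if ln == 0 and parts[0] == "protein_id":
            continue
        if len(parts) < 2:
            raise ValueError(f"malformed signal-peptide row {ln + 1}: {line!r}")
        out[parts[0]] = int(parts[1])
    return out
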