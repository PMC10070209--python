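"""Coordinate-file input and Mn-site extraction.

Reads PDB/mmCIF files into a flat :class:`Structure` of atoms and locates
Mn centers together with their candidate ligand shells (O/N by default).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default distance cutoff (Å) for Mn–ligand bonds.  Wide enough to admit
#: Mn(II)–O (~2.2 Å) and Jahn–Teller-elongated axial bonds (~2.3–2.5 Å)
#: while excluding second-shell atoms.
DEFAULT_CUTOFF = 2.9

#: Ligand elements accepted by default.
DEFAULT_ELEMENTS = frozenset({"O", "N"})


class StructureError(ValueError):
    """Raised for unreadable or empty coordinate files."""


@dataclass(frozen=True)
class Atom:
    """One atom of a parsed structure (coordinates in Å)."""

    serial: int
    name: str
    element: str
    res_name: str
    res_seq: int
    chain_id: str
    coord: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    model_id: int = 0

    def __post_init__(self) -> None:
        coord = np.asarray(self.coord, dtype=float)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise StructureError(f"atom {self.serial} has invalid coordinates {self.coord!r}")
        object.__setattr__(self, "coord", coord)
        object.__setattr__(self, "element", self.element.strip().upper())


@dataclass
class Structure:
    """Flat atom container; order follows the source file."""

    atoms: list[Atom]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"structure {self.source!r} contains no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms], dtype=float)

    def select(self, element: str | None = None, model_id: int | None = None) -> list[Atom]:
        out = self.atoms
        if element is not None:
            element = element.upper()
            out = [a for a in out if a.element == element]
        if model_id is not None:
            out = [a for a in out if a.model_id == model_id]
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigid-body transformed copy (used by invariance tests)."""
        rotation = np.asarray(rotation, float)
        translation = np.asarray(translation, float)
        atoms = [
            Atom(a.serial, a.name, a.element, a.res_name, a.res_seq, a.chain_id,
                 rotation @ a.coord + translation, a.occupancy, a.altloc, a.model_id)
            for a in self.atoms
        ]
        return Structure(atoms, source=self.source)


@dataclass(frozen=True)
class Ligand:
    """A coordinating atom of a Mn center."""

    element: str
    coord: np.ndarray
    distance: float
    atom_name: str = ""
    res_name: str = ""
    res_seq: int = 0
    chain_id: str = ""
    serial: int = 0


@dataclass
class MnSite:
    """One Mn center with its retained ligand shell."""

    mn_coord: np.ndarray
    ligands: list[Ligand]
    chain_id: str = ""
    monomer_id: str = ""
    site_label: str = ""
    serial: int = 0
    res_name: str = ""

    @property
    def distances(self) -> np.ndarray:
        return np.array([lig.distance for lig in self.ligands], dtype=float)

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)


@dataclass(frozen=True)
class RejectedMn:
    """Mn atom that failed the coordination requirement."""

    serial: int
    chain_id: str
    site_label: str
    n_neighbors: int
    required: int


@dataclass
class SiteScan:
    """Result of a Mn-site search: accepted sites plus a rejection report."""

    sites: list[MnSite] = field(default_factory=list)
    rejected: list[RejectedMn] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def _element_from_name(name: str, res_name: str) -> str:
    """PDB-convention fallback when the element column is absent.

    Columns 13–14 of the atom name carry the element, right-justified for
    single-letter elements; two-letter metals (MN, FE, CA...) fill both.
    """
    name = name.strip()
    if not name:
        return ""
    two = name[:2].upper()
    if two in {"MN", "FE", "CA", "MG", "ZN", "NA", "CL", "CU", "NI", "CO"} and not name[0].isdigit():
        return two
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return ""


def _pick_altloc(atoms: Sequence) -> "object":
    """Highest occupancy wins; ties broken by altloc identifier order."""
    def key(a):
        occ = a.get_occupancy()
        occ = 0.0 if occ is None else occ
        return (-occ, a.get_altloc())

    return sorted(atoms, key=key)[0]


def load_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Heteroatoms are included; alternate locations are resolved to the
    highest-occupancy conformer (ties by altloc id).  ``format`` may be
    ``pdb``, ``mmcif`` or ``auto`` (extension-based).
    """
    from Bio.PDB import MMCIFParser, PDBParser

    path = Path(path)
    if not path.exists():
        raise StructureError(f"no such file: {path}")
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    if format not in {"pdb", "mmcif"}:
        raise ValueError(f"unknown format {format!r}")

    parser = PDBParser(QUIET=True) if format == "pdb" else MMCIFParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parsed = parser.get_structure(path.stem, str(path))
    except Exception as exc:  # Biopython raises heterogeneous types
        raise StructureError(f"cannot parse {path} as {format}: {exc}") from exc

    atoms: list[Atom] = []
    for model in parsed:
        for chain in model:
            for residue in chain:
                for atom in residue:
                    if atom.is_disordered():
                        atom = _pick_altloc(atom.disordered_get_list())
                    element = (atom.element or "").strip().upper()
                    if not element:
                        element = _element_from_name(atom.get_name(), residue.get_resname())
                    atoms.append(Atom(
                        serial=atom.get_serial_number() or len(atoms) + 1,
                        name=atom.get_name(),
                        element=element,
                        res_name=residue.get_resname(),
                        res_seq=residue.get_id()[1],
                        chain_id=chain.get_id(),
                        coord=np.asarray(atom.get_coord(), dtype=float),
                        occupancy=atom.get_occupancy() or 1.0,
                        altloc=atom.get_altloc() or "",
                        model_id=model.get_id(),
                    ))
    return Structure(atoms, source=str(path))


def scan_mn_sites(
    structure: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    allowed_elements: Iterable[str] = DEFAULT_ELEMENTS,
    required_coordination: int = 6,
) -> SiteScan:
    """Locate Mn atoms and their ligand shells, reporting rejections.

    A Mn atom is accepted when at least ``required_coordination`` atoms of
    ``allowed_elements`` lie within ``cutoff`` Å; the nearest
    ``required_coordination`` are kept.  Mn atoms that fail are recorded in
    the rejection report with their actual neighbor count.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if required_coordination < 4:
        raise ValueError("required_coordination must be >= 4")
    allowed = {e.upper() for e in allowed_elements}

    scan = SiteScan()
    mn_atoms = structure.select(element="MN")
    if not mn_atoms:
        msg = f"no Mn atoms found in {structure.source or 'structure'}"
        scan.warnings.append(msg)
        logger.warning(msg)
        return scan

    by_model: dict[int, list[Atom]] = {}
    for a in structure.atoms:
        by_model.setdefault(a.model_id, []).append(a)

    for mn in mn_atoms:
        candidates = [
            a for a in by_model[mn.model_id]
            if a.element in allowed and a is not mn
        ]
        if candidates:
            coords = np.array([a.coord for a in candidates], dtype=float)
            dists = np.linalg.norm(coords - mn.coord, axis=1)
            within = np.nonzero((dists > 0) & (dists <= cutoff))[0]
        else:
            dists = np.empty(0)
            within = np.empty(0, dtype=int)

        label = mn.name if mn.name.upper() != "MN" else f"MN{mn.serial}"
        if len(within) < required_coordination:
            rej = RejectedMn(mn.serial, mn.chain_id, label, len(within), required_coordination)
            scan.rejected.append(rej)
            msg = (f"Mn serial {mn.serial} (chain {mn.chain_id}) has "
                   f"{len(within)} allowed neighbors within {cutoff} Å; "
                   f"{required_coordination} required")
            scan.warnings.append(msg)
            logger.warning(msg)
            continue

        keep = within[np.argsort(dists[within], kind="stable")[:required_coordination]]
        ligands = [
            Ligand(
                element=candidates[i].element,
                coord=candidates[i].coord,
                distance=float(dists[i]),
                atom_name=candidates[i].name,
                res_name=candidates[i].res_name,
                res_seq=candidates[i].res_seq,
                chain_id=candidates[i].chain_id,
                serial=candidates[i].serial,
            )
            for i in keep
        ]
        scan.sites.append(MnSite(
            mn_coord=mn.coord,
            ligands=ligands,
            chain_id=mn.chain_id,
            site_label=label,
            serial=mn.serial,
            res_name=mn.res_name,
        ))
    return scan


def find_mn_sites(
    structure: Structure,
    cutoff: float = DEFAULT_CUTOFF,
    allowed_elements: Iterable[str] = DEFAULT_ELEMENTS,
    required_coordination: int = 6,
) -> list[MnSite]:
    """Convenience wrapper around :func:`scan_mn_sites` returning sites only."""
    return scan_mn_sites(structure, cutoff, allowed_elements, required_coordination).sites
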