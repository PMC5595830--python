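"""Structure and trajectory I/O.

Structures are read from PDB files (via biotite), trajectories from XTC or
DCD coordinate files (via mdtraj's format readers).  Coordinates are held in
Angstrom throughout; residue numbering is 1-based PDB author numbering,
frame indices are 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: residue names treated as environment (solvent, ions, membrane), never as ligand
DEFAULT_NON_LIGAND_RESNAMES = frozenset(
    {"HOH", "WAT", "TIP3", "SOL", "NA", "CL", "SOD", "CLA", "K", "POT", "MG", "ZN", "CA2", "POPC", "CHL1"}
)

#: backbone atom names; everything else in a residue counts as sidechain
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"})


class StructureParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


@dataclass
class MolecularStructure:
    """Atom records plus coordinates of a single model.

    Parameters
    ----------
    serial, name, element, resid, resname, chain
        Per-atom record fields (numpy arrays of equal length).
    is_ligand
        True for HETATM records whose residue name is not in the
        environment exclusion list.
    xyz
        ``(n_atoms, 3)`` coordinates in Angstrom.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    resid: np.ndarray
    resname: np.ndarray
    chain: np.ndarray
    is_ligand: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n_atoms, 3)")
        n = self.xyz.shape[0]
        for fname in ("serial", "name", "element", "resid", "resname", "chain", "is_ligand"):
            arr = np.asarray(getattr(self, fname))
            if arr.shape[0] != n:
                raise ValueError(f"field {fname!r} length {arr.shape[0]} != n_atoms {n}")
            setattr(self, fname, arr)

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raises :class:`StructureParseError`."""
        if self.n_atoms == 0:
            raise StructureParseError("structure contains no atoms")
        if len(np.unique(self.serial)) != self.n_atoms:
            raise StructureParseError("atom serial numbers are not unique")
        if not np.all(np.isfinite(self.xyz)):
            raise StructureParseError("non-finite coordinates")
        for ch in np.unique(self.chain):
            resids = self.resid[self.chain == ch]
            if np.any(np.diff(resids) < 0):
                raise StructureParseError(f"residue numbers decrease within chain {ch!r}")

    # -- accessors --------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return int(self.xyz.shape[0])

    def protein_mask(self) -> np.ndarray:
        return ~self.is_ligand & ~np.isin(self.resname, list(DEFAULT_NON_LIGAND_RESNAMES))

    def residue_numbers(self) -> np.ndarray:
        """Sorted unique residue numbers of the protein part."""
        return np.unique(self.resid[self.protein_mask()])

    def atom_indices(self, resid: int, names: Iterable[str] | None = None) -> np.ndarray:
        mask = (self.resid == resid) & ~self.is_ligand
        if names is not None:
            mask &= np.isin(self.name, list(names))
        return np.flatnonzero(mask)

    def ca_index(self, resid: int) -> int:
        idx = self.atom_indices(resid, names=["CA"])
        if idx.size != 1:
            raise KeyError(f"residue {resid} has {idx.size} CA atoms")
        return int(idx[0])

    def sidechain_heavy_indices(self, resid: int) -> np.ndarray:
        """Heavy sidechain atoms of a residue; glycine falls back to its CA."""
        mask = (self.resid == resid) & ~self.is_ligand & (self.element != "H")
        mask &= ~np.isin(self.name, list(BACKBONE_ATOMS))
        idx = np.flatnonzero(mask)
        if idx.size == 0:  # glycine (or missing sidechain): CA proxy
            idx = self.atom_indices(resid, names=["CA"])
        if idx.size == 0:
            raise KeyError(f"residue {resid} has no sidechain heavy atoms and no CA")
        return idx

    def ligand_indices(self, heavy_only: bool = True) -> np.ndarray:
        mask = self.is_ligand.astype(bool)
        if heavy_only:
            mask &= self.element != "H"
        return np.flatnonzero(mask)


@dataclass
class ResidueSelection:
    """Strictly increasing list of residue numbers known to the topology."""

    residues: tuple[int, ...]

    def __post_init__(self) -> None:
        res = tuple(int(r) for r in self.residues)
        if any(b <= a for a, b in zip(res, res[1:])):
            raise ValueError("residue selection must be strictly increasing")
        self.residues = res

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self):
        return iter(self.residues)


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing one topology.

    ``frames`` is a list of ``(n_frames, n_atoms, 3)`` arrays in Angstrom;
    ``frame_interval_ns`` is the sampling interval of every trajectory.
    """

    topology: MolecularStructure
    frames: list[np.ndarray]
    frame_interval_ns: float

    def __post_init__(self) -> None:
        if self.frame_interval_ns <= 0:
            raise ValueError("frame interval must be positive")
        if not self.frames:
            raise ValueError("ensemble contains no trajectories")
        checked = []
        for i, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.ndim != 3 or f.shape[2] != 3:
                raise ValueError(f"trajectory {i}: frames must have shape (n_frames, n_atoms, 3)")
            if f.shape[0] < 1:
                raise ValueError(f"trajectory {i}: needs at least one frame")
            if f.shape[1] != self.topology.n_atoms:
                raise ValueError(
                    f"trajectory {i}: {f.shape[1]} atoms vs topology {self.topology.n_atoms}"
                )
            checked.append(f)
        self.frames = checked

    @property
    def n_trajectories(self) -> int:
        return len(self.frames)

    @property
    def n_frames_total(self) -> int:
        return int(sum(f.shape[0] for f in self.frames))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    n_coord_records = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            n_coord_records += 1
            try:
                [float(line[30:38]), float(line[38:46]), float(line[46:54])]
            except (ValueError, IndexError) as exc:
                raise StructureParseError(
                    f"{path.name}: malformed coordinate record at line {lineno}"
                ) from exc
    if n_coord_records == 0:
        raise StructureParseError(f"{path.name}: no ATOM/HETATM records")


def read_structure(
    path: str | Path,
    non_ligand_resnames: frozenset[str] = DEFAULT_NON_LIGAND_RESNAMES,
) -> MolecularStructure:
    """Read a PDB file into a :class:`MolecularStructure`.

    HETATM records whose residue name is not in ``non_ligand_resnames`` are
    flagged as ligand atoms; water, ions and membrane lipids are excluded by
    default.
    """
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prescan_pdb(path)
    pdb_file = pdb.PDBFile.read(str(path))
    atoms = pdb_file.get_structure(model=1, extra_fields=["atom_id"])
    is_ligand = atoms.hetero & ~np.isin(atoms.res_name, list(non_ligand_resnames))
    structure = MolecularStructure(
        serial=np.asarray(atoms.atom_id, dtype=int),
        name=np.asarray(atoms.atom_name, dtype="U6"),
        element=np.char.upper(np.asarray(atoms.element, dtype="U2")),
        resid=np.asarray(atoms.res_id, dtype=int),
        resname=np.asarray(atoms.res_name, dtype="U6"),
        chain=np.asarray(atoms.chain_id, dtype="U4"),
        is_ligand=np.asarray(is_ligand, dtype=bool),
        xyz=np.asarray(atoms.coord, dtype=float),
    )
    structure.validate()
    return structure


def write_structure(path: str | Path, structure: MolecularStructure) -> Path:
    """Write a structure as a PDB file (ligand atoms become HETATM records)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    atoms = struc.AtomArray(structure.n_atoms)
    atoms.coord = structure.xyz.astype(np.float32)
    atoms.chain_id = structure.chain.astype("U4")
    atoms.res_id = structure.resid.astype(int)
    atoms.res_name = structure.resname.astype("U5")
    atoms.atom_name = structure.name.astype("U6")
    atoms.element = structure.element.astype("U2")
    atoms.hetero = structure.is_ligand.astype(bool)
    atoms.set_annotation("atom_id", structure.serial.astype(int))
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(atoms)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pdb_file.write(str(path))
    return path


def _read_coordinate_file(path: Path) -> np.ndarray:
    """Return frames in Angstrom from one XTC or DCD file."""
    suffix = path.suffix.lower()
    if suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as fh:
            xyz, _, _, _ = fh.read()
        return np.asarray(xyz, dtype=float) * 10.0  # nm -> A
    if suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _, _ = fh.read()
        return np.asarray(xyz, dtype=float)  # DCD is native Angstrom
    raise ValueError(f"unsupported trajectory format: {path.name} (expected .xtc or .dcd)")


def read_trajectory(
    paths: Sequence[str | Path],
    topology: MolecularStructure,
    frame_interval_ns: float,
) -> TrajectoryEnsemble:
    """Read XTC/DCD coordinate files; one trajectory per file, order preserved."""
    frames = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(p)
        xyz = _read_coordinate_file(p)
        if xyz.shape[1] != topology.n_atoms:
            raise ValueError(
                f"{p.name}: {xyz.shape[1]} atoms per frame but topology has {topology.n_atoms}"
            )
        frames.append(xyz)
    return TrajectoryEnsemble(topology=topology, frames=frames, frame_interval_ns=frame_interval_ns)


def write_xtc(path: str | Path, frames: np.ndarray) -> Path:
    """Write frames (Angstrom) to an XTC file."""
    from mdtraj.formats import XTCTrajectoryFile

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with XTCTrajectoryFile(str(path), "w") as fh:
        fh.write(np.asarray(frames, dtype=np.float32) / 10.0)  # A -> nm
    return path


def select_every_kth(
    topology: MolecularStructure, start_res: int, end_res: int, k: int
) -> ResidueSelection:
    """Residues ``start_res, start_res + k, ... <= end_res`` present in the topology.

    This is the uniform-spacing selection used to thin the Calpha set before
    building pair-distance descriptors (e.g. every third residue of the
    receptor span gives 97 residues for the 64-352 range).
    """
    if start_res > end_res:
        raise ValueError("start_res must be <= end_res")
    if k < 1:
        raise ValueError("k must be >= 1")
    wanted = np.arange(start_res, end_res + 1, k)
    present = set(topology.residue_numbers().tolist())
    missing = [int(r) for r in wanted if int(r) not in present]
    if missing:
        raise KeyError(f"residues absent from topology: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    if wanted.size == 0:
        raise ValueError("selection is empty")
    return ResidueSelection(tuple(int(r) for r in wanted))
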