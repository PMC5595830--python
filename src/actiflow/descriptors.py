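"""Structural descriptors, order parameters and interaction fingerprints.

Descriptor families
-------------------
Three families describe receptor conformation and ligand binding per frame:

* ``ca_pair_distance`` — Calpha-Calpha distances over all unordered pairs of
  a thinned residue selection (Angstrom),
* ``sidechain_contact`` — binary contact (minimum sidechain heavy-atom
  distance below a 7 A cutoff) for residue pairs that touch in at least one
  reference (crystal) structure,
* ``ligand_contact`` — binary contact between each residue's heavy atoms and
  the ligand heavy atoms (7 A cutoff).

Contacts use a strict ``<`` comparison at the cutoff so that tests are
bit-exact at the boundary.

Interaction fingerprints
------------------------
Per residue, seven bits in fixed order: apolar, aromatic face-to-face,
aromatic edge-to-face, hydrogen bond with the protein as donor, hydrogen
bond with the protein as acceptor, electrostatic with a positively charged
residue, electrostatic with a negatively charged residue.  Apolar contacts
use a 4.5 A cutoff between non-polar atoms; aromatic and electrostatic
interactions a 4 A cutoff.  Only residue sidechain atoms are considered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .trajio import MolecularStructure, ResidueSelection, TrajectoryEnsemble

__all__ = [
    "Descriptor",
    "DescriptorSet",
    "FeatureMatrix",
    "OrderParameterTrace",
    "LigandTyping",
    "FINGERPRINT_BITS",
    "build_descriptor_set",
    "compute_features",
    "segment_rmsd",
    "pair_distance",
    "detect_hbond",
    "compute_fingerprint",
]

# ---------------------------------------------------------------------------
# residue chemistry tables (sidechain heavy atoms only)
# ---------------------------------------------------------------------------

#: non-polar sidechain atoms (C and S); aromatic ring carbons are typed
#: aromatic instead and deliberately excluded here so the two classes are
#: disjoint.  Glycine is represented by its CA proxy.
APOLAR_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB",),
    "TYR": ("CB",),
    "TRP": ("CB", "CG", "CD1"),
    "PRO": ("CB", "CG", "CD"),
    "CYS": ("CB", "SG"),
    "LYS": ("CB", "CG", "CD", "CE"),
    "ARG": ("CB", "CG", "CD"),
    "GLU": ("CB", "CG"),
    "GLN": ("CB", "CG"),
    "ASP": ("CB",),
    "ASN": ("CB",),
    "THR": ("CG2",),
    "HIS": ("CB",),
    "SER": ("CB",),
    "GLY": ("CA",),
}

#: aromatic ring atom names per residue (single best-defined ring)
AROMATIC_RINGS: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}

#: sidechain heavy atoms able to donate a hydrogen bond
DONOR_ATOMS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "ASN": ("ND2",),
    "GLN": ("NE2",),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}

#: sidechain heavy atoms able to accept a hydrogen bond
ACCEPTOR_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
    "MET": ("SD",),
}

#: formally charged sidechain atoms at physiological pH
POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2", "CZ"),
}
NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

KNOWN_RESNAMES = (
    set(APOLAR_ATOMS) | set(AROMATIC_RINGS) | set(DONOR_ATOMS) | set(ACCEPTOR_ATOMS)
    | set(POSITIVE_ATOMS) | set(NEGATIVE_ATOMS)
)

FINGERPRINT_BITS = (
    "apolar",
    "aromatic_face",
    "aromatic_edge",
    "hbond_donor",
    "hbond_acceptor",
    "electrostatic_positive",
    "electrostatic_negative",
)

APOLAR_CUTOFF = 4.5  # A
AROMATIC_CUTOFF = 4.0  # A (ring centroid distance)
ELECTROSTATIC_CUTOFF = 4.0  # A
HBOND_DISTANCE = 3.5  # A, donor-acceptor heavy atoms
HBOND_ANGLE = 120.0  # degrees, D-H...A, applied only when hydrogens exist


# ---------------------------------------------------------------------------
# descriptor definitions and feature matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Descriptor:
    kind: Literal["ca_pair_distance", "sidechain_contact", "ligand_contact"]
    res_a: int
    res_b: int | None = None  # None for ligand contacts
    cutoff: float | None = None  # None for plain distances

    @property
    def label(self) -> str:
        if self.kind == "ca_pair_distance":
            return f"dCA_{self.res_a}_{self.res_b}"
        if self.kind == "sidechain_contact":
            return f"scc_{self.res_a}_{self.res_b}"
        return f"lig_{self.res_a}"


@dataclass
class DescriptorSet:
    descriptors: tuple[Descriptor, ...]

    def __post_init__(self) -> None:
        descs = tuple(self.descriptors)
        if len(set(descs)) != len(descs):
            raise ValueError("duplicate descriptor definitions")
        self.descriptors = descs

    def __len__(self) -> int:
        return len(self.descriptors)

    def count(self, kind: str) -> int:
        return sum(1 for d in self.descriptors if d.kind == kind)

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.descriptors]


@dataclass
class FeatureMatrix:
    """Per-trajectory descriptor values.

    ``blocks[i]`` has shape ``(n_frames_i, n_descriptors)``; distances are in
    Angstrom and contact columns are binary.
    """

    blocks: list[np.ndarray]
    names: list[str]
    frame_interval_ns: float
    kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ncol = len(self.names)
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        for b in self.blocks:
            if b.ndim != 2 or b.shape[1] != ncol:
                raise ValueError("every block must have one column per descriptor")

    @property
    def stacked(self) -> np.ndarray:
        return np.vstack(self.blocks)

    @property
    def n_frames_total(self) -> int:
        return int(sum(b.shape[0] for b in self.blocks))


@dataclass
class OrderParameterTrace:
    name: str
    blocks: list[np.ndarray]
    units: str = "A"
    frame_interval_ns: float = 1.0

    def __post_init__(self) -> None:
        self.blocks = [np.asarray(b, dtype=float) for b in self.blocks]
        for b in self.blocks:
            if not np.all(np.isfinite(b)):
                raise ValueError(f"trace {self.name!r} contains non-finite values")

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.blocks)


def _min_group_distance(xyz: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Per-frame minimum distance between two atom groups; xyz (n, n_atoms, 3)."""
    a = xyz[:, idx_a, :]  # (n, na, 3)
    b = xyz[:, idx_b, :]  # (n, nb, 3)
    diff = a[:, :, None, :] - b[:, None, :, :]
    return np.sqrt(np.einsum("nabk,nabk->nab", diff, diff)).min(axis=(1, 2))


def build_descriptor_set(
    topology: MolecularStructure,
    selection: ResidueSelection,
    reference_structures: Sequence[MolecularStructure] = (),
    ligand_range: tuple[int, int] | None = None,
    sidechain_cutoff: float = 7.0,
    ligand_cutoff: float = 7.0,
) -> DescriptorSet:
    """Assemble the three descriptor families.

    Calpha pair distances cover all unordered pairs of ``selection``
    (``n(n-1)/2`` descriptors).  Sidechain contacts are defined for residue
    pairs whose minimum sidechain heavy-atom distance is below
    ``sidechain_cutoff`` in ANY of the ``reference_structures``.  Ligand
    contacts get one descriptor per residue in ``ligand_range`` (inclusive).
    """
    if len(selection) == 0:
        raise ValueError("selection is empty")
    descriptors: list[Descriptor] = []
    residues = list(selection)
    for i, ra in enumerate(residues):
        for rb in residues[i + 1 :]:
            descriptors.append(Descriptor("ca_pair_distance", ra, rb))

    if reference_structures:
        pair_found: set[tuple[int, int]] = set()
        for ref in reference_structures:
            res = [int(r) for r in ref.residue_numbers()]
            groups = {r: ref.sidechain_heavy_indices(r) for r in res}
            xyz = ref.xyz[None, :, :]
            for i, ra in enumerate(res):
                for rb in res[i + 1 :]:
                    if (ra, rb) in pair_found:
                        continue
                    d = _min_group_distance(xyz, groups[ra], groups[rb])[0]
                    if d < sidechain_cutoff:
                        pair_found.add((ra, rb))
        for ra, rb in sorted(pair_found):
            descriptors.append(Descriptor("sidechain_contact", ra, rb, cutoff=sidechain_cutoff))

    if ligand_range is not None:
        lo, hi = ligand_range
        present = set(int(r) for r in topology.residue_numbers())
        for r in range(lo, hi + 1):
            if r in present:
                descriptors.append(Descriptor("ligand_contact", r, cutoff=ligand_cutoff))
    return DescriptorSet(tuple(descriptors))


def compute_features(trajectory: TrajectoryEnsemble, descriptors: DescriptorSet) -> FeatureMatrix:
    """Evaluate every descriptor on every frame of every trajectory."""
    top = trajectory.topology
    plans = []
    for d in descriptors.descriptors:
        try:
            if d.kind == "ca_pair_distance":
                plans.append(("ca", np.array([top.ca_index(d.res_a)]), np.array([top.ca_index(d.res_b)]), None))
            elif d.kind == "sidechain_contact":
                plans.append(
                    ("min", top.sidechain_heavy_indices(d.res_a), top.sidechain_heavy_indices(d.res_b), d.cutoff)
                )
            else:  # ligand_contact
                res_idx = top.atom_indices(d.res_a)
                res_idx = res_idx[top.element[res_idx] != "H"]
                lig_idx = top.ligand_indices(heavy_only=True)
                if lig_idx.size == 0:
                    raise KeyError("topology contains no ligand atoms")
                plans.append(("min", res_idx, lig_idx, d.cutoff))
            if plans[-1][1].size == 0 or plans[-1][2].size == 0:
                raise KeyError("empty atom group")
        except KeyError as exc:
            raise KeyError(f"descriptor {d.label}: missing atoms ({exc})") from exc

    blocks = []
    for xyz in trajectory.frames:
        cols = np.empty((xyz.shape[0], len(plans)))
        for j, (mode, ia, ib, cutoff) in enumerate(plans):
            dmin = _min_group_distance(xyz, ia, ib)
            cols[:, j] = dmin if cutoff is None else (dmin < cutoff).astype(float)
        blocks.append(cols)
    return FeatureMatrix(
        blocks=blocks,
        names=descriptors.labels,
        frame_interval_ns=trajectory.frame_interval_ns,
        kinds=[d.kind for d in descriptors.descriptors],
    )


# ---------------------------------------------------------------------------
# order parameters
# ---------------------------------------------------------------------------

def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto target."""
    mu_m = mobile.mean(axis=0)
    mu_t = target.mean(axis=0)
    H = (mobile - mu_m).T @ (target - mu_t)
    U, _, Vt = np.linalg.svd(H)
    sign = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, sign])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_m
    return R, t


def segment_rmsd(
    trajectory: TrajectoryEnsemble,
    reference: MolecularStructure,
    segment: tuple[int, int],
    fit_selection: ResidueSelection | None = None,
) -> OrderParameterTrace:
    """Calpha RMSD of a residue segment after rigid superposition on a fit set.

    Each frame is superposed onto ``reference`` over the Calpha atoms of
    ``fit_selection`` (default: all residues shared by trajectory topology
    and reference), then the RMSD is computed over the Calpha atoms of
    ``segment`` (inclusive interval) without refitting — so the trace
    reports how far the segment departs from the reference within the common
    molecular frame.
    """
    top = trajectory.topology
    lo, hi = segment
    seg_res = [r for r in range(lo, hi + 1) if r in set(int(x) for x in top.residue_numbers())]
    if not seg_res:
        raise ValueError("segment contains no residues present in the topology")
    if fit_selection is None:
        shared = sorted(
            set(int(r) for r in top.residue_numbers()) & set(int(r) for r in reference.residue_numbers())
        )
        fit_selection = ResidueSelection(tuple(shared))
    fit_idx_traj = np.array([top.ca_index(r) for r in fit_selection])
    fit_idx_ref = np.array([reference.ca_index(r) for r in fit_selection])
    seg_idx_traj = np.array([top.ca_index(r) for r in seg_res])
    seg_idx_ref = np.array([reference.ca_index(r) for r in seg_res])
    ref_fit = reference.xyz[fit_idx_ref]
    ref_seg = reference.xyz[seg_idx_ref]
    blocks = []
    for xyz in trajectory.frames:
        vals = np.empty(xyz.shape[0])
        for f in range(xyz.shape[0]):
            R, t = _kabsch(xyz[f, fit_idx_traj], ref_fit)
            moved = xyz[f, seg_idx_traj] @ R.T + t
            vals[f] = np.sqrt(np.mean(np.sum((moved - ref_seg) ** 2, axis=1)))
        blocks.append(vals)
    return OrderParameterTrace(
        name=f"rmsd_{lo}_{hi}", blocks=blocks, units="A", frame_interval_ns=trajectory.frame_interval_ns
    )


def _as_ensemble(obj: TrajectoryEnsemble | MolecularStructure) -> TrajectoryEnsemble:
    if isinstance(obj, TrajectoryEnsemble):
        return obj
    return TrajectoryEnsemble(topology=obj, frames=[obj.xyz[None, :, :]], frame_interval_ns=1.0)


def pair_distance(
    trajectory: TrajectoryEnsemble | MolecularStructure,
    res_a: int,
    res_b: int,
    mode: Literal["ca", "min_sidechain", "min_heavy"] = "ca",
) -> OrderParameterTrace:
    """Per-frame distance between two residues (Angstrom).

    ``ca`` uses the Calpha atoms, ``min_sidechain`` the minimum over
    sidechain heavy atoms (glycine falls back to CA), ``min_heavy`` the
    minimum over all heavy atoms.
    """
    ens = _as_ensemble(trajectory)
    top = ens.topology
    if mode == "ca":
        ia = np.array([top.ca_index(res_a)])
        ib = np.array([top.ca_index(res_b)])
    elif mode == "min_sidechain":
        ia = top.sidechain_heavy_indices(res_a)
        ib = top.sidechain_heavy_indices(res_b)
    elif mode == "min_heavy":
        ia = top.atom_indices(res_a)
        ia = ia[top.element[ia] != "H"]
        ib = top.atom_indices(res_b)
        ib = ib[top.element[ib] != "H"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if ia.size == 0 or ib.size == 0:
        raise KeyError(f"residue {res_a} or {res_b} lacks atoms for mode {mode!r}")
    blocks = [_min_group_distance(xyz, ia, ib) for xyz in ens.frames]
    return OrderParameterTrace(
        name=f"d_{mode}_{res_a}_{res_b}", blocks=blocks, units="A",
        frame_interval_ns=ens.frame_interval_ns,
    )


def _attached_hydrogens(top: MolecularStructure, xyz: np.ndarray, heavy_idx: int) -> np.ndarray:
    same_res = (top.resid == top.resid[heavy_idx]) & (top.element == "H")
    cand = np.flatnonzero(same_res)
    if cand.size == 0:
        return cand
    d = np.linalg.norm(xyz[cand] - xyz[heavy_idx], axis=1)
    return cand[d < 1.3]


def detect_hbond(
    trajectory: TrajectoryEnsemble | MolecularStructure,
    donor_res: int,
    acceptor_res: int,
    distance_cutoff: float = HBOND_DISTANCE,
    angle_cutoff: float = HBOND_ANGLE,
) -> OrderParameterTrace:
    """Binary sidechain hydrogen-bond trace between a donor and an acceptor residue.

    Criterion: donor-acceptor heavy-atom distance <= 3.5 A and, when the
    donor carries explicit hydrogens, a D-H...A angle >= 120 degrees for at
    least one hydrogen.  Without hydrogens the distance criterion alone
    decides.
    """
    ens = _as_ensemble(trajectory)
    top = ens.topology

    def _typed(resid: int, table: dict[str, tuple[str, ...]]) -> np.ndarray:
        resname = str(top.resname[top.resid == resid][0])
        names = table.get(resname, ())
        return top.atom_indices(resid, names=names)

    donors = _typed(donor_res, DONOR_ATOMS)
    acceptors = _typed(acceptor_res, ACCEPTOR_ATOMS)
    if donors.size == 0:
        raise KeyError(f"residue {donor_res} has no sidechain donor atoms")
    if acceptors.size == 0:
        raise KeyError(f"residue {acceptor_res} has no sidechain acceptor atoms")

    blocks = []
    for xyz in ens.frames:
        vals = np.zeros(xyz.shape[0])
        for f in range(xyz.shape[0]):
            formed = False
            for di in donors:
                hyd = _attached_hydrogens(top, xyz[f], int(di))
                for ai in acceptors:
                    dda = np.linalg.norm(xyz[f, ai] - xyz[f, di])
                    if dda > distance_cutoff:
                        continue
                    if hyd.size == 0:
                        formed = True
                        break
                    for hi in hyd:
                        v1 = xyz[f, di] - xyz[f, hi]
                        v2 = xyz[f, ai] - xyz[f, hi]
                        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        if angle >= angle_cutoff:
                            formed = True
                            break
                    if formed:
                        break
                if formed:
                    break
            vals[f] = float(formed)
        blocks.append(vals)
    return OrderParameterTrace(
        name=f"hbond_{donor_res}_{acceptor_res}", blocks=blocks, units="bool",
        frame_interval_ns=ens.frame_interval_ns,
    )


# ---------------------------------------------------------------------------
# interaction fingerprints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LigandTyping:
    """Chemical classes of the ligand atoms, by atom name.

    ``aromatic_rings`` is a tuple of rings, each a tuple of atom names.
    Aromatic-ring carbons are excluded from the apolar class to keep the
    interaction classes disjoint.
    """

    apolar: tuple[str, ...] = ()
    aromatic_rings: tuple[tuple[str, ...], ...] = ()
    hbond_donor: tuple[str, ...] = ()
    hbond_acceptor: tuple[str, ...] = ()
    positive: tuple[str, ...] = ()
    negative: tuple[str, ...] = ()


def _ring_geometry(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = xyz.mean(axis=0)
    _, _, Vt = np.linalg.svd(xyz - centroid)
    return centroid, Vt[-1]


def _plane_angle(n1: np.ndarray, n2: np.ndarray) -> float:
    cosang = abs(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def compute_fingerprint(
    structure: MolecularStructure,
    ligand_typing: LigandTyping,
    frame: np.ndarray | None = None,
    apolar_cutoff: float = APOLAR_CUTOFF,
    aromatic_cutoff: float = AROMATIC_CUTOFF,
    electrostatic_cutoff: float = ELECTROSTATIC_CUTOFF,
    face_angle: float = 30.0,
    edge_angle_range: tuple[float, float] = (60.0, 120.0),
) -> pd.DataFrame:
    """Per-residue 7-bit interaction fingerprint against the ligand.

    Returns a DataFrame indexed by residue number with the seven bit columns
    of :data:`FINGERPRINT_BITS`.  Residues with unknown residue names get a
    warning and all-zero bits.  Distance comparisons are strict ``<`` at the
    cutoffs; interplanar angles are folded to [0, 90] degrees so the
    edge-to-face band (60-120) maps to >= 60.
    """
    xyz = structure.xyz if frame is None else np.asarray(frame, dtype=float)
    lig_mask = structure.is_ligand.astype(bool)

    def lig_idx(names: Iterable[str]) -> np.ndarray:
        return np.flatnonzero(lig_mask & np.isin(structure.name, list(names)))

    lig_apolar = lig_idx(ligand_typing.apolar)
    lig_donor = lig_idx(ligand_typing.hbond_donor)
    lig_acceptor = lig_idx(ligand_typing.hbond_acceptor)
    lig_positive = lig_idx(ligand_typing.positive)
    lig_negative = lig_idx(ligand_typing.negative)
    lig_rings = [lig_idx(ring) for ring in ligand_typing.aromatic_rings]
    lig_ring_geo = [_ring_geometry(xyz[r]) for r in lig_rings if r.size >= 3]

    def min_dist(ia: np.ndarray, ib: np.ndarray) -> float:
        if ia.size == 0 or ib.size == 0:
            return np.inf
        diff = xyz[ia][:, None, :] - xyz[ib][None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).min())

    rows = {}
    for resid in structure.residue_numbers():
        resid = int(resid)
        resname = str(structure.resname[(structure.resid == resid) & ~lig_mask][0])
        bits = dict.fromkeys(FINGERPRINT_BITS, 0)
        if resname not in KNOWN_RESNAMES:
            warnings.warn(f"residue {resname}{resid}: unknown type, fingerprint left empty")
            rows[resid] = bits
            continue

        def res_idx(table: dict[str, tuple[str, ...]]) -> np.ndarray:
            return structure.atom_indices(resid, names=table.get(resname, ()))

        if min_dist(res_idx(APOLAR_ATOMS), lig_apolar) < apolar_cutoff:
            bits["apolar"] = 1
        ring_names = AROMATIC_RINGS.get(resname)
        if ring_names and lig_ring_geo:
            ridx = structure.atom_indices(resid, names=ring_names)
            if ridx.size >= 3:
                c_res, n_res = _ring_geometry(xyz[ridx])
                for c_lig, n_lig in lig_ring_geo:
                    if np.linalg.norm(c_res - c_lig) < aromatic_cutoff:
                        ang = _plane_angle(n_res, n_lig)
                        if ang <= face_angle:
                            bits["aromatic_face"] = 1
                        elif edge_angle_range[0] <= ang <= min(edge_angle_range[1], 90.0) or (
                            180.0 - edge_angle_range[1] <= ang <= 90.0
                        ):
                            bits["aromatic_edge"] = 1
        if min_dist(res_idx(DONOR_ATOMS), lig_acceptor) <= HBOND_DISTANCE and res_idx(DONOR_ATOMS).size:
            bits["hbond_donor"] = 1
        if min_dist(res_idx(ACCEPTOR_ATOMS), lig_donor) <= HBOND_DISTANCE and res_idx(ACCEPTOR_ATOMS).size:
            bits["hbond_acceptor"] = 1
        if min_dist(res_idx(POSITIVE_ATOMS), lig_negative) < electrostatic_cutoff:
            bits["electrostatic_positive"] = 1
        if min_dist(res_idx(NEGATIVE_ATOMS), lig_positive) < electrostatic_cutoff:
            bits["electrostatic_negative"] = 1
        rows[resid] = bits

    frame_df = pd.DataFrame.from_dict(rows, orient="index", columns=list(FINGERPRINT_BITS))
    frame_df.index.name = "residue"
    return frame_df.astype(int)
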