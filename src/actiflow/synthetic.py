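"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline (featurisation, tICA, MSM/PCCA+,
transition-path analysis, transfer entropy, fingerprints) is exercised on
data generated here, where the right answer is known by construction:

* :func:`simulate_markov_chain` — discrete metastable dynamics with an exact
  transition matrix (ground truth for MSM estimation and TPT).
* :func:`simulate_multiwell` — overdamped Langevin diffusion in a sum-of-
  Gaussian-wells potential, optionally embedded into a two-pseudo-atom
  "trajectory" whose interatomic distance is an affine map of the latent
  coordinate (ground truth for featurisation and tICA).
* :func:`simulate_coupled_contacts` — binary driver/follower processes with
  a known direction of information flow (ground truth for transfer entropy).
* :func:`build_toy_complex` — receptor-ligand toy structures whose atom
  placements trigger chosen interaction-fingerprint bits at exact distances.
* :func:`crystal_fragment` — synthetic stand-ins for the inactive/activated
  receptor crystal fragments, constructed to published inter-residue
  distances (the deposited coordinates are not shipped with this package).

All generators are deterministic given their spec (which includes the seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .trajio import MolecularStructure, TrajectoryEnsemble

__all__ = [
    "MarkovChainSpec",
    "MultiWellSpec",
    "CoupledContactSpec",
    "ToyComplexSpec",
    "simulate_markov_chain",
    "simulate_multiwell",
    "embed_latent_as_distance",
    "simulate_coupled_contacts",
    "build_toy_complex",
    "crystal_fragment",
    "linear_chain_structure",
    "metastable_two_block_matrix",
]


# ---------------------------------------------------------------------------
# discrete Markov dynamics
# ---------------------------------------------------------------------------

@dataclass
class MarkovChainSpec:
    transition_matrix: np.ndarray
    n_frames: int
    seed: int
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        if T.ndim != 2 or T.shape[0] != T.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(T < 0):
            raise ValueError("transition matrix entries must be non-negative")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1 within 1e-12")
        self.transition_matrix = T
        if self.initial_distribution is not None:
            p0 = np.asarray(self.initial_distribution, dtype=float)
            if p0.shape != (T.shape[0],) or not np.isclose(p0.sum(), 1.0):
                raise ValueError("initial distribution must be a length-K probability vector")
            self.initial_distribution = p0
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def simulate_markov_chain(spec: MarkovChainSpec) -> np.ndarray:
    """Sample a discrete state trajectory from an exact transition matrix."""
    rng = np.random.default_rng(spec.seed)
    K = spec.transition_matrix.shape[0]
    cumulative = np.cumsum(spec.transition_matrix, axis=1)
    cumulative[:, -1] = 1.0  # guard against rounding
    if spec.initial_distribution is None:
        state = int(rng.integers(K))
    else:
        state = int(rng.choice(K, p=spec.initial_distribution))
    u = rng.random(spec.n_frames - 1)
    out = np.empty(spec.n_frames, dtype=np.int64)
    out[0] = state
    for t in range(1, spec.n_frames):
        state = int(np.searchsorted(cumulative[state], u[t - 1], side="right"))
        out[t] = state
    return out


def metastable_two_block_matrix(
    n_states: int = 4, intra: float = 0.95, inter: float = 0.05
) -> np.ndarray:
    """Block-metastable chain: two blocks of ``n_states/2`` states.

    Within a block the self/partner split is ``intra``; a fraction ``inter``
    of probability leaks to the other block, spread uniformly.  The resulting
    matrix is doubly metastable with a slow block-exchange mode — the
    standard parameter-recovery test bed for MSM estimators.
    """
    if n_states % 2:
        raise ValueError("n_states must be even")
    half = n_states // 2
    T = np.zeros((n_states, n_states))
    for i in range(n_states):
        block = i // half
        mates = [j for j in range(block * half, (block + 1) * half)]
        others = [j for j in range(n_states) if j // half != block]
        for j in mates:
            T[i, j] = intra / half
        for j in others:
            T[i, j] = inter / half
    T /= T.sum(axis=1, keepdims=True)
    return T


# ---------------------------------------------------------------------------
# continuous multi-well diffusion
# ---------------------------------------------------------------------------

@dataclass
class MultiWellSpec:
    """Overdamped diffusion in ``V(x) = -sum_i depth_i exp(-(x-c_i)^2 / 2 w_i^2)``.

    Units are reduced: positions in Angstrom-like units, energies in kT
    multiples.  ``kT`` scales the noise relative to the well depths,
    ``diffusion`` and ``dt`` set the time scale of the Euler-Maruyama steps.
    ``confinement`` adds a weak harmonic restraint ``0.5 k x^2`` that keeps
    the walker near the wells (a bare sum of Gaussians is flat far away, so
    an unconfined walker would eventually diffuse off to infinity).
    """

    centers: np.ndarray
    depths: np.ndarray
    widths: np.ndarray | float = 0.5
    confinement: float = 0.0
    kT: float = 1.0
    diffusion: float = 1.0
    dt: float = 0.01
    n_frames: int = 1000
    seed: int = 0
    x0: float | None = None

    def __post_init__(self) -> None:
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.depths = np.atleast_1d(np.asarray(self.depths, dtype=float))
        if np.isscalar(self.widths):
            self.widths = np.full_like(self.centers, float(self.widths))
        else:
            self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if self.centers.shape != self.depths.shape or self.centers.shape != self.widths.shape:
            raise ValueError("centers, depths and widths must have equal length")
        if self.dt <= 0 or self.diffusion <= 0:
            raise ValueError("dt and diffusion must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _multiwell_force(x: float, spec: MultiWellSpec) -> float:
    # F = -dV/dx for V = -sum depth * exp(-(x-c)^2 / (2 w^2))
    dx = x - spec.centers
    g = spec.depths * np.exp(-(dx**2) / (2.0 * spec.widths**2))
    return float(np.sum(-g * dx / spec.widths**2) - spec.confinement * x)


def simulate_multiwell(spec: MultiWellSpec) -> np.ndarray:
    """Euler-Maruyama trajectory of the latent coordinate.

    Raises if the integration diverges (position leaves a generous bounding
    box around the wells), which indicates too large a time step.
    """
    rng = np.random.default_rng(spec.seed)
    bound = float(np.max(np.abs(spec.centers)) + 50.0 * np.max(spec.widths) + 50.0)
    x = float(spec.x0) if spec.x0 is not None else float(spec.centers[0])
    noise = rng.standard_normal(spec.n_frames - 1) * np.sqrt(2.0 * spec.diffusion * spec.dt)
    mobility = spec.diffusion / spec.kT
    out = np.empty(spec.n_frames)
    out[0] = x
    for t in range(1, spec.n_frames):
        x = x + mobility * _multiwell_force(x, spec) * spec.dt + noise[t - 1]
        if not np.isfinite(x) or abs(x) > bound:
            raise FloatingPointError(
                "multiwell integration diverged; reduce dt (or increase kT)"
            )
        out[t] = x
    return out


def embed_latent_as_distance(
    latent: np.ndarray,
    offset: float = 10.0,
    scale: float = 1.0,
    frame_interval_ns: float = 1.0,
) -> TrajectoryEnsemble:
    """Embed a latent trace as the distance between two pseudo Calpha atoms.

    Atom 0 sits at the origin; atom 1 at ``(offset + scale * x_t, 0, 0)``.
    A featurizer measuring the Calpha pair distance therefore recovers the
    affine-mapped latent coordinate exactly, which downstream tests exploit.
    ``offset`` must keep the distance positive over the trace.
    """
    latent = np.asarray(latent, dtype=float)
    distances = offset + scale * latent
    if np.any(distances <= 0):
        raise ValueError("affine map yields non-positive distances; increase offset")
    n = latent.shape[0]
    xyz = np.zeros((n, 2, 3))
    xyz[:, 1, 0] = distances
    topology = MolecularStructure(
        serial=np.array([1, 2]),
        name=np.array(["CA", "CA"]),
        element=np.array(["C", "C"]),
        resid=np.array([1, 2]),
        resname=np.array(["GLY", "GLY"]),
        chain=np.array(["A", "A"]),
        is_ligand=np.array([False, False]),
        xyz=xyz[0],
    )
    return TrajectoryEnsemble(topology=topology, frames=[xyz], frame_interval_ns=frame_interval_ns)


# ---------------------------------------------------------------------------
# coupled binary contacts
# ---------------------------------------------------------------------------

@dataclass
class CoupledContactSpec:
    """Driver/follower binary processes with a known information-flow direction.

    Channels not named as followers in ``coupling`` are i.i.d. Bernoulli(0.5)
    drivers.  A follower copies its driver delayed by ``lag`` frames, with
    each copied bit flipped independently with probability ``noise``.
    """

    n_channels: int
    coupling: Mapping[int, int]  # follower -> driver
    lag: int = 1
    noise: float = 0.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        if not 0.0 <= self.noise <= 0.5:
            raise ValueError("noise probability must be in [0, 0.5]")
        for f, d in self.coupling.items():
            if not (0 <= f < self.n_channels and 0 <= d < self.n_channels):
                raise KeyError(f"coupling {d}->{f} references a missing channel")
            if f == d:
                raise ValueError("a channel cannot drive itself")
        if any(f in set(self.coupling.values()) for f in self.coupling):
            raise ValueError("a follower cannot also be a driver")


def simulate_coupled_contacts(spec: CoupledContactSpec) -> np.ndarray:
    """Binary matrix (n_frames, n_channels) with planted directional coupling."""
    rng = np.random.default_rng(spec.seed)
    x = rng.integers(0, 2, size=(spec.n_frames, spec.n_channels)).astype(np.int8)
    for follower, driver in spec.coupling.items():
        flips = rng.random((spec.n_frames,)) < spec.noise
        x[spec.lag :, follower] = x[: -spec.lag, driver] ^ flips[spec.lag :]
    return x


# ---------------------------------------------------------------------------
# toy receptor-ligand complexes for fingerprints
# ---------------------------------------------------------------------------

#: archetype -> (residue name, interaction atom, its element, ligand partner
#: atom name, partner element)
_ARCHETYPES = {
    "apolar": ("LEU", "CD1", "C", "C1", "C"),
    "aromatic_face": ("PHE", None, None, None, None),  # rings handled specially
    "aromatic_edge": ("PHE", None, None, None, None),
    "hbond_donor": ("SER", "OG", "O", "O1", "O"),  # protein donor, ligand acceptor
    "hbond_acceptor": ("SER", "OG", "O", "N1", "N"),  # protein acceptor, ligand donor
    "electrostatic_positive": ("LYS", "NZ", "N", "O2", "O"),  # positive residue, ligand anion
    "electrostatic_negative": ("ASP", "OD1", "O", "N2", "N"),  # negative residue, ligand cation
}

_DIRECTIONS = np.array(
    [
        [1, 0, 0],
        [-1, 0, 0],
        [0, 1, 0],
        [0, -1, 0],
        [0, 0, 1],
        [0, 0, -1],
        [1, 1, 1],
    ],
    dtype=float,
)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)

_LIGAND_RADIUS = 1.5  # A: distance of each ligand partner atom from the origin


@dataclass
class ToyComplexSpec:
    """Requested placements: list of ``(archetype, distance_A)`` pairs."""

    placements: Sequence[tuple[str, float]]

    def __post_init__(self) -> None:
        if len(self.placements) > len(_DIRECTIONS):
            raise ValueError(f"at most {len(_DIRECTIONS)} placements supported")
        for archetype, d in self.placements:
            if archetype not in _ARCHETYPES:
                raise KeyError(f"unknown archetype {archetype!r}")
            if d <= 0:
                raise ValueError("placement distance must be positive")


def _ring_coords(center: np.ndarray, normal: np.ndarray, radius: float = 1.39) -> np.ndarray:
    """Six points of a planar hexagon with the given centroid and plane normal."""
    normal = normal / np.linalg.norm(normal)
    # two in-plane orthonormal axes
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, normal)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    a = np.cross(normal, helper)
    a /= np.linalg.norm(a)
    b = np.cross(normal, a)
    angles = np.arange(6) * np.pi / 3.0
    return center + radius * (np.outer(np.cos(angles), a) + np.outer(np.sin(angles), b))


def _perpendicular(direction: np.ndarray) -> np.ndarray:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, direction)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p = np.cross(direction, helper)
    return p / np.linalg.norm(p)


def build_toy_complex(spec: ToyComplexSpec):
    """Construct a toy receptor-ligand complex triggering chosen fingerprint bits.

    Returns ``(structure, ligand_typing)`` where ``ligand_typing`` is a
    :class:`actiflow.descriptors.LigandTyping` naming the chemical classes of
    the ligand atoms.  Each placement puts one residue archetype along its own
    spatial direction so that the minimum relevant atom-pair distance equals
    the requested distance to within 1e-6 A, verified before returning.
    """
    from .descriptors import LigandTyping  # deferred: avoids import cycle

    records: list[tuple[int, str, str, str, np.ndarray, bool]] = []  # resid, resname, atom, element, xyz, is_ligand
    lig_apolar: list[str] = []
    lig_rings: list[list[str]] = []
    lig_donor: list[str] = []
    lig_acceptor: list[str] = []
    lig_positive: list[str] = []
    lig_negative: list[str] = []
    intended: list[tuple[np.ndarray, np.ndarray, float]] = []

    # central ligand anchor so an empty spec still yields a ligand
    records.append((900, "LIG", "C0", "C", np.zeros(3), True))

    ring_serial = 0
    for i, (archetype, dist) in enumerate(spec.placements):
        u = _DIRECTIONS[i]
        resid = i + 1
        base = _LIGAND_RADIUS * u
        resname, res_atom, res_elem, lig_atom, lig_elem = _ARCHETYPES[archetype]
        if archetype in ("aromatic_face", "aromatic_edge"):
            # ligand benzene ring centred on the anchor axis, plane normal = u
            lig_names = [f"CR{ring_serial}{j}" for j in range(6)]
            ring_serial += 1
            for nm, xyz in zip(lig_names, _ring_coords(base, u)):
                records.append((900, "LIG", nm, "C", xyz, True))
            lig_rings.append(lig_names)
            res_center = (_LIGAND_RADIUS + dist) * u
            res_normal = u if archetype == "aromatic_face" else _perpendicular(u)
            ring = _ring_coords(res_center, res_normal)
            for nm, xyz in zip(["CG", "CD1", "CD2", "CE1", "CE2", "CZ"], ring):
                records.append((resid, resname, nm, "C", xyz, False))
            records.append((resid, resname, "CB", "C", res_center + 2.6 * u, False))
            records.append((resid, resname, "CA", "C", res_center + 4.0 * u, False))
            records.append((resid, resname, "N", "N", res_center + 4.0 * u + 1.2 * _perpendicular(u), False))
            intended.append((base, res_center, dist))
        else:
            records.append((900, "LIG", lig_atom, lig_elem, base, True))
            contact = (_LIGAND_RADIUS + dist) * u
            records.append((resid, resname, res_atom, res_elem, contact, False))
            records.append((resid, resname, "CB", "C", contact + 1.5 * u, False))
            records.append((resid, resname, "CA", "C", contact + 3.0 * u, False))
            records.append((resid, resname, "N", "N", contact + 3.0 * u + 1.2 * _perpendicular(u), False))
            intended.append((base, contact, dist))
            if archetype == "apolar":
                lig_apolar.append(lig_atom)
            elif archetype == "hbond_donor":
                lig_acceptor.append(lig_atom)
            elif archetype == "hbond_acceptor":
                lig_donor.append(lig_atom)
            elif archetype == "electrostatic_positive":
                lig_negative.append(lig_atom)
            elif archetype == "electrostatic_negative":
                lig_positive.append(lig_atom)

    for anchor, partner, dist in intended:
        realised = float(np.linalg.norm(partner - anchor))
        if abs(realised - dist) > 1e-6:
            raise ValueError("conflicting placements: realised distance deviates from request")

    n = len(records)
    structure = MolecularStructure(
        serial=np.arange(1, n + 1),
        name=np.array([r[2] for r in records], dtype="U6"),
        element=np.array([r[3] for r in records], dtype="U2"),
        resid=np.array([r[0] for r in records], dtype=int),
        resname=np.array([r[1] for r in records], dtype="U6"),
        chain=np.array(["L" if r[5] else "A" for r in records], dtype="U4"),
        is_ligand=np.array([r[5] for r in records], dtype=bool),
        xyz=np.array([r[4] for r in records], dtype=float),
    )
    # sort by (is_ligand, resid) so residue numbering is non-decreasing per chain
    order = np.lexsort((structure.resid, structure.is_ligand))
    structure = MolecularStructure(
        serial=np.arange(1, n + 1),
        name=structure.name[order],
        element=structure.element[order],
        resid=structure.resid[order],
        resname=structure.resname[order],
        chain=structure.chain[order],
        is_ligand=structure.is_ligand[order],
        xyz=structure.xyz[order],
    )
    structure.validate()
    typing = LigandTyping(
        apolar=tuple(lig_apolar),
        aromatic_rings=tuple(tuple(r) for r in lig_rings),
        hbond_donor=tuple(lig_donor),
        hbond_acceptor=tuple(lig_acceptor),
        positive=tuple(lig_positive),
        negative=tuple(lig_negative),
    )
    return structure, typing


def linear_chain_structure(
    start_res: int, end_res: int, spacing: float = 3.8, with_ligand: bool = False
) -> MolecularStructure:
    """Minimal Calpha-trace topology covering a residue span.

    One glycine Calpha per residue, laid out along x with the given spacing;
    optionally a single-atom ligand placed above the chain midpoint.  Useful
    for exercising selection and descriptor-count logic on receptor-sized
    residue ranges without real coordinates.
    """
    resids = list(range(start_res, end_res + 1))
    n = len(resids)
    records = []
    for i, r in enumerate(resids):
        records.append((r, "GLY", "CA", "C", np.array([i * spacing, 0.0, 0.0]), False))
    if with_ligand:
        records.append((max(resids) + 500, "LIG", "C1", "C",
                        np.array([n * spacing / 2.0, 8.0, 0.0]), True))
    m = len(records)
    structure = MolecularStructure(
        serial=np.arange(1, m + 1),
        name=np.array([r[2] for r in records], dtype="U6"),
        element=np.array([r[3] for r in records], dtype="U2"),
        resid=np.array([r[0] for r in records], dtype=int),
        resname=np.array([r[1] for r in records], dtype="U6"),
        chain=np.array(["L" if r[5] else "A" for r in records], dtype="U4"),
        is_ligand=np.array([r[5] for r in records], dtype=bool),
        xyz=np.array([r[4] for r in records], dtype=float),
    )
    structure.validate()
    return structure


# ---------------------------------------------------------------------------
# synthetic crystal-fragment stand-ins
# ---------------------------------------------------------------------------

def _res(records, resid, resname, atoms):
    for name, element, xyz in atoms:
        records.append((resid, resname, name, element, np.asarray(xyz, dtype=float)))


def crystal_fragment(state: str) -> MolecularStructure:
    """Synthetic stand-in for an inactive or activated receptor crystal fragment.

    These structures are generated geometry, NOT deposited crystal
    coordinates: atoms of the marker residues are placed so that published
    inter-residue distances hold by construction — the TM3-TM6 Calpha
    distance (R165-T279) is 8.0 A in the inactive and 14.0 A in the activated
    fragment, and the minimum sidechain heavy-atom distance between the
    binding-pocket residues A240 and H297 is 4.4 A (inactive) and 4.0 A
    (activated).  The NPxxYA segment (residues 332-337) of the activated
    fragment is displaced from the inactive conformation.  They serve to
    exercise the order-parameter and fingerprint machinery on realistic
    residue names and numbering.
    """
    if state not in ("inactive", "active"):
        raise ValueError("state must be 'inactive' or 'active'")
    records: list[tuple[int, str, str, str, np.ndarray]] = []

    # TM3 anchor: R165 (and D164 for the adjacent salt bridge partner)
    _res(records, 164, "ASP", [
        ("N", "N", (-1.0, -1.5, 0.0)), ("CA", "C", (0.0, -2.0, 0.0)),
        ("C", "C", (1.0, -1.5, 0.5)), ("O", "O", (1.2, -1.8, 1.6)),
        ("CB", "C", (0.0, -3.5, 0.0)), ("CG", "C", (1.2, -4.2, 0.3)),
        ("OD1", "O", (2.3, -3.7, 0.2)), ("OD2", "O", (1.1, -5.4, 0.6)),
    ])
    _res(records, 165, "ARG", [
        ("N", "N", (-1.0, 0.5, 0.0)), ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (1.2, 0.8, 0.3)), ("O", "O", (1.3, 1.9, -0.2)),
        ("CB", "C", (0.1, -1.2, -0.9)), ("CG", "C", (1.3, -2.1, -0.8)),
        ("CD", "C", (1.3, -3.1, -1.9)), ("NE", "N", (2.4, -4.0, -1.8)),
        ("CZ", "C", (2.5, -5.1, -2.5)), ("NH1", "N", (3.5, -5.8, -2.3)),
        ("NH2", "N", (1.6, -5.4, -3.4)),
    ])
    # TM5 marker Y252
    _res(records, 252, "TYR", [
        ("N", "N", (4.0, 6.5, 0.0)), ("CA", "C", (5.0, 7.0, 0.5)),
        ("C", "C", (6.2, 6.4, 0.0)), ("O", "O", (6.3, 5.2, 0.1)),
        ("CB", "C", (5.0, 8.5, 0.3)), ("OH", "O", (5.5, 12.4, 0.2)),
    ])
    # binding pocket: A240 / H297; nearest sidechain pair = A240:CB - H297:CG
    pocket = 4.4 if state == "inactive" else 4.0
    _res(records, 240, "ALA", [
        ("N", "N", (-1.0, 10.0, 8.0)), ("CA", "C", (0.0, 10.5, 8.5)),
        ("C", "C", (1.2, 9.8, 8.0)), ("O", "O", (1.3, 8.6, 8.2)),
        ("CB", "C", (0.0, 12.0, 8.5)),
    ])
    _res(records, 279, "THR", [
        ("N", "N", (8.0 if state == "inactive" else 14.0, -1.0, 0.5)),
        ("CA", "C", (8.0 if state == "inactive" else 14.0, 0.0, 0.0)),
        ("C", "C", (9.0 if state == "inactive" else 15.0, 1.0, 0.3)),
        ("O", "O", (9.1 if state == "inactive" else 15.1, 2.1, -0.3)),
        ("CB", "C", (8.5 if state == "inactive" else 14.5, -0.8, -1.2)),
        ("OG1", "O", (7.6 if state == "inactive" else 13.6, -1.6, -1.9)),
        ("CG2", "C", (9.6 if state == "inactive" else 15.6, -0.1, -2.1)),
    ])
    _res(records, 297, "HIS", [
        ("N", "N", (-1.0, 10.0 + pocket + 2.9, 8.0)),
        ("CA", "C", (0.0, 10.5 + pocket + 2.9, 8.5)),
        ("C", "C", (1.2, 9.8 + pocket + 2.9, 8.9)),
        ("O", "O", (1.3, 8.7 + pocket + 2.9, 9.4)),
        ("CB", "C", (0.0, 13.4 + pocket, 8.5)),
        ("CG", "C", (0.0, 12.0 + pocket, 8.5)),  # exactly `pocket` from A240:CB
        ("ND1", "N", (1.1, 12.6 + pocket, 9.1)),
        ("CD2", "C", (-0.9, 12.7 + pocket, 9.2)),
        ("CE1", "C", (0.9, 13.9 + pocket, 9.4)),
        ("NE2", "N", (-0.3, 14.2 + pocket, 9.5)),
    ])
    # NPxxYA segment 332-337 along TM7; activated fragment displaced in z
    dz = 0.0 if state == "inactive" else 3.2
    seg = [("ASN", 332), ("PRO", 333), ("ILE", 334), ("LEU", 335), ("TYR", 336), ("ALA", 337)]
    for j, (resname, resid) in enumerate(seg):
        x0 = -6.0 + 1.5 * j
        _res(records, resid, resname, [
            ("N", "N", (x0 - 0.8, 4.0, 4.0 + dz)),
            ("CA", "C", (x0, 4.5, 4.5 + dz)),
            ("C", "C", (x0 + 0.9, 3.9, 4.1 + dz)),
            ("O", "O", (x0 + 1.0, 2.8, 4.4 + dz)),
            ("CB", "C", (x0, 6.0, 4.5 + dz)),
        ])

    records.sort(key=lambda r: r[0])
    n = len(records)
    structure = MolecularStructure(
        serial=np.arange(1, n + 1),
        name=np.array([r[2] for r in records], dtype="U6"),
        element=np.array([r[3] for r in records], dtype="U2"),
        resid=np.array([r[0] for r in records], dtype=int),
        resname=np.array([r[1] for r in records], dtype="U6"),
        chain=np.array(["A"] * n, dtype="U4"),
        is_ligand=np.zeros(n, dtype=bool),
        xyz=np.array([r[4] for r in records], dtype=float),
    )
    structure.validate()
    return structure
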