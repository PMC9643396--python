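"""Geometry layer for docked poses and multi-model PDB trajectories.

Covers the structural questions of the discovery cascade: which pocket
residues a docked ligand contacts (and through which interaction type), where
steric clashes arise when a pose is transplanted onto a homologous structure,
how far two poses' centers of mass sit apart, what the side-chain chi1
dihedral of a pocket residue does over a trajectory, and backbone RMSD with
or without rotational fitting.

All distances are in Angstrom, angles in degrees.  Hydrogens are ignored in
contact and clash detection (docked poses frequently lack them); van der
Waals radii are Bondi values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import AnalysisError, StructureParseError

__all__ = [
    "Atom",
    "Residue",
    "ProteinStructure",
    "Pose",
    "Trajectory",
    "DihedralSeries",
    "RotamerSummary",
    "Contact",
    "ContactReport",
    "ContactCutoffs",
    "Clash",
    "RigidTransform",
    "load_structure",
    "write_pdb",
    "detect_contacts",
    "detect_clashes",
    "com_distance",
    "chi1_series",
    "dihedral",
    "rotamer_summary",
    "superpose_rmsd",
    "VDW_RADII",
    "ATOMIC_MASSES",
]

# Bondi (1964) van der Waals radii, Angstrom
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
_DEFAULT_VDW = 1.70

# standard atomic weights, Da
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
}

# aromatic ring templates per residue type (atom-name tuples)
_RESIDUE_RINGS = {
    "TRP": (("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
            ("CG", "CD1", "NE1", "CE2", "CD2")),
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}

_GAMMA_ATOMS = ("CG", "OG", "OG1", "CG1", "SG", "G")


def _vdw(element: str) -> float:
    return VDW_RADII.get(element.upper(), _DEFAULT_VDW)


def _mass(element: str) -> float:
    try:
        return ATOMIC_MASSES[element.upper()]
    except KeyError:
        raise AnalysisError(f"no atomic mass for element {element!r}") from None


@dataclass(eq=False)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,)
    aromatic: bool = False
    tag: str | None = None

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise AnalysisError(f"atom {self.name}: coordinates must be finite 3-vectors")


@dataclass(eq=False)
class Residue:
    chain: str
    number: int
    name: str
    atoms: list[Atom]

    @property
    def id(self) -> str:
        return f"{self.chain}:{self.number}:{self.name}"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise AnalysisError(f"residue {self.id} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)


@dataclass
class ProteinStructure:
    residues: list[Residue]

    def __post_init__(self) -> None:
        seen = set()
        for r in self.residues:
            key = (r.chain, r.number)
            if key in seen:
                raise AnalysisError(f"duplicate residue number {key}")
            seen.add(key)

    def atoms(self) -> Iterable[tuple[Residue, Atom]]:
        for r in self.residues:
            for a in r.atoms:
                yield r, a


@dataclass
class Pose:
    """A docked ligand: atoms, optional energy, optional aromatic ring index sets."""

    atoms: list[Atom]
    energy: float | None = None  # kcal/mol
    rings: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        if not self.atoms:
            raise AnalysisError("pose must contain at least one atom")

    def coords(self) -> np.ndarray:
        return np.array([a.coord for a in self.atoms])


@dataclass
class Trajectory:
    """Frames over a fixed atom roster.

    ``atom_table`` rows are (chain, resnum, resname, atom name, element);
    ``coords`` has shape (n_frames, n_atoms, 3); ``dt`` is ps per frame.
    """

    atom_table: list[tuple[str, int, str, str, str]]
    coords: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != len(self.atom_table):
            raise AnalysisError("coords must be (n_frames, n_atoms, 3) matching the roster")
        if not np.all(np.isfinite(self.coords)):
            raise AnalysisError("trajectory coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> ProteinStructure:
        """Materialize frame ``i`` as a ProteinStructure."""
        residues: dict[tuple[str, int], Residue] = {}
        for (chain, resnum, resname, aname, elem), xyz in zip(
            self.atom_table, self.coords[i]
        ):
            key = (chain, resnum)
            if key not in residues:
                residues[key] = Residue(chain, resnum, resname, [])
            residues[key].atoms.append(Atom(aname, elem, xyz))
        return ProteinStructure(list(residues.values()))


@dataclass
class DihedralSeries:
    residue_id: str
    angles: np.ndarray  # degrees, (-180, 180]
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.size and (
            np.any(self.angles <= -180.0) or np.any(self.angles > 180.0)
        ):
            raise AnalysisError("chi1 angles must lie in (-180, 180]")


@dataclass
class RotamerSummary:
    occupancies: dict[str, float]  # gauche-minus / gauche-plus / trans
    dominant: str
    circular_mean: float  # degrees
    resultant_length: float  # in [0, 1]


@dataclass(frozen=True)
class Contact:
    residue_id: str
    kind: str  # hbond | pi-pi | pi-alkyl | vdw
    distance: float
    atoms: tuple[str, ...]  # participating atom names (protein side, ligand side)


@dataclass
class ContactReport:
    contacts: list[Contact]
    per_residue: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.per_residue:
            for c in self.contacts:
                self.per_residue.setdefault(c.residue_id, []).append(c.kind)

    def fingerprint(self) -> set[tuple[str, str]]:
        return {(c.residue_id, c.kind) for c in self.contacts}


@dataclass(frozen=True)
class ContactCutoffs:
    """Distance cutoffs (Angstrom) per interaction type.

    hbond: donor/acceptor heavy-atom pair; pi_pi: ring centroid to ring
    centroid; pi_alkyl: ring centroid to aliphatic carbon; vdw: heavy-atom
    distance within the Bondi-radii sum plus ``vdw_margin``.
    """

    hbond: float = 3.5
    pi_pi: float = 5.5
    pi_alkyl: float = 4.5
    vdw_margin: float = 0.5


@dataclass(frozen=True)
class Clash:
    atom_a: str  # "resid/atom" or "ligand/atom"
    atom_b: str
    distance: float
    overlap: float  # penetration depth below the scaled radii sum


@dataclass
class RigidTransform:
    """mobile' = (mobile - mobile_centroid) @ rotation.T + ref_centroid"""

    rotation: np.ndarray
    mobile_centroid: np.ndarray
    ref_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.mobile_centroid) @ self.rotation.T + self.ref_centroid


# ---------------------------------------------------------------------------
# PDB I/O (fixed-column, via biotite)


def _validate_pdb_lines(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise StructureParseError("truncated ATOM/HETATM record", lineno)
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                text = line[lo:hi]
                try:
                    value = float(text)
                except ValueError:
                    raise StructureParseError(
                        f"malformed coordinate field {text.strip()!r}", lineno
                    ) from None
                if not math.isfinite(value):
                    raise StructureParseError(
                        f"non-finite coordinate {text.strip()!r}", lineno
                    )


def load_structure(path) -> "ProteinStructure | Pose | Trajectory":
    """Read a fixed-column PDB file.

    Multi-model files become a :class:`Trajectory`; files containing only
    HETATM records become a :class:`Pose`; otherwise a
    :class:`ProteinStructure`.  Elements come from columns 77-78 with an
    atom-name fallback.
    """
    import biotite.structure.io.pdb as pdb

    _validate_pdb_lines(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure()  # AtomArrayStack
    except Exception as exc:  # biotite raises assorted exception types
        raise StructureParseError(f"cannot parse PDB file: {exc}") from exc
    if not np.all(np.isfinite(stack.coord)):
        raise StructureParseError("non-finite coordinates in PDB file")

    n_models = stack.stack_depth()
    arr0 = stack[0]

    def element_of(i) -> str:
        elem = str(arr0.element[i]).strip()
        if elem:
            return elem.upper()
        name = str(arr0.atom_name[i]).strip()
        return name[:1].upper()

    if n_models > 1:
        table = [
            (
                str(arr0.chain_id[i]) or "A",
                int(arr0.res_id[i]),
                str(arr0.res_name[i]),
                str(arr0.atom_name[i]),
                element_of(i),
            )
            for i in range(arr0.array_length())
        ]
        return Trajectory(atom_table=table, coords=np.asarray(stack.coord, dtype=float))

    if bool(np.all(arr0.hetero)):
        atoms = [
            Atom(str(arr0.atom_name[i]), element_of(i), arr0.coord[i])
            for i in range(arr0.array_length())
        ]
        return Pose(atoms=atoms)

    residues: dict[tuple[str, int], Residue] = {}
    for i in range(arr0.array_length()):
        key = (str(arr0.chain_id[i]) or "A", int(arr0.res_id[i]))
        if key not in residues:
            residues[key] = Residue(key[0], key[1], str(arr0.res_name[i]), [])
        residues[key].atoms.append(
            Atom(str(arr0.atom_name[i]), element_of(i), arr0.coord[i])
        )
    return ProteinStructure(list(residues.values()))


def write_pdb(path, obj: "ProteinStructure | Pose | Trajectory") -> None:
    """Write any of the three structure containers as a fixed-column PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    def _atom_array(names, elements, resnames, resnums, chains, coords, hetero):
        arr = struc.AtomArray(len(names))
        arr.atom_name = names
        arr.element = elements
        arr.res_name = resnames
        arr.res_id = resnums
        arr.chain_id = chains
        arr.hetero = hetero
        arr.coord = np.asarray(coords, dtype=float)
        return arr

    if isinstance(obj, Trajectory):
        names = [row[3] for row in obj.atom_table]
        arrs = []
        for f in range(obj.n_frames):
            arrs.append(
                _atom_array(
                    names,
                    [row[4] for row in obj.atom_table],
                    [row[2] for row in obj.atom_table],
                    [row[1] for row in obj.atom_table],
                    [row[0] for row in obj.atom_table],
                    obj.coords[f],
                    np.zeros(len(names), dtype=bool),
                )
            )
        stack = struc.stack(arrs)
        out = pdb.PDBFile()
        out.set_structure(stack)
    elif isinstance(obj, Pose):
        arr = _atom_array(
            [a.name for a in obj.atoms],
            [a.element for a in obj.atoms],
            ["LIG"] * len(obj.atoms),
            [1] * len(obj.atoms),
            ["L"] * len(obj.atoms),
            [a.coord for a in obj.atoms],
            np.ones(len(obj.atoms), dtype=bool),
        )
        out = pdb.PDBFile()
        out.set_structure(arr)
    else:
        rows = [(r, a) for r, a in obj.atoms()]
        arr = _atom_array(
            [a.name for _, a in rows],
            [a.element for _, a in rows],
            [r.name for r, _ in rows],
            [r.number for r, _ in rows],
            [r.chain for r, _ in rows],
            [a.coord for _, a in rows],
            np.zeros(len(rows), dtype=bool),
        )
        out = pdb.PDBFile()
        out.set_structure(arr)
    out.write(str(path))


# ---------------------------------------------------------------------------
# contacts and clashes


def _protein_rings(protein: ProteinStructure):
    """Yield (residue, ring atom names, centroid) for aromatic side-chain rings."""
    for res in protein.residues:
        for ring in _RESIDUE_RINGS.get(res.name, ()):
            if all(res.has_atom(n) for n in ring):
                centroid = np.mean([res.atom(n).coord for n in ring], axis=0)
                yield res, ring, centroid


def detect_contacts(
    protein: ProteinStructure,
    pose: Pose,
    cutoffs: ContactCutoffs = ContactCutoffs(),
) -> ContactReport:
    """Classify protein-ligand contacts by the most specific qualifying type.

    Priority is hbond > pi-pi > pi-alkyl > vdw; every atom pair is reported
    at most once, under its most specific type.  Hydrogens are ignored.
    """
    if not pose.atoms:
        raise AnalysisError("empty pose")
    contacts: list[Contact] = []
    used_pairs: set[tuple[int, int, int]] = set()  # (res index, protein atom idx, ligand idx)

    res_list = protein.residues
    heavy_lig = [
        (j, a) for j, a in enumerate(pose.atoms) if a.element.upper() != "H"
    ]
    ring_membership = {j for ring in pose.rings for j in ring}

    # hydrogen bonds: N/O heavy-atom pairs
    for ri, res in enumerate(res_list):
        for pi_idx, patom in enumerate(res.atoms):
            if patom.element.upper() not in ("N", "O"):
                continue
            for j, latom in heavy_lig:
                if latom.element.upper() not in ("N", "O"):
                    continue
                d = float(np.linalg.norm(patom.coord - latom.coord))
                if d <= cutoffs.hbond:
                    contacts.append(
                        Contact(res.id, "hbond", d, (patom.name, latom.name))
                    )
                    used_pairs.add((ri, pi_idx, j))

    # pi-pi: protein aromatic ring centroid vs ligand ring centroid
    lig_coords = pose.coords()
    for res, ring_names, centroid in _protein_rings(protein):
        ri = res_list.index(res)
        ring_atom_idx = [res.atoms.index(res.atom(n)) for n in ring_names]
        for lig_ring in pose.rings:
            lig_centroid = lig_coords[list(lig_ring)].mean(axis=0)
            d = float(np.linalg.norm(centroid - lig_centroid))
            if d <= cutoffs.pi_pi:
                contacts.append(
                    Contact(
                        res.id,
                        "pi-pi",
                        d,
                        tuple(ring_names) + tuple(pose.atoms[j].name for j in lig_ring),
                    )
                )
                for pi_idx in ring_atom_idx:
                    for j in lig_ring:
                        used_pairs.add((ri, pi_idx, j))

    # pi-alkyl: protein ring centroid vs aliphatic ligand carbon
    for res, ring_names, centroid in _protein_rings(protein):
        ri = res_list.index(res)
        ring_atom_idx = [res.atoms.index(res.atom(n)) for n in ring_names]
        for j, latom in heavy_lig:
            if latom.element.upper() != "C" or latom.aromatic or j in ring_membership:
                continue
            d = float(np.linalg.norm(centroid - latom.coord))
            if d <= cutoffs.pi_alkyl:
                already = any((ri, pi_idx, j) in used_pairs for pi_idx in ring_atom_idx)
                if not already:
                    contacts.append(
                        Contact(res.id, "pi-alkyl", d, tuple(ring_names) + (latom.name,))
                    )
                    for pi_idx in ring_atom_idx:
                        used_pairs.add((ri, pi_idx, j))

    # van der Waals: anything left within the scaled radii sum
    for ri, res in enumerate(res_list):
        for pi_idx, patom in enumerate(res.atoms):
            if patom.element.upper() == "H":
                continue
            for j, latom in heavy_lig:
                if (ri, pi_idx, j) in used_pairs:
                    continue
                cutoff = _vdw(patom.element) + _vdw(latom.element) + cutoffs.vdw_margin
                d = float(np.linalg.norm(patom.coord - latom.coord))
                if d <= cutoff:
                    contacts.append(
                        Contact(res.id, "vdw", d, (patom.name, latom.name))
                    )
                    used_pairs.add((ri, pi_idx, j))

    return ContactReport(contacts=contacts)


def _entity_atoms(entity) -> list[tuple[str, Atom]]:
    if isinstance(entity, Pose):
        return [(f"ligand/{a.name}", a) for a in entity.atoms]
    if isinstance(entity, ProteinStructure):
        return [(f"{r.id}/{a.name}", a) for r, a in entity.atoms()]
    raise AnalysisError(f"unsupported entity type {type(entity).__name__}")


def detect_clashes(a, b, factor: float = 0.7) -> list[Clash]:
    """Steric clashes between two entities: d < factor * (r_vdw_i + r_vdw_j).

    Hydrogens are excluded.  Pairs are returned sorted by decreasing
    penetration depth.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    clashes: list[Clash] = []
    atoms_a = [(lab, at) for lab, at in _entity_atoms(a) if at.element.upper() != "H"]
    atoms_b = [(lab, at) for lab, at in _entity_atoms(b) if at.element.upper() != "H"]
    for lab_a, at_a in atoms_a:
        for lab_b, at_b in atoms_b:
            limit = factor * (_vdw(at_a.element) + _vdw(at_b.element))
            d = float(np.linalg.norm(at_a.coord - at_b.coord))
            if d < limit:
                clashes.append(Clash(lab_a, lab_b, d, limit - d))
    clashes.sort(key=lambda c: -c.overlap)
    return clashes


def com_distance(
    a: Pose, b: Pose, exclude_tags: set[str] | None = None, weighting: str = "mass"
) -> float:
    """Distance between the centers of mass of two poses.

    Atoms whose ``tag`` is in ``exclude_tags`` (e.g. a biotin linker) are
    dropped before the computation.  ``weighting="geometric"`` uses unweighted
    centroids instead of standard atomic masses.
    """
    exclude_tags = exclude_tags or set()

    def center(pose: Pose) -> np.ndarray:
        kept = [at for at in pose.atoms if at.tag not in exclude_tags]
        if not kept:
            raise AnalysisError("all atoms excluded from center-of-mass computation")
        coords = np.array([at.coord for at in kept])
        if weighting == "geometric":
            return coords.mean(axis=0)
        masses = np.array([_mass(at.element) for at in kept])
        return (coords * masses[:, None]).sum(axis=0) / masses.sum()

    return float(np.linalg.norm(center(a) - center(b)))


# ---------------------------------------------------------------------------
# dihedrals and rotamers


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, range (-180, 180].

    Standard atan2 formulation with the IUPAC sign convention (positive =
    clockwise rotation of the p2-p3 bond relative to p0-p1, viewed from p1
    toward p2).
    """
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2)
    m1 = np.cross(n1, b2n)
    angle = math.degrees(math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2))))
    if angle <= -180.0:
        angle += 360.0
    return angle


def chi1_series(traj: Trajectory, residue: tuple[str, int] | int) -> DihedralSeries:
    """chi1 (N-CA-CB-gamma) per frame for the selected residue.

    ``residue`` is (chain, resnum) or a bare residue number.  The gamma atom
    is the first of CG/OG/OG1/CG1/SG present in the roster.
    """
    if isinstance(residue, int):
        chain = None
        resnum = residue
    else:
        chain, resnum = residue

    def find(aname_options) -> int:
        for i, (ch, num, _rn, an, _el) in enumerate(traj.atom_table):
            if num == resnum and (chain is None or ch == chain):
                if an in aname_options:
                    return i
        return -1

    idx_n, idx_ca, idx_cb = find(("N",)), find(("CA",)), find(("CB",))
    idx_g = find(_GAMMA_ATOMS)
    missing = [
        nm
        for nm, ix in (("N", idx_n), ("CA", idx_ca), ("CB", idx_cb), ("gamma", idx_g))
        if ix < 0
    ]
    if missing:
        raise AnalysisError(
            f"residue {residue} lacks required chi1 atoms: {', '.join(missing)}"
        )
    angles = np.array(
        [
            dihedral(
                traj.coords[f, idx_n],
                traj.coords[f, idx_ca],
                traj.coords[f, idx_cb],
                traj.coords[f, idx_g],
            )
            for f in range(traj.n_frames)
        ]
    )
    ch, num, rn, _, _ = traj.atom_table[idx_ca]
    return DihedralSeries(residue_id=f"{ch}:{num}:{rn}", angles=angles, dt=traj.dt)


def _rotamer_bin(angle: float) -> str:
    # gauche-: [-120, 0); gauche+: [0, 120); trans: [120, 180] u (-180, -120)
    if -120.0 <= angle < 0.0:
        return "gauche-"
    if 0.0 <= angle < 120.0:
        return "gauche+"
    return "trans"


def rotamer_summary(series: DihedralSeries) -> RotamerSummary:
    """Rotamer-state occupancies and circular statistics of a chi1 series."""
    angles = series.angles
    if angles.size == 0:
        raise AnalysisError("empty dihedral series")
    n = angles.size
    counts = {"gauche-": 0, "gauche+": 0, "trans": 0}
    for a in angles:
        counts[_rotamer_bin(float(a))] += 1
    occ = {k: v / n for k, v in counts.items()}
    rad = np.radians(angles)
    z = np.exp(1j * rad).mean()
    mean_deg = math.degrees(math.atan2(z.imag, z.real))
    if mean_deg <= -180.0:
        mean_deg += 360.0
    dominant = max(("gauche-", "gauche+", "trans"), key=lambda k: counts[k])
    return RotamerSummary(
        occupancies=occ,
        dominant=dominant,
        circular_mean=mean_deg,
        resultant_length=float(abs(z)),
    )


# ---------------------------------------------------------------------------
# superposition / RMSD

_BACKBONE = frozenset({"N", "CA", "C"})


def _matched_coords(
    ref: ProteinStructure, mobile: ProteinStructure, selection: frozenset[str] | set[str]
):
    keys = []
    ref_map = {}
    for r, a in ref.atoms():
        if a.name in selection:
            ref_map[(r.chain, r.number, a.name)] = a.coord
            keys.append((r.chain, r.number, a.name))
    mob_map = {
        (r.chain, r.number, a.name): a.coord
        for r, a in mobile.atoms()
        if a.name in selection
    }
    if set(ref_map) != set(mob_map):
        raise AnalysisError(
            "selected atoms do not correspond between reference and mobile frames"
        )
    if not keys:
        raise AnalysisError("empty atom selection")
    ref_xyz = np.array([ref_map[k] for k in keys])
    mob_xyz = np.array([mob_map[k] for k in keys])
    return keys, ref_xyz, mob_xyz


def superpose_rmsd(
    ref: ProteinStructure,
    mobile: ProteinStructure,
    selection: set[str] = _BACKBONE,
    mode: str = "full",
    per_residue: bool = False,
):
    """Superpose ``mobile`` onto ``ref`` over a named-atom selection and return RMSD.

    ``mode="center-only"`` removes translation only (centroid subtraction);
    ``mode="full"`` additionally applies the optimal (Kabsch) rotation.
    Returns ``(rmsd, transform)`` or ``(rmsd, transform, per_residue_rmsd)``.
    """
    if mode not in ("full", "center-only"):
        raise ValueError(f"unknown mode {mode!r}")
    keys, ref_xyz, mob_xyz = _matched_coords(ref, mobile, frozenset(selection))
    ref_c = ref_xyz.mean(axis=0)
    mob_c = mob_xyz.mean(axis=0)
    ref0 = ref_xyz - ref_c
    mob0 = mob_xyz - mob_c
    if mode == "full":
        # Kabsch via SVD
        h = mob0.T @ ref0
        u, _s, vt = np.linalg.svd(h)
        sign = np.sign(np.linalg.det(vt.T @ u.T))
        d = np.diag([1.0, 1.0, sign])
        rot = vt.T @ d @ u.T
    else:
        rot = np.eye(3)
    fitted = mob0 @ rot.T
    diff = fitted - ref0
    sq = np.sum(diff**2, axis=1)
    rmsd = float(np.sqrt(sq.mean()))
    transform = RigidTransform(rotation=rot, mobile_centroid=mob_c, ref_centroid=ref_c)
    if not per_residue:
        return rmsd, transform
    per_res: dict[tuple[str, int], list[float]] = {}
    for (chain, num, _an), s in zip(keys, sq):
        per_res.setdefault((chain, num), []).append(float(s))
    per_res_rmsd = {k: float(np.sqrt(np.mean(v))) for k, v in per_res.items()}
    return rmsd, transform, per_res_rmsd
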