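"""Seeded generators for every stage of the discovery cascade.

Each generator draws from its own :class:`numpy.random.Generator` seeded per
call, stores the ground truth it realized (descriptor labels, contact lists,
per-frame dihedrals, kinetic parameters, ...), and is deterministic: the
same (seed, parameters) reproduce identical output.  Downstream recovery
tests compare analysis output against these stored labels.

Stages
------
library      descriptor-diverse small-molecule sets from a hand-verified
             SMILES catalog, with per-rule violation fractions
pocket       an idealized TRP/ARG/SER binding pocket plus a ligand pose
             realizing requested residue contacts at requested distances
trajectory   four-atom (N, CA, CB, gamma) residues whose chi1 follows a
             von Mises mixture, with optional per-frame rigid-body motion
luminescence damped-cosine circadian reporter traces with trend and noise
decay        one-phase exponential decay traces (translation-inhibitor chase)
pk           one-compartment first-order absorption i.p. profiles sampled at
             the in-vivo design timepoints (0, 0.5, 1, 2, 4, 8, 12, 24 h)
survival     two-arm exponential time-to-event cohorts with administrative
             censoring
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .catalog import FAIL_ENTRIES, PASS_ENTRIES, CatalogEntry
from .errors import ConfigurationError, GenerationError
from .ligand_screen import RULE_NAMES, DescriptorSet, Molecule
from .pharmacometrics import PKProfile, SurvivalRecord
from .rhythm_kinetics import LuminescenceTrace
from .structure_analysis import (
    Atom,
    Pose,
    ProteinStructure,
    Residue,
    Trajectory,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticMolecule",
    "SyntheticPocket",
    "SyntheticTrajectory",
    "SyntheticTrace",
    "SyntheticPK",
    "SyntheticCohort",
    "gen_ligand_library",
    "gen_pocket_and_pose",
    "gen_rotamer_trajectory",
    "gen_luminescence",
    "gen_decay_curve",
    "gen_pk_profile",
    "gen_survival_cohort",
    "generate",
    "STAGES",
    "PK_DESIGN_TIMEPOINTS",
]

STAGES = ("library", "pocket", "trajectory", "luminescence", "decay", "pk", "survival")

PK_DESIGN_TIMEPOINTS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)

_METHYL_MASS = 14.027  # CH2 increment of a methyl replacing an aromatic H


@dataclass(frozen=True)
class GeneratorConfig:
    """Declarative description of one synthetic dataset."""

    seed: int
    stage: str
    params: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.stage not in STAGES:
            raise ConfigurationError(
                f"unknown stage {self.stage!r}; expected one of {STAGES}"
            )


# ---------------------------------------------------------------------------
# ligand library


@dataclass
class SyntheticMolecule(Molecule):
    """Library member carrying the generator's intended ground truth."""

    true_descriptors: DescriptorSet | None = None
    intended_failed_rules: tuple[str, ...] = ()
    catalog_key: str = ""
    n_methyls: int = 0


def _normalize_profile(profile) -> dict[str, float]:
    """Return per-rule violation fractions; empty dict means all-pass."""
    if profile == "all-pass":
        return {}
    if isinstance(profile, str):
        if profile.startswith("fail-one:"):
            try:
                frac = float(profile.split(":", 1)[1])
            except ValueError:
                raise ConfigurationError(f"bad profile fraction in {profile!r}") from None
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("violation fraction must lie in [0, 1]")
            return {rule: frac / len(RULE_NAMES) for rule in RULE_NAMES}
        raise ConfigurationError(f"unknown profile {profile!r}")
    fractions = dict(profile)
    unknown = set(fractions) - set(RULE_NAMES)
    if unknown:
        raise ConfigurationError(f"unknown profile keys: {sorted(unknown)}")
    total = sum(fractions.values())
    if any(f < 0 for f in fractions.values()) or total > 1.0 + 1e-12:
        raise ConfigurationError("violation fractions must be >= 0 and sum to <= 1")
    return fractions


def _methylate(smiles: str, n: int, rng: np.random.Generator) -> str:
    """Attach ``n`` methyls at random aromatic C-H positions."""
    from rdkit import Chem

    base = Chem.MolFromSmiles(smiles)
    aromatic_ch = {
        a.GetIdx()
        for a in base.GetAtoms()
        if a.GetIsAromatic() and a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    }
    Chem.Kekulize(base, clearAromaticFlags=True)
    mol = Chem.RWMol(base)
    for _ in range(n):
        sites = sorted(aromatic_ch)
        site = sites[int(rng.integers(len(sites)))]
        aromatic_ch.discard(site)
        new_idx = mol.AddAtom(Chem.Atom(6))
        mol.AddBond(site, new_idx, Chem.BondType.SINGLE)
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


_FAILERS = {e.fails: e for e in FAIL_ENTRIES}


def gen_ligand_library(
    n: int = 100, seed: int = 0, profile="all-pass"
) -> list[SyntheticMolecule]:
    """Generate ``n`` molecules with known per-rule filter verdicts.

    ``profile`` is ``"all-pass"``, ``"fail-one:<fraction>"`` (the fraction of
    molecules that violate exactly one rule, spread evenly over the seven),
    or a mapping of rule name to violation fraction.  Violating molecules
    come from single-rule failer scaffolds; passing molecules are drawn from
    the pass-all scaffolds with 0-3 methyl decorations (mass ground truth is
    adjusted by 14.027 Da per methyl; every other count is unaffected and the
    logP margin absorbs the perturbation).
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    fractions = _normalize_profile(profile)
    rng = np.random.default_rng(seed)
    rules = list(fractions)
    edges = np.cumsum([fractions[r] for r in rules])
    out: list[SyntheticMolecule] = []
    for i in range(n):
        u = rng.random()
        rule = None
        for r, edge in zip(rules, edges):
            if u < edge:
                rule = r
                break
        if rule is not None:
            entry = _FAILERS[rule]
            out.append(
                SyntheticMolecule(
                    id=f"LIG{i + 1:06d}",
                    smiles=entry.smiles,
                    true_descriptors=entry.descriptors,
                    intended_failed_rules=(rule,),
                    catalog_key=entry.key,
                )
            )
            continue
        entry: CatalogEntry = PASS_ENTRIES[int(rng.integers(len(PASS_ENTRIES)))]
        k = int(rng.integers(entry.max_methyls + 1))
        smiles = _methylate(entry.smiles, k, rng) if k else entry.smiles
        d = entry.descriptors
        true = DescriptorSet(
            hbd=d.hbd, hba=d.hba, mw=d.mw + _METHYL_MASS * k, logp=d.logp,
            rotb=d.rotb, aromatic_rings=d.aromatic_rings, ring_count=d.ring_count,
        )
        out.append(
            SyntheticMolecule(
                id=f"LIG{i + 1:06d}",
                smiles=smiles,
                true_descriptors=true,
                intended_failed_rules=(),
                catalog_key=entry.key,
                n_methyls=k,
            )
        )
    return out


# ---------------------------------------------------------------------------
# pocket and pose

_POCKET_RADIUS = 16.0  # residue feature points sit on this circle, Angstrom
_RESNUM_PREFS = {"TRP": [292, 399], "ARG": [293], "SER": [396, 414]}

_CONTACT_TYPES = ("hbond", "pi-pi", "pi-alkyl", "vdw")
_TYPE_CUTOFF = {"hbond": 3.5, "pi-pi": 5.5, "pi-alkyl": 4.5, "vdw": 3.9}
_TYPE_MIN = {"hbond": 2.4, "pi-pi": 3.0, "pi-alkyl": 3.0, "vdw": 3.0}


@dataclass
class SyntheticPocket:
    protein: ProteinStructure
    pose: Pose
    true_contacts: list[tuple[str, str, float]]  # (residue id, type, distance)

    def fingerprint(self) -> set[tuple[str, str]]:
        return {(rid, kind) for rid, kind, _ in self.true_contacts}


def _regular_polygon(n: int, side: float) -> np.ndarray:
    radius = side / (2.0 * math.sin(math.pi / n))
    angles = np.arange(n) * 2.0 * math.pi / n
    return np.column_stack(
        [radius * np.cos(angles), radius * np.sin(angles), np.zeros(n)]
    )


def _build_indole() -> dict[str, np.ndarray]:
    """Planar idealized indole (z = 0), 6-ring centroid at the origin."""
    hexagon = _regular_polygon(6, 1.39)
    names6 = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
    coords = {name: hexagon[i] for i, name in enumerate(names6)}
    # fuse the pentagon on the CD2-CE2 edge, ring order CG-CD1-NE1-CE2-CD2
    p1, p2 = coords["CD2"], coords["CE2"]
    mid = (p1 + p2) / 2.0
    out_dir = mid / np.linalg.norm(mid)
    apothem = 1.39 / (2.0 * math.tan(math.pi / 5))
    center5 = mid + apothem * out_dir
    vertices = {}
    for k in range(5):
        ang = 2.0 * math.pi * k / 5
        rot = np.array(
            [[math.cos(ang), -math.sin(ang), 0.0],
             [math.sin(ang), math.cos(ang), 0.0],
             [0.0, 0.0, 1.0]]
        )
        vertices[k] = center5 + rot @ (p1 - center5)
    # pick the rotation direction that walks CD2 -> CG -> CD1 -> NE1 -> CE2
    if np.linalg.norm(vertices[4] - p2) < 1e-6:
        order = [vertices[1], vertices[2], vertices[3]]
    else:
        order = [vertices[4], vertices[3], vertices[2]]
    coords["CG"], coords["CD1"], coords["NE1"] = order
    # planar backbone stub growing away from the pentagon
    cg = coords["CG"]
    away = cg - center5
    away /= np.linalg.norm(away)
    coords["CB"] = cg + 1.53 * away
    coords["CA"] = coords["CB"] + 1.53 * _rot_z(away, math.radians(50.0))
    coords["N"] = coords["CA"] + 1.46 * _rot_z(away, math.radians(-50.0))
    return coords


def _rot_z(v: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def _zigzag_chain(names: Sequence[str], lengths: Sequence[float]) -> dict[str, np.ndarray]:
    """Planar zigzag with 120-degree angles, first atom at the origin,
    growing toward -x."""
    coords = {names[0]: np.zeros(3)}
    direction_up = True
    pos = np.zeros(3)
    for name, length in zip(names[1:], lengths):
        dy = math.sin(math.radians(30.0)) * (1 if direction_up else -1)
        dx = -math.cos(math.radians(30.0))
        step = np.array([dx, dy, 0.0])
        pos = pos + length * step
        coords[name] = pos
        direction_up = not direction_up
    return coords


def _build_residue_template(resname: str, kind: str) -> tuple[dict[str, np.ndarray], dict]:
    """Local-frame template with the contact feature at the origin and the
    probe direction +x.  Returns (coords, info) where info carries ring
    definitions and probe placement hints."""
    if resname == "TRP":
        indole = _build_indole()
        if kind in ("pi-pi", "pi-alkyl"):
            # ring plane -> yz-plane so the 6-ring normal is +x
            center5 = np.mean([indole[n] for n in ("CG", "CD1", "NE1", "CE2", "CD2")], axis=0)
            w = -center5 / np.linalg.norm(center5)  # in-plane, away from pentagon
            coords = {}
            for name, xyz in indole.items():
                # local (y, z) = in-plane coordinates, x = out-of-plane (0)
                coords[name] = np.array([0.0, xyz[0], xyz[1]])
            w3 = np.array([0.0, w[0], w[1]])
            return coords, {"tilt_dir": w3}
        if kind in ("hbond", "vdw"):
            feature = "NE1" if kind == "hbond" else "CB"
            # exterior direction at the feature atom
            if kind == "hbond":
                neighbors = (indole["CD1"] + indole["CE2"]) / 2.0
                ext = indole["NE1"] - neighbors
            else:
                ext = indole["CB"] - indole["CG"]
            ext /= np.linalg.norm(ext)
            # rotate template so feature sits at origin with ext -> +x
            shifted = {k: v - indole[feature] for k, v in indole.items()}
            angle = -math.atan2(ext[1], ext[0])
            coords = {k: _rot_z(v, angle) for k, v in shifted.items()}
            return coords, {}
        raise GenerationError(f"unsupported interaction {kind!r} for TRP")
    if resname == "ARG":
        if kind in ("pi-pi", "pi-alkyl"):
            raise GenerationError("ARG has no aromatic ring for pi interactions")
        chain = _zigzag_chain(
            ["NH1", "CZ", "NE", "CD", "CG", "CB", "CA", "N"],
            [1.33, 1.33, 1.46, 1.52, 1.52, 1.53, 1.46],
        )
        # NH2 on the other side of CZ
        cz = chain["CZ"]
        chain["NH2"] = cz + _rot_z(chain["NH1"] - cz, math.radians(120.0))
        if kind == "vdw":
            shifted = {k: v - chain["CB"] for k, v in chain.items()}
            ext = chain["CB"] - chain["CG"]
            ext /= np.linalg.norm(ext)
            angle = -math.atan2(ext[1], ext[0])
            return {k: _rot_z(v, angle) for k, v in shifted.items()}, {}
        return chain, {}
    if resname == "SER":
        if kind in ("pi-pi", "pi-alkyl"):
            raise GenerationError("SER has no aromatic ring for pi interactions")
        chain = _zigzag_chain(["OG", "CB", "CA", "N"], [1.42, 1.53, 1.46])
        if kind == "vdw":
            shifted = {k: v - chain["CB"] for k, v in chain.items()}
            ext = chain["CB"] - chain["OG"]
            ext /= np.linalg.norm(ext)
            angle = -math.atan2(ext[1], ext[0])
            return {k: _rot_z(v, angle) for k, v in shifted.items()}, {}
        return chain, {}
    raise GenerationError(f"residue type {resname!r} not in the pocket vocabulary")


_ELEMENT_FROM_NAME = lambda name: name[:1]


def gen_pocket_and_pose(
    seed: int = 0,
    contact_spec: Sequence[tuple[str, str, float]] = (),
) -> SyntheticPocket:
    """Build an idealized pocket realizing each requested contact exactly.

    ``contact_spec`` entries are (residue type in {TRP, ARG, SER},
    interaction type in {hbond, pi-pi, pi-alkyl, vdw}, distance in Angstrom).
    Residues are spaced around a 16 Angstrom circle so contacts cannot
    cross-talk; an empty spec yields a default TRP/ARG/SER pocket with the
    ligand core >= 10 Angstrom from every residue.  Unsatisfiable requests
    (pi interactions on ARG/SER, distances beyond the type cutoff) raise
    :class:`GenerationError`.
    """
    rng = np.random.default_rng(seed)
    spec = list(contact_spec)
    for resname, kind, dist in spec:
        if resname not in ("TRP", "ARG", "SER"):
            raise GenerationError(f"residue type {resname!r} not supported")
        if kind not in _CONTACT_TYPES:
            raise GenerationError(f"unknown interaction type {kind!r}")
        if dist <= 0:
            raise GenerationError("contact distances must be positive")
        if not _TYPE_MIN[kind] <= dist <= _TYPE_CUTOFF[kind]:
            raise GenerationError(
                f"{kind} at {dist:.2f} A is geometrically unsatisfiable "
                f"(needs {_TYPE_MIN[kind]}-{_TYPE_CUTOFF[kind]} A)"
            )

    slots = spec if spec else [("TRP", None, None), ("ARG", None, None), ("SER", None, None)]
    n_slots = len(slots)
    counters: dict[str, int] = {}
    residues: list[Residue] = []
    lig_atoms: list[Atom] = []
    lig_rings: list[tuple[int, ...]] = []
    true_contacts: list[tuple[str, str, float]] = []
    atom_serial = 0

    for i, (resname, kind, dist) in enumerate(slots):
        theta = 2.0 * math.pi * i / max(n_slots, 1)
        u = np.array([math.cos(theta), math.sin(theta), 0.0])  # outward
        # rotate the +x local frame onto -u (probe direction points inward)
        angle = math.atan2(-u[1], -u[0])
        build_kind = kind if kind is not None else ("hbond" if resname != "TRP" else "pi-pi")
        coords, info = _build_residue_template(resname, build_kind)

        def to_world(v: np.ndarray) -> np.ndarray:
            return _rot_z(v, angle) + _POCKET_RADIUS * u

        prefs = _RESNUM_PREFS[resname]
        idx = counters.get(resname, 0)
        counters[resname] = idx + 1
        resnum = prefs[idx] if idx < len(prefs) else 500 + i
        atoms = [
            Atom(name, "N" if name.startswith("N") else ("O" if name.startswith("O") else "C"),
                 to_world(xyz),
                 aromatic=resname == "TRP" and name in
                 ("CG", "CD1", "NE1", "CE2", "CD2", "CE3", "CZ2", "CZ3", "CH2"))
            for name, xyz in coords.items()
        ]
        res = Residue("A", resnum, resname, atoms)
        residues.append(res)

        if kind is None:
            continue
        inward = -u
        if kind == "hbond":
            probe = to_world(np.zeros(3)) + dist * inward
            atom_serial += 1
            lig_atoms.append(Atom(f"O{atom_serial}", "O", probe))
        elif kind == "pi-alkyl":
            tilt = math.radians(25.0)
            w_world = _rot_z(info["tilt_dir"], angle)
            probe = (
                to_world(np.zeros(3))
                + dist * (math.cos(tilt) * inward + math.sin(tilt) * w_world)
            )
            atom_serial += 1
            lig_atoms.append(Atom(f"C{atom_serial}", "C", probe))
        elif kind == "pi-pi":
            centroid = to_world(np.zeros(3)) + dist * inward
            ring_local = _regular_polygon(6, 1.39)
            start = len(lig_atoms)
            for v in ring_local:
                # ring plane parallel to the indole plane (perpendicular to inward)
                offset = _rot_z(np.array([0.0, v[0], v[1]]), angle)
                atom_serial += 1
                lig_atoms.append(
                    Atom(f"C{atom_serial}", "C", centroid + offset, aromatic=True)
                )
            lig_rings.append(tuple(range(start, start + 6)))
        elif kind == "vdw":
            probe = to_world(np.zeros(3)) + dist * inward
            atom_serial += 1
            lig_atoms.append(Atom(f"C{atom_serial}", "C", probe))
        true_contacts.append((res.id, kind, float(dist)))

    # small aliphatic core at the pocket center, far from every residue
    jitter = rng.normal(scale=0.05, size=(3, 3))
    core = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.5, 0.0]]) + jitter
    for xyz in core:
        atom_serial += 1
        lig_atoms.append(Atom(f"C{atom_serial}", "C", xyz))

    protein = ProteinStructure(residues)
    pose = Pose(atoms=lig_atoms, rings=tuple(lig_rings))
    return SyntheticPocket(protein=protein, pose=pose, true_contacts=true_contacts)


# ---------------------------------------------------------------------------
# rotamer trajectories


@dataclass
class SyntheticTrajectory:
    trajectory: Trajectory
    true_chi1: dict[str, np.ndarray]  # residue id -> degrees per frame


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def gen_rotamer_trajectory(
    residues: Sequence[tuple[str, Sequence[float], Sequence[float], Sequence[float]]] = (
        ("TRP", (180.0,), (20.0,), (1.0,)),
    ),
    n_frames: int = 100,
    dt: float = 10.0,
    seed: int = 0,
    rigid_motion: bool = False,
) -> SyntheticTrajectory:
    """Four-atom residues whose chi1 follows a von Mises mixture.

    ``residues`` entries are (name, state means in degrees, concentrations
    kappa, weights); ``math.inf`` concentration collapses a state to a delta
    at its mean.  Each frame places N, CA, CB at idealized geometry
    (N-CA 1.46, CA-CB 1.53, CB-gamma 1.52 Angstrom, tetrahedral angles) and
    rotates the gamma atom about the CA-CB axis to realize the sampled
    angle.  ``rigid_motion`` applies an independent random rigid-body
    transform per frame; the angle stream is drawn from its own child
    generator, so toggling rigid motion leaves the chi1 series unchanged.
    """
    if n_frames < 1:
        raise ConfigurationError("n_frames must be >= 1")
    if not residues:
        raise ConfigurationError("at least one residue spec required")
    seq = np.random.SeedSequence(seed)
    child_angles, child_rigid = seq.spawn(2)
    rng_angles = np.random.default_rng(child_angles)
    rng_rigid = np.random.default_rng(child_rigid)

    theta_t = math.acos(-1.0 / 3.0)  # tetrahedral, ~109.47 deg

    table = []
    base_coords = []
    chi_truth: dict[str, np.ndarray] = {}
    all_samples = []
    for r, (name, means, kappas, weights) in enumerate(residues):
        means = np.asarray(means, dtype=float)
        kappas = np.asarray(kappas, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if not (len(means) == len(kappas) == len(weights)):
            raise ConfigurationError("means, concentrations and weights must align")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ConfigurationError("rotamer state weights must sum to 1")
        comp = rng_angles.choice(len(weights), size=n_frames, p=weights)
        chi = np.empty(n_frames)
        for j in range(len(weights)):
            mask = comp == j
            n_j = int(mask.sum())
            if n_j == 0:
                continue
            if math.isinf(kappas[j]):
                chi[mask] = math.radians(means[j])
            else:
                chi[mask] = rng_angles.vonmises(math.radians(means[j]), kappas[j], n_j)
        chi_deg = np.degrees(np.arctan2(np.sin(chi), np.cos(chi)))
        chi_deg[chi_deg <= -180.0] += 360.0
        all_samples.append(chi)

        gamma_name = "OG" if name == "SER" else "CG"
        gamma_elem = "O" if name == "SER" else "C"
        offset = np.array([12.0 * r, 0.0, 0.0])
        ca = offset
        cb = offset + np.array([0.0, 0.0, 1.53])
        n_at = offset + 1.46 * np.array([math.sin(theta_t), 0.0, math.cos(theta_t)])
        table.extend(
            [
                ("A", r + 1, name, "N", "N"),
                ("A", r + 1, name, "CA", "C"),
                ("A", r + 1, name, "CB", "C"),
                ("A", r + 1, name, gamma_name, gamma_elem),
            ]
        )
        base_coords.append((n_at, ca, cb))
        chi_truth[f"A:{r + 1}:{name}"] = chi_deg

    n_atoms = 4 * len(residues)
    coords = np.zeros((n_frames, n_atoms, 3))
    for r, ((n_at, ca, cb), chi) in enumerate(zip(base_coords, all_samples)):
        v = cb - ca
        v_hat = v / np.linalg.norm(v)
        # reference perpendicular toward N gives chi1 = 0 (syn)
        n_perp = (n_at - ca) - np.dot(n_at - ca, v_hat) * v_hat
        w0 = n_perp / np.linalg.norm(n_perp)
        w_ortho = np.cross(v_hat, w0)
        cos_b = math.cos(math.pi - theta_t)  # angle of CB->G with +v
        sin_b = math.sin(math.pi - theta_t)
        base = 4 * r
        for f in range(n_frames):
            # IUPAC-positive chi corresponds to rotating w0 by -chi about v
            ang = -chi[f]
            w_chi = math.cos(ang) * w0 + math.sin(ang) * w_ortho
            g = cb + 1.52 * (cos_b * v_hat + sin_b * w_chi)
            coords[f, base + 0] = n_at
            coords[f, base + 1] = ca
            coords[f, base + 2] = cb
            coords[f, base + 3] = g

    if rigid_motion:
        for f in range(n_frames):
            rot = _random_rotation(rng_rigid)
            trans = rng_rigid.uniform(-20.0, 20.0, size=3)
            coords[f] = coords[f] @ rot.T + trans

    traj = Trajectory(atom_table=table, coords=coords, dt=dt)
    return SyntheticTrajectory(trajectory=traj, true_chi1=chi_truth)


# ---------------------------------------------------------------------------
# kinetic traces


@dataclass
class SyntheticTrace:
    trace: LuminescenceTrace
    truth: dict


def gen_luminescence(
    period: float = 24.0,
    amplitude: float = 100.0,
    damping: float = 0.01,
    phase: float = 0.0,
    baseline: float = 200.0,
    trend: float = 0.0,
    sigma: float = 0.0,
    duration: float = 120.0,
    step: float = 0.5,
    seed: int = 0,
) -> SyntheticTrace:
    """Damped-cosine reporter trace:
    y = baseline + trend*t + A*exp(-damping*t)*cos(2*pi*(t - phase)/period) + noise.
    """
    if period <= 0 or step <= 0:
        raise ConfigurationError("period and step must be positive")
    if damping < 0 or sigma < 0:
        raise ConfigurationError("damping and sigma must be >= 0")
    if duration < 2.0 * period:
        raise ConfigurationError(
            f"duration {duration} h must cover at least two periods ({2 * period} h)"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + step / 2.0, step)
    clean = baseline + trend * t + amplitude * np.exp(-damping * t) * np.cos(
        2.0 * math.pi * (t - phase) / period
    )
    noise = rng.normal(scale=sigma, size=t.size) if sigma > 0 else 0.0
    trace = LuminescenceTrace(time=t, signal=clean + noise, metadata={"stage": "luminescence"})
    return SyntheticTrace(
        trace=trace,
        truth=dict(period=period, amplitude=amplitude, damping=damping,
                   phase=phase, baseline=baseline, trend=trend, sigma=sigma),
    )


def gen_decay_curve(
    y0: float = 1000.0,
    plateau: float = 0.0,
    k: float = 0.1155,
    sigma: float = 0.0,
    duration: float = 24.0,
    step: float = 1.0 / 6.0,
    seed: int = 0,
) -> SyntheticTrace:
    """One-phase exponential decay trace: y = (y0 - plateau)*exp(-kt) + plateau."""
    if k <= 0:
        raise ConfigurationError("decay rate k must be positive")
    if plateau < 0 or y0 < plateau:
        raise ConfigurationError("need y0 >= plateau >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + step / 2.0, step)
    clean = (y0 - plateau) * np.exp(-k * t) + plateau
    noise = rng.normal(scale=sigma, size=t.size) if sigma > 0 else 0.0
    trace = LuminescenceTrace(time=t, signal=clean + noise, metadata={"stage": "decay"})
    return SyntheticTrace(
        trace=trace,
        truth=dict(y0=y0, plateau=plateau, k=k, t_half=math.log(2.0) / k, sigma=sigma),
    )


@dataclass
class SyntheticPK:
    profile: PKProfile
    truth: dict


def gen_pk_profile(
    dose: float = 100.0,
    bioavailability: float = 0.9,
    volume: float = 5.0,
    ka: float = 1.0,
    kel: float = 0.127,
    times: Sequence[float] = PK_DESIGN_TIMEPOINTS,
    cv: float = 0.0,
    seed: int = 0,
) -> SyntheticPK:
    """One-compartment first-order-absorption profile with lognormal noise.

    C(t) = F*D*ka / (V*(ka - kel)) * (exp(-kel*t) - exp(-ka*t)); the noise is
    mean-one multiplicative lognormal with coefficient of variation ``cv``,
    matching bioanalytical error structure (concentrations stay positive).
    """
    if ka <= 0 or kel <= 0:
        raise ConfigurationError("ka and kel must be positive")
    if ka == kel:
        raise ConfigurationError("ka must differ from kel (flip-flop limit rejected)")
    rng = np.random.default_rng(seed)
    t = np.asarray(list(times), dtype=float)
    conc = (
        bioavailability * dose * ka / (volume * (ka - kel))
        * (np.exp(-kel * t) - np.exp(-ka * t))
    )
    conc = np.clip(conc, 0.0, None)
    if cv > 0:
        s = math.sqrt(math.log(1.0 + cv**2))
        conc = conc * np.exp(rng.normal(scale=s, size=t.size) - s**2 / 2.0)
    tmax_true = math.log(ka / kel) / (ka - kel)
    return SyntheticPK(
        profile=PKProfile(time=t, concentration=conc,
                          metadata={"dose_mg_kg": dose, "route": "i.p."}),
        truth=dict(dose=dose, F=bioavailability, V=volume, ka=ka, kel=kel,
                   t_half=math.log(2.0) / kel, tmax=tmax_true, cv=cv),
    )


@dataclass
class SyntheticCohort:
    records: list[SurvivalRecord]
    truth: dict


def gen_survival_cohort(
    n_per_arm: int = 9,
    median_ctrl: float = 24.0,
    hazard_ratio: float = 0.7,
    censor_at: float = 40.0,
    seed: int = 0,
) -> SyntheticCohort:
    """Two-arm exponential survival cohort with administrative censoring.

    Control events are exponential with rate ln2/median_ctrl; the treated
    arm's rate is hazard_ratio times that (hazard_ratio < 1 = protective).
    Subjects alive at ``censor_at`` weeks are censored there.
    """
    if n_per_arm < 2:
        raise ConfigurationError("n_per_arm must be >= 2")
    if hazard_ratio <= 0 or median_ctrl <= 0:
        raise ConfigurationError("hazard_ratio and median_ctrl must be positive")
    if censor_at < 0:
        raise ConfigurationError("censor_at must be >= 0")
    rng = np.random.default_rng(seed)
    rate_ctrl = math.log(2.0) / median_ctrl
    records: list[SurvivalRecord] = []
    for arm, rate in (("vehicle", rate_ctrl), ("treated", hazard_ratio * rate_ctrl)):
        raw = rng.exponential(scale=1.0 / rate, size=n_per_arm)
        for i, t_event in enumerate(raw):
            observed = t_event <= censor_at
            records.append(
                SurvivalRecord(
                    subject=f"{arm[:1].upper()}{i + 1:03d}",
                    arm=arm,
                    time=float(t_event if observed else censor_at),
                    event=bool(observed),
                )
            )
    return SyntheticCohort(
        records=records,
        truth=dict(
            n_per_arm=n_per_arm, median_ctrl=median_ctrl,
            median_treated=median_ctrl / hazard_ratio,
            hazard_ratio=hazard_ratio, censor_at=censor_at,
        ),
    )


# ---------------------------------------------------------------------------
# dispatcher

_GENERATORS = {
    "library": gen_ligand_library,
    "pocket": gen_pocket_and_pose,
    "trajectory": gen_rotamer_trajectory,
    "luminescence": gen_luminescence,
    "decay": gen_decay_curve,
    "pk": gen_pk_profile,
    "survival": gen_survival_cohort,
}


def generate(config: GeneratorConfig):
    """Run the generator named by ``config.stage`` with ``config.params``."""
    import inspect

    func = _GENERATORS[config.stage]
    sig = inspect.signature(func)
    unknown = set(config.params) - set(sig.parameters)
    if unknown:
        raise ConfigurationError(
            f"unknown parameters for stage {config.stage!r}: {sorted(unknown)}"
        )
    return func(**{**config.params, "seed": config.seed})
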