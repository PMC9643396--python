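"""Drug-likeness descriptors, the seven-rule library filter, and energy triage.

The screening cascade this module supports is the front end of a
structure-based discovery campaign against the CRY1 primary pocket: a large
vendor library is reduced by physicochemical rules before docking, and the
docked hits are triaged by binding energy to a short list for wet-lab
follow-up.

Descriptor conventions
----------------------
hbd
    Hydrogen-bond donor count.  Default convention counts donor *hydrogens*
    (every O-H and N-H hydrogen contributes 1, the classic Lipinski count);
    ``hbd_convention="heavy"`` counts donor heavy atoms instead.
hba
    Hydrogen-bond acceptor count: number of nitrogen and oxygen atoms.
mw
    Average-atomic-weight molecular mass in Da.
logp
    Crippen atom-contribution octanol/water partition estimate; a
    library-supplied precomputed value overrides it.
rotb
    Rotatable bonds: non-ring single bonds between non-terminal heavy atoms,
    amide C-N excluded (strict definition).
aromatic_rings / ring_count
    SSSR rings whose atoms are all aromatic / total SSSR ring count.  The
    aromaticity model is RDKit's default perception and is recorded in the
    screen summary metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .errors import AnalysisError, MoleculeParseError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "DescriptorSet",
    "Molecule",
    "FilterRules",
    "FilterVerdict",
    "DockResult",
    "ScreenSummary",
    "TriageResult",
    "compute_descriptors",
    "apply_filter",
    "screen_library",
    "triage_by_energy",
    "read_smi",
    "write_smi",
    "read_sdf",
    "RULE_NAMES",
]

RULE_NAMES = ("hbd", "hba", "mw", "logp", "rotb", "aromatic_rings", "ring_count")


@dataclass(frozen=True)
class DescriptorSet:
    """The seven descriptors the library filter consumes."""

    hbd: int
    hba: int
    mw: float
    logp: float
    rotb: int
    aromatic_rings: int
    ring_count: int

    def __post_init__(self) -> None:
        for name in ("hbd", "hba", "rotb", "aromatic_rings", "ring_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.aromatic_rings > self.ring_count:
            raise ValueError("aromatic_rings cannot exceed ring_count")


@dataclass
class Molecule:
    """A library member: id, SMILES, and an optional precomputed descriptor set.

    When ``descriptors`` is present (vendor-supplied properties), screening
    uses it verbatim instead of recomputing from the SMILES.
    """

    id: str
    smiles: str
    descriptors: DescriptorSet | None = None


@dataclass(frozen=True)
class FilterRules:
    """Thresholds of the seven-rule drug-likeness filter.

    Defaults are the campaign's screening rules: hbd < 7, hba < 12,
    mw < 600 Da, logP < 7, rotatable bonds <= 8, >= 3 aromatic rings and
    >= 4 rings in total.  Strict/non-strict inequalities follow the stated
    rules exactly (hbd of exactly 7 fails; rotb of exactly 8 passes).
    """

    hbd_lt: int = 7
    hba_lt: int = 12
    mw_lt: float = 600.0
    logp_lt: float = 7.0
    rotb_le: int = 8
    aromatic_rings_ge: int = 3
    ring_count_ge: int = 4

    def evaluate(self, d: DescriptorSet) -> dict[str, bool]:
        return {
            "hbd": d.hbd < self.hbd_lt,
            "hba": d.hba < self.hba_lt,
            "mw": d.mw < self.mw_lt,
            "logp": d.logp < self.logp_lt,
            "rotb": d.rotb <= self.rotb_le,
            "aromatic_rings": d.aromatic_rings >= self.aromatic_rings_ge,
            "ring_count": d.ring_count >= self.ring_count_ge,
        }


DEFAULT_RULES = FilterRules()


@dataclass(frozen=True)
class FilterVerdict:
    """Outcome of the seven-rule filter with complete failure attribution."""

    flags: Mapping[str, bool]
    overall: bool
    failed_rules: tuple[str, ...]


@dataclass(frozen=True)
class DockResult:
    """One docking outcome: molecule id and Vina-style binding energy."""

    molecule_id: str
    energy: float  # kcal/mol, more negative = stronger

    def __post_init__(self) -> None:
        import math

        if not math.isfinite(self.energy):
            raise ValueError(f"energy must be finite, got {self.energy}")


@dataclass
class ScreenSummary:
    passed: list[Molecule]
    pass_count: int
    total: int
    failure_tallies: dict[str, int]
    verdicts: dict[str, FilterVerdict]
    rejected_records: list[tuple[str, str]]  # (id, reason)
    metadata: dict = field(default_factory=dict)


@dataclass
class TriageResult:
    selected: list[DockResult]
    energy_min: float | None
    energy_max: float | None
    truncated: bool  # True when fewer results were available than requested


def _mol_from_smiles(smiles: str, record_id: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise MoleculeParseError(record_id)
    return mol


def compute_descriptors(m: Molecule, hbd_convention: str = "hydrogens") -> DescriptorSet:
    """Compute the seven-descriptor set for a molecule from its SMILES.

    Parameters
    ----------
    m
        Molecule whose ``smiles`` is parsed; a precomputed ``descriptors``
        attribute is *not* consulted here (see :func:`screen_library`).
    hbd_convention
        ``"hydrogens"`` counts each O-H/N-H hydrogen (default);
        ``"heavy"`` counts donor heavy atoms bearing at least one hydrogen.
    """
    if hbd_convention not in ("hydrogens", "heavy"):
        raise ValueError(f"unknown hbd_convention {hbd_convention!r}")
    mol = _mol_from_smiles(m.smiles, m.id)
    if hbd_convention == "hydrogens":
        hbd = Lipinski.NHOHCount(mol)
    else:
        # donor heavy atoms: every N or O bearing at least one hydrogen
        hbd = sum(
            1
            for a in mol.GetAtoms()
            if a.GetSymbol() in ("N", "O") and a.GetTotalNumHs() >= 1
        )
    return DescriptorSet(
        hbd=hbd,
        hba=Lipinski.NOCount(mol),
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        rotb=rdMolDescriptors.CalcNumRotatableBonds(
            mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
        ),
        aromatic_rings=rdMolDescriptors.CalcNumAromaticRings(mol),
        ring_count=rdMolDescriptors.CalcNumRings(mol),
    )


def apply_filter(d: DescriptorSet, rules: FilterRules = DEFAULT_RULES) -> FilterVerdict:
    """Evaluate all seven rules (no short-circuit) and attribute failures."""
    flags = rules.evaluate(d)
    failed = tuple(name for name in RULE_NAMES if not flags[name])
    return FilterVerdict(flags=flags, overall=not failed, failed_rules=failed)


def screen_library(
    lib: Sequence[Molecule],
    rules: FilterRules = DEFAULT_RULES,
    hbd_convention: str = "hydrogens",
) -> ScreenSummary:
    """Filter a library, tallying per-rule failures and collecting parse rejects.

    Molecules carrying a precomputed :class:`DescriptorSet` are judged on it
    verbatim; all others are computed from SMILES.  Unparseable records are
    reported in ``rejected_records`` and screening continues.
    """
    if not lib:
        raise AnalysisError("screen_library requires a nonempty library")
    passed: list[Molecule] = []
    tallies = {name: 0 for name in RULE_NAMES}
    verdicts: dict[str, FilterVerdict] = {}
    rejected: list[tuple[str, str]] = []
    for mol in lib:
        try:
            d = mol.descriptors or compute_descriptors(mol, hbd_convention)
        except MoleculeParseError as exc:
            rejected.append((mol.id, str(exc)))
            continue
        verdict = apply_filter(d, rules)
        verdicts[mol.id] = verdict
        for name in verdict.failed_rules:
            tallies[name] += 1
        if verdict.overall:
            passed.append(mol)
    return ScreenSummary(
        passed=passed,
        pass_count=len(passed),
        total=len(lib),
        failure_tallies=tallies,
        verdicts=verdicts,
        rejected_records=rejected,
        metadata={
            "aromaticity_model": "rdkit-default",
            "hbd_convention": hbd_convention,
            "rules": rules,
        },
    )


def triage_by_energy(
    results: Sequence[DockResult],
    n: int,
    window: tuple[float, float] | None = None,
) -> TriageResult:
    """Select the top-``n`` docking results by binding energy.

    Sort is ascending in energy (most negative binding first) with a
    deterministic lexicographic tie-break on molecule id, so the selection is
    invariant to input order.  An optional inclusive energy window
    ``(emin, emax)`` restricts the candidate pool before the cut.  When fewer
    results are available than requested, all are returned and
    ``truncated`` is set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pool = list(results)
    if window is not None:
        emin, emax = window
        if emin > emax:
            raise ValueError("window must satisfy emin <= emax")
        pool = [r for r in pool if emin <= r.energy <= emax]
    pool.sort(key=lambda r: (r.energy, r.molecule_id))
    selected = pool[:n]
    energies = [r.energy for r in selected]
    return TriageResult(
        selected=selected,
        energy_min=min(energies) if energies else None,
        energy_max=max(energies) if energies else None,
        truncated=len(pool) < n,
    )


# ---------------------------------------------------------------------------
# I/O helpers


def read_smi(path) -> list[Molecule]:
    """Read a ``SMILES<TAB>ID`` file; lines without an id get a positional one."""
    mols: list[Molecule] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"MOL{i + 1:06d}"
            mols.append(Molecule(id=mol_id, smiles=smiles))
    return mols


def write_smi(path, mols: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for m in mols:
            fh.write(f"{m.smiles}\t{m.id}\n")


def read_sdf(path) -> list[Molecule]:
    """Read an SDF file; molecule names become ids."""
    mols: list[Molecule] = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            mols.append(Molecule(id=f"SDF{i + 1:06d}", smiles="<unparseable>"))
            continue
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else f"SDF{i + 1:06d}"
        mols.append(Molecule(id=name, smiles=Chem.MolToSmiles(mol)))
    return mols


def attach_descriptor_overrides(
    mols: Sequence[Molecule], overrides: Mapping[str, DescriptorSet]
) -> list[Molecule]:
    """Return molecules with vendor-supplied descriptor sets attached by id."""
    return [
        replace_descriptors(m, overrides[m.id]) if m.id in overrides else m
        for m in mols
    ]


def replace_descriptors(m: Molecule, d: DescriptorSet) -> Molecule:
    return replace(m, descriptors=d) if hasattr(m, "__dataclass_fields__") else m
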