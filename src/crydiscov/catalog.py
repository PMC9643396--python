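"""Hand-verified SMILES catalog backing the synthetic ligand-library generator.

Each entry's counts (hbd, hba, rotb, aromatic rings, total rings) were counted
by hand on the drawn structure and the mass computed from the molecular
formula with standard atomic weights (C 12.011, H 1.008, N 14.007, O 15.999,
I 126.904).  ``logp`` is a frozen nominal Crippen value recorded once for
label bookkeeping; only the rule verdict it implies is treated as ground
truth, with a wide margin to the logP < 7 threshold in every entry that is
not a deliberate logP failer.

``fails`` names the single screening rule the entry is designed to violate
(``None`` for pass-all scaffolds), judged against the default seven-rule
filter.  Reference entries (benzene, naphthalene, water) are descriptor
oracles only and are excluded from library sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ligand_screen import DescriptorSet

__all__ = ["CatalogEntry", "PASS_ENTRIES", "FAIL_ENTRIES", "REFERENCE_ENTRIES", "ALL_ENTRIES"]


@dataclass(frozen=True)
class CatalogEntry:
    key: str
    smiles: str
    formula: str
    descriptors: DescriptorSet
    fails: str | None = None  # name of the single violated rule, if any
    # number of aromatic C-H positions safe for methyl decoration without
    # flipping any rule verdict (mass margin > 60 Da, logP margin > 2)
    max_methyls: int = 0


def _d(hbd, hba, mw, logp, rotb, arom, rings) -> DescriptorSet:
    return DescriptorSet(
        hbd=hbd, hba=hba, mw=mw, logp=logp, rotb=rotb,
        aromatic_rings=arom, ring_count=rings,
    )


PASS_ENTRIES: tuple[CatalogEntry, ...] = (
    CatalogEntry("pyrene", "c1cc2ccc3cccc4ccc(c1)c2c34", "C16H10",
                 _d(0, 0, 202.256, 4.58, 0, 4, 4), None, 3),
    CatalogEntry("n-phenylcarbazole", "c1ccc(-n2c3ccccc3c3ccccc32)cc1", "C18H13N",
                 _d(0, 1, 243.309, 4.78, 1, 4, 4), None, 3),
    CatalogEntry("naphthyl-quinoxaline", "c1ccc2nc(-c3ccc4ccccc4c3)cnc2c1", "C18H12N2",
                 _d(0, 2, 256.308, 4.45, 1, 4, 4), None, 3),
    CatalogEntry("carbazolyl-phenol", "Oc1ccc(-n2c3ccccc3c3ccccc32)cc1", "C18H13NO",
                 _d(1, 2, 259.308, 4.49, 1, 4, 4), None, 3),
    CatalogEntry("biphenyl-quinolinamide", "O=C(Nc1ccc(-c2ccccc2)cc1)c1ccc2ccccc2n1",
                 "C22H16N2O", _d(1, 3, 324.383, 5.15, 3, 4, 4), None, 2),
    CatalogEntry("phenyl-fluorenone", "O=C1c2ccccc2-c2ccc(-c3ccccc3)cc21", "C19H12O",
                 _d(0, 1, 256.304, 4.57, 1, 3, 4), None, 3),
    CatalogEntry("anisyl-acridine", "COc1ccc(-c2cc3cc4ccccc4nc3cc2)cc1", "C20H15NO",
                 _d(0, 2, 285.346, 5.06, 2, 4, 4), None, 2),
    CatalogEntry("pyridyl-dibenzofuran", "c1ccc(-c2ccc3c(c2)oc2ccccc23)nc1", "C17H11NO",
                 _d(0, 2, 245.281, 4.65, 1, 4, 4), None, 3),
    CatalogEntry("phenanthrolinyl-phenol", "Oc1ccc(-c2ccnc3c2ccc2cccnc23)cc1", "C18H12N2O",
                 _d(1, 3, 272.307, 4.16, 1, 4, 4), None, 3),
    CatalogEntry("naphthyl-quinazolinone", "O=c1[nH]c2ccccc2n1-c1ccc2ccccc2c1", "C17H12N2O",
                 _d(1, 3, 260.296, 3.47, 1, 4, 4), None, 3),
)

FAIL_ENTRIES: tuple[CatalogEntry, ...] = (
    # 2x NH2 + 3x OH = 7 donor hydrogens -> fails hbd < 7 only
    CatalogEntry("hbd-failer", "Nc1cc(N)c(-n2c3ccc(O)cc3c3cc(O)ccc32)cc1O",
                 "C18H15N3O3", _d(7, 6, 321.336, 3.06, 1, 4, 4), "hbd"),
    # 9 ring N + 3 OMe O = 12 N/O -> fails hba < 12 only
    CatalogEntry("hba-failer",
                 "COc1ccnc(-c2nc(-c3nc(OC)ccn3)nc(-c3nc(OC)ccn3)n2)n1",
                 "C18H15N9O3", _d(0, 12, 405.378, 1.27, 6, 4, 4), "hba"),
    # two iodines push the mass past 600 Da -> fails mw < 600 only
    CatalogEntry("mw-failer",
                 "O=C(c1ccc2c(c1)c1cc(I)ccc1n2-c1ccc(I)cc1)N1CCOCC1",
                 "C23H18I2N2O2", _d(0, 4, 608.217, 5.47, 2, 4, 5), "mw"),
    # tetra-tert-butylpyrene, Crippen logP ~ 9.8 -> fails logp < 7 only
    CatalogEntry("logp-failer",
                 "CC(C)(C)c1cc(C(C)(C)C)c2ccc3c(C(C)(C)C)cc(C(C)(C)C)c4ccc1c2c34",
                 "C32H42", _d(0, 0, 426.688, 9.77, 0, 4, 4), "logp"),
    # triethyleneglycol-monomethyl ether arm: 11 rotatable bonds -> fails rotb <= 8
    CatalogEntry("rotb-failer", "COCCOCCOCCOc1ccc2c(c1)c1ccccc1n2-c1ccccc1",
                 "C25H27NO4", _d(0, 5, 405.494, 4.84, 11, 4, 4), "rotb"),
    # bis-morpholino biphenyl: 4 rings but only 2 aromatic -> fails aromatic_rings >= 3
    CatalogEntry("aromatic-failer", "O1CCN(c2ccc(-c3ccc(N4CCOCC4)cc3)cc2)CC1",
                 "C20H24N2O2", _d(0, 4, 324.424, 3.03, 3, 2, 4), "aromatic_rings"),
    # 2-phenylquinoxaline: 3 aromatic rings but only 3 rings -> fails ring_count >= 4
    CatalogEntry("ring-count-failer", "c1ccc(-c2cnc3ccccc3n2)cc1", "C14H10N2",
                 _d(0, 2, 206.248, 3.30, 1, 3, 3), "ring_count"),
)

REFERENCE_ENTRIES: tuple[CatalogEntry, ...] = (
    CatalogEntry("benzene", "c1ccccc1", "C6H6", _d(0, 0, 78.114, 1.69, 0, 1, 1)),
    CatalogEntry("naphthalene", "c1ccc2ccccc2c1", "C10H8", _d(0, 0, 128.174, 2.84, 0, 2, 2)),
    CatalogEntry("water", "O", "H2O", _d(2, 1, 18.015, -0.82, 0, 0, 0)),
)

ALL_ENTRIES: tuple[CatalogEntry, ...] = PASS_ENTRIES + FAIL_ENTRIES + REFERENCE_ENTRIES
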