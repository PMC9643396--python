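"""Determinism, ground-truth labels and error handling of the generators."""

import math

import numpy as np
import pytest

from crydiscov.errors import ConfigurationError, GenerationError
from crydiscov.synthetic_data import (
    GeneratorConfig,
    gen_decay_curve,
    gen_ligand_library,
    gen_luminescence,
    gen_pk_profile,
    gen_pocket_and_pose,
    gen_rotamer_trajectory,
    gen_survival_cohort,
    generate,
)

# ------------------------------------------------------------- determinism


def test_library_byte_identical_across_calls():
    a = gen_ligand_library(50, seed=42, profile="fail-one:0.3")
    b = gen_ligand_library(50, seed=42, profile="fail-one:0.3")
    assert [(m.id, m.smiles, m.intended_failed_rules) for m in a] == [
        (m.id, m.smiles, m.intended_failed_rules) for m in b
    ]


def test_trajectory_deterministic():
    a = gen_rotamer_trajectory([("TRP", [60.0], [10.0], [1.0])], 20, seed=5,
                               rigid_motion=True)
    b = gen_rotamer_trajectory([("TRP", [60.0], [10.0], [1.0])], 20, seed=5,
                               rigid_motion=True)
    np.testing.assert_array_equal(a.trajectory.coords, b.trajectory.coords)


def test_kinetic_generators_deterministic():
    t1 = gen_luminescence(sigma=5.0, seed=3).trace
    t2 = gen_luminescence(sigma=5.0, seed=3).trace
    np.testing.assert_array_equal(t1.signal, t2.signal)
    p1 = gen_pk_profile(cv=0.2, seed=3).profile
    p2 = gen_pk_profile(cv=0.2, seed=3).profile
    np.testing.assert_array_equal(p1.concentration, p2.concentration)
    c1 = gen_survival_cohort(seed=3).records
    c2 = gen_survival_cohort(seed=3).records
    assert c1 == c2


def test_different_seeds_differ():
    a = gen_luminescence(sigma=5.0, seed=1).trace.signal
    b = gen_luminescence(sigma=5.0, seed=2).trace.signal
    assert not np.array_equal(a, b)


# ------------------------------------------------------------------ library


def test_library_rejects_empty_request():
    with pytest.raises(ConfigurationError):
        gen_ligand_library(0, seed=1)


def test_library_unknown_profile_key():
    with pytest.raises(ConfigurationError):
        gen_ligand_library(10, seed=1, profile={"molecular_volume": 0.2})
    with pytest.raises(ConfigurationError):
        gen_ligand_library(10, seed=1, profile="weird")


def test_library_all_pass_ground_truth(all_pass_library):
    from crydiscov.ligand_screen import apply_filter

    for mol in all_pass_library:
        assert mol.intended_failed_rules == ()
        assert apply_filter(mol.true_descriptors).overall


def test_library_violation_fractions_targeted():
    lib = gen_ligand_library(2000, seed=11, profile={"mw": 0.2, "rotb": 0.1})
    mw_frac = sum(m.intended_failed_rules == ("mw",) for m in lib) / len(lib)
    rotb_frac = sum(m.intended_failed_rules == ("rotb",) for m in lib) / len(lib)
    assert mw_frac == pytest.approx(0.2, abs=0.03)
    assert rotb_frac == pytest.approx(0.1, abs=0.03)


def test_library_methyl_mass_ground_truth():
    """Decorated molecules carry a mass label equal to base + 14.027 per methyl."""
    from crydiscov.ligand_screen import Molecule, compute_descriptors

    lib = gen_ligand_library(60, seed=13, profile="all-pass")
    decorated = [m for m in lib if m.n_methyls > 0]
    assert decorated, "expected some methylated molecules"
    for mol in decorated[:10]:
        d = compute_descriptors(Molecule(mol.id, mol.smiles))
        assert d.mw == pytest.approx(mol.true_descriptors.mw, abs=0.01)
        assert d.hbd == mol.true_descriptors.hbd
        assert d.rotb == mol.true_descriptors.rotb
        assert d.ring_count == mol.true_descriptors.ring_count


# ------------------------------------------------------------------- pocket


def test_pocket_unsatisfiable_specs_raise():
    with pytest.raises(GenerationError):
        gen_pocket_and_pose(1, [("SER", "pi-pi", 4.0)])  # no aromatic ring
    with pytest.raises(GenerationError):
        gen_pocket_and_pose(1, [("TRP", "pi-alkyl", 6.0)])  # beyond cutoff
    with pytest.raises(GenerationError):
        gen_pocket_and_pose(1, [("TRP", "hbond", -1.0)])
    with pytest.raises(GenerationError):
        gen_pocket_and_pose(1, [("LYS", "hbond", 2.9)])


def test_pocket_ground_truth_labels(four_contact_pocket):
    kinds = sorted(kind for _, kind, _ in four_contact_pocket.true_contacts)
    assert kinds == ["hbond", "hbond", "pi-alkyl", "pi-pi"]
    for _, _, dist in four_contact_pocket.true_contacts:
        assert dist > 0


# --------------------------------------------------------------- trajectory


def test_trajectory_weight_normalization_enforced():
    with pytest.raises(ConfigurationError):
        gen_rotamer_trajectory([("TRP", [0.0, 120.0], [5.0, 5.0], [0.5, 0.6])], 10)
    with pytest.raises(ConfigurationError):
        gen_rotamer_trajectory([], 10)
    with pytest.raises(ConfigurationError):
        gen_rotamer_trajectory([("TRP", [0.0], [5.0], [1.0])], 0)


def test_trajectory_circular_mean_recovery(vonmises_trajectory):
    truth = vonmises_trajectory.true_chi1["A:1:TRP"]
    rad = np.radians(truth)
    z = np.exp(1j * rad).mean()
    mean = math.degrees(math.atan2(z.imag, z.real))
    assert abs(mean - (-65.0)) < 2.0  # 1000 frames at kappa = 20


def test_trajectory_multi_residue_layout():
    st = gen_rotamer_trajectory(
        [("TRP", [180.0], [math.inf], [1.0]), ("SER", [-60.0], [math.inf], [1.0])],
        5, seed=2,
    )
    assert st.trajectory.coords.shape == (5, 8, 3)
    assert set(st.true_chi1) == {"A:1:TRP", "A:2:SER"}
    names = [row[3] for row in st.trajectory.atom_table]
    assert names == ["N", "CA", "CB", "CG", "N", "CA", "CB", "OG"]


# ----------------------------------------------------------------- kinetics


def test_luminescence_validation():
    with pytest.raises(ConfigurationError):
        gen_luminescence(period=24.0, duration=40.0)  # < 2 periods
    with pytest.raises(ConfigurationError):
        gen_luminescence(period=-1.0)


def test_luminescence_noiseless_closed_form():
    synth = gen_luminescence(period=24.0, amplitude=10.0, damping=0.05, phase=2.0,
                             baseline=100.0, trend=0.5, sigma=0.0, seed=1)
    t = synth.trace.time
    expected = (100.0 + 0.5 * t
                + 10.0 * np.exp(-0.05 * t) * np.cos(2 * np.pi * (t - 2.0) / 24.0))
    np.testing.assert_allclose(synth.trace.signal, expected, rtol=1e-12)


def test_decay_validation():
    with pytest.raises(ConfigurationError):
        gen_decay_curve(k=-0.1)
    with pytest.raises(ConfigurationError):
        gen_decay_curve(y0=10.0, plateau=20.0)


def test_pk_profile_zero_at_time_zero():
    for cv in (0.0, 0.2):
        synth = gen_pk_profile(cv=cv, seed=9)
        assert synth.profile.concentration[0] == 0.0


def test_pk_rejects_equal_rates():
    with pytest.raises(ConfigurationError):
        gen_pk_profile(ka=0.127, kel=0.127)


def test_pk_tmax_on_sampling_grid():
    """Observed Tmax is the design point nearest the analytic tmax."""
    synth = gen_pk_profile(ka=1.0, kel=0.127, cv=0.2, seed=9)
    t = synth.profile.time
    tmax_true = synth.truth["tmax"]
    observed_tmax = t[np.argmax(synth.profile.concentration)]
    grid_neighbors = t[np.argsort(np.abs(t - tmax_true))[:3]]
    assert observed_tmax in grid_neighbors


# ----------------------------------------------------------------- survival


def test_survival_validation():
    with pytest.raises(ConfigurationError):
        gen_survival_cohort(n_per_arm=1)
    with pytest.raises(ConfigurationError):
        gen_survival_cohort(hazard_ratio=0.0)


def test_survival_censoring_at_zero_censors_everything():
    cohort = gen_survival_cohort(5, 24.0, 0.7, censor_at=0.0, seed=1)
    assert all(not r.event and r.time == 0.0 for r in cohort.records)


def test_survival_protective_hazard_lengthens_treated_medians():
    """HR = 0.7 gives a longer treated KM median in nearly all replicates."""
    from crydiscov.pharmacometrics import km_estimate

    wins = 0
    n_rep = 100
    for i in range(n_rep):
        cohort = gen_survival_cohort(200, 24.0, 0.7, 120.0, seed=3000 + i)
        result = km_estimate(cohort.records)
        wins += result.medians["treated"] > result.medians["vehicle"]
    assert wins / n_rep >= 0.95


# --------------------------------------------------------------- dispatcher


def test_generator_config_dispatch():
    cfg = GeneratorConfig(seed=7, stage="decay", params={"k": 0.2, "sigma": 0.0})
    synth = generate(cfg)
    assert synth.truth["k"] == 0.2


def test_generator_config_validation():
    with pytest.raises(ConfigurationError):
        GeneratorConfig(seed=1, stage="nonsense")
    with pytest.raises(ConfigurationError):
        GeneratorConfig(seed=None, stage="decay")
    with pytest.raises(ConfigurationError):
        generate(GeneratorConfig(seed=1, stage="decay", params={"bogus": 1}))
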