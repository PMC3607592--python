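"""Shared fixtures: hand-written structures and session-scoped simulation
datasets reused by unit and acceptance tests."""

import numpy as np
import pytest

from clampmf import rigidpca, structio, toysystems, wham

TINY_PDB = """\
ATOM      1  N   GLY A   1      10.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.000   0.500   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1      12.000   1.000   0.500  1.00  0.00           C
ATOM      4  O   GLY A   1      12.500   2.000   0.500  1.00  0.00           O
ATOM      5  CB  SER A   2      13.000   2.500   1.000  1.00  0.00           C
ATOM      6  CA  SER A   2      14.000   3.000   1.000  1.00  0.00           C
ATOM      7  N   ALA A   3      15.000   3.500   1.500  1.00  0.00           N
ATOM      8  CA  ALA A   3      16.000   4.000   2.000  1.00  0.00           C
END
"""


@pytest.fixture
def tiny_structure() -> structio.Structure:
    return structio.read_pdb(TINY_PDB, label="tiny")


@pytest.fixture
def ladder_structure() -> structio.Structure:
    """10 residues, one CA each, along x at 0.1 nm spacing."""
    atoms = [
        structio.Atom(
            serial=i + 1,
            name="CA",
            residue_number=i + 1,
            residue_name="GLY",
            chain="A",
            position=np.array([0.1 * i, 0.0, 0.0]),
            element="C",
        )
        for i in range(10)
    ]
    return structio.Structure(atoms, label="ladder")


def make_clamshell_fixture(seed=5, n_frames=600, jitter=0.004):
    """Toy clamshell with three planted modes whose Cartesian displacement
    stds are 0.4 / 0.28 / 0.2 nm (variance ratios 4 : 1.96 : 1)."""
    base = toysystems.ClamshellToyParams(seed=seed)
    dirs, gains = toysystems.planted_mode_directions(base)
    target = np.array([0.4, 0.28, 0.2])  # nm, sqrt(2)*std of each sinusoid
    amps = target / gains
    params = toysystems.ClamshellToyParams(
        bend_amplitude=amps[0],
        twist_amplitude=amps[1],
        rock_amplitude=amps[2],
        jitter_sigma=jitter,
        seed=seed,
    )
    ct = toysystems.generate_clamshell_trajectory(params, n_frames)
    return ct, params, dirs, target


@pytest.fixture(scope="session")
def clamshell_dataset():
    """(ClamshellTrajectory, params, planted 3N directions, planted cart amplitudes)."""
    return make_clamshell_fixture()


@pytest.fixture(scope="session")
def clamshell_model(clamshell_dataset):
    ct, _, _, _ = clamshell_dataset
    top = ct.trajectory.topology
    return rigidpca.RigidBodyModel(
        structio.select_residues(top, ct.dom1_ranges, label="dom1"),
        structio.select_residues(top, ct.dom2_ranges, label="dom2"),
        structio.select_residues(top, ct.hinge_ranges, label="hinge"),
    )


@pytest.fixture(scope="session")
def harmonic_umbrella_dataset():
    """Seeded umbrella windows on a harmonic potential (analytic PMF oracle)."""
    pot = toysystems.HarmonicPotential(k=20.0, x0=0.2)
    centers = np.arange(-0.2, 0.61, 0.2)
    params = toysystems.LangevinParams(
        timestep=0.001, n_steps=200000, seed=3, save_stride=2, n_equil=2000
    )
    windows = toysystems.generate_umbrella_dataset(pot, centers, 50.0, params)
    return pot, windows


@pytest.fixture(scope="session")
def double_well_umbrella_dataset():
    """Seeded umbrella windows on the asymmetric double well (delta = 1.19)."""
    pot = toysystems.double_well(x1=0.4, x2=1.0, barrier=4.0, delta=1.19)
    centers = np.arange(0.3, 1.101, 0.05)
    # Euler discretization bias in the steep quartic walls scales with dt;
    # 1e-4 keeps it well below the 0.15 kcal/mol acceptance tolerance
    params = toysystems.LangevinParams(
        timestep=1e-4, n_steps=400000, seed=11, save_stride=4, n_equil=4000
    )
    windows = toysystems.generate_umbrella_dataset(pot, centers, 500.0, params)
    return pot, windows


def run_staged_double_well_metad(seed=2, n_steps=1200000):
    """Staged metadynamics on the asymmetric double well (planted
    minimum-to-minimum difference 1.0 kcal/mol, barrier 7):
    0.5 kcal hills -> 0.2 -> 0.05, mirroring a refine-as-you-go protocol."""
    from clampmf import metad

    pot = toysystems.double_well(x1=0.4, x2=1.0, barrier=7.0, delta=1.0)
    sched = metad.HillSchedule(
        [
            metad.HillPhase(0.5, 0.5, 100.0),
            metad.HillPhase(0.2, 1.0, 300.0),
            metad.HillPhase(0.05, 0.5, None),
        ]
    )
    params = toysystems.LangevinParams(
        timestep=0.001, n_steps=n_steps, seed=seed, save_stride=20
    )
    result = metad.run_metadynamics(pot, sched, widths=0.05, params=params, x0=0.4)
    return pot, sched, params, result


@pytest.fixture(scope="session")
def staged_double_well_run():
    return run_staged_double_well_metad()


@pytest.fixture(scope="session")
def triple_well_umbrella_dataset():
    """Seeded umbrella windows over the clamshell triple well."""
    pot = toysystems.clamshell_triple_well()
    centers = np.arange(0.45, 1.251, 0.05)
    # dt resolves the stiffest well curvature (~1.2e3 kcal/mol/nm^2)
    params = toysystems.LangevinParams(
        timestep=2e-4, n_steps=150000, seed=23, save_stride=3, n_equil=5000
    )
    windows = toysystems.generate_umbrella_dataset(pot, centers, 500.0, params)
    return pot, windows
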