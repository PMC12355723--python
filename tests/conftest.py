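"""Shared geometries, reference values, and session-scoped SCF results.

Reference energies were generated once with an independent established
quantum-chemistry program (SCF converged to 1e-12, reference grids) and
frozen here; the tests never depend on that program being installed.
"""

import numpy as np
import pytest

from huzembed import MoleculeSpec, build_context

# frozen external reference values (hartree; s^2 dimensionless)
ORACLE = {
    "rohf_h_sto3g": -0.46658184955727533,
    "rohf_oh_sto3g": -74.36156195793284,
    "rohf_ch3_sto3g": -39.072133026851645,
    "rohf_ch2_sto3g": -38.42488795500943,
    "rohf_h2o_sto3g": -74.96302313846292,
    "uhf_oh_sto3g": -74.36266919476725,
    "uhf_oh_sto3g_s2": 0.7532619427147171,
    "uhf_ch3_sto3g": -39.07670895882333,
    "uhf_ch3_sto3g_s2": 0.7652231713261854,
    "uhf_ch2_sto3g": -38.42843143706603,
    "uhf_ch2_sto3g_s2": 2.0131847848009063,
    "uhf_h2o_sto3g": -74.96302313846289,
    "uhf_h2o_cation_631g": -75.5805492590738,
    "uhf_h2o_cation_631g_s2": 0.7552804050643971,
    "uks_pbe_h2o_631g": -76.29810567472774,
    "uks_pbe0_h2o_631g": -76.30103238526843,
    "uks_pbe_oh_sto3g": -74.57225017664466,
    "uks_pbe0_oh_sto3g": -74.594632240683,
    "uks_pbe_ch3_sto3g": -39.27462900024946,
    "uks_pbe0_ch3_sto3g": -39.29192357160546,
    "uks_lda_h2o_sto3g": -74.7291168089956,
    "roks_pbe_ch3_sto3g": -39.27337166380496,
    "roks_pbe0_ch3_sto3g": -39.290251413168335,
    "roks_pbe_ch2_sto3g": -38.57531100181624,
    "roks_pbe0_ch2_sto3g": -38.593205473943016,
    "rmp2_h2o_631g_ecorr": -0.1288509171605294,
    "ump2_ch3_sto3g_ecorr": -0.03828715798165652,
    "romp2_oh_sto3g_ecorr": -0.01603441240740248,
    "romp2_ch2_sto3g_ecorr": -0.024785155406658727,
}

# geometries matching the frozen references exactly (angstrom)


def h_atom():
    return MoleculeSpec.from_lists(["H"], [[0.0, 0.0, 0.0]], 0, 2)


def oh_radical():
    return MoleculeSpec.from_lists(
        ["O", "H"], [[0, 0, 0], [0, 0, 0.97]], 0, 2)


def ch3_radical():
    return MoleculeSpec.from_lists(
        ["C", "H", "H", "H"],
        [[0, 0, 0], [1.079, 0, 0], [-0.5395, 0.9344, 0],
         [-0.5395, -0.9344, 0]], 0, 2)


def ch2_triplet():
    return MoleculeSpec.from_lists(
        ["C", "H", "H"],
        [[0, 0, 0], [1.078, 0, 0], [-0.335, 1.025, 0]], 0, 3)


def h2o():
    return MoleculeSpec.from_lists(
        ["O", "H", "H"],
        [[0, 0, 0.1173], [0, 0.7572, -0.4692], [0, -0.7572, -0.4692]], 0, 1)


def heh_radical(distance=2.0):
    return MoleculeSpec.from_lists(
        ["He", "H"], [[0, 0, 0], [0, 0, distance]], 0, 2)


@pytest.fixture(scope="session")
def water_dimer_pbe_embedding():
    """PBE0-in-PBE on the water dimer, donor water active (shared)."""
    from huzembed import XCFunctionalSpec, get_fixture, run_uks_embedding
    mol = get_fixture("water_dimer")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    return run_uks_embedding(mol, ctx, XCFunctionalSpec.resolve("pbe"),
                             XCFunctionalSpec.resolve("pbe0"), [0, 1, 2])


@pytest.fixture(scope="session")
def hydroxyl_roks_embedding():
    """ROKS PBE0-in-PBE on OH-radical/water, OH active (shared)."""
    from huzembed import XCFunctionalSpec, get_fixture, run_roks_embedding
    mol = get_fixture("hydroxyl_water")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    res = run_roks_embedding(mol, ctx, XCFunctionalSpec.resolve("pbe"),
                             XCFunctionalSpec.resolve("pbe0"), [0, 1])
    res.extras["ctx"] = ctx
    return res
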