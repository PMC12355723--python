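"""Orbital localization and subsystem partitioning."""

import numpy as np
import pytest

from huzembed import (XCFunctionalSpec, build_context, get_fixture,
                      solve_uks, spade_partition)
from huzembed.partition import (PartitionError, boys_localize,
                                mulliken_populations, mulliken_select)

HF = XCFunctionalSpec.resolve("hf")


@pytest.fixture(scope="module")
def dimer_scf():
    mol = get_fixture("water_dimer")
    ctx = build_context(mol, "sto-3g")
    return mol, ctx, solve_uks(mol, ctx, HF)


def test_spade_splits_water_dimer(dimer_scf):
    mol, ctx, r = dimer_scf
    C_occ = r.C_alpha[:, :r.n_alpha]
    part = spade_partition(C_occ, ctx, [0, 1, 2], occupation=2.0)
    assert part.n_active == 5                 # one water = 5 doubly occupied
    assert part.L_env.shape[1] == 5


def test_spade_orbitals_span_occupied_space(dimer_scf):
    _, ctx, r = dimer_scf
    C_occ = r.C_alpha[:, :r.n_alpha]
    part = spade_partition(C_occ, ctx, [0, 1, 2], occupation=2.0)
    L = np.hstack([part.L_active, part.L_env])
    # rotated orbitals stay orthonormal and reproduce the total density
    assert np.allclose(L.T @ ctx.S @ L, np.eye(10), atol=1e-10)
    assert np.allclose(L @ L.T, C_occ @ C_occ.T, atol=1e-10)


def test_spade_density_partition_additive(dimer_scf):
    _, ctx, r = dimer_scf
    C_occ = r.C_alpha[:, :r.n_alpha]
    part = spade_partition(C_occ, ctx, [0, 1, 2], occupation=2.0)
    D_tot = 2.0 * C_occ @ C_occ.T
    assert np.allclose(part.D_active + part.D_env, D_tot, atol=1e-10)
    tr = np.einsum("mn,mn", part.D_active, ctx.S)
    assert tr == pytest.approx(10.0, abs=1e-8)


def test_spade_trivial_selections(dimer_scf):
    mol, ctx, r = dimer_scf
    C_occ = r.C_alpha[:, :r.n_alpha]
    full = spade_partition(C_occ, ctx, list(range(mol.n_atoms)),
                           occupation=2.0)
    assert full.n_active == C_occ.shape[1]
    empty = spade_partition(C_occ, ctx, [], occupation=2.0)
    assert empty.n_active == 0


def test_spade_localizes_symmetric_dimer():
    mol = get_fixture("he_dimer", separation=3.0)
    ctx = build_context(mol, "sto-3g")
    r = solve_uks(mol, ctx, HF)
    # canonical orbitals are delocalized g/u combinations; SPADE still
    # finds exactly one orbital on the active atom
    part = spade_partition(r.C_alpha[:, :2], ctx, [0], occupation=2.0)
    assert part.n_active == 1


def test_spade_indistinguishable_orbitals_raise():
    from scipy.linalg import fractional_matrix_power
    mol = get_fixture("he_dimer", separation=3.0)
    ctx = build_context(mol, "6-31g")
    # two orthonormal vectors living entirely on the active atom: the
    # SPADE singular values are all 1 and no gap exists
    X = fractional_matrix_power(ctx.S, -0.5)
    with pytest.raises(PartitionError):
        spade_partition(np.real(X[:, :2]), ctx, [0], occupation=2.0)


def test_mulliken_populations_complementary(dimer_scf):
    mol, ctx, r = dimer_scf
    C_occ = r.C_alpha[:, :r.n_alpha]
    p_act = mulliken_populations(C_occ, ctx, [0, 1, 2])
    p_env = mulliken_populations(C_occ, ctx, [3, 4, 5])
    # active + environment populations account for each full orbital
    assert np.allclose(p_act + p_env, 1.0, atol=1e-10)


def test_mulliken_select_threshold(dimer_scf):
    mol, ctx, r = dimer_scf
    C_occ = r.C_alpha[:, :r.n_alpha]
    L, _ = boys_localize(C_occ, ctx)
    part = mulliken_select(L, ctx, [0, 1, 2], threshold=0.3)
    assert part.n_active == 5                 # localized: one water's orbitals


def test_boys_localization_invariants(dimer_scf):
    _, ctx, r = dimer_scf
    C_occ = r.C_alpha[:, :r.n_alpha]
    L, W = boys_localize(C_occ, ctx)
    assert np.allclose(W.T @ W, np.eye(10), atol=1e-10)
    assert np.allclose(L.T @ ctx.S @ L, np.eye(10), atol=1e-10)
    assert np.allclose(L @ L.T, C_occ @ C_occ.T, atol=1e-10)
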