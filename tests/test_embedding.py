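"""Huzinaga embedding machinery: operator structure, exactness, potentials."""

import numpy as np
import pytest

from huzembed import (XCFunctionalSpec, build_context, get_fixture,
                      huzinaga_operator, run_roks_embedding,
                      run_uks_embedding, solve_ro, solve_uks)

HF = XCFunctionalSpec.resolve("hf")
PBE = XCFunctionalSpec.resolve("pbe")


def test_huzinaga_operator_symmetric():
    rng = np.random.default_rng(3)
    n = 6
    F = rng.standard_normal((n, n))
    F = F + F.T
    S = np.eye(n) + 0.1 * np.ones((n, n))
    L = rng.standard_normal((n, 2))
    R = L @ L.T
    H = huzinaga_operator(F, R, S)
    assert np.allclose(H, H.T, atol=1e-12)


def test_huzinaga_shifts_environment_orbitals():
    # for an S-orthonormal environment orbital v: H v = F v - S R F v - ...
    # the expectation <v|H|v> = -<v|F|v>, flipping occupied env levels up
    mol = get_fixture("he_dimer")
    ctx = build_context(mol, "sto-3g")
    r = solve_uks(mol, ctx, HF)
    from huzembed.uks import build_uks_fock
    Fa, _ = build_uks_fock(r.densities, ctx, HF)
    v = r.C_alpha[:, [1]]
    R = v @ v.T
    H = huzinaga_operator(Fa, R, ctx.S)
    e_f = float((v.T @ Fa @ v).item())
    e_h = float((v.T @ H @ v).item())
    assert e_h == pytest.approx(-e_f, abs=1e-10)


def test_same_level_exactness_uks(water_dimer_pbe_embedding):
    from huzembed import run_uks_embedding
    mol = get_fixture("water_dimer")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    sup = solve_uks(mol, ctx, PBE)
    res = run_uks_embedding(mol, ctx, PBE, PBE, [0, 1, 2], supersystem=sup)
    assert abs(res.E_pbe - sup.energy) < 1e-9


def test_first_order_correction_small(water_dimer_pbe_embedding):
    res = water_dimer_pbe_embedding
    # the correction is a genuine first-order term: much smaller than the
    # high-minus-low subsystem relaxation it accompanies
    assert abs(res.correction) < abs(res.E_high_A - res.E_low_A)
    assert abs(res.correction) < 0.05


def test_embedded_orbitals_orthogonal_to_environment(
        water_dimer_pbe_embedding, hydroxyl_roks_embedding):
    assert water_dimer_pbe_embedding.orthogonality_residual < 1e-7
    assert hydroxyl_roks_embedding.orthogonality_residual < 1e-7


def test_roks_embedding_spin_expectation(hydroxyl_roks_embedding):
    # restricted open-shell ansatz is spin-pure by construction
    assert hydroxyl_roks_embedding.s_squared == pytest.approx(0.75, abs=1e-12)


def test_uks_vs_roks_agree_closed_shell():
    mol = get_fixture("water_dimer")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    r_u = run_uks_embedding(mol, ctx, PBE, XCFunctionalSpec.resolve("pbe0"),
                            [0, 1, 2])
    r_r = run_roks_embedding(mol, ctx, PBE, XCFunctionalSpec.resolve("pbe0"),
                             [0, 1, 2])
    # with no open shells both formulations solve the same problem
    assert r_u.E_pbe == pytest.approx(r_r.E_pbe, abs=1e-9)


def test_deterministic_rerun(water_dimer_pbe_embedding):
    mol = get_fixture("water_dimer")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    res = run_uks_embedding(mol, ctx, PBE, XCFunctionalSpec.resolve("pbe0"),
                            [0, 1, 2])
    assert res.E_pbe == water_dimer_pbe_embedding.E_pbe   # byte-identical
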