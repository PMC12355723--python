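"""Mixed ansatz combinations and quasi-restricted orbitals."""

import numpy as np
import pytest

from huzembed import (XCFunctionalSpec, build_context, get_fixture,
                      natural_orbitals, quasi_restricted_orbitals,
                      roks_in_uks, run_roks_embedding, run_uks_embedding,
                      solve_uks, uks_in_roks)

from conftest import ch3_radical

PBE = XCFunctionalSpec.resolve("pbe")
PBE0 = XCFunctionalSpec.resolve("pbe0")


def test_qro_occupations_methyl():
    mol = ch3_radical()
    ctx = build_context(mol, "sto-3g", grid_level=1)
    r = solve_uks(mol, ctx, PBE)
    nos = quasi_restricted_orbitals(r, ctx.S)
    assert nos.n_doubly == 4 and nos.n_singly == 1
    assert nos.occupations.sum() == pytest.approx(9.0, abs=1e-8)
    # doubly occupied natural occupations near 2, singly near 1
    assert nos.occupations[:4].min() > 1.9
    assert 0.9 < nos.occupations[4] < 1.1
    # orthonormal in the overlap metric
    C = nos.coefficients
    assert np.allclose(C.T @ ctx.S @ C, np.eye(C.shape[1]), atol=1e-8)


def test_natural_orbitals_idempotent_input():
    mol = get_fixture("water")
    ctx = build_context(mol, "sto-3g")
    r = solve_uks(mol, ctx, XCFunctionalSpec.resolve("hf"))
    nos = natural_orbitals(r.densities.total, ctx.S, 5, 0)
    assert np.allclose(nos.occupations[:5], 2.0, atol=1e-10)
    assert np.allclose(nos.occupations[5:], 0.0, atol=1e-10)


def test_all_combinations_agree_closed_shell():
    """With no open shells all four ansatz pairings coincide."""
    mol = get_fixture("water_dimer")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    active = [0, 1, 2]
    energies = [
        run_uks_embedding(mol, ctx, PBE, PBE0, active).E_pbe,
        run_roks_embedding(mol, ctx, PBE, PBE0, active).E_pbe,
        uks_in_roks(mol, ctx, PBE, PBE0, active).E_pbe,
        roks_in_uks(mol, ctx, PBE, PBE0, active).E_pbe,
    ]
    assert np.ptp(energies) < 1e-9


def test_open_shell_combinations_consistent():
    """On a radical the four pairings stay within chemical tightness."""
    mol = get_fixture("hydroxyl_water")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    active = [0, 1]
    energies = {
        "uks-in-uks": run_uks_embedding(mol, ctx, PBE, PBE0, active).E_pbe,
        "roks-in-roks": run_roks_embedding(mol, ctx, PBE, PBE0,
                                           active).E_pbe,
        "uks-in-roks": uks_in_roks(mol, ctx, PBE, PBE0, active).E_pbe,
        "roks-in-uks": roks_in_uks(mol, ctx, PBE, PBE0, active).E_pbe,
    }
    vals = np.array(list(energies.values()))
    assert np.ptp(vals) < 2e-3          # ~1 kcal/mol ansatz spread


def test_mixed_ansatz_carry_spin_metadata():
    mol = get_fixture("hydroxyl_water")
    ctx = build_context(mol, "sto-3g", grid_level=1)
    r = roks_in_uks(mol, ctx, PBE, PBE0, [0, 1])
    assert r.s_squared == pytest.approx(0.75, abs=1e-12)
    r2 = uks_in_roks(mol, ctx, PBE, PBE0, [0, 1])
    assert 0.75 <= r2.s_squared < 0.80  # unrestricted relaxation
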