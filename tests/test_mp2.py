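"""Second-order correlation against frozen external references.

The restricted open-shell values use the semicanonical convention
(occupied and virtual blocks of the per-spin Fock matrices diagonalized
separately); the references were generated with the same convention.
"""

import pytest

from huzembed import (XCFunctionalSpec, build_context, mp2_rhf, mp2_ro,
                      solve_ro, solve_uks, ump2_energy)
from huzembed.uks import SpinDensities, build_uks_fock

from conftest import ORACLE, ch2_triplet, ch3_radical, h2o, oh_radical

HF = XCFunctionalSpec.resolve("hf")


def test_rmp2_water():
    mol = h2o()
    ctx = build_context(mol, "6-31g")
    r = solve_uks(mol, ctx, HF)
    Fa, _ = build_uks_fock(r.densities, ctx, HF)
    e = mp2_rhf(ctx, r.C_alpha, r.n_alpha, Fa)
    assert e == pytest.approx(ORACLE["rmp2_h2o_631g_ecorr"], abs=1e-8)


def test_ump2_methyl():
    mol = ch3_radical()
    ctx = build_context(mol, "sto-3g")
    r = solve_uks(mol, ctx, HF)
    Fa, Fb = build_uks_fock(r.densities, ctx, HF)
    e = ump2_energy(ctx,
                    (r.C_alpha[:, :r.n_alpha], r.C_beta[:, :r.n_beta]),
                    (r.C_alpha[:, r.n_alpha:], r.C_beta[:, r.n_beta:]),
                    (Fa, Fb))
    assert e == pytest.approx(ORACLE["ump2_ch3_sto3g_ecorr"], abs=1e-8)


@pytest.mark.parametrize("mol,key", [
    (oh_radical(), "romp2_oh_sto3g_ecorr"),
    (ch2_triplet(), "romp2_ch2_sto3g_ecorr"),
])
def test_romp2_semicanonical(mol, key):
    ctx = build_context(mol, "sto-3g")
    r = solve_ro(mol, ctx, HF)
    d = r.densities
    Fa, Fb = build_uks_fock(SpinDensities(d.D_alpha, d.D_beta), ctx, HF)
    e = mp2_ro(ctx, r.C, r.n_closed, r.n_open, Fa, Fb)
    assert e == pytest.approx(ORACLE[key], abs=1e-8)


def test_rmp2_equals_ump2_closed_shell():
    mol = h2o()
    ctx = build_context(mol, "sto-3g")
    r = solve_uks(mol, ctx, HF)
    Fa, Fb = build_uks_fock(r.densities, ctx, HF)
    e_u = ump2_energy(ctx,
                      (r.C_alpha[:, :5], r.C_beta[:, :5]),
                      (r.C_alpha[:, 5:], r.C_beta[:, 5:]), (Fa, Fb))
    e_r = mp2_rhf(ctx, r.C_alpha, 5, Fa)
    assert e_u == pytest.approx(e_r, abs=1e-12)
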