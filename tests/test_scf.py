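"""SCF equivalence against frozen external references.

Hartree-Fock energies must match to 1e-8 (grid-free).  Density
functional energies are compared at grid level 2 with a 2e-5 hartree
tolerance, the resolution limit of the numerical quadrature difference
between this engine and the reference program's finer grid.
"""

import numpy as np
import pytest

from huzembed import (XCFunctionalSpec, build_context, build_ensemble,
                      solve_ro, solve_uks)
from huzembed.molecule import ConfigurationError

from conftest import ORACLE, ch2_triplet, ch3_radical, h2o, h_atom, oh_radical

HF = XCFunctionalSpec.resolve("hf")
DFT_TOL = 2e-5


def _uks(mol, bas, fn, gl=2):
    ctx = build_context(mol, bas, grid_level=gl)
    return solve_uks(mol, ctx, XCFunctionalSpec.resolve(fn))


def _ro(mol, bas, fn, gl=2):
    ctx = build_context(mol, bas, grid_level=gl)
    return solve_ro(mol, ctx, XCFunctionalSpec.resolve(fn))


@pytest.mark.parametrize("mol,key", [
    (oh_radical(), "uhf_oh_sto3g"),
    (ch3_radical(), "uhf_ch3_sto3g"),
    (ch2_triplet(), "uhf_ch2_sto3g"),
    (h2o(), "uhf_h2o_sto3g"),
])
def test_uhf_oracle(mol, key):
    r = _uks(mol, "sto-3g", "hf")
    assert r.energy == pytest.approx(ORACLE[key], abs=1e-8)
    if key + "_s2" in ORACLE:
        assert r.s_squared == pytest.approx(ORACLE[key + "_s2"], abs=1e-7)


def test_uhf_cation_split_valence():
    mol = h2o()
    cation = type(mol).from_lists(list(mol.symbols),
                                  mol.coords_angstrom.tolist(), 1, 2)
    r = _uks(cation, "6-31g", "hf")
    assert r.energy == pytest.approx(ORACLE["uhf_h2o_cation_631g"], abs=1e-8)
    assert r.s_squared == pytest.approx(
        ORACLE["uhf_h2o_cation_631g_s2"], abs=1e-7)


@pytest.mark.parametrize("mol,key", [
    (oh_radical(), "uks_pbe_oh_sto3g"),
    (ch3_radical(), "uks_pbe0_ch3_sto3g"),
    (h2o(), "uks_lda_h2o_sto3g"),
])
def test_uks_oracle_sto3g(mol, key):
    fn = key.split("_")[1]
    r = _uks(mol, "sto-3g", fn)
    assert r.energy == pytest.approx(ORACLE[key], abs=DFT_TOL)


@pytest.mark.parametrize("fn,key", [
    ("pbe", "uks_pbe_h2o_631g"), ("pbe0", "uks_pbe0_h2o_631g")])
def test_uks_oracle_631g(fn, key):
    r = _uks(h2o(), "6-31g", fn)
    assert r.energy == pytest.approx(ORACLE[key], abs=DFT_TOL)


@pytest.mark.parametrize("mol,key", [
    (ch3_radical(), "roks_pbe_ch3_sto3g"),
    (ch3_radical(), "roks_pbe0_ch3_sto3g"),
    (ch2_triplet(), "roks_pbe_ch2_sto3g"),
    (ch2_triplet(), "roks_pbe0_ch2_sto3g"),
])
def test_roks_oracle(mol, key):
    fn = key.split("_")[1]
    r = _ro(mol, "sto-3g", fn)
    assert r.energy == pytest.approx(ORACLE[key], abs=DFT_TOL)
    s = (mol.multiplicity - 1) / 2
    assert r.s_squared == pytest.approx(s * (s + 1), abs=1e-12)


def test_rohf_closed_shell_equals_rhf_limit():
    # with no open shells the restricted open-shell solver is plain RKS/RHF
    r = _ro(h2o(), "sto-3g", "hf")
    assert r.energy == pytest.approx(ORACLE["rohf_h2o_sto3g"], abs=1e-8)


def test_ensemble_parameters():
    ens = build_ensemble(3, 2)
    assert ens.f == 0.5 and ens.a == 1.0 and ens.b == 2.0
    assert (ens.a_bar, ens.b_bar, ens.c_bar) == (0.0, -2.0, 2.0)
    with pytest.raises(ConfigurationError):
        build_ensemble(3, 1)            # open-shell count inconsistent


def test_density_traces_after_scf():
    r = _uks(oh_radical(), "sto-3g", "hf")
    ctx = build_context(oh_radical(), "sto-3g")
    na, nb = r.densities.electron_counts(ctx.S)
    assert na == pytest.approx(5.0, abs=1e-10)
    assert nb == pytest.approx(4.0, abs=1e-10)


def test_h_atom_trivial():
    r = _uks(h_atom(), "sto-3g", "hf")
    assert r.energy == pytest.approx(ORACLE["rohf_h_sto3g"], abs=1e-10)
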