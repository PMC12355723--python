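"""Structural properties of the self-contained integral engine."""

import numpy as np
import pytest

from huzembed import build_context
from huzembed import integrals as ig
from huzembed.basis import build_shells

from conftest import h2o, oh_radical


@pytest.fixture(scope="module")
def ctx():
    return build_context(h2o(), "6-31g")


def test_overlap_properties(ctx):
    S = ctx.S
    assert np.allclose(S, S.T, atol=1e-14)
    assert np.allclose(np.diag(S), 1.0, atol=1e-12)        # normalized AOs
    assert np.linalg.eigvalsh(S).min() > 0                 # positive definite


def test_kinetic_positive_definite(ctx):
    T = ig.kinetic(ctx.shells)
    assert np.allclose(T, T.T, atol=1e-14)
    assert np.linalg.eigvalsh(T).min() > 0


def test_eri_eightfold_symmetry(ctx):
    eri = ctx.eri
    rng = np.random.default_rng(7)
    n = eri.shape[0]
    for _ in range(40):
        m, nn, t, s = rng.integers(0, n, 4)
        v = eri[m, nn, t, s]
        for perm in ((nn, m, t, s), (m, nn, s, t), (t, s, m, nn),
                     (s, t, nn, m)):
            assert eri[perm] == pytest.approx(v, abs=1e-12)


def test_coulomb_exchange_traces(ctx):
    # Tr[D J(D)] and Tr[D K(D)] positive for a positive semidefinite D
    rng = np.random.default_rng(0)
    A = rng.standard_normal((ctx.n_ao, 3))
    D = A @ A.T
    assert np.einsum("mn,mn", D, ctx.coulomb(D)) > 0
    assert np.einsum("mn,mn", D, ctx.exchange(D)) > 0


def test_dipole_translation_rule():
    sh = build_shells(oh_radical(), "sto-3g")
    S = ig.overlap(sh)
    d0 = ig.dipole(sh, (0.0, 0.0, 0.0))
    d1 = ig.dipole(sh, (0.0, 0.0, 0.5))
    # shifting the origin by t subtracts t * S componentwise
    assert np.allclose(d1[2], d0[2] - 0.5 * S, atol=1e-12)
    assert np.allclose(d1[0], d0[0], atol=1e-12)


def test_nuclear_attraction_sign(ctx):
    V = ig.charge_attraction(ctx.shells, ctx.molecule.coords_bohr,
                             ctx.molecule.charges)
    assert np.linalg.eigvalsh(0.5 * (V + V.T)).max() < 0   # attractive
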