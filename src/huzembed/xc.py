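"""Spin-polarized exchange-correlation functionals on a numerical grid.

Implemented functionals: Slater (LDA) exchange, PW92 local correlation,
PBE exchange and PBE correlation.  Energy densities are coded once as
analytic expressions; derivative factors for the potential matrices are
obtained by complex-step differentiation, which is exact to machine
precision for these analytic forms and keeps the energy and potential
strictly consistent (a requirement for variational SCF and for the
first-order embedding correction).

The GGA potential matrix uses the standard weak form
V_munu = int [ (de/drho_s) X_mu X_nu + 2 (de/dgamma_ss) grad rho_s . grad(X_mu X_nu) + ... ]
with gamma_st = grad rho_s . grad rho_t.
"""

from __future__ import annotations

import numpy as np

_CS_H = 1e-30          # complex-step size
_RHO_FLOOR = 1e-12


def _cstep(f, args, idx):
    """d f / d args[idx] by complex step; f must be analytic elementwise."""
    cargs = [np.asarray(a, dtype=complex) for a in args]
    cargs[idx] = cargs[idx] + 1j * _CS_H
    return np.imag(f(*cargs)) / _CS_H


# ----------------------------------------------------------------- LDA / PW92

_CX = -(3.0 / 4.0) * (3.0 / np.pi) ** (1.0 / 3.0)


def _e_slater(ra, rb):
    """Slater exchange energy density per volume (spin scaled)."""
    return 0.5 * _CX * ((2.0 * ra) ** (4.0 / 3.0) + (2.0 * rb) ** (4.0 / 3.0))


_PW92 = {
    # A, alpha1, beta1..4
    "e0": (0.031091, 0.21370, 7.5957, 3.5876, 1.6382, 0.49294),
    "e1": (0.015545, 0.20548, 14.1189, 6.1977, 3.3662, 0.62517),
    "ac": (0.016887, 0.11125, 10.357, 3.6231, 0.88026, 0.49671),
}
_FZ_DD0 = 1.709920934161365          # f''(0)


def _pw92_G(rs, p):
    A, a1, b1, b2, b3, b4 = p
    srs = np.sqrt(rs)
    Q = A * 2.0 * (b1 * srs + b2 * rs + b3 * rs * srs + b4 * rs * rs)
    return -2.0 * A * (1.0 + a1 * rs) * np.log(1.0 + 1.0 / Q)


def _pw92_eps(rs, zeta):
    e0 = _pw92_G(rs, _PW92["e0"])
    e1 = _pw92_G(rs, _PW92["e1"])
    ac = -_pw92_G(rs, _PW92["ac"])
    fz = ((1.0 + zeta) ** (4.0 / 3.0) + (1.0 - zeta) ** (4.0 / 3.0) - 2.0) \
        / (2.0 ** (4.0 / 3.0) - 2.0)
    z4 = zeta ** 4
    return e0 + ac * fz / _FZ_DD0 * (1.0 - z4) + (e1 - e0) * fz * z4


def _e_pw92(ra, rb):
    """PW92 correlation energy per volume."""
    rho = ra + rb
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    zeta = (ra - rb) / rho
    return rho * _pw92_eps(rs, zeta)


# ------------------------------------------------------------------------ PBE

_PBE_KAPPA = 0.804
_PBE_MU = 0.2195149727645171
_PBE_BETA = 0.06672455060314922
_PBE_GAMMA = (1.0 - np.log(2.0)) / np.pi ** 2


def _e_pbe_x(rho, gamma):
    """PBE exchange per volume for one spin channel, closed-shell variables.

    Called with (2 rho_s, 4 gamma_ss) and weighted by 1/2 (spin scaling).
    """
    kf = (3.0 * np.pi ** 2 * rho) ** (1.0 / 3.0)
    ex_unif = _CX * rho ** (4.0 / 3.0)
    s2 = gamma / (4.0 * kf ** 2 * rho ** 2)
    F = 1.0 + _PBE_KAPPA - _PBE_KAPPA / (1.0 + _PBE_MU * s2 / _PBE_KAPPA)
    return ex_unif * F


def _e_pbe_c(ra, rb, gamma_tot):
    """PBE correlation per volume; gamma_tot = |grad rho|^2."""
    rho = ra + rb
    rs = (3.0 / (4.0 * np.pi * rho)) ** (1.0 / 3.0)
    zeta = (ra - rb) / rho
    eps = _pw92_eps(rs, zeta)
    phi = 0.5 * ((1.0 + zeta) ** (2.0 / 3.0) + (1.0 - zeta) ** (2.0 / 3.0))
    kf = (3.0 * np.pi ** 2 * rho) ** (1.0 / 3.0)
    ks = np.sqrt(4.0 * kf / np.pi)
    t2 = gamma_tot / (2.0 * phi * ks * rho) ** 2
    expo = np.exp(-eps / (_PBE_GAMMA * phi ** 3))
    A = _PBE_BETA / _PBE_GAMMA / (expo - 1.0)
    num = 1.0 + A * t2
    den = 1.0 + A * t2 + (A * t2) ** 2
    H = _PBE_GAMMA * phi ** 3 * np.log(
        1.0 + _PBE_BETA / _PBE_GAMMA * t2 * num / den)
    return rho * (eps + H)


_COMPONENTS = {}


def _register(name, needs_gamma, fn):
    _COMPONENTS[name] = (needs_gamma, fn)


def _comp_slater(ra, rb, gaa, gab, gbb):
    return _e_slater(ra, rb)


def _comp_pw92(ra, rb, gaa, gab, gbb):
    return _e_pw92(ra, rb)


def _comp_pbe_x(ra, rb, gaa, gab, gbb):
    return 0.5 * (_e_pbe_x(2.0 * ra, 4.0 * gaa) + _e_pbe_x(2.0 * rb, 4.0 * gbb))


def _comp_pbe_c(ra, rb, gaa, gab, gbb):
    return _e_pbe_c(ra, rb, gaa + 2.0 * gab + gbb)


_register("slater_x", False, _comp_slater)
_register("pw92_c", False, _comp_pw92)
_register("pbe_x", True, _comp_pbe_x)
_register("pbe_c", True, _comp_pbe_c)


def eval_xc(components, rho_a, rho_b, grad_a=None, grad_b=None):
    """Energy density and derivative factors for a weighted component sum.

    ``components`` is a list of (weight, name).  Returns dict with keys
    ``e`` (energy per volume), ``vra``, ``vrb`` and, when gradients are
    supplied, ``vgaa``, ``vgab``, ``vgbb`` (derivatives w.r.t. the
    gamma invariants).
    """
    ra = np.maximum(rho_a, _RHO_FLOOR)
    rb = np.maximum(rho_b, _RHO_FLOOR)
    if grad_a is not None:
        gaa = np.einsum("pd,pd->p", grad_a, grad_a)
        gab = np.einsum("pd,pd->p", grad_a, grad_b)
        gbb = np.einsum("pd,pd->p", grad_b, grad_b)
        gaa = np.maximum(gaa, _RHO_FLOOR ** 2)
        gbb = np.maximum(gbb, _RHO_FLOOR ** 2)
    else:
        gaa = gab = gbb = np.zeros_like(ra)
    out = {k: np.zeros_like(ra) for k in
           ("e", "vra", "vrb", "vgaa", "vgab", "vgbb")}
    for weight, name in components:
        needs_gamma, fn = _COMPONENTS[name]
        args = (ra, rb, gaa, gab, gbb)
        out["e"] += weight * fn(*args)
        out["vra"] += weight * _cstep(fn, args, 0)
        out["vrb"] += weight * _cstep(fn, args, 1)
        if needs_gamma and grad_a is not None:
            out["vgaa"] += weight * _cstep(fn, args, 2)
            out["vgab"] += weight * _cstep(fn, args, 3)
            out["vgbb"] += weight * _cstep(fn, args, 4)
    return out
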