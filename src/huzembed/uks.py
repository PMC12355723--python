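"""Spin-unrestricted HF/KS self-consistent field.

Separate alpha and beta spatial orbitals; the usual price is spin
contamination, which the <S^2> diagnostic quantifies.  This solver serves
the low-level supersystem and subsystem calculations and is the base of
the unrestricted embedded solver.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh

from .adapter import AOBasisContext, XCFunctionalSpec
from .molecule import MoleculeSpec
from .scf_common import DIIS, commutator_residual, lowdin_x, sad_guess


class SCFConvergenceError(RuntimeError):
    """SCF failed to converge within the iteration budget."""


@dataclasses.dataclass
class SpinDensities:
    """Per-spin density matrices of a (sub)system."""

    D_alpha: np.ndarray
    D_beta: np.ndarray
    label: str = "AB"

    @property
    def total(self) -> np.ndarray:
        return self.D_alpha + self.D_beta

    def electron_counts(self, S: np.ndarray) -> tuple[float, float]:
        return (float(np.einsum("mn,mn", self.D_alpha, S)),
                float(np.einsum("mn,mn", self.D_beta, S)))


@dataclasses.dataclass
class UKSResult:
    energy: float                     # total, including V_nn
    C_alpha: np.ndarray
    C_beta: np.ndarray
    eps_alpha: np.ndarray
    eps_beta: np.ndarray
    n_alpha: int
    n_beta: int
    converged: bool
    n_iter: int
    s_squared: float
    densities: SpinDensities = None

    @property
    def D_alpha(self):
        return self.densities.D_alpha

    @property
    def D_beta(self):
        return self.densities.D_beta


def build_uks_fock(dens: SpinDensities, ctx: AOBasisContext,
                   xc: XCFunctionalSpec):
    """F_sigma = h + J[D] - a_HF K[D_sigma] + V_xc^sigma."""
    J = ctx.coulomb(dens.total)
    E_xc, Va, Vb = ctx.xc_eval(dens.D_alpha, dens.D_beta, xc)
    Fa = ctx.h_core + J + Va
    Fb = ctx.h_core + J + Vb
    if xc.a_hf:
        Fa = Fa - xc.a_hf * ctx.exchange(dens.D_alpha)
        Fb = Fb - xc.a_hf * ctx.exchange(dens.D_beta)
    return Fa, Fb


def uks_energy(dens: SpinDensities, ctx: AOBasisContext,
               xc: XCFunctionalSpec) -> float:
    """Electronic energy (V_nn not included)."""
    Dt = dens.total
    e = float(np.einsum("mn,mn", ctx.h_core, Dt))
    e += 0.5 * float(np.einsum("mn,mn", Dt, ctx.coulomb(Dt)))
    if xc.a_hf:
        e -= 0.5 * xc.a_hf * float(
            np.einsum("mn,mn", dens.D_alpha, ctx.exchange(dens.D_alpha))
            + np.einsum("mn,mn", dens.D_beta, ctx.exchange(dens.D_beta)))
    if not xc.is_pure_hf:
        E_xc, _, _ = ctx.xc_eval(dens.D_alpha, dens.D_beta, xc)
        e += E_xc
    return e


def s_squared_uhf(C_alpha, C_beta, n_alpha, n_beta, S) -> float:
    """<S^2> = Sz(Sz+1) + n_beta - sum_ij |<phi_i^a|phi_j^b>|^2."""
    sz = 0.5 * (n_alpha - n_beta)
    if n_alpha == 0 or n_beta == 0:
        return sz * (sz + 1.0)
    Sab = C_alpha[:, :n_alpha].T @ S @ C_beta[:, :n_beta]
    return sz * (sz + 1.0) + n_beta - float(np.sum(Sab ** 2))


def solve_uks(molecule: MoleculeSpec, ctx: AOBasisContext,
              xc: XCFunctionalSpec, initial_guess=None,
              e_tol: float = 1e-9, res_tol: float = 1e-7,
              max_iter: int = 150, diis_size: int = 8,
              raise_on_failure: bool = True, log=None) -> UKSResult:
    """Self-consistent solution of the spin-unrestricted KS equations."""
    na, nb = molecule.n_alpha, molecule.n_beta
    S = ctx.S
    X = lowdin_x(S)
    if initial_guess is None:
        Dt = sad_guess(ctx)
        scale = molecule.n_electrons / max(np.einsum("mn,mn", Dt, S), 1e-8)
        Dt = Dt * scale
        frac = na / max(na + nb, 1)
        dens = SpinDensities(frac * Dt, (1.0 - frac) * Dt)
    else:
        dens = initial_guess
    diis = DIIS(diis_size)
    e_old = 0.0
    Ca = Cb = None
    ea = eb = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Fa, Fb = build_uks_fock(dens, ctx, xc)
        ra = commutator_residual(Fa, dens.D_alpha, S, X)
        rb = commutator_residual(Fb, dens.D_beta, S, X)
        res = max(np.abs(ra).max(), np.abs(rb).max() if nb else 0.0)
        fvec = diis.update(np.concatenate([Fa.ravel(), Fb.ravel()]),
                           np.concatenate([ra.ravel(), rb.ravel()]))
        n2 = ctx.n_ao ** 2
        Fa_d = fvec[:n2].reshape(ctx.n_ao, ctx.n_ao)
        Fb_d = fvec[n2:].reshape(ctx.n_ao, ctx.n_ao)
        ea, Ca = eigh(Fa_d, S)
        eb, Cb = eigh(Fb_d, S)
        dens = SpinDensities(Ca[:, :na] @ Ca[:, :na].T,
                             Cb[:, :nb] @ Cb[:, :nb].T, dens.label)
        e_new = uks_energy(dens, ctx, xc) + ctx.V_nn
        de = e_new - e_old
        if log is not None:
            log(f"iter {it:3d}  E={e_new:.10f}  |[F,D]|={res:.3e}  dE={de:.3e}")
        if abs(de) < e_tol and res < res_tol:
            converged = True
            e_old = e_new
            break
        e_old = e_new
    if not converged and raise_on_failure:
        raise SCFConvergenceError(
            f"UKS did not converge in {max_iter} iterations "
            f"(did not yield an SCF solution)")
    s2 = s_squared_uhf(Ca, Cb, na, nb, S)
    return UKSResult(e_old, Ca, Cb, ea, eb, na, nb, converged, it, s2, dens)
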