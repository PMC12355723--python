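"""Spin-unrestricted Huzinaga projection-based embedding.

The active subsystem A is reoptimized at the high level inside the
frozen potential of the environment B.  The embedding potential is the
low-level potential difference between supersystem and subsystem, the
orthogonality of A against B's orbitals is enforced by the Huzinaga
operator, and the multilevel energy carries a first-order correction for
the density relaxation of A.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh

from .adapter import AOBasisContext, XCFunctionalSpec
from .scf_common import DIIS, lowdin_x
from .uks import (SCFConvergenceError, SpinDensities, build_uks_fock,
                  s_squared_uhf, uks_energy)


@dataclasses.dataclass
class UKSEmbeddingPotential:
    """Frozen per-spin matrices representing dE_12/dD^{sigma,A}."""

    V_alpha: np.ndarray
    V_beta: np.ndarray
    dJ: np.ndarray
    dK_alpha: np.ndarray
    dK_beta: np.ndarray
    dVxc_alpha: np.ndarray
    dVxc_beta: np.ndarray


@dataclasses.dataclass
class EmbeddingResult:
    """Decomposed multilevel energy (all terms in hartree)."""

    E_low_AB: float              # electronic, supersystem, low level
    E_low_A: float               # electronic, subsystem A, low level
    E_high_A: float              # electronic, reoptimized A, high level
    correction: float            # first-order density-relaxation trace
    V_nn: float
    E_pbe: float                 # multilevel total energy
    orthogonality_residual: float
    E_cor: float = 0.0           # correlation energy of the embedded system
    E_disp: float = 0.0          # dispersion correction (if enabled)
    n_iter: int = 0
    s_squared: float = 0.0
    densities: object = None     # relaxed subsystem densities
    C: object = None             # embedded orbitals (per spin or shared)
    orbital_energies: object = None
    extras: dict = dataclasses.field(default_factory=dict)

    @property
    def E_total(self) -> float:
        return self.E_pbe + self.E_cor + self.E_disp


def build_embedding_potential_uks(D_AB: SpinDensities, D_A: SpinDensities,
                                  ctx: AOBasisContext,
                                  xc_low: XCFunctionalSpec) -> UKSEmbeddingPotential:
    """V_emb_sigma = dJ - a_HF,2 dK_sigma + dV_xc,sigma (frozen)."""
    if D_AB.D_alpha.shape != D_A.D_alpha.shape:
        raise ValueError("supersystem/subsystem dimension mismatch")
    dJ = ctx.coulomb(D_AB.total - D_A.total)
    z = np.zeros_like(dJ)
    dKa = ctx.exchange(D_AB.D_alpha - D_A.D_alpha) if xc_low.a_hf else z
    dKb = ctx.exchange(D_AB.D_beta - D_A.D_beta) if xc_low.a_hf else z
    if xc_low.is_pure_hf:
        dVa, dVb = z, z
    else:
        _, Va_AB, Vb_AB = ctx.xc_eval(D_AB.D_alpha, D_AB.D_beta, xc_low)
        _, Va_A, Vb_A = ctx.xc_eval(D_A.D_alpha, D_A.D_beta, xc_low)
        dVa, dVb = Va_AB - Va_A, Vb_AB - Vb_A
    return UKSEmbeddingPotential(
        dJ - xc_low.a_hf * dKa + dVa, dJ - xc_low.a_hf * dKb + dVb,
        dJ, dKa, dKb, dVa, dVb)


def huzinaga_operator(F: np.ndarray, R_env: np.ndarray,
                      S: np.ndarray) -> np.ndarray:
    """H = F - F R_env S - S R_env F; environment orbitals are repelled."""
    H = F - F @ R_env @ S - S @ R_env @ F
    return 0.5 * (H + H.T)


def _occupy(eps, C, n_occ, R_env, S, guard: float = 0.5):
    """Indices of the n_occ lowest eigenvectors that live outside B."""
    if n_occ == 0:
        return np.arange(0)
    if R_env is None or not np.any(R_env):
        return np.arange(n_occ)
    ov = np.einsum("mi,mn,np,pq,qi->i", C, S, R_env, S, C, optimize=True)
    keep = [i for i in range(C.shape[1]) if ov[i] <= guard]
    if len(keep) < n_occ:
        raise SCFConvergenceError(
            "embedded SCF cannot place all electrons outside the "
            "environment span (electron-count drift)")
    return np.asarray(keep[:n_occ])


def solve_embedded_uks(D_A0: SpinDensities, n_alpha: int, n_beta: int,
                       pot: UKSEmbeddingPotential,
                       R_env_alpha: np.ndarray, R_env_beta: np.ndarray,
                       ctx: AOBasisContext, xc_high: XCFunctionalSpec,
                       e_tol: float = 1e-9, res_tol: float = 1e-7,
                       max_iter: int = 150, raise_on_failure: bool = True,
                       log=None):
    """SCF on the per-spin Huzinaga operators in the frozen potential.

    Returns (C_alpha, C_beta, eps_alpha, eps_beta, D_tilde, n_iter).
    """
    S, X = ctx.S, lowdin_x(ctx.S)
    nao = ctx.n_ao
    dens = SpinDensities(D_A0.D_alpha.copy(), D_A0.D_beta.copy(), "A")
    diis = DIIS()
    e_old, converged = 0.0, False
    Ca = Cb = ea = eb = None
    it = 0
    for it in range(1, max_iter + 1):
        Fa, Fb = build_uks_fock(dens, ctx, xc_high)
        Fa = Fa + pot.V_alpha
        Fb = Fb + pot.V_beta
        Ha = huzinaga_operator(Fa, R_env_alpha, S)
        Hb = huzinaga_operator(Fb, R_env_beta, S)
        ra = X.T @ (Ha @ dens.D_alpha @ S - S @ dens.D_alpha @ Ha) @ X
        rb = X.T @ (Hb @ dens.D_beta @ S - S @ dens.D_beta @ Hb) @ X
        res = max(np.abs(ra).max(), np.abs(rb).max() if n_beta else 0.0)
        fv = diis.update(np.concatenate([Ha.ravel(), Hb.ravel()]),
                         np.concatenate([ra.ravel(), rb.ravel()]))
        Ha = fv[:nao * nao].reshape(nao, nao)
        Hb = fv[nao * nao:].reshape(nao, nao)
        ea, Ca = eigh(Ha, S)
        eb, Cb = eigh(Hb, S)
        ia = _occupy(ea, Ca, n_alpha, R_env_alpha, S)
        ib = _occupy(eb, Cb, n_beta, R_env_beta, S)
        dens = SpinDensities(Ca[:, ia] @ Ca[:, ia].T,
                             Cb[:, ib] @ Cb[:, ib].T, "A")
        # energy proxy: high-level electronic energy + frozen interaction
        e_new = uks_energy(dens, ctx, xc_high) + float(
            np.einsum("mn,mn", dens.D_alpha, pot.V_alpha)
            + np.einsum("mn,mn", dens.D_beta, pot.V_beta))
        de = e_new - e_old
        if log is not None:
            log(f"embed iter {it:3d}  E={e_new:.10f}  res={res:.3e}")
        if abs(de) < e_tol and res < res_tol:
            converged = True
            break
        e_old = e_new
    if not converged and raise_on_failure:
        raise SCFConvergenceError(
            f"embedded UKS did not converge in {max_iter} iterations "
            "(did not yield an SCF solution)")
    return Ca, Cb, ea, eb, dens, it


def orthogonality_residual(C_occ_list, L_env_list, S) -> float:
    """max |C~^T S L^B| over the provided spin channels."""
    r = 0.0
    for C_occ, L_env in zip(C_occ_list, L_env_list):
        if C_occ.size == 0 or L_env.size == 0:
            continue
        r = max(r, float(np.abs(C_occ.T @ S @ L_env).max()))
    return r


def assemble_energy_uks(E_low_AB: float, E_low_A: float, E_high_A: float,
                        D_tilde: SpinDensities, D_A: SpinDensities,
                        pot: UKSEmbeddingPotential, ctx: AOBasisContext,
                        orth_res: float = 0.0, n_iter: int = 0,
                        s_squared: float = 0.0, C=None,
                        eps=None) -> EmbeddingResult:
    """Multilevel energy with the first-order density-relaxation trace."""
    corr = float(
        np.einsum("mn,mn", D_tilde.D_alpha - D_A.D_alpha, pot.V_alpha)
        + np.einsum("mn,mn", D_tilde.D_beta - D_A.D_beta, pot.V_beta))
    e_pbe = E_low_AB - E_low_A + E_high_A + ctx.V_nn + corr
    return EmbeddingResult(E_low_AB, E_low_A, E_high_A, corr, ctx.V_nn,
                           e_pbe, orth_res, n_iter=n_iter,
                           s_squared=s_squared, densities=D_tilde,
                           C=C, orbital_energies=eps)


def _partition_spin(C, n_occ, ctx, active_atoms, method, threshold):
    from .partition import (boys_localize, mulliken_select, spade_partition)
    C_occ = C[:, :n_occ]
    if method == "spade":
        return spade_partition(C_occ, ctx, active_atoms, occupation=1.0)
    if method == "mulliken":
        L, _ = boys_localize(C_occ, ctx)
        return mulliken_select(L, ctx, active_atoms, threshold,
                               occupation=1.0)
    raise ValueError(f"unknown partition method {method!r}")


def run_uks_embedding(molecule, ctx: AOBasisContext,
                      xc_low: XCFunctionalSpec, xc_high: XCFunctionalSpec,
                      active_atoms, partition_method: str = "spade",
                      mulliken_threshold: float = 0.3,
                      supersystem=None, log=None,
                      scf_kwargs=None) -> EmbeddingResult:
    """Full unrestricted Huzinaga embedding workflow.

    ``supersystem`` may carry a converged low-level result (an object with
    C_alpha/C_beta/densities); when absent the low-level supersystem SCF
    is run here.
    """
    from .uks import solve_uks
    scf_kwargs = scf_kwargs or {}
    if supersystem is None:
        supersystem = solve_uks(molecule, ctx, xc_low, **scf_kwargs)
    na, nb = molecule.n_alpha, molecule.n_beta
    pa = _partition_spin(supersystem.C_alpha, na, ctx, active_atoms,
                         partition_method, mulliken_threshold)
    pb = _partition_spin(supersystem.C_beta, nb, ctx, active_atoms,
                         partition_method, mulliken_threshold)
    if log is not None and pa.n_active != pb.n_active:
        log(f"spin-asymmetric partition: {pa.n_active} alpha / "
            f"{pb.n_active} beta active orbitals")
    D_AB = SpinDensities(supersystem.C_alpha[:, :na] @ supersystem.C_alpha[:, :na].T,
                         supersystem.C_beta[:, :nb] @ supersystem.C_beta[:, :nb].T,
                         "AB")
    D_A = SpinDensities(pa.D_active, pb.D_active, "A")
    E_low_AB = uks_energy(D_AB, ctx, xc_low)
    E_low_A = uks_energy(D_A, ctx, xc_low)
    pot = build_embedding_potential_uks(D_AB, D_A, ctx, xc_low)
    Ca, Cb, ea, eb, D_t, n_it = solve_embedded_uks(
        D_A, pa.n_active, pb.n_active, pot, pa.R_env, pb.R_env, ctx, xc_high,
        log=log)
    orth = orthogonality_residual(
        [Ca[:, :pa.n_active], Cb[:, :pb.n_active]],
        [pa.L_env, pb.L_env], ctx.S)
    E_high_A = uks_energy(D_t, ctx, xc_high)
    s2 = s_squared_uhf(Ca, Cb, pa.n_active, pb.n_active, ctx.S)
    res = assemble_energy_uks(E_low_AB, E_low_A, E_high_A, D_t, D_A, pot,
                              ctx, orth, n_it, s2, (Ca, Cb), (ea, eb))
    res.extras.update(partition_alpha=pa, partition_beta=pb,
                      potential=pot, supersystem=supersystem)
    return res
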