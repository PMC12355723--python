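"""Restricted open-shell Huzinaga projection-based embedding.

The supersystem is solved with the restricted open-shell ensemble SCF,
its closed shells are partitioned into active/environment sets (every
open shell stays active), and the active subsystem is reoptimized with
the high-level unified RO Fock inside the frozen low-level potential.
The environment enters through an embedded core Hamiltonian, frozen xc
potential differences, and the Huzinaga projection against the
environment's closed-shell orbitals.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh

from .adapter import AOBasisContext, XCFunctionalSpec
from .embed_uks import (EmbeddingResult, _occupy, huzinaga_operator,
                        orthogonality_residual)
from .molecule import ConfigurationError
from .ro import (MicrostateEnsemble, ROFockAssembly, ShellDensities,
                 build_ensemble, build_unified_fock, ro_energy,
                 shell_densities)
from .scf_common import DIIS, lowdin_x
from .uks import SCFConvergenceError


@dataclasses.dataclass
class ROKSEmbeddingPotential:
    """Frozen RO embedding matrices (shell derivatives of E_12)."""

    dE_dDc: np.ndarray        # derivative w.r.t. the closed-shell density
    dE_dDo: np.ndarray        # derivative w.r.t. the open-shell density
    h_core_AinB: np.ndarray   # embedded core Hamiltonian
    Vxc_emb_c: np.ndarray     # frozen closed-channel xc difference
    Vxc_emb_o: np.ndarray     # frozen open-channel xc difference
    dJ: np.ndarray
    dK: np.ndarray


def build_embedding_potential_roks(D_AB: ShellDensities, D_A: ShellDensities,
                                   ctx: AOBasisContext,
                                   xc_low: XCFunctionalSpec) -> ROKSEmbeddingPotential:
    """Shared Coulomb/exchange core plus per-shell xc differences.

    Because the environment holds no spin density, the closed- and
    open-shell derivatives share the identical dJ/dK core built from
    total densities; they differ only in the xc channel (spin-averaged
    for the closed shells, alpha for the open shells).

    ``D_AB`` may be any density carrier exposing total/D_alpha/D_beta —
    in the mixed restricted-in-unrestricted scheme the supersystem block
    is genuinely spin-polarized.
    """
    if D_AB.total.shape != D_A.total.shape:
        raise ValueError("supersystem/subsystem dimension mismatch")
    dD = D_AB.total - D_A.total
    dJ = ctx.coulomb(dD)
    z = np.zeros_like(dJ)
    dK = ctx.exchange(dD) if xc_low.a_hf else z
    core = dJ - 0.5 * xc_low.a_hf * dK
    if xc_low.is_pure_hf:
        dVa = dVb = z
    else:
        _, Va_AB, Vb_AB = ctx.xc_eval(D_AB.D_alpha, D_AB.D_beta, xc_low)
        _, Va_A, Vb_A = ctx.xc_eval(D_A.D_alpha, D_A.D_beta, xc_low)
        dVa, dVb = Va_AB - Va_A, Vb_AB - Vb_A
    Vc = 0.5 * (dVa + dVb)
    Vo = dVa
    return ROKSEmbeddingPotential(core + Vc, core + Vo,
                                  ctx.h_core + core, Vc, Vo, dJ, dK)


def build_embedded_unified_fock(dens: ShellDensities,
                                pot: ROKSEmbeddingPotential,
                                ensemble: MicrostateEnsemble,
                                ctx: AOBasisContext,
                                xc_high: XCFunctionalSpec,
                                R_c: np.ndarray,
                                R_o: np.ndarray) -> ROFockAssembly:
    """Unified RO Fock with the embedded core Hamiltonian and frozen xc."""
    return build_unified_fock(dens, ensemble, ctx, xc_high, R_c, R_o,
                              h_core=pot.h_core_AinB,
                              V_c_extra=pot.Vxc_emb_c,
                              V_o_extra=pot.Vxc_emb_o)


def huzinaga_operator_roks(F_unified: np.ndarray, R_cB: np.ndarray,
                           S: np.ndarray) -> np.ndarray:
    """H = F - F R_cB S - S R_cB F against environment closed shells."""
    return huzinaga_operator(F_unified, R_cB, S)


def solve_embedded_roks(C0: np.ndarray, n_closed_A: int, n_open: int,
                        pot: ROKSEmbeddingPotential, R_cB: np.ndarray,
                        ensemble: MicrostateEnsemble, ctx: AOBasisContext,
                        xc_high: XCFunctionalSpec,
                        e_tol: float = 1e-9, res_tol: float = 1e-7,
                        max_iter: int = 150, raise_on_failure: bool = True,
                        log=None):
    """Iterative diagonalization of the embedded RO Huzinaga operator.

    ``C0`` supplies start orbitals ordered closed-A, open, rest.
    Returns (C, eps, dens_tilde, n_iter).
    """
    S, X = ctx.S, lowdin_x(ctx.S)
    nao = ctx.n_ao
    C = C0
    diis = DIIS()
    e_old, converged = 0.0, False
    eps = None
    it = 0
    for it in range(1, max_iter + 1):
        Cc = C[:, :n_closed_A]
        Co = C[:, n_closed_A:n_closed_A + n_open]
        R_c, R_o = Cc @ Cc.T, Co @ Co.T
        dens = shell_densities(C, n_closed_A, n_open, ensemble, "A")
        asm = build_embedded_unified_fock(dens, pot, ensemble, ctx,
                                          xc_high, R_c, R_o)
        H = huzinaga_operator_roks(asm.F_unified, R_cB, S)
        rc = X.T @ (H @ R_c @ S - S @ R_c @ H) @ X
        ro_ = X.T @ (H @ R_o @ S - S @ R_o @ H) @ X
        res = max(np.abs(rc).max(), np.abs(ro_).max() if n_open else 0.0)
        H = diis.update(H.ravel(), np.concatenate([rc.ravel(), ro_.ravel()])
                        ).reshape(nao, nao)
        eps, C_new = eigh(H, S)
        idx = _occupy(eps, C_new, n_closed_A + n_open, R_cB, S)
        rest = [i for i in range(nao) if i not in set(idx)]
        order = list(idx) + rest
        C = C_new[:, order]
        eps = eps[order]
        dens = shell_densities(C, n_closed_A, n_open, ensemble, "A")
        e_new = ro_energy(dens, ensemble, ctx, xc_high) + float(
            np.einsum("mn,mn", dens.D_c, pot.dE_dDc)
            + np.einsum("mn,mn", dens.D_o, pot.dE_dDo))
        de = e_new - e_old
        if log is not None:
            log(f"ro embed iter {it:3d}  E={e_new:.10f}  res={res:.3e}")
        if abs(de) < e_tol and res < res_tol:
            converged = True
            break
        e_old = e_new
    if not converged and raise_on_failure:
        raise SCFConvergenceError(
            f"embedded RO SCF did not converge in {max_iter} iterations "
            "(did not yield an SCF solution)")
    dens = shell_densities(C, n_closed_A, n_open, ensemble, "A")
    return C, eps, dens, it


def assemble_energy_roks(E_low_AB: float, E_low_A: float, E_high_A: float,
                         dens_tilde: ShellDensities, dens_A: ShellDensities,
                         pot: ROKSEmbeddingPotential, ctx: AOBasisContext,
                         n_open: int, orth_res: float = 0.0,
                         n_iter: int = 0, C=None, eps=None) -> EmbeddingResult:
    """Multilevel RO energy with the shell-resolved first-order trace."""
    corr = float(
        np.einsum("mn,mn", dens_tilde.D_c - dens_A.D_c, pot.dE_dDc)
        + np.einsum("mn,mn", dens_tilde.D_o - dens_A.D_o, pot.dE_dDo))
    e_pbe = E_low_AB - E_low_A + E_high_A + ctx.V_nn + corr
    s = 0.5 * n_open
    return EmbeddingResult(E_low_AB, E_low_A, E_high_A, corr, ctx.V_nn,
                           e_pbe, orth_res, n_iter=n_iter,
                           s_squared=s * (s + 1.0), densities=dens_tilde,
                           C=C, orbital_energies=eps)


def partition_ro(supersystem, ctx: AOBasisContext, active_atoms,
                 method: str = "spade", threshold: float = 0.3, log=None):
    """Partition the closed shells; open shells always stay active.

    ``supersystem`` is an ROResult.  Returns (partition, C_open).
    """
    from .partition import (PartitionError, boys_localize, mulliken_select,
                            spade_partition)
    nc, no = supersystem.n_closed, supersystem.n_open
    C_closed = supersystem.C[:, :nc]
    C_open = supersystem.C[:, nc:nc + no]
    if method == "spade":
        part = spade_partition(C_closed, ctx, active_atoms, occupation=2.0)
    elif method == "mulliken":
        L, _ = boys_localize(C_closed, ctx)
        part = mulliken_select(L, ctx, active_atoms, threshold,
                               occupation=2.0)
    else:
        raise ConfigurationError(f"unknown partition method {method!r}")
    if no and log is not None:
        from .partition import mulliken_populations
        pop = mulliken_populations(C_open, ctx, active_atoms)
        if np.any(pop < 0.5):
            log("warning: an open-shell orbital has dominant environment "
                "character; it is kept active by construction")
    return part, C_open


def run_roks_embedding(molecule, ctx: AOBasisContext,
                       xc_low: XCFunctionalSpec, xc_high: XCFunctionalSpec,
                       active_atoms, partition_method: str = "spade",
                       mulliken_threshold: float = 0.3,
                       supersystem=None, log=None,
                       scf_kwargs=None) -> EmbeddingResult:
    """Full restricted open-shell Huzinaga embedding workflow."""
    from .ro import solve_ro
    scf_kwargs = scf_kwargs or {}
    ensemble = build_ensemble(molecule.multiplicity,
                              molecule.multiplicity - 1)
    if supersystem is None:
        supersystem = solve_ro(molecule, ctx, xc_low, ensemble, **scf_kwargs)
    nc, no = supersystem.n_closed, supersystem.n_open
    part, C_open = partition_ro(supersystem, ctx, active_atoms,
                                partition_method, mulliken_threshold, log)
    D_AB = shell_densities(supersystem.C, nc, no, ensemble, "AB")
    Lo = C_open
    dens_A = ShellDensities(part.D_active, 2.0 * ensemble.f * Lo @ Lo.T,
                            ensemble.f, "A")
    E_low_AB = ro_energy(D_AB, ensemble, ctx, xc_low)
    E_low_A = ro_energy(dens_A, ensemble, ctx, xc_low)
    pot = build_embedding_potential_roks(D_AB, dens_A, ctx, xc_low)
    R_cB = part.R_env
    # warm start: active closed orbitals, open orbitals, then the rest of
    # the supersystem orbitals
    rest = np.hstack([part.L_env, supersystem.C[:, nc + no:]])
    C0 = np.hstack([part.L_active, C_open, rest])
    n_closed_A = part.n_active
    C, eps, dens_t, n_it = solve_embedded_roks(
        C0, n_closed_A, no, pot, R_cB, ensemble, ctx, xc_high, log=log)
    orth = orthogonality_residual(
        [C[:, :n_closed_A + no]], [part.L_env], ctx.S)
    E_high_A = ro_energy(dens_t, ensemble, ctx, xc_high)
    res = assemble_energy_roks(E_low_AB, E_low_A, E_high_A, dens_t, dens_A,
                               pot, ctx, no, orth, n_it, C, eps)
    res.extras.update(partition=part, potential=pot,
                      supersystem=supersystem, n_closed_A=n_closed_A,
                      ensemble=ensemble)
    return res
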