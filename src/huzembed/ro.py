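"""Restricted open-shell HF/KS in the microstate-ensemble formalism.

Both spins share one set of spatial orbitals, split into closed shells
(occupation 2), open shells (fractional average occupation 2f) and
virtuals.  The ensemble density is spin-adapted: <S^2> is exactly S(S+1).
Only the high-spin case is supported, where the ensemble collapses to a
single all-parallel microstate with f = 1/2 and Roothaan's
orbital-independent coupling parameters a = 1, b = 2.

The two shell Fock operators are merged into one unified matrix through
the shell-coupling construction (Q, T, gamma below), so a single
diagonalization per iteration yields both shells.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh

from .adapter import AOBasisContext, XCFunctionalSpec
from .molecule import ConfigurationError, MoleculeSpec
from .scf_common import DIIS, lowdin_x, sad_guess
from .uks import SCFConvergenceError, SpinDensities


@dataclasses.dataclass(frozen=True)
class MicrostateEnsemble:
    """Weights and coupling parameters of the high-spin ensemble."""

    n_open: int
    f: float = 0.5
    a: float = 1.0
    b: float = 2.0

    @property
    def a_bar(self) -> float:
        return (1.0 - self.a) / (1.0 - self.f)

    @property
    def b_bar(self) -> float:
        return (1.0 - self.b) / (1.0 - self.f)

    @property
    def c_bar(self) -> float:
        return 1.0 / (1.0 - self.f)

    def omega(self, n_closed: int, n_basis: int) -> np.ndarray:
        w = np.ones(n_basis)
        w[n_closed:n_closed + self.n_open] = self.f
        w[n_closed + self.n_open:] = 0.0
        return w


def build_ensemble(multiplicity: int, n_open: int) -> MicrostateEnsemble:
    """High-spin ensemble: one all-parallel microstate, f=1/2, a=1, b=2."""
    if n_open != multiplicity - 1:
        raise ConfigurationError(
            "only high-spin states with half-filled open shells are "
            f"supported (need n_open = multiplicity-1, got {n_open} vs "
            f"{multiplicity - 1})")
    return MicrostateEnsemble(n_open=n_open)


@dataclasses.dataclass
class ShellDensities:
    """Closed-shell, open-shell and total densities of the RO formalism."""

    D_c: np.ndarray
    D_o: np.ndarray
    f: float = 0.5
    label: str = "AB"

    @property
    def total(self) -> np.ndarray:
        return self.D_c + self.D_o

    @property
    def D_alpha(self) -> np.ndarray:
        # per-spin view of the high-spin single determinant
        return 0.5 * self.D_c + self.D_o

    @property
    def D_beta(self) -> np.ndarray:
        return 0.5 * self.D_c

    def as_spin(self, label=None) -> SpinDensities:
        return SpinDensities(self.D_alpha, self.D_beta,
                             label or self.label)


def shell_densities(C: np.ndarray, n_closed: int, n_open: int,
                    ensemble: MicrostateEnsemble, label="AB") -> ShellDensities:
    if n_closed + n_open > C.shape[1]:
        raise ValueError("occupancy exceeds basis size")
    Cc = C[:, :n_closed]
    Co = C[:, n_closed:n_closed + n_open]
    D_c = 2.0 * Cc @ Cc.T
    D_o = 2.0 * ensemble.f * Co @ Co.T
    return ShellDensities(D_c, D_o, ensemble.f, label)


def ro_energy(dens: ShellDensities, ensemble: MicrostateEnsemble,
              ctx: AOBasisContext, xc: XCFunctionalSpec) -> float:
    """Ensemble electronic energy as a function of the shell densities."""
    Dc, Do = dens.D_c, dens.D_o
    a_hf, a, b = xc.a_hf, ensemble.a, ensemble.b
    Jc, Jo = ctx.coulomb(Dc), ctx.coulomb(Do)
    e = float(np.einsum("mn,mn", ctx.h_core, Dc + Do))
    e += 0.5 * float(np.einsum("mn,mn", Dc, Jc))
    e += 0.5 * a * float(np.einsum("mn,mn", Do, Jo))
    e += float(np.einsum("mn,mn", Do, Jc))
    if a_hf:
        Kc, Ko = ctx.exchange(Dc), ctx.exchange(Do)
        e -= 0.25 * a_hf * float(np.einsum("mn,mn", Dc, Kc))
        e -= 0.25 * a_hf * b * float(np.einsum("mn,mn", Do, Ko))
        e -= 0.5 * a_hf * float(np.einsum("mn,mn", Do, Kc))
    if not xc.is_pure_hf:
        E_xc, _, _ = ctx.xc_eval(dens.D_alpha, dens.D_beta, xc)
        e += E_xc
    return e


@dataclasses.dataclass
class ROFockAssembly:
    F_c: np.ndarray
    Q: np.ndarray
    T: np.ndarray
    gamma: np.ndarray
    F_unified: np.ndarray
    V_xc_c: np.ndarray
    V_xc_o: np.ndarray


def shell_xc_potentials(dens: ShellDensities, ctx, xc):
    """(E_xc, V_xc^c, V_xc^o) averaged over the single microstate.

    V^c = (V^alpha + V^beta)/2;  V^o = V^alpha for half-filled parallel
    spins (the 1/2f weight cancels the single alpha occupation).
    """
    E_xc, Va, Vb = ctx.xc_eval(dens.D_alpha, dens.D_beta, xc)
    return E_xc, 0.5 * (Va + Vb), Va


def build_unified_fock(dens: ShellDensities, ensemble: MicrostateEnsemble,
                       ctx: AOBasisContext, xc: XCFunctionalSpec,
                       R_c: np.ndarray, R_o: np.ndarray,
                       h_core: np.ndarray = None,
                       V_c_extra: np.ndarray = None,
                       V_o_extra: np.ndarray = None) -> ROFockAssembly:
    """Closed Fock, coupling correction Q and shell-coupling matrix T.

    ``R_c``/``R_o`` are the projectors sum_k C_k C_k^T of the current
    closed/open orbitals.  ``h_core`` overrides the bare core Hamiltonian
    and ``V_*_extra`` add frozen contributions to the shell xc potentials
    (both used by the embedded variant; defaults recover the plain case).
    """
    S = ctx.S
    D = dens.total
    _, V_c, V_o = (0.0, np.zeros_like(D), np.zeros_like(D)) \
        if xc.is_pure_hf else shell_xc_potentials(dens, ctx, xc)
    if V_c_extra is not None:
        V_c = V_c + V_c_extra
    if V_o_extra is not None:
        V_o = V_o + V_o_extra
    h = ctx.h_core if h_core is None else h_core
    F_c = h + ctx.coulomb(D) + V_c
    if xc.a_hf:
        F_c = F_c - 0.5 * xc.a_hf * ctx.exchange(D)
    a_bar, b_bar, c_bar, f = (ensemble.a_bar, ensemble.b_bar,
                              ensemble.c_bar, ensemble.f)
    if ensemble.n_open == 0:
        z = np.zeros_like(D)
        return ROFockAssembly(F_c, z, z, z, F_c, V_c, V_o)
    Q = a_bar * ctx.coulomb(dens.D_o)
    if xc.a_hf:
        Q = Q - 0.5 * xc.a_hf * b_bar * ctx.exchange(dens.D_o)
    gamma = R_c @ S - (1.0 / c_bar) * np.eye(len(S)) + 0.5 * c_bar * R_o @ S
    T = (S @ R_c @ Q + Q @ R_c @ S + f * (S @ R_o @ Q + Q @ R_o @ S))
    dV = V_c - V_o
    T = T + c_bar * (gamma.T @ dV @ R_o @ S) + c_bar * (S @ R_o @ dV @ gamma)
    T = 0.5 * (T + T.T)
    F_unified = F_c - Q + T
    return ROFockAssembly(F_c, Q, T, gamma, 0.5 * (F_unified + F_unified.T),
                          V_c, V_o)


@dataclasses.dataclass
class ROResult:
    energy: float
    C: np.ndarray
    shell_labels: list
    orbital_energies: np.ndarray
    n_closed: int
    n_open: int
    converged: bool
    n_iter: int
    densities: ShellDensities = None

    @property
    def s_squared(self) -> float:
        s = 0.5 * self.n_open
        return s * (s + 1.0)


def _select_open(C, e, n_closed, n_open, mode, R_o_prev, S):
    """Choose which orbitals carry the open shells this iteration."""
    if mode == "aufbau" or R_o_prev is None:
        return np.arange(n_closed, n_closed + n_open)
    # overlap tracking: maximal projection onto the previous open space
    proj = np.einsum("mi,mn,np,pq,qi->i", C, S, R_o_prev, S, C, optimize=True)
    order = np.argsort(-proj)
    return np.sort(order[:n_open])


def solve_ro(molecule: MoleculeSpec, ctx: AOBasisContext,
             xc: XCFunctionalSpec, ensemble: MicrostateEnsemble = None,
             initial_guess=None, e_tol: float = 1e-9, res_tol: float = 1e-7,
             max_iter: int = 150, diis_size: int = 8,
             open_shell_selection: str = "aufbau",
             level_shift: float = 0.2,
             raise_on_failure: bool = True, log=None) -> ROResult:
    """Iterative diagonalization of the unified RO Fock matrix."""
    if ensemble is None:
        ensemble = build_ensemble(molecule.multiplicity,
                                  molecule.multiplicity - 1)
    n_open = ensemble.n_open
    n_closed = (molecule.n_electrons - n_open) // 2
    S, X = ctx.S, lowdin_x(ctx.S)
    nao = ctx.n_ao
    if n_closed + n_open > nao:
        raise ConfigurationError("more occupied shells than basis functions")
    if initial_guess is None:
        Dt = sad_guess(ctx)
        F0 = ctx.h_core + ctx.coulomb(Dt) - 0.25 * ctx.exchange(Dt)
        _, C = eigh(F0, S)
    else:
        C = initial_guess
    diis = DIIS(diis_size)
    e_old, converged = 0.0, False
    R_o_prev = None
    shift_left = 0
    eps = None
    it = 0
    for it in range(1, max_iter + 1):
        Cc = C[:, :n_closed]
        Co = C[:, n_closed:n_closed + n_open]
        R_c, R_o = Cc @ Cc.T, Co @ Co.T
        dens = shell_densities(C, n_closed, n_open, ensemble)
        asm = build_unified_fock(dens, ensemble, ctx, xc, R_c, R_o)
        F = asm.F_unified
        rc = X.T @ (F @ R_c @ S - S @ R_c @ F) @ X
        ro_ = X.T @ (F @ R_o @ S - S @ R_o @ F) @ X
        res = max(np.abs(rc).max(), np.abs(ro_).max() if n_open else 0.0)
        F = diis.update(F.ravel(), np.concatenate([rc.ravel(), ro_.ravel()])
                        ).reshape(nao, nao)
        if shift_left > 0:
            # push virtuals up to open a closed-open gap
            P_occ = (R_c + R_o) @ S
            F = F + level_shift * (S - S @ P_occ).T @ X @ X.T @ (S - S @ P_occ)
            shift_left -= 1
        eps, C_new = eigh(F, S)
        open_idx = _select_open(C_new, eps, n_closed, n_open,
                                open_shell_selection, R_o_prev, S)
        closed_idx = [i for i in range(nao) if i not in set(open_idx)][:n_closed]
        order = list(closed_idx) + list(open_idx) + \
            [i for i in range(nao) if i not in set(closed_idx) | set(open_idx)]
        C = C_new[:, order]
        eps = eps[order]
        R_o_prev = R_o
        dens = shell_densities(C, n_closed, n_open, ensemble)
        e_new = ro_energy(dens, ensemble, ctx, xc) + ctx.V_nn
        de = e_new - e_old
        if log is not None:
            log(f"iter {it:3d}  E={e_new:.10f}  |[F,R]|={res:.3e}  dE={de:.3e}")
        if n_open and shift_left == 0 and it > 1:
            gap = eps[n_closed] - eps[n_closed - 1] if n_closed else 1.0
            if gap < 0.01:
                shift_left = 5
        if abs(de) < e_tol and res < res_tol:
            converged = True
            e_old = e_new
            break
        e_old = e_new
    if not converged and raise_on_failure:
        raise SCFConvergenceError(
            f"RO SCF did not converge in {max_iter} iterations "
            "(did not yield an SCF solution)")
    labels = (["closed"] * n_closed + ["open"] * n_open
              + ["virtual"] * (nao - n_closed - n_open))
    dens = shell_densities(C, n_closed, n_open, ensemble)
    return ROResult(e_old, C, labels, eps, n_closed, n_open,
                    converged, it, dens)
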