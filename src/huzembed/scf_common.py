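"""Shared SCF machinery: DIIS, orthogonalization, atomic-density guess."""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh, fractional_matrix_power

from .adapter import AOBasisContext
from .basis import build_shells
from . import integrals as ig
from .molecule import MoleculeSpec


def lowdin_x(S: np.ndarray) -> np.ndarray:
    """Symmetric orthogonalization matrix S^{-1/2}."""
    e, U = np.linalg.eigh(S)
    if e.min() < 1e-10:
        raise np.linalg.LinAlgError("AO overlap is numerically singular")
    return (U / np.sqrt(e)) @ U.T


class DIIS:
    """Pulay convergence acceleration on the [F, D] commutator residual."""

    def __init__(self, max_vec: int = 8):
        self.max_vec = max_vec
        self.focks: list[np.ndarray] = []
        self.errors: list[np.ndarray] = []

    def update(self, fock_flat: np.ndarray, error_flat: np.ndarray) -> np.ndarray:
        self.focks.append(fock_flat.copy())
        self.errors.append(error_flat.copy())
        if len(self.focks) > self.max_vec:
            self.focks.pop(0)
            self.errors.pop(0)
        n = len(self.focks)
        if n < 2:
            return fock_flat
        B = -np.ones((n + 1, n + 1))
        B[n, n] = 0.0
        for i in range(n):
            for j in range(n):
                B[i, j] = np.dot(self.errors[i], self.errors[j])
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:n]
        except np.linalg.LinAlgError:
            self.focks = self.focks[-1:]
            self.errors = self.errors[-1:]
            return fock_flat
        return sum(ci * fi for ci, fi in zip(c, self.focks))


def commutator_residual(F: np.ndarray, D: np.ndarray, S: np.ndarray,
                        X: np.ndarray) -> np.ndarray:
    """Orthonormal-basis representation of FDS - SDF (zero at convergence)."""
    R = F @ D @ S - S @ D @ F
    return X.T @ R @ X


_SAD_CACHE: dict[tuple[str, str], np.ndarray] = {}


def atomic_density(symbol: str, basis_name: str) -> np.ndarray:
    """Spherically averaged atomic HF density (fractional occupations).

    Degenerate valence levels are filled evenly, which keeps the guess
    rotationally symmetric.
    """
    key = (symbol, basis_name)
    if key in _SAD_CACHE:
        return _SAD_CACHE[key]
    atom = MoleculeSpec.from_lists([symbol], [[0.0, 0.0, 0.0]],
                                   charge=0,
                                   multiplicity=1 if _z(symbol) % 2 == 0 else 2)
    shells = build_shells(atom, basis_name)
    S = ig.overlap(shells)
    h = ig.kinetic(shells) + ig.charge_attraction(
        shells, atom.coords_bohr, atom.charges)
    eri = ig.electron_repulsion(shells)
    n_elec = atom.n_electrons
    X = lowdin_x(S)
    D = np.zeros_like(S)
    for _ in range(60):
        J = np.einsum("ts,mnts->mn", D, eri, optimize=True)
        K = np.einsum("ts,mtsn->mn", D, eri, optimize=True)
        F = h + J - 0.5 * K
        e, C = eigh(F, S)
        occ = _fractional_aufbau(e, n_elec)
        D_new = (C * occ) @ C.T
        if np.abs(D_new - D).max() < 1e-8:
            D = D_new
            break
        D = 0.6 * D_new + 0.4 * D
    _SAD_CACHE[key] = D
    return D


def _z(symbol: str) -> int:
    from .molecule import ATOMIC_NUMBER
    return ATOMIC_NUMBER[symbol]


def _fractional_aufbau(energies: np.ndarray, n_elec: int) -> np.ndarray:
    """Fill levels bottom-up, sharing electrons evenly over degenerate sets."""
    occ = np.zeros_like(energies)
    remaining = float(n_elec)
    i = 0
    while remaining > 1e-12 and i < len(energies):
        j = i
        while j + 1 < len(energies) and energies[j + 1] - energies[i] < 1e-6:
            j += 1
        n_deg = j - i + 1
        fill = min(remaining, 2.0 * n_deg)
        occ[i:j + 1] = fill / n_deg
        remaining -= fill
        i = j + 1
    return occ


def sad_guess(ctx: AOBasisContext) -> np.ndarray:
    """Superposition-of-atomic-densities total density matrix."""
    D = np.zeros((ctx.n_ao, ctx.n_ao))
    for sym, (lo, hi) in zip(ctx.molecule.symbols, ctx.atom_ao_ranges):
        D[lo:hi, lo:hi] = atomic_density(sym, ctx.basis_name)
    return D
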