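"""Occupied-orbital localization and active/environment partitioning.

Occupied orbitals are localized (SPADE rotation or Foster-Boys), assigned
to the active subsystem A or the frozen environment B, and turned into
subsystem density matrices and environment projectors.  UKS treatments
partition alpha and beta orbitals independently; RO treatments partition
the closed shells only, with every open shell kept in A by construction.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import integrals as ig
from .adapter import AOBasisContext
from .molecule import ConfigurationError


class PartitionError(ConfigurationError):
    """Ambiguous or unsupported orbital partition."""


def _active_ao_indices(ctx: AOBasisContext, active_atoms) -> np.ndarray:
    idx = []
    for a in sorted(active_atoms):
        lo, hi = ctx.atom_ao_ranges[a]
        idx.extend(range(lo, hi))
    return np.asarray(idx, dtype=int)


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Scale each column so its largest-magnitude entry is positive."""
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def spade_vectors(C_occ: np.ndarray, ctx: AOBasisContext, active_atoms):
    """Singular values/rotation of the active-AO block of X^-1 C_occ.

    Returns (singular values descending, right singular vectors W with
    fixed signs).
    """
    e, U = np.linalg.eigh(ctx.S)
    S_half = (U * np.sqrt(e)) @ U.T
    C_orth = S_half @ C_occ
    rows = _active_ao_indices(ctx, active_atoms)
    block = C_orth[rows, :]
    _, sig, Vt = np.linalg.svd(block, full_matrices=True)
    W = _fix_signs(Vt.T.copy())
    sig = np.concatenate([sig, np.zeros(C_occ.shape[1] - len(sig))])
    return sig, W


def boys_localize(C_occ: np.ndarray, ctx: AOBasisContext,
                  max_sweeps: int = 200, tol: float = 1e-10):
    """Foster-Boys localization by Jacobi sweeps; returns (L, W).

    Maximizes sum_i |<i|r|i>|^2 over orthogonal 2x2 rotations.
    """
    n = C_occ.shape[1]
    W = np.eye(n)
    if n < 2:
        return C_occ.copy(), W
    mu = ig.dipole(ctx.shells)
    L = C_occ.copy()
    # dipole matrix elements in the current localized basis
    d = np.einsum("mi,dmn,nj->dij", L, mu, L, optimize=True)
    for sweep in range(max_sweeps):
        delta = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                v = d[:, i, j]
                u = d[:, i, i] - d[:, j, j]
                A = float(v @ v - 0.25 * (u @ u))
                B = float(u @ v)
                if abs(A) < 1e-16 and abs(B) < 1e-16:
                    continue
                theta = 0.25 * np.arctan2(B, -A)
                gain = A + np.sqrt(A * A + B * B)
                if gain < tol:
                    continue
                c, s = np.cos(theta), np.sin(theta)
                Wi, Wj = W[:, i].copy(), W[:, j].copy()
                W[:, i], W[:, j] = c * Wi + s * Wj, -s * Wi + c * Wj
                di, dj = d[:, :, i].copy(), d[:, :, j].copy()
                d[:, :, i], d[:, :, j] = c * di + s * dj, -s * di + c * dj
                di, dj = d[:, i, :].copy(), d[:, j, :].copy()
                d[:, i, :], d[:, j, :] = c * di + s * dj, -s * di + c * dj
                delta = max(delta, gain)
        if delta < tol:
            break
    else:
        raise RuntimeError("Boys localization did not converge")
    return C_occ @ _fix_signs(W), _fix_signs(W)


def localize_orbitals(C_occ: np.ndarray, ctx: AOBasisContext,
                      method: str = "spade", active_atoms=None):
    """Localized occupied coefficients L = C_occ W with W orthogonal."""
    if C_occ.shape[1] == 0:
        return C_occ.copy(), np.zeros((0, 0))
    if method.lower() == "boys":
        return boys_localize(C_occ, ctx)
    if method.lower() == "spade":
        if not active_atoms:
            raise PartitionError("SPADE localization needs active_atoms")
        _, W = spade_vectors(C_occ, ctx, active_atoms)
        return C_occ @ W, W
    raise ConfigurationError(f"unknown localization method {method!r}")


@dataclasses.dataclass
class OrbitalPartition:
    """Localized orbitals split into active (A) and environment (B) sets."""

    L: np.ndarray                 # all localized occupied coefficients
    W: np.ndarray                 # localization rotation
    active_idx: np.ndarray
    env_idx: np.ndarray
    occupation: float             # per-orbital density weight (2, 1 or 2f)
    singular_values: np.ndarray = None

    @property
    def L_active(self) -> np.ndarray:
        return self.L[:, self.active_idx]

    @property
    def L_env(self) -> np.ndarray:
        return self.L[:, self.env_idx]

    @property
    def n_active(self) -> int:
        return len(self.active_idx)

    @property
    def R_env(self) -> np.ndarray:
        """Environment projector sum_{i in B} L_i L_i^T (no occupation)."""
        Lb = self.L_env
        return Lb @ Lb.T

    @property
    def D_active(self) -> np.ndarray:
        La = self.L_active
        return self.occupation * La @ La.T

    @property
    def D_env(self) -> np.ndarray:
        Lb = self.L_env
        return self.occupation * Lb @ Lb.T


def spade_partition(C_occ: np.ndarray, ctx: AOBasisContext, active_atoms,
                    occupation: float = 1.0, log=None) -> OrbitalPartition:
    """Split occupied orbitals at the largest SPADE singular-value gap."""
    n_occ = C_occ.shape[1]
    n_atoms = ctx.molecule.n_atoms
    if not active_atoms or set(active_atoms) == set(range(n_atoms)):
        # trivial partitions: everything active (or everything env if empty)
        L = C_occ.copy()
        act = np.arange(n_occ) if active_atoms else np.arange(0)
        env = np.arange(0) if active_atoms else np.arange(n_occ)
        return OrbitalPartition(L, np.eye(n_occ), act, env, occupation)
    sig, W = spade_vectors(C_occ, ctx, active_atoms)
    if n_occ == 1:
        # no gap to split: assign by majority weight on the active atoms
        n_act = 1 if sig[0] ** 2 > 0.5 else 0
        return OrbitalPartition(C_occ @ W, W, np.arange(n_act),
                                np.arange(n_act, 1), occupation,
                                singular_values=sig)
    if n_occ > 1 and sig.max() - sig.min() < 1e-8:
        raise PartitionError(
            "SPADE singular values are all equal; the active-atom choice "
            "does not distinguish the orbitals — pick a different active "
            "region or use mulliken selection")
    gaps = sig[:-1] - sig[1:]
    best = np.argmax(gaps)
    # tie: prefer the smaller active set
    for i in range(len(gaps)):
        if i < best and gaps[i] > gaps[best] - 1e-8:
            best = i
            if log is not None:
                log("SPADE gap tie; choosing the smaller active set")
            break
    n_act = best + 1
    L = C_occ @ W
    return OrbitalPartition(L, W, np.arange(n_act), np.arange(n_act, n_occ),
                            occupation, singular_values=sig)


def mulliken_populations(L: np.ndarray, ctx: AOBasisContext,
                         active_atoms) -> np.ndarray:
    """Per-orbital Mulliken population on the active atoms' AOs."""
    SL = ctx.S @ L
    rows = _active_ao_indices(ctx, active_atoms)
    return np.einsum("mi,mi->i", SL[rows, :], L[rows, :])


def mulliken_select(L: np.ndarray, ctx: AOBasisContext, active_atoms,
                    threshold: float = 0.3, occupation: float = 1.0,
                    forced_active=()) -> OrbitalPartition:
    """Orbital i is active iff its active-atom Mulliken population exceeds
    ``threshold``; indices in ``forced_active`` (open shells) always are."""
    pop = mulliken_populations(L, ctx, active_atoms)
    act = [i for i in range(L.shape[1])
           if pop[i] > threshold or i in set(forced_active)]
    env = [i for i in range(L.shape[1]) if i not in set(act)]
    return OrbitalPartition(L.copy(), np.eye(L.shape[1]),
                            np.asarray(act, int), np.asarray(env, int),
                            occupation)


def subsystem_densities(partition: OrbitalPartition):
    """(D_active, D_env) with the partition's occupation folded in."""
    return partition.D_active, partition.D_env
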