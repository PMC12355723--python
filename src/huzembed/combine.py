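"""Mixed restricted/unrestricted embedding schemes and restricted orbitals.

Two crossover workflows connect the ansatz of the supersystem (low
level) with the ansatz of the embedded subsystem (high level):

* ``uks_in_roks`` — restricted open-shell supersystem, spin-polarized
  relaxation of the active subsystem (UKS/UHF-in-ROKS).
* ``roks_in_uks`` — unrestricted supersystem, natural orbitals of the
  total density restore a restricted picture, and the active subsystem
  is reoptimized with the restricted open-shell machinery
  (ROKS/ROHF-in-UKS).

``quasi_restricted_orbitals`` provides the same natural-orbital
construction as a reference set for open-shell correlation treatments
with unrestricted SCF solutions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.linalg import eigh

import warnings

from .adapter import AOBasisContext, XCFunctionalSpec
from .embed_roks import (assemble_energy_roks, build_embedding_potential_roks,
                         run_roks_embedding, solve_embedded_roks)
from .embed_uks import (EmbeddingResult, assemble_energy_uks,
                        build_embedding_potential_uks, orthogonality_residual,
                        run_uks_embedding, solve_embedded_uks)
from .partition import spade_partition
from .ro import ShellDensities, build_ensemble, ro_energy, shell_densities
from .uks import SpinDensities, s_squared_uhf, uks_energy


@dataclasses.dataclass
class NaturalOrbitalSet:
    """Eigenvectors/occupations of a total density in the S-metric."""

    coefficients: np.ndarray
    occupations: np.ndarray           # descending, in [0, 2]
    classification: list              # per orbital: doubly | singly | virtual

    @property
    def n_doubly(self) -> int:
        return self.classification.count("doubly")

    @property
    def n_singly(self) -> int:
        return self.classification.count("singly")


def natural_orbitals(D_total: np.ndarray, S: np.ndarray, n_closed: int,
                     n_open: int, gap_warn: float = 0.05) -> NaturalOrbitalSet:
    """Diagonalize S D S in the S-metric; classify by descending occupation."""
    occ, C = eigh(S @ D_total @ S, S)
    order = np.argsort(-occ)
    occ, C = occ[order], C[:, order]
    occ = np.clip(occ, 0.0, 2.0)
    cls = (["doubly"] * n_closed + ["singly"] * n_open
           + ["virtual"] * (len(occ) - n_closed - n_open))
    if n_open and n_closed:
        if occ[n_closed - 1] - occ[n_closed] < gap_warn:
            warnings.warn("ambiguous doubly/singly natural-occupation "
                          "split; classifying by electron count")
    return NaturalOrbitalSet(C, occ, cls)


def quasi_restricted_orbitals(uks_result, S: np.ndarray) -> NaturalOrbitalSet:
    """Restricted orbital set spanning the unrestricted occupied space.

    Natural orbitals of the spin-averaged density, classified with the
    (n_closed, n_open) counts of the unrestricted solution.
    """
    n_open = uks_result.n_alpha - uks_result.n_beta
    n_closed = uks_result.n_beta
    return natural_orbitals(uks_result.densities.total, S,
                            n_closed, n_open)


class _ROAsUKS:
    """Adapter presenting a restricted open-shell solution as per-spin data."""

    def __init__(self, ro_result):
        self.C_alpha = ro_result.C
        self.C_beta = ro_result.C
        d = ro_result.densities
        self.densities = SpinDensities(d.D_alpha, d.D_beta, "AB")
        self.energy = ro_result.energy


def uks_in_roks(molecule, ctx: AOBasisContext, xc_low: XCFunctionalSpec,
                xc_high: XCFunctionalSpec, active_atoms,
                partition_method: str = "spade",
                mulliken_threshold: float = 0.3, supersystem=None,
                log=None) -> EmbeddingResult:
    """Restricted open-shell supersystem, unrestricted embedded subsystem.

    The restricted orbitals define per-spin occupied sets (alpha: closed
    + open, beta: closed); the low-level supersystem energy is the
    unrestricted energy expression on the per-spin views, and everything
    downstream is the standard unrestricted embedding.
    """
    from .ro import solve_ro
    if supersystem is None:
        supersystem = solve_ro(molecule, ctx, xc_low)
    res = run_uks_embedding(molecule, ctx, xc_low, xc_high, active_atoms,
                            partition_method, mulliken_threshold,
                            supersystem=_ROAsUKS(supersystem), log=log)
    res.extras["supersystem_ro"] = supersystem
    return res


def roks_in_uks(molecule, ctx: AOBasisContext, xc_low: XCFunctionalSpec,
                xc_high: XCFunctionalSpec, active_atoms,
                partition_method: str = "spade",
                mulliken_threshold: float = 0.3, supersystem=None,
                log=None) -> EmbeddingResult:
    """Unrestricted supersystem, restricted open-shell embedded subsystem.

    Natural orbitals of the unrestricted total density provide spatially
    restricted doubly/singly occupied orbitals; the closed shells are
    partitioned, the low-level subsystem energy is evaluated on the
    per-spin views of the restricted subsystem densities, and the
    restricted open-shell embedding machinery runs at the high level.
    """
    from .uks import solve_uks
    if supersystem is None:
        supersystem = solve_uks(molecule, ctx, xc_low)
    n_open = supersystem.n_alpha - supersystem.n_beta
    n_closed = supersystem.n_beta
    ensemble = build_ensemble(n_open + 1, n_open)
    nos = natural_orbitals(supersystem.densities.total, ctx.S,
                           n_closed, n_open)
    C = nos.coefficients
    # partition the doubly occupied natural orbitals; open shells active
    part = spade_partition(C[:, :n_closed], ctx, active_atoms,
                           occupation=2.0)
    C_open = C[:, n_closed:n_closed + n_open]
    dens_A = ShellDensities(part.D_active,
                            2.0 * ensemble.f * C_open @ C_open.T,
                            ensemble.f, "A")
    E_low_AB = supersystem.energy - ctx.V_nn       # electronic, unrestricted
    E_low_A = uks_energy(SpinDensities(dens_A.D_alpha, dens_A.D_beta, "A"),
                         ctx, xc_low)
    pot = build_embedding_potential_roks(supersystem.densities, dens_A,
                                         ctx, xc_low)
    rest = np.hstack([part.L_env, C[:, n_closed + n_open:]])
    C0 = np.hstack([part.L_active, C_open, rest])
    C_emb, eps, dens_t, n_it = solve_embedded_roks(
        C0, part.n_active, n_open, pot, part.R_env, ensemble, ctx, xc_high,
        log=log)
    orth = orthogonality_residual(
        [C_emb[:, :part.n_active + n_open]], [part.L_env], ctx.S)
    E_high_A = ro_energy(dens_t, ensemble, ctx, xc_high)
    res = assemble_energy_roks(E_low_AB, E_low_A, E_high_A, dens_t, dens_A,
                               pot, ctx, n_open, orth, n_it, C_emb, eps)
    res.extras.update(partition=part, potential=pot,
                      supersystem=supersystem, natural_orbitals=nos,
                      n_closed_A=part.n_active, ensemble=ensemble)
    return res
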