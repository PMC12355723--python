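"""Integral/DFT engine contract used by every SCF and embedding routine.

`AOBasisContext` packages, for one molecule + basis, the AO overlap, core
Hamiltonian, nuclear repulsion, the Coulomb/exchange contraction builders
and a shared quadrature grid.  One grid instance is reused for every xc
evaluation on the context — supersystem, subsystem and embedded alike — so
that subtractive multilevel energies cancel quadrature error exactly.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import integrals as ig
from . import xc as xcmod
from .basis import build_shells, atom_ao_ranges
from .grid import MolecularGrid, ao_values
from .molecule import ConfigurationError, MoleculeSpec

#: registry of functionals: exact-exchange fraction and weighted components.
#: Weights include all hybrid-mixing factors, so the evaluated xc energy is
#: added to the electronic energy as-is (the engine's normalization of the
#: (1 - a_HF) E_xc term of hybrid theory).
FUNCTIONALS = {
    "hf":     (1.0, ()),
    "slater": (0.0, ((1.0, "slater_x"),)),
    "lda":    (0.0, ((1.0, "slater_x"), (1.0, "pw92_c"))),
    "pbe":    (0.0, ((1.0, "pbe_x"), (1.0, "pbe_c"))),
    "pbe0":   (0.25, ((0.75, "pbe_x"), (1.0, "pbe_c"))),
}


@dataclasses.dataclass(frozen=True)
class XCFunctionalSpec:
    """Functional identifier, exact-exchange fraction and dispersion flag."""

    name: str
    a_hf: float
    components: tuple[tuple[float, str], ...]
    dispersion: str = "none"

    @classmethod
    def resolve(cls, name: str, dispersion: str = "none") -> "XCFunctionalSpec":
        key = name.lower()
        if key not in FUNCTIONALS:
            raise ConfigurationError(
                f"unknown functional {name!r} (have {sorted(FUNCTIONALS)})")
        a_hf, comps = FUNCTIONALS[key]
        return cls(key, a_hf, tuple(comps), dispersion)

    @property
    def is_pure_hf(self) -> bool:
        return not self.components

    @property
    def needs_gradients(self) -> bool:
        return any(name.startswith("pbe") for _, name in self.components)


class AOBasisContext:
    """Integrals, contraction builders, and the shared grid for one system."""

    def __init__(self, molecule: MoleculeSpec, basis_name: str,
                 grid_level: int = 1,
                 point_charges: Sequence[tuple[float, tuple[float, float, float]]] = ()):
        self.molecule = molecule
        self.basis_name = basis_name
        self.shells = build_shells(molecule, basis_name)
        self.S = ig.overlap(self.shells)
        self.n_ao = self.S.shape[0]
        kin = ig.kinetic(self.shells)
        nuc = ig.charge_attraction(self.shells, molecule.coords_bohr,
                                   molecule.charges)
        self.h_core = kin + nuc
        self.V_nn = molecule.nuclear_repulsion()
        self.point_charges = tuple(point_charges)
        if point_charges:
            q = [pc[0] for pc in point_charges]
            pos = [pc[1] for pc in point_charges]    # bohr
            self.h_core = self.h_core + ig.charge_attraction(self.shells, pos, q)
            # nuclei-point charge interaction joins the nuclear repulsion
            z = molecule.charges
            r = molecule.coords_bohr
            for qc, pc in zip(q, pos):
                for za, ra in zip(z, r):
                    self.V_nn += qc * za / np.linalg.norm(ra - np.asarray(pc))
        self.atom_ao_ranges = atom_ao_ranges(self.shells, molecule.n_atoms)
        self._eri = None
        self.grid_level = grid_level
        self._grid = None
        self._ao_grid = None
        self._xc_memo: dict = {}

    # lazy heavy pieces ------------------------------------------------------
    @property
    def eri(self) -> np.ndarray:
        if self._eri is None:
            self._eri = ig.electron_repulsion(self.shells)
        return self._eri

    @property
    def grid(self) -> MolecularGrid:
        if self._grid is None:
            self._grid = MolecularGrid(self.molecule, self.grid_level)
        return self._grid

    def _ao_on_grid(self) -> np.ndarray:
        if self._ao_grid is None:
            self._ao_grid = ao_values(self.shells, self.grid.points)
        return self._ao_grid

    # contraction builders ---------------------------------------------------
    def coulomb(self, D: np.ndarray) -> np.ndarray:
        """J[D]_munu = sum_ts D_ts (mu nu | t s)."""
        return np.einsum("ts,mnts->mn", D, self.eri, optimize=True)

    def exchange(self, D: np.ndarray) -> np.ndarray:
        """K[D]_munu = sum_ts D_ts (mu t | s nu) (chemists' notation)."""
        return np.einsum("ts,mtsn->mn", D, self.eri, optimize=True)

    # xc ---------------------------------------------------------------------
    def xc_eval(self, D_alpha: np.ndarray, D_beta: np.ndarray,
                xc: XCFunctionalSpec):
        """(E_xc, V_alpha, V_beta) of the weighted DFT components.

        Pure HF specs return zeros.  Potentials are the matrix derivatives
        dE_xc/dD_sigma evaluated on the context grid.
        """
        for D in (D_alpha, D_beta):
            if not np.allclose(D, D.T, atol=1e-10):
                raise ValueError("xc_eval requires symmetric densities")
        if xc.is_pure_hf:
            z = np.zeros_like(D_alpha)
            return 0.0, z, z.copy()
        key = (D_alpha.tobytes(), D_beta.tobytes(), xc.name, xc.components)
        hit = self._xc_memo.get(key)
        if hit is not None:
            return hit
        ao = self._ao_on_grid()
        w = self.grid.weights
        val = ao[0]
        rho_a = np.einsum("pm,mn,pn->p", val, D_alpha, val, optimize=True)
        rho_b = np.einsum("pm,mn,pn->p", val, D_beta, val, optimize=True)
        if xc.needs_gradients:
            grad_a = 2.0 * np.einsum("dpm,mn,pn->pd",
                                     ao[1:], D_alpha, val, optimize=True)
            grad_b = 2.0 * np.einsum("dpm,mn,pn->pd",
                                     ao[1:], D_beta, val, optimize=True)
        else:
            grad_a = grad_b = None
        res = xcmod.eval_xc(xc.components, rho_a, rho_b, grad_a, grad_b)
        E = float(np.dot(w, res["e"]))
        Va = np.einsum("p,pm,pn->mn", w * res["vra"], val, val, optimize=True)
        Vb = np.einsum("p,pm,pn->mn", w * res["vrb"], val, val, optimize=True)
        if xc.needs_gradients:
            # weak-form gradient terms: 2 de/dgss grad rho_s + de/dgab grad rho_t
            fa = (2.0 * res["vgaa"][:, None] * grad_a
                  + res["vgab"][:, None] * grad_b) * w[:, None]
            fb = (2.0 * res["vgbb"][:, None] * grad_b
                  + res["vgab"][:, None] * grad_a) * w[:, None]
            ta = np.einsum("pd,dpm,pn->mn", fa, ao[1:], val, optimize=True)
            tb = np.einsum("pd,dpm,pn->mn", fb, ao[1:], val, optimize=True)
            Va = Va + ta + ta.T
            Vb = Vb + tb + tb.T
        out = (E, 0.5 * (Va + Va.T), 0.5 * (Vb + Vb.T))
        if len(self._xc_memo) > 8:
            self._xc_memo.clear()
        self._xc_memo[key] = out
        return out


def build_context(molecule: MoleculeSpec, basis_name: str,
                  grid_level: int = 1, point_charges=()) -> AOBasisContext:
    """Resolve molecule + basis into an AO context (engine entry point)."""
    return AOBasisContext(molecule, basis_name, grid_level, point_charges)
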