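"""Competing focused models: vacuum embedding, ONIOM-ME and ONIOM-EE.

The active region is cut out of the parent molecule, dangling bonds are
saturated with link hydrogens at 1.08 A, and the subtractive two-layer
energy is assembled.  Electronic embedding represents the environment as
a point-charge field derived from intrinsic atomic orbital (IAO) or
Mulliken populations, with charges of the border atoms zeroed and the
residual evenly redistributed.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from . import integrals as ig
from .adapter import XCFunctionalSpec, build_context
from .basis import build_shells
from .molecule import ConfigurationError, MoleculeSpec

LINK_DISTANCE_ANGSTROM = 1.08


@dataclasses.dataclass
class ModelSystem:
    """Capped active region of a parent molecule."""

    parent: MoleculeSpec
    model: MoleculeSpec          # active atoms + link hydrogens
    active_atoms: tuple
    border_pairs: tuple          # (active index, environment index) pairs
    link_positions: tuple        # angstrom coordinates of the link hydrogens


def cap_with_link_atoms(molecule: MoleculeSpec, active_atoms, border_pairs=(),
                        charge: int = None,
                        multiplicity: int = None) -> ModelSystem:
    """Cut out the active atoms and saturate each cut with a hydrogen.

    Each border pair (active atom, environment atom) yields one hydrogen
    on the segment from the active atom toward the environment atom at
    1.08 A.  The model inherits the parent's charge and, when the
    radical sits in the active region (parent open-shell), the parent's
    multiplicity; both are overridable.
    """
    active = sorted(set(active_atoms))
    env = set(range(molecule.n_atoms)) - set(active)
    coords = molecule.coords_angstrom
    links = []
    for a, b in border_pairs:
        if a not in set(active) or b not in env:
            raise ConfigurationError(
                f"border pair ({a}, {b}) must connect an active atom to an "
                "environment atom")
        direction = coords[b] - coords[a]
        norm = np.linalg.norm(direction)
        if norm < 1e-8:
            raise ConfigurationError("degenerate border pair geometry")
        links.append(coords[a] + direction / norm * LINK_DISTANCE_ANGSTROM)
    symbols = [molecule.symbols[i] for i in active] + ["H"] * len(links)
    positions = [coords[i].tolist() for i in active] + \
        [list(map(float, p)) for p in links]
    if charge is None:
        charge = molecule.charge
    if multiplicity is None:
        multiplicity = molecule.multiplicity
        n_elec = sum_z(symbols) - charge
        if (n_elec - (multiplicity - 1)) % 2:
            multiplicity = 1 if n_elec % 2 == 0 else 2
    model = MoleculeSpec.from_lists(symbols, positions, charge, multiplicity)
    return ModelSystem(molecule, model, tuple(active), tuple(border_pairs),
                       tuple(tuple(p) for p in links))


def sum_z(symbols) -> int:
    from .molecule import ATOMIC_NUMBER
    return sum(ATOMIC_NUMBER[s] for s in symbols)


@dataclasses.dataclass
class ChargeField:
    """Environment point charges after border zeroing and redistribution."""

    charges: np.ndarray          # one value per environment atom
    positions_bohr: np.ndarray
    atom_indices: tuple          # parent-atom index of each charge
    zeroed: tuple                # border environment atoms set to zero

    def as_point_charges(self):
        return tuple((float(q), tuple(p))
                     for q, p in zip(self.charges, self.positions_bohr))

    @property
    def total(self) -> float:
        return float(self.charges.sum())


def build_charge_field(model: ModelSystem, atom_charges) -> ChargeField:
    """Point-charge field of the environment atoms.

    Charges of environment atoms in a border pair are zeroed, and the
    difference between the target total (parent charge minus model
    charge) and the current sum is spread evenly over the remaining
    charges.
    """
    parent = model.parent
    env = [i for i in range(parent.n_atoms) if i not in set(model.active_atoms)]
    border_env = {b for _, b in model.border_pairs}
    q = np.array([atom_charges[i] for i in env], dtype=float)
    for k, i in enumerate(env):
        if i in border_env:
            q[k] = 0.0
    target = float(parent.charge - model.model.charge)
    keep = [k for k, i in enumerate(env) if i not in border_env]
    if keep:
        q[keep] += (target - q.sum()) / len(keep)
    pos = parent.coords_bohr[env]
    return ChargeField(q, pos, tuple(env), tuple(sorted(border_env)))


def mulliken_charges(D_total: np.ndarray, ctx) -> np.ndarray:
    """q_A = Z_A - sum_{mu in A} (D S)_{mu mu}."""
    pop = np.einsum("mn,nm->m", D_total, ctx.S)
    q = np.array(ctx.molecule.charges, dtype=float)
    for a, (lo, hi) in enumerate(ctx.atom_ao_ranges):
        q[a] -= pop[lo:hi].sum()
    return q


def _sym_orth(C: np.ndarray, S: np.ndarray) -> np.ndarray:
    M = C.T @ S @ C
    e, U = np.linalg.eigh(M)
    return C @ (U / np.sqrt(e)) @ U.T


def iao_charges(D_total: np.ndarray, ctx,
                minao: str = "sto-3g") -> np.ndarray:
    """Intrinsic-atomic-orbital populations (Knizia construction).

    The occupied space is taken from the natural orbitals of the total
    density (occupation above 1e-6), which covers restricted,
    unrestricted and fractional references alike.  A missing element in
    the minimal reference basis raises; callers fall back to Mulliken
    populations.
    """
    from scipy.linalg import eigh as geigh
    S1 = ctx.S
    ref_shells = build_shells(ctx.molecule, minao)
    S2 = ig.overlap(ref_shells)
    S12 = ig.overlap(ctx.shells, ref_shells)
    S1inv = np.linalg.inv(S1)
    S2inv = np.linalg.inv(S2)
    P12 = S1inv @ S12
    occ, nat = geigh(S1 @ D_total @ S1, S1)
    C = nat[:, occ > 1e-6]
    Ct = _sym_orth(S1inv @ S12 @ S2inv @ S12.T @ C, S1)
    P_o = C @ C.T @ S1
    P_t = Ct @ Ct.T @ S1
    eye = np.eye(len(S1))
    A = P_o @ P_t @ P12 + (eye - P_o) @ (eye - P_t) @ P12
    A = _sym_orth(A, S1)
    # population of each IAO in the total density
    pop = np.einsum("mi,mn,nt,ts,si->i", A, S1, D_total, S1, A,
                    optimize=True)
    # map minao AOs to atoms
    q = np.array(ctx.molecule.charges, dtype=float)
    k = 0
    for sh in ref_shells:
        for _ in range(sh.n_components):
            q[sh.atom] -= pop[k]
            k += 1
    return q


def iao_or_mulliken_charges(D_total: np.ndarray, ctx,
                            scheme: str = "iao") -> np.ndarray:
    if scheme.lower() == "mulliken":
        return mulliken_charges(D_total, ctx)
    if scheme.lower() != "iao":
        raise ConfigurationError(f"unknown charge scheme {scheme!r}")
    try:
        return iao_charges(D_total, ctx)
    except (KeyError, ConfigurationError) as exc:
        warnings.warn(f"IAO reference basis missing {exc}; falling back "
                      "to Mulliken charges")
        return mulliken_charges(D_total, ctx)


def _solve(molecule: MoleculeSpec, xc: XCFunctionalSpec, basis: str,
           grid_level: int = 1, ansatz: str = "uks", point_charges=(),
           scf_kwargs=None) -> float:
    from .ro import solve_ro
    from .uks import solve_uks
    ctx = build_context(molecule, basis, grid_level, point_charges)
    kw = scf_kwargs or {}
    if ansatz == "roks":
        return solve_ro(molecule, ctx, xc, **kw).energy
    return solve_uks(molecule, ctx, xc, **kw).energy


def vacuum_embedding_energy(model: ModelSystem, xc_high: XCFunctionalSpec,
                            basis: str, grid_level: int = 1,
                            ansatz: str = "uks", scf_kwargs=None) -> float:
    """High-level energy of the capped model system alone."""
    return _solve(model.model, xc_high, basis, grid_level, ansatz,
                  scf_kwargs=scf_kwargs)


def oniom_me(model: ModelSystem, xc_high: XCFunctionalSpec,
             xc_low: XCFunctionalSpec, basis: str, grid_level: int = 1,
             ansatz: str = "uks", scf_kwargs=None) -> float:
    """Mechanical-embedding ONIOM: E_low(AB) - E_low(model) + E_high(model)."""
    e_low_ab = _solve(model.parent, xc_low, basis, grid_level, ansatz,
                      scf_kwargs=scf_kwargs)
    e_low_m = _solve(model.model, xc_low, basis, grid_level, ansatz,
                     scf_kwargs=scf_kwargs)
    e_high_m = _solve(model.model, xc_high, basis, grid_level, ansatz,
                      scf_kwargs=scf_kwargs)
    return e_low_ab - e_low_m + e_high_m


def oniom_ee(model: ModelSystem, xc_high: XCFunctionalSpec,
             xc_low: XCFunctionalSpec, basis: str, grid_level: int = 1,
             ansatz: str = "uks", charge_scheme: str = "iao",
             charge_scale: float = 1.0, scf_kwargs=None) -> float:
    """Electronic-embedding ONIOM: the model sees the environment charges.

    Charges derive from the low-level supersystem density; they enter
    both model calculations so that the classical terms cancel in the
    subtraction.  ``charge_scale`` linearly scales the field (0 recovers
    mechanical embedding).
    """
    from .uks import solve_uks
    from .ro import solve_ro
    ctx = build_context(model.parent, basis, grid_level)
    kw = scf_kwargs or {}
    if ansatz == "roks":
        sup = solve_ro(model.parent, ctx, xc_low, **kw)
    else:
        sup = solve_uks(model.parent, ctx, xc_low, **kw)
    q_atom = iao_or_mulliken_charges(sup.densities.total, ctx, charge_scheme)
    field = build_charge_field(model, q_atom)
    pcs = tuple((charge_scale * q, p) for q, p in field.as_point_charges())
    e_low_ab = sup.energy
    e_low_m = _solve(model.model, xc_low, basis, grid_level, ansatz,
                     point_charges=pcs, scf_kwargs=scf_kwargs)
    e_high_m = _solve(model.model, xc_high, basis, grid_level, ansatz,
                      point_charges=pcs, scf_kwargs=scf_kwargs)
    return e_low_ab - e_low_m + e_high_m
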