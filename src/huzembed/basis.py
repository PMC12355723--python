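"""Contracted Gaussian shells over the built-in basis tables.

Only s and p shells are supported, which covers the bundled bases
(STO-3G, 6-31G) for the elements of the test systems.  For l <= 1 the
cartesian and spherical-harmonic representations coincide, so AOs are
stored as cartesian components.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from ._basis_data import BASIS_TABLES
from .molecule import ANGSTROM_TO_BOHR, MoleculeSpec, ConfigurationError

#: cartesian component exponents per angular momentum
CART_COMPONENTS = {
    0: [(0, 0, 0)],
    1: [(1, 0, 0), (0, 1, 0), (0, 0, 1)],
}


def _primitive_norm(alpha: float, l: int) -> float:
    # norm of x^l * exp(-a r^2) cartesian primitive (axis-aligned component)
    df = 1.0
    for k in range(2 * l - 1, 0, -2):
        df *= k
    return (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / math.sqrt(df)


@dataclasses.dataclass(frozen=True)
class Shell:
    """One contracted shell: center, angular momentum, primitives."""

    atom: int
    l: int
    center: tuple[float, float, float]        # bohr
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]           # include primitive norms

    @property
    def n_components(self) -> int:
        return len(CART_COMPONENTS[self.l])


def _normalize_contraction(l, exps, coefs):
    """Scale contraction so the axis-aligned contracted function is unit-norm."""
    exps = np.asarray(exps)
    coefs = np.asarray(coefs) * np.array([_primitive_norm(a, l) for a in exps])
    # <g_i|g_j> for x^l-type primitives along one axis
    df = 1.0
    for k in range(2 * l - 1, 0, -2):
        df *= k
    p = exps[:, None] + exps[None, :]
    s = df * (math.pi / p) ** 1.5 / (2.0 * p) ** l
    norm2 = coefs @ s @ coefs
    return exps, coefs / math.sqrt(norm2)


def build_shells(mol: MoleculeSpec, basis_name: str) -> list[Shell]:
    key = basis_name.lower().replace("_", "-")
    if key not in BASIS_TABLES:
        raise ConfigurationError(
            f"basis {basis_name!r} not bundled (have {sorted(BASIS_TABLES)})")
    table = BASIS_TABLES[key]
    shells: list[Shell] = []
    coords = mol.coords_bohr
    for ia, sym in enumerate(mol.symbols):
        if sym not in table:
            raise ConfigurationError(
                f"element {sym} not available in bundled basis {basis_name}")
        for block in table[sym]:
            l = block[0]
            if l > 1:
                raise ConfigurationError(
                    "built-in engine supports s and p shells only")
            exps = [row[0] for row in block[1:]]
            coefs = [row[1] for row in block[1:]]
            e, c = _normalize_contraction(l, exps, coefs)
            shells.append(Shell(ia, l, tuple(coords[ia]), tuple(e), tuple(c)))
    return shells


def ao_labels(shells: list[Shell]) -> list[tuple[int, int, tuple[int, int, int]]]:
    """Flat AO list as (atom, l, cartesian powers)."""
    out = []
    for sh in shells:
        for comp in CART_COMPONENTS[sh.l]:
            out.append((sh.atom, sh.l, comp))
    return out


def atom_ao_ranges(shells: list[Shell], n_atoms: int) -> list[tuple[int, int]]:
    """Contiguous [start, stop) AO index range per atom.

    Shells are generated atom-by-atom, so ranges are contiguous by
    construction.
    """
    counts = [0] * n_atoms
    for sh in shells:
        counts[sh.atom] += sh.n_components
    ranges, start = [], 0
    for c in counts:
        ranges.append((start, start + c))
        start += c
    return ranges
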