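"""Molecular structures: elements, geometries, charge/spin bookkeeping, XYZ I/O.

Coordinates are stored internally in bohr; the XYZ interface speaks angstrom,
as is conventional for that format.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ANGSTROM_TO_BOHR = 1.0 / 0.52917721092
BOHR_TO_ANGSTROM = 0.52917721092
HARTREE_TO_KCAL = 627.509474

_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar",
]
ATOMIC_NUMBER = {s: i for i, s in enumerate(_SYMBOLS) if i}

# Bragg-Slater radii (angstrom), used for Becke cell functions.
BRAGG_RADII = {
    "H": 0.35, "He": 0.31, "Li": 1.45, "Be": 1.05, "B": 0.85, "C": 0.70,
    "N": 0.65, "O": 0.60, "F": 0.50, "Ne": 0.38, "Na": 1.80, "Mg": 1.50,
    "Al": 1.25, "Si": 1.10, "P": 1.00, "S": 1.00, "Cl": 1.00, "Ar": 0.71,
}


class ConfigurationError(ValueError):
    """Unresolvable element, basis, or inconsistent charge/multiplicity."""


@dataclasses.dataclass(frozen=True)
class MoleculeSpec:
    """A molecule plus the subsystem annotation used by focused models.

    ``atoms`` holds ``(symbol, (x, y, z))`` with coordinates in angstrom;
    ``active_atoms`` are 0-based indices of the atoms assigned to the
    chemically interesting (high-level) region.  ``multiplicity`` is 2S+1.
    """

    atoms: tuple[tuple[str, tuple[float, float, float]], ...]
    charge: int = 0
    multiplicity: int = 1
    active_atoms: frozenset[int] = frozenset()

    def __post_init__(self):
        for sym, _ in self.atoms:
            if sym not in ATOMIC_NUMBER:
                raise ConfigurationError(f"unknown element symbol {sym!r}")
        n_elec = self.n_electrons
        if self.multiplicity < 1:
            raise ConfigurationError("multiplicity must be >= 1")
        if (n_elec - (self.multiplicity - 1)) % 2 != 0:
            raise ConfigurationError(
                f"multiplicity {self.multiplicity} inconsistent with "
                f"{n_elec} electrons"
            )
        bad = [i for i in self.active_atoms if not 0 <= i < len(self.atoms)]
        if bad:
            raise ConfigurationError(f"active atom indices out of range: {bad}")

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_lists(cls, symbols: Sequence[str], coords, charge=0,
                   multiplicity=1, active_atoms: Iterable[int] = ()) -> "MoleculeSpec":
        coords = np.asarray(coords, dtype=float).reshape(len(symbols), 3)
        atoms = tuple((s, tuple(map(float, xyz))) for s, xyz in zip(symbols, coords))
        return cls(atoms, int(charge), int(multiplicity), frozenset(active_atoms))

    def with_active(self, active_atoms: Iterable[int]) -> "MoleculeSpec":
        return dataclasses.replace(self, active_atoms=frozenset(active_atoms))

    def replaced(self, **kw) -> "MoleculeSpec":
        return dataclasses.replace(self, **kw)

    # -- properties -----------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def symbols(self) -> list[str]:
        return [s for s, _ in self.atoms]

    @property
    def charges(self) -> np.ndarray:
        """Nuclear charges Z_A."""
        return np.array([ATOMIC_NUMBER[s] for s, _ in self.atoms], dtype=float)

    @property
    def coords_angstrom(self) -> np.ndarray:
        return np.array([xyz for _, xyz in self.atoms], dtype=float)

    @property
    def coords_bohr(self) -> np.ndarray:
        return self.coords_angstrom * ANGSTROM_TO_BOHR

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    @property
    def n_alpha(self) -> int:
        return (self.n_electrons + self.multiplicity - 1) // 2

    @property
    def n_beta(self) -> int:
        return self.n_electrons - self.n_alpha

    def nuclear_repulsion(self) -> float:
        """V_nn = sum_{A<B} Z_A Z_B / |r_A - r_B| (hartree)."""
        z = self.charges
        r = self.coords_bohr
        e = 0.0
        for i in range(len(z)):
            for j in range(i + 1, len(z)):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e


def read_xyz(path, charge=0, multiplicity=1, active_atoms=()) -> MoleculeSpec:
    """Read a standard XYZ file (count line, comment, `El x y z` in angstrom)."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0].split()[0])
    symbols, coords = [], []
    for ln in lines[2:2 + n]:
        parts = ln.split()
        symbols.append(parts[0].capitalize())
        coords.append([float(x) for x in parts[1:4]])
    return MoleculeSpec.from_lists(symbols, coords, charge, multiplicity,
                                   active_atoms)


def write_xyz(mol: MoleculeSpec, path, comment: str = "") -> None:
    with open(path, "w") as f:
        f.write(f"{mol.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in mol.atoms:
            f.write(f"{sym} {x:18.10f} {y:18.10f} {z:18.10f}\n")
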