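"""Programmatically generated small test systems.

Every fixture is built from standard bond lengths and idealized angles —
no external files.  The set covers the situations the embedding schemes
must handle: noncovalent complexes, covalently cut radicals of
increasing chain length, a sulfur-containing radical pair, a carbene
with two spin states, and deliberately pathological cases (stretched H2,
parametric He dimer).
"""

from __future__ import annotations

import math

import numpy as np

from .molecule import MoleculeSpec

_CC = 1.54          # single C-C bond, angstrom
_CDC = 1.33         # C=C double bond
_CH = 1.09
_ANG = math.radians(111.6)


def water(origin=(0.0, 0.0, 0.0)) -> MoleculeSpec:
    o = np.asarray(origin)
    return MoleculeSpec.from_lists(
        ["O", "H", "H"],
        [(o + d).tolist() for d in
         [np.array([0.0, 0.0, 0.1173]),
          np.array([0.0, 0.7572, -0.4692]),
          np.array([0.0, -0.7572, -0.4692])]], 0, 1)


def water_dimer() -> MoleculeSpec:
    return MoleculeSpec.from_lists(
        ["O", "H", "H", "O", "H", "H"],
        [[-1.551007, -0.114520, 0.0],
         [-1.934259, 0.762503, 0.0],
         [-0.599677, 0.040712, 0.0],
         [1.350625, 0.111469, 0.0],
         [1.680398, -0.373741, -0.758561],
         [1.680398, -0.373741, 0.758561]], 0, 1)


def he_dimer(separation: float = 3.0) -> MoleculeSpec:
    return MoleculeSpec.from_lists(
        ["He", "He"], [[0.0, 0.0, 0.0], [0.0, 0.0, separation]], 0, 1)


def stretched_h2(distance: float = 2.5) -> MoleculeSpec:
    return MoleculeSpec.from_lists(
        ["H", "H"], [[0.0, 0.0, 0.0], [0.0, 0.0, distance]], 0, 1)


def hydroxyl_water() -> MoleculeSpec:
    """OH radical hydrogen-bonded above a water molecule (doublet)."""
    return MoleculeSpec.from_lists(
        ["O", "H", "O", "H", "H"],
        [[0.0, 0.0, 2.8], [0.0, 0.0, 3.77],
         [0.0, 0.0, 0.0], [0.0, 0.7572, -0.5692],
         [0.0, -0.7572, -0.5692]], 0, 2)


def _chain_carbons(n: int, bond_from=None):
    """Zigzag carbon skeleton in the xz-plane."""
    pos = [np.zeros(3)]
    direction = 1.0
    for i in range(1, n):
        d = _CDC if bond_from is not None and (i - 1) in bond_from else _CC
        pos.append(pos[-1] + np.array([d * math.sin(_ANG / 2), 0.0,
                                       d * math.cos(_ANG / 2) * direction]))
        direction = -direction
    return pos


def _alkyl_radical(n_carbon: int, double_first_bond: bool = False):
    """CH3-(CH2)...-CH2 radical chain; optionally CH2=CH- at the far end."""
    carbons = _chain_carbons(n_carbon,
                             bond_from={0} if double_first_bond else None)
    syms, xyz = [], []
    for i, c in enumerate(carbons):
        syms.append("C")
        xyz.append(c.tolist())
    for i, c in enumerate(carbons):
        if double_first_bond and i == 0:
            # sp2 CH2= terminus: two in-plane hydrogens
            for sgn in (1.0, -1.0):
                h = c + np.array([-_CH * math.cos(math.radians(30)),
                                  0.0, sgn * _CH * math.sin(math.radians(60))])
                syms.append("H")
                xyz.append(h.tolist())
            continue
        if double_first_bond and i == 1:
            # sp2 =CH-: one in-plane hydrogen opposite the chain bend
            syms.append("H")
            xyz.append((c + np.array([0.0, 0.0,
                                      _CH * (1 if i % 2 else -1)])).tolist())
            continue
        # sp3: two out-of-plane hydrogens
        for sgn in (1.0, -1.0):
            h = c + np.array([0.0, sgn * _CH * math.sin(math.radians(54)),
                              -_CH * math.cos(math.radians(54))
                              * (1.0 if i % 2 == 0 else -1.0)])
            syms.append("H")
            xyz.append(h.tolist())
        if i == 0 and not double_first_bond:
            # terminal methyl: one extra in-plane hydrogen
            syms.append("H")
            xyz.append((c + np.array([-_CH * math.sin(_ANG / 2), 0.0,
                                      _CH * math.cos(_ANG / 2)])).tolist())
    return MoleculeSpec.from_lists(syms, xyz, 0, 2)


def ethyl_radical() -> MoleculeSpec:
    return _alkyl_radical(2)


def propyl_radical() -> MoleculeSpec:
    return _alkyl_radical(3)


def pentyl_radical() -> MoleculeSpec:
    return _alkyl_radical(5)


def pentenyl_radical() -> MoleculeSpec:
    """Pent-4-enyl radical: CH2=CH-CH2-CH2-CH2 (radical on the last C)."""
    return _alkyl_radical(5, double_first_bond=True)


def allyl_radical() -> MoleculeSpec:
    """Prop-2-enyl radical: CH2=CH-CH2 (radical on the last C)."""
    return _alkyl_radical(3, double_first_bond=True)


def ethene() -> MoleculeSpec:
    d = _CDC
    return MoleculeSpec.from_lists(
        ["C", "C", "H", "H", "H", "H"],
        [[0.0, 0.0, 0.0], [d, 0.0, 0.0],
         [-0.55, 0.94, 0.0], [-0.55, -0.94, 0.0],
         [d + 0.55, 0.94, 0.0], [d + 0.55, -0.94, 0.0]], 0, 1)


def methyl_propanoate_radical() -> MoleculeSpec:
    """CH3-O-C(=O)-CH2 radical: small ester-backbone radical analog."""
    return MoleculeSpec.from_lists(
        ["C", "O", "C", "O", "C", "H", "H", "H", "H", "H"],
        [[-2.30, 0.20, 0.0],       # methyl C
         [-1.05, -0.45, 0.0],      # ester O
         [0.05, 0.30, 0.0],        # carbonyl C
         [0.05, 1.52, 0.0],        # carbonyl O
         [1.30, -0.45, 0.0],       # radical CH2
         [-2.35, 0.84, 0.89], [-2.35, 0.84, -0.89], [-3.12, -0.52, 0.0],
         [1.33, -1.10, 0.87], [1.33, -1.10, -0.87]], 0, 2)


def ethanethiol_oh() -> MoleculeSpec:
    """Ethanethiol with an approaching hydroxyl radical (doublet complex)."""
    return MoleculeSpec.from_lists(
        ["C", "C", "S", "H", "H", "H", "H", "H", "H", "O", "H"],
        [[-2.10, 0.0, 0.0], [-0.75, 0.70, 0.0], [0.70, -0.40, 0.0],
         [-2.15, -0.65, 0.88], [-2.15, -0.65, -0.88], [-2.95, 0.70, 0.0],
         [-0.70, 1.35, 0.88], [-0.70, 1.35, -0.88],
         [0.45, -1.25, 0.95],
         [2.40, 0.80, 0.0], [3.05, 0.10, 0.0]], 0, 2)


def imidazol_2_ylidene(triplet: bool = False) -> MoleculeSpec:
    """N-heterocyclic carbene; singlet ground state, triplet on request."""
    # planar five-membered ring: C2 (carbene), N1, N3, C4, C5
    r = 1.05
    ring = []
    for k, ang in enumerate([90.0, 162.0, 234.0, 306.0, 18.0]):
        a = math.radians(ang)
        ring.append([r * math.cos(a), r * math.sin(a), 0.0])
    c2, n1, c5, c4, n3 = ring
    def out(p, scale):
        v = np.asarray(p)
        return (v + v / np.linalg.norm(v) * scale).tolist()
    return MoleculeSpec.from_lists(
        ["C", "N", "N", "C", "C", "H", "H", "H", "H"],
        [c2, n1, n3, c4, c5,
         out(n1, 1.01), out(n3, 1.01), out(c4, 1.08), out(c5, 1.08)],
        0, 3 if triplet else 1)


FIXTURES = {
    "water": water,
    "water_dimer": water_dimer,
    "he_dimer": he_dimer,
    "stretched_h2": stretched_h2,
    "hydroxyl_water": hydroxyl_water,
    "ethyl_radical": ethyl_radical,
    "propyl_radical": propyl_radical,
    "pentyl_radical": pentyl_radical,
    "pentenyl_radical": pentenyl_radical,
    "allyl_radical": allyl_radical,
    "ethene": ethene,
    "methyl_propanoate_radical": methyl_propanoate_radical,
    "ethanethiol_oh": ethanethiol_oh,
    "imidazol_2_ylidene": imidazol_2_ylidene,
}


def get_fixture(name: str, **kwargs) -> MoleculeSpec:
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r} (have {sorted(FIXTURES)})")
    return FIXTURES[name](**kwargs)
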