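"""Pairwise dispersion correction with subsystem restriction.

The multilevel schemes assign the dispersion correction of the active
region by summing only the pairs whose atoms both belong to a chosen
atom subset; the full-molecule sum is the standard correction.  The
pairwise backend is a C6/R^6 model with Fermi damping and published
per-element parameters (Grimme's 2006 set); three-body terms are not
included.
"""

from __future__ import annotations

import numpy as np

from .molecule import MoleculeSpec

# C6 in J nm^6 mol^-1 and vdW radii in angstrom
_C6_JNM6 = {"H": 0.14, "He": 0.08, "C": 1.75, "N": 1.23, "O": 0.70,
            "F": 0.75, "S": 5.57, "Cl": 5.07}
_R0_ANG = {"H": 1.001, "He": 1.012, "C": 1.452, "N": 1.397, "O": 1.342,
           "F": 1.287, "S": 1.683, "Cl": 1.639}
_JNM6_TO_AU = 17.34527758
_DAMP_D = 20.0

#: global scaling per parent functional (1.0 when unknown)
S6_BY_FUNCTIONAL = {"pbe": 0.75, "pbe0": 0.6, "lda": 1.0, "hf": 1.0}


def dispersion_energy(molecule: MoleculeSpec, atom_subset=None,
                      s6: float = 1.0) -> float:
    """Damped pairwise dispersion over pairs fully inside ``atom_subset``.

    ``atom_subset=None`` means all atoms; an empty subset gives 0.
    Returns hartree (the value is negative or zero).
    """
    if atom_subset is None:
        atom_subset = range(molecule.n_atoms)
    idx = sorted(atom_subset)
    syms = molecule.symbols
    coords = molecule.coords_angstrom
    au = _JNM6_TO_AU
    e = 0.0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            si, sj = syms[i], syms[j]
            if si not in _C6_JNM6 or sj not in _C6_JNM6:
                raise ValueError(f"no dispersion parameters for {si}/{sj}")
            c6 = np.sqrt(_C6_JNM6[si] * _C6_JNM6[sj]) * au
            r_ang = np.linalg.norm(coords[i] - coords[j])
            r = r_ang / 0.52917721092
            rr = (_R0_ANG[si] + _R0_ANG[sj]) / 0.52917721092
            f = 1.0 / (1.0 + np.exp(-_DAMP_D * (r / rr - 1.0)))
            e -= s6 * c6 / r ** 6 * f
    return e
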