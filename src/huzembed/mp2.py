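"""Second-order Moller-Plesset correlation for plain and embedded references.

One semicanonical spin-unrestricted kernel serves every case: closed-shell
RHF (alpha = beta), UHF, restricted open-shell references through their
per-spin views, and embedded subsystems (active occupied orbitals only,
full virtual space, environment occupied excluded).  Occupied and virtual
blocks are diagonalized separately in the supplied Fock matrices, which is
exact for canonical orbitals and the standard semicanonical treatment for
restricted open-shell and embedded references.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import eigh

from .adapter import AOBasisContext


def semicanonicalize(C_block: np.ndarray, F_ao: np.ndarray):
    """Diagonalize the Fock matrix within the span of ``C_block``.

    Returns (rotated coefficients, orbital energies).
    """
    if C_block.shape[1] == 0:
        return C_block, np.zeros(0)
    f = C_block.T @ F_ao @ C_block
    e, U = eigh(0.5 * (f + f.T))
    return C_block @ U, e


def _transform(eri, Co1, Cv1, Co2, Cv2):
    """(ov|ov) block of the two-electron integrals, chemists' notation."""
    t = np.einsum("mnts,mi->ints", eri, Co1, optimize=True)
    t = np.einsum("ints,na->iats", t, Cv1, optimize=True)
    t = np.einsum("iats,tj->iajs", t, Co2, optimize=True)
    return np.einsum("iajs,sb->iajb", t, Cv2, optimize=True)


def ump2_energy(ctx: AOBasisContext, C_occ, C_vir, F_ao) -> float:
    """Semicanonical unrestricted MP2 correlation energy.

    ``C_occ``/``C_vir``/``F_ao`` are (alpha, beta) pairs of AO-basis
    occupied coefficients, virtual coefficients, and Fock matrices.
    """
    (Coa, Cob), (Cva, Cvb), (Fa, Fb) = C_occ, C_vir, F_ao
    Coa, eoa = semicanonicalize(Coa, Fa)
    Cob, eob = semicanonicalize(Cob, Fb)
    Cva, eva = semicanonicalize(Cva, Fa)
    Cvb, evb = semicanonicalize(Cvb, Fb)
    eri = ctx.eri
    e = 0.0
    # same-spin channels
    for Co, Cv, eo, ev in ((Coa, Cva, eoa, eva), (Cob, Cvb, eob, evb)):
        if Co.shape[1] == 0 or Cv.shape[1] == 0:
            continue
        g = _transform(eri, Co, Cv, Co, Cv)
        denom = (eo[:, None, None, None] - ev[None, :, None, None]
                 + eo[None, None, :, None] - ev[None, None, None, :])
        e += 0.5 * float(np.sum(g * (g - g.transpose(0, 3, 2, 1)) / denom))
    # opposite-spin channel
    if Coa.shape[1] and Cob.shape[1] and Cva.shape[1] and Cvb.shape[1]:
        g = _transform(eri, Coa, Cva, Cob, Cvb)
        denom = (eoa[:, None, None, None] - eva[None, :, None, None]
                 + eob[None, None, :, None] - evb[None, None, None, :])
        e += float(np.sum(g * g / denom))
    return e


def mp2_rhf(ctx: AOBasisContext, C: np.ndarray, n_occ: int,
            F_ao: np.ndarray) -> float:
    """Closed-shell MP2 from a restricted solution."""
    occ, vir = C[:, :n_occ], C[:, n_occ:]
    return ump2_energy(ctx, (occ, occ), (vir, vir), (F_ao, F_ao))


def mp2_ro(ctx: AOBasisContext, C: np.ndarray, n_closed: int, n_open: int,
           F_alpha: np.ndarray, F_beta: np.ndarray) -> float:
    """Semicanonical restricted open-shell MP2 from shared spatial orbitals.

    Alpha occupies closed + open shells, beta only the closed shells;
    each spin keeps its own virtual complement of the shared orbital set.
    """
    na, nb = n_closed + n_open, n_closed
    return ump2_energy(ctx, (C[:, :na], C[:, :nb]),
                       (C[:, na:], C[:, nb:]), (F_alpha, F_beta))
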