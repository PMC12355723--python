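"""Becke-partitioned molecular quadrature grid and AO evaluation.

Radial quadrature uses the Mura-Knowles log mapping; angular integration is
a Gauss-Legendre (polar) x uniform (azimuthal) product rule.  The same grid
object is attached to one AO context and reused for every exchange-
correlation evaluation on that context, so subtractive embedding schemes
cancel grid errors exactly.
"""

from __future__ import annotations

import numpy as np

from .basis import CART_COMPONENTS
from .molecule import ANGSTROM_TO_BOHR, BRAGG_RADII, MoleculeSpec

#: points per (radial, polar, azimuthal) direction for grid levels 0..3
GRID_LEVELS = {
    0: (20, 6, 12),
    1: (35, 8, 16),
    2: (50, 12, 24),
    3: (75, 16, 32),
}


def _radial_mura_knowles(n: int, alpha: float = 5.0):
    x = (np.arange(n) + 0.5) / n
    r = -alpha * np.log1p(-x ** 3)
    w = alpha * 3.0 * x ** 2 / ((1.0 - x ** 3) * n)
    return r, w * r ** 2                      # includes r^2 of the volume element


def _angular_product(n_theta: int, n_phi: int):
    x, wx = np.polynomial.legendre.leggauss(n_theta)   # cos(theta)
    phi = 2.0 * np.pi * (np.arange(n_phi) + 0.5) / n_phi
    wphi = 2.0 * np.pi / n_phi
    st = np.sqrt(1.0 - x ** 2)
    pts = np.empty((n_theta * n_phi, 3))
    w = np.empty(n_theta * n_phi)
    k = 0
    for i in range(n_theta):
        for j in range(n_phi):
            pts[k] = (st[i] * np.cos(phi[j]), st[i] * np.sin(phi[j]), x[i])
            w[k] = wx[i] * wphi
            k += 1
    return pts, w


def _becke_step(mu):
    # thrice-iterated smoothing polynomial of the fuzzy Voronoi scheme
    for _ in range(3):
        mu = 1.5 * mu - 0.5 * mu ** 3
    return 0.5 * (1.0 - mu)


class MolecularGrid:
    """Atom-centered quadrature with Becke cell weights."""

    def __init__(self, mol: MoleculeSpec, level: int = 1):
        n_rad, n_th, n_ph = GRID_LEVELS[level]
        ang_pts, ang_w = _angular_product(n_th, n_ph)
        coords = mol.coords_bohr
        radii = np.array([BRAGG_RADII[s] for s in mol.symbols]) * ANGSTROM_TO_BOHR
        all_pts, all_w, owner = [], [], []
        for ia in range(mol.n_atoms):
            r, wr = _radial_mura_knowles(n_rad)
            pts = coords[ia] + r[:, None, None] * ang_pts[None, :, :]
            w = wr[:, None] * ang_w[None, :]
            all_pts.append(pts.reshape(-1, 3))
            all_w.append(w.ravel())
            owner.append(np.full(n_rad * len(ang_w), ia))
        pts = np.concatenate(all_pts)
        w = np.concatenate(all_w)
        owner = np.concatenate(owner)
        w = w * self._becke_weights(pts, owner, coords, radii)
        keep = w > 1e-14
        self.points = pts[keep]
        self.weights = w[keep]
        self.level = level

    @staticmethod
    def _becke_weights(pts, owner, coords, radii):
        n_at = len(coords)
        if n_at == 1:
            return np.ones(len(pts))
        dist = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
        # Becke atomic-size adjustment
        chi = radii[:, None] / radii[None, :]
        u = (chi - 1.0) / (chi + 1.0)
        a = np.clip(u / (u ** 2 - 1.0), -0.5, 0.5)
        P = np.ones((len(pts), n_at))
        rij = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        for i in range(n_at):
            for j in range(n_at):
                if i == j:
                    continue
                mu = (dist[:, i] - dist[:, j]) / rij[i, j]
                mu = mu + a[i, j] * (1.0 - mu ** 2)
                P[:, i] *= _becke_step(mu)
        tot = P.sum(axis=1)
        return P[np.arange(len(pts)), owner] / np.where(tot > 0, tot, 1.0)


def ao_values(shells, points, deriv: bool = True) -> np.ndarray:
    """AO values (and cartesian gradients) on grid points.

    Returns shape (4, npts, nao) when ``deriv`` else (1, npts, nao);
    component 0 is the value, 1..3 are d/dx, d/dy, d/dz.
    """
    npts = len(points)
    nao = sum(sh.n_components for sh in shells)
    out = np.zeros((4 if deriv else 1, npts, nao))
    col = 0
    for sh in shells:
        d = points - np.array(sh.center)
        r2 = np.einsum("pd,pd->p", d, d)
        exps = np.array(sh.exponents)
        coefs = np.array(sh.coefficients)
        # distance cutoff: smallest exponent decides the reach
        rad = coefs[None, :] * np.exp(-exps[None, :] * r2[:, None])
        g = rad.sum(axis=1)                       # contracted radial value
        dg = -(rad * exps[None, :]).sum(axis=1)   # d/d(r2)
        for comp in CART_COMPONENTS[sh.l]:
            poly = d[:, 0] ** comp[0] * d[:, 1] ** comp[1] * d[:, 2] ** comp[2]
            out[0, :, col] = poly * g
            if deriv:
                for ax in range(3):
                    dpoly = 0.0
                    if comp[ax] > 0:
                        powers = list(comp)
                        powers[ax] -= 1
                        dpoly = comp[ax] * (d[:, 0] ** powers[0]
                                            * d[:, 1] ** powers[1]
                                            * d[:, 2] ** powers[2])
                    out[1 + ax, :, col] = dpoly * g + poly * 2.0 * d[:, ax] * dg
            col += 1
    return out
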