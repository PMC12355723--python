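"""McMurchie-Davidson evaluation of Gaussian one- and two-electron integrals.

Hermite expansion coefficients are vectorized over primitive pairs; shell
quartets are assembled in python loops, which is adequate for the basis
sizes this engine targets (a few dozen AOs).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import hyp1f1

from .basis import CART_COMPONENTS, Shell

TWO_PI_5_2 = 2.0 * math.pi ** 2.5


def boys(n_max: int, x: np.ndarray) -> np.ndarray:
    """Boys functions F_0..F_n for an array x, shape (n_max+1, *x.shape).

    F_n is evaluated at n_max by Kummer's function and propagated downward,
    which is stable for all x >= 0.
    """
    x = np.asarray(x, dtype=float)
    out = np.empty((n_max + 1,) + x.shape)
    out[n_max] = hyp1f1(n_max + 0.5, n_max + 1.5, -x) / (2 * n_max + 1)
    if n_max:
        ex = np.exp(-x)
        for n in range(n_max, 0, -1):
            out[n - 1] = (2.0 * x * out[n] + ex) / (2 * n - 1)
    return out


def hermite_e(la: int, lb: int, a, b, ab_dist):
    """E_t^{ij} per dimension, vectorized over primitive pairs.

    Parameters are arrays over the primitive-pair axis; ``ab_dist`` has
    shape (npp, 3).  Returns array (3, npp, la+1, lb+1, la+lb+1).
    """
    a = np.asarray(a)[:, None]
    b = np.asarray(b)[:, None]
    npp = a.shape[0]
    p = a + b
    mu = a * b / p
    nt = la + lb + 1
    E = np.zeros((3, npp, la + 1, lb + 1, nt))
    for d in range(3):
        AB = ab_dist[:, d][:, None]
        PA = -b / p * AB    # P - A
        PB = a / p * AB     # P - B
        E[d, :, 0, 0, 0] = np.exp(-mu[:, 0] * AB[:, 0] ** 2)
        # raise i then j by the standard recurrences
        for i in range(la):
            for t in range(i + 2):
                val = PA[:, 0] * E[d, :, i, 0, t]
                if t > 0:
                    val += E[d, :, i, 0, t - 1] / (2.0 * p[:, 0])
                if t + 1 <= i:
                    val += (t + 1) * E[d, :, i, 0, t + 1]
                E[d, :, i + 1, 0, t] = val
        for i in range(la + 1):
            for j in range(lb):
                for t in range(i + j + 2):
                    val = PB[:, 0] * E[d, :, i, j, t]
                    if t > 0:
                        val += E[d, :, i, j, t - 1] / (2.0 * p[:, 0])
                    if t + 1 <= i + j:
                        val += (t + 1) * E[d, :, i, j, t + 1]
                    E[d, :, i, j + 1, t] = val
    return E


class _ShellPair:
    """Precomputed primitive-pair data for one ordered shell pair."""

    __slots__ = ("sh_a", "sh_b", "p", "P", "coef", "E", "la", "lb", "herm")

    def __init__(self, sh_a: Shell, sh_b: Shell):
        self.sh_a, self.sh_b = sh_a, sh_b
        ea = np.array(sh_a.exponents)
        eb = np.array(sh_b.exponents)
        ca = np.array(sh_a.coefficients)
        cb = np.array(sh_b.coefficients)
        A = np.array(sh_a.center)
        B = np.array(sh_b.center)
        a = np.repeat(ea, len(eb))
        b = np.tile(eb, len(ea))
        self.p = a + b
        self.P = (a[:, None] * A + b[:, None] * B) / self.p[:, None]
        self.coef = np.repeat(ca, len(cb)) * np.tile(cb, len(ca))
        ab = np.broadcast_to(A - B, (len(a), 3)).copy()
        self.la, self.lb = sh_a.l, sh_b.l
        self.E = hermite_e(self.la, self.lb, a, b, ab)
        # hermite tensor per component pair:
        # herm[npp, ncomp_a, ncomp_b, t, u, v]
        comps_a = CART_COMPONENTS[self.la]
        comps_b = CART_COMPONENTS[self.lb]
        nt = self.la + self.lb + 1
        H = np.zeros((len(a), len(comps_a), len(comps_b), nt, nt, nt))
        for ia_, pa in enumerate(comps_a):
            for ib_, pb in enumerate(comps_b):
                ex = self.E[0, :, pa[0], pb[0], :pa[0] + pb[0] + 1]
                ey = self.E[1, :, pa[1], pb[1], :pa[1] + pb[1] + 1]
                ez = self.E[2, :, pa[2], pb[2], :pa[2] + pb[2] + 1]
                H[:, ia_, ib_, :ex.shape[1], :ey.shape[1], :ez.shape[1]] = (
                    ex[:, :, None, None] * ey[:, None, :, None]
                    * ez[:, None, None, :])
        self.herm = H * self.coef[:, None, None, None, None, None]


def _hermite_coulomb(n_max, alpha, R_pc):
    """R_{tuv} table, shape (*batch, n+1, n+1, n+1) at order 0.

    ``alpha`` broadcastable to batch shape, ``R_pc`` (*batch, 3).
    """
    x2 = np.einsum("...d,...d->...", R_pc, R_pc)
    F = boys(n_max, alpha * x2)
    batch = x2.shape
    # R^n_{000} = (-2 alpha)^n F_n
    Rn = {(n, 0, 0, 0): ((-2.0 * alpha) ** n) * F[n]
          for n in range(n_max + 1)}
    X, Y, Z = R_pc[..., 0], R_pc[..., 1], R_pc[..., 2]

    def get(n, t, u, v):
        if t < 0 or u < 0 or v < 0:
            return 0.0
        key = (n, t, u, v)
        if key in Rn:
            return Rn[key]
        if t > 0:
            val = X * get(n + 1, t - 1, u, v)
            if t > 1:
                val = val + (t - 1) * get(n + 1, t - 2, u, v)
        elif u > 0:
            val = Y * get(n + 1, t, u - 1, v)
            if u > 1:
                val = val + (u - 1) * get(n + 1, t, u - 2, v)
        else:
            val = Z * get(n + 1, t, u, v - 1)
            if v > 1:
                val = val + (v - 1) * get(n + 1, t, u, v - 2)
        Rn[key] = val
        return val

    out = np.zeros(batch + (n_max + 1,) * 3)
    for t in range(n_max + 1):
        for u in range(n_max + 1 - t):
            for v in range(n_max + 1 - t - u):
                out[..., t, u, v] = get(0, t, u, v)
    return out


def _shell_offsets(shells):
    offs, n = [], 0
    for sh in shells:
        offs.append(n)
        n += sh.n_components
    return offs, n


def overlap(shells_a, shells_b=None) -> np.ndarray:
    """AO overlap matrix; cross-basis when two shell lists are given."""
    sym = shells_b is None
    if sym:
        shells_b = shells_a
    offa, na = _shell_offsets(shells_a)
    offb, nb = _shell_offsets(shells_b)
    S = np.zeros((na, nb))
    for i, sa in enumerate(shells_a):
        for j, sb in enumerate(shells_b):
            if sym and j < i:
                continue
            pair = _ShellPair(sa, sb)
            pref = (math.pi / pair.p) ** 1.5
            blk = np.einsum("n,nab->ab", pref, pair.herm[:, :, :, 0, 0, 0])
            S[offa[i]:offa[i] + sa.n_components,
              offb[j]:offb[j] + sb.n_components] = blk
            if sym and j > i:
                S[offb[j]:offb[j] + sb.n_components,
                  offa[i]:offa[i] + sa.n_components] = blk.T
    return S


def kinetic(shells) -> np.ndarray:
    """Kinetic-energy matrix from 1D overlap factors."""
    offs, n = _shell_offsets(shells)
    T = np.zeros((n, n))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j < i:
                continue
            ea = np.array(sa.exponents)
            eb = np.array(sb.exponents)
            ca = np.array(sa.coefficients)
            cb = np.array(sb.coefficients)
            a = np.repeat(ea, len(eb))
            b = np.tile(eb, len(ea))
            coef = np.repeat(ca, len(cb)) * np.tile(cb, len(ca))
            A = np.array(sa.center)
            B = np.array(sb.center)
            ab = np.broadcast_to(A - B, (len(a), 3)).copy()
            # E with lb+2 to form d^2/dx^2 contributions
            E = hermite_e(sa.l, sb.l + 2, a, b, ab)
            p = a + b
            pref = np.sqrt(math.pi / p)
            # 1D overlap S[d, npp, i, j] for j up to lb+2
            S1 = E[:, :, :, :, 0] * pref[None, :, None, None]
            comps_a = CART_COMPONENTS[sa.l]
            comps_b = CART_COMPONENTS[sb.l]
            blk = np.zeros((len(comps_a), len(comps_b)))
            for ia_, pa in enumerate(comps_a):
                for ib_, pb in enumerate(comps_b):
                    s = [S1[d, :, pa[d], pb[d]] for d in range(3)]
                    t1d = []
                    for d in range(3):
                        jj = pb[d]
                        t = (b * (2 * jj + 1) * S1[d, :, pa[d], jj]
                             - 2.0 * b ** 2 * S1[d, :, pa[d], jj + 2])
                        if jj >= 2:
                            t -= 0.5 * jj * (jj - 1) * S1[d, :, pa[d], jj - 2]
                        t1d.append(t)
                    val = (t1d[0] * s[1] * s[2] + s[0] * t1d[1] * s[2]
                           + s[0] * s[1] * t1d[2])
                    blk[ia_, ib_] = np.dot(coef, val)
            T[offs[i]:offs[i] + sa.n_components,
              offs[j]:offs[j] + sb.n_components] = blk
            if j > i:
                T[offs[j]:offs[j] + sb.n_components,
                  offs[i]:offs[i] + sa.n_components] = blk.T
    return T


def charge_attraction(shells, positions, charges) -> np.ndarray:
    """Matrix of -sum_C q_C <mu| 1/|r-R_C| |nu> for point charges q_C.

    With nuclear positions/charges this is the nuclear-attraction part of
    the core Hamiltonian; with embedding point charges it is the external
    field operator of electronic-embedding models.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    charges = np.asarray(charges, dtype=float)
    offs, n = _shell_offsets(shells)
    V = np.zeros((n, n))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j < i:
                continue
            pair = _ShellPair(sa, sb)
            lt = pair.la + pair.lb
            # batch over (npp, ncharges)
            Rpc = pair.P[:, None, :] - positions[None, :, :]
            alpha = pair.p[:, None]
            R = _hermite_coulomb(lt, alpha, Rpc)
            pref = 2.0 * math.pi / pair.p
            nt = lt + 1
            herm = pair.herm[:, :, :, :nt, :nt, :nt]
            # contract charges and primitive pairs
            Rq = np.einsum("c,nctuv->ntuv", charges, R)
            blk = -np.einsum("n,nabtuv,ntuv->ab", pref, herm, Rq)
            V[offs[i]:offs[i] + sa.n_components,
              offs[j]:offs[j] + sb.n_components] = blk
            if j > i:
                V[offs[j]:offs[j] + sb.n_components,
                  offs[i]:offs[i] + sa.n_components] = blk.T
    return V



def _pair_tables(pair: "_ShellPair"):
    """Flattened Hermite tensor and signed variant for one shell pair."""
    lt = pair.la + pair.lb
    nb = lt + 1
    h = np.ascontiguousarray(pair.herm[:, :, :, :nb, :nb, :nb])
    m, ca, cb = h.shape[:3]
    flat = h.reshape(m, ca * cb, nb ** 3)
    idx = np.arange(nb)
    sgn = ((-1.0) ** (idx[:, None, None] + idx[None, :, None]
                      + idx[None, None, :])).ravel()
    return flat, flat * sgn, nb


def _quartet(bra, ket, hb_flat, hk_signed, nb, nk):
    """Contracted ERI block for one shell quartet, shape (ab, cd)."""
    lt = nb + nk - 2
    p = bra.p[:, None]
    q = ket.p[None, :]
    alpha = p * q / (p + q)
    Rpq = bra.P[:, None, :] - ket.P[None, :, :]
    R = _hermite_coulomb(lt, alpha, Rpq)
    pref = TWO_PI_5_2 / (p * q * np.sqrt(p + q))
    m, qn = R.shape[:2]
    # windowed view RS[m,q,t,u,v,x,y,z] = R[m,q,t+x,u+y,v+z]
    s = R.strides
    RS = np.lib.stride_tricks.as_strided(
        R, shape=(m, qn, nb, nb, nb, nk, nk, nk),
        strides=(s[0], s[1], s[2], s[3], s[4], s[2], s[3], s[4]))
    RS = (RS * pref[:, :, None, None, None, None, None, None]).reshape(
        m, qn, nb ** 3, nk ** 3)
    # G[m, t, cd] = sum_{q, x} RS[m,q,t,x] hk_signed[q,cd,x]
    A = RS.transpose(0, 2, 1, 3).reshape(m, nb ** 3, qn * nk ** 3)
    B = hk_signed.transpose(0, 2, 1).reshape(qn * nk ** 3, -1)
    G = A @ B                                  # (m, nb^3, cd)
    nab = hb_flat.shape[1]
    H = hb_flat.transpose(1, 0, 2).reshape(nab, m * nb ** 3)
    return H @ G.reshape(m * nb ** 3, -1)      # (ab, cd)


def electron_repulsion(shells, screen_thresh: float = 1e-14) -> np.ndarray:
    """Full (mu nu | lam sig) tensor in chemists' notation, 8-fold symmetric.

    Negligible shell quartets are skipped via Cauchy-Schwarz bounds
    sqrt((ab|ab))*sqrt((cd|cd)) < ``screen_thresh``.
    """
    offs, n = _shell_offsets(shells)
    pairs = []
    for i in range(len(shells)):
        for j in range(i, len(shells)):
            pair = _ShellPair(shells[i], shells[j])
            pairs.append((i, j, pair) + _pair_tables(pair))
    qbound = np.empty(len(pairs))
    diag_blocks = []
    for a, (i, j, pair, hf, hs, nb) in enumerate(pairs):
        blk = _quartet(pair, pair, hf, hs, nb, nb)
        diag_blocks.append(blk)
        qbound[a] = math.sqrt(max(np.abs(np.diagonal(blk)).max(), 1e-300))
    eri = np.zeros((n, n, n, n))

    def scatter(a, b, blk):
        i, j = pairs[a][0], pairs[a][1]
        k, l = pairs[b][0], pairs[b][1]
        ni, nj = shells[i].n_components, shells[j].n_components
        nk_, nl = shells[k].n_components, shells[l].n_components
        blk4 = blk.reshape(ni, nj, nk_, nl)
        sl_i = slice(offs[i], offs[i] + ni)
        sl_j = slice(offs[j], offs[j] + nj)
        sl_k = slice(offs[k], offs[k] + nk_)
        sl_l = slice(offs[l], offs[l] + nl)
        eri[sl_i, sl_j, sl_k, sl_l] = blk4
        eri[sl_j, sl_i, sl_k, sl_l] = blk4.transpose(1, 0, 2, 3)
        eri[sl_i, sl_j, sl_l, sl_k] = blk4.transpose(0, 1, 3, 2)
        eri[sl_j, sl_i, sl_l, sl_k] = blk4.transpose(1, 0, 3, 2)
        eri[sl_k, sl_l, sl_i, sl_j] = blk4.transpose(2, 3, 0, 1)
        eri[sl_l, sl_k, sl_i, sl_j] = blk4.transpose(3, 2, 0, 1)
        eri[sl_k, sl_l, sl_j, sl_i] = blk4.transpose(2, 3, 1, 0)
        eri[sl_l, sl_k, sl_j, sl_i] = blk4.transpose(3, 2, 1, 0)

    for a in range(len(pairs)):
        scatter(a, a, diag_blocks[a])
        i, j, bra, hbf, _, nb = pairs[a]
        for b in range(a + 1, len(pairs)):
            if qbound[a] * qbound[b] < screen_thresh:
                continue
            k, l, ket, _, hks, nk = pairs[b]
            scatter(a, b, _quartet(bra, ket, hbf, hks, nb, nk))
    return eri


def dipole(shells, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Electric-dipole matrices <mu|(r - origin)_d|nu>, shape (3, nao, nao)."""
    offs, n = _shell_offsets(shells)
    O = np.asarray(origin, dtype=float)
    M = np.zeros((3, n, n))
    for i, sa in enumerate(shells):
        for j, sb in enumerate(shells):
            if j < i:
                continue
            pair = _ShellPair(sa, sb)
            pref = (math.pi / pair.p) ** 1.5 * pair.coef
            comps_a = CART_COMPONENTS[sa.l]
            comps_b = CART_COMPONENTS[sb.l]
            blk = np.zeros((3, sa.n_components, sb.n_components))
            for ia_, pa in enumerate(comps_a):
                for ib_, pb in enumerate(comps_b):
                    e0 = [pair.E[d, :, pa[d], pb[d], 0] for d in range(3)]
                    for d in range(3):
                        # <x> = E^1 + (P - O) E^0 in dimension d
                        nt = pa[d] + pb[d] + 1
                        e1 = (pair.E[d, :, pa[d], pb[d], 1]
                              if nt > 1 else np.zeros_like(e0[d]))
                        md = e1 + (pair.P[:, d] - O[d]) * e0[d]
                        others = [e0[k] for k in range(3) if k != d]
                        blk[d, ia_, ib_] = np.dot(
                            pref, md * others[0] * others[1])
            M[:, offs[i]:offs[i] + sa.n_components,
              offs[j]:offs[j] + sb.n_components] = blk
            if j > i:
                M[:, offs[j]:offs[j] + sb.n_components,
                  offs[i]:offs[i] + sa.n_components] = blk.transpose(0, 2, 1)
    return M
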