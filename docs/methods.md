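# Methods

This document records the working equations and conventions
implemented in `huzembed`. All quantities are in Hartree atomic units
unless stated; density matrices are in the atomic-orbital (AO) basis
with overlap `S`.

## 1. Multilevel energy

The system AB is split into an active subsystem A and an environment
B at the level of occupied orbitals. The projection-based embedding
(PbE) energy is

```
E = E_low(AB) - E_low(A) + E_high(A~) + V_nn
    + Tr[(D~A - D_A) dE12/dD_A]
```

where `E_low(AB)` is the electronic low-level supersystem energy,
`E_low(A)` the low-level energy of the frozen subsystem-A density
`D_A`, `E_high(A~)` the high-level energy of the subsystem density
`D~A` reoptimized in the environment's presence, and the final trace
is the first-order correction for evaluating the interaction energy
`E12 = E_low(AB) - E_low(A) - E_low(B)` at the frozen rather than the
relaxed subsystem density. When the two levels coincide the relaxed
density equals the frozen one and the expression telescopes to
`E_low(AB) + V_nn` exactly; this same-level exactness is the method's
defining property and is tested to ~1e-13 hartree.

## 2. Huzinaga equation

Orthogonality between the relaxed subsystem orbitals and the frozen
environment orbitals is enforced by replacing the Fock operator `F`
of the embedded subsystem with the Huzinaga operator

```
H = F - F R_B S - S R_B F ,      R_B = C_B C_B^T
```

(symmetrized numerically). For an S-orthonormal environment orbital
`v`, `<v|H|v> = -<v|F|v>`: occupied environment levels are reflected
up in the spectrum, so the aufbau principle fills only orbitals
outside B. No adjustable level-shift parameter enters. During the
embedded SCF the eigenvectors are additionally screened by their
projection onto the environment span (threshold 0.5) to guard
against electron-count drift; convergence uses DIIS on the Huzinaga
commutator residual.

## 3. Unrestricted embedding potential

For spin-unrestricted references the frozen-environment potential is
the derivative of `E12` with respect to the per-spin subsystem
densities:

```
V_emb^s = J[D_AB - D_A] - a2 K[D^s_AB - D^s_A]
          + V_xc^s[D_AB] - V_xc^s[D_A] ,    s = alpha, beta
```

with `a2` the exact-exchange fraction of the low-level functional.
The one-electron core cancels in the difference. The embedded Fock
matrix is the high-level Fock of the current subsystem density plus
`V_emb^s`, wrapped in the Huzinaga projection. The first-order
correction is `sum_s Tr[(D~s - D^s_A) V_emb^s]`. Both potentials are
validated against central finite differences of `E12` (relative
agreement ~1e-10 at a strictly positive subsystem density).

## 4. Restricted open-shell SCF and embedding

The restricted open-shell state is represented as a one-microstate
ensemble with fractional open-shell occupation `f = 1/2` and coupling
constants `a = 1`, `b = 2` (high-spin case), giving the derived
constants `a_bar = (1-a)/(1-f) = 0`, `b_bar = (1-b)/(1-f) = -2`,
`c_bar = 1/(1-f) = 2`. Densities are carried per shell: closed `D_c`
(trace `2 n_closed`) and open `D_o = 2f C_o C_o^T` (trace `n_open` at
f = 1/2), with spin views `D_alpha = D_c/2 + D_o`,
`D_beta = D_c/2`.

The unified Fock matrix combines the closed-shell operator `F_c`, the
open-shell coupling correction `Q`, and a projection-dependent
coupling term `T`:

```
F = F_c - Q + T
Q = a_bar J[D_o] - (a_hf/2) b_bar K[D_o]
gamma = R_c S - (1/c_bar) 1 + (c_bar/2) R_o S
T = S R_c Q + Q R_c S + f (S R_o Q + Q R_o S)
    + c_bar (gamma^T dV R_o S + S R_o dV gamma),   dV = V_c - V_o
```

where `V_c = (V_xc^alpha + V_xc^beta)/2` and `V_o = V_xc^alpha` are
the shell exchange-correlation potentials evaluated on the spin
views, `R_c`/`R_o` are closed/open orbital projectors, and the result
is symmetrized. Diagonalizing one unified Fock yields shared spatial
orbitals; `<S^2> = S(S+1)` holds to machine precision by
construction. Open-shell selection can follow aufbau or overlap
tracking; a small level shift stabilizes near-degenerate
closed/open gaps.

For restricted open-shell embedding the environment is closed-shell
(`D_o^AB = D_o^A`), and the derivative of `E12` with respect to the
two shell densities shares a spin-summed core:

```
core        = J[dD] - (a2/2) K[dD] ,     dD = D_AB,tot - D_A,tot
dE12/dD_c   = core + (dV_xc^alpha + dV_xc^beta)/2
dE12/dD_o   = core + dV_xc^alpha
```

with `dV_xc^s = V_xc^s[D_AB] - V_xc^s[D_A]` on the spin views. The
embedded unified Fock uses the embedded core Hamiltonian
`h + core` and the shell potentials above; the Huzinaga projection
acts with the environment's closed projector. The first-order
correction becomes
`Tr[(D~c - D_c^A) dE12/dD_c] + Tr[(D~o - D_o^A) dE12/dD_o]`.

## 5. Orbital partitioning

**SPADE.** The occupied block is rotated by the right singular
vectors of the active-atom row block of `S^(1/2) C_occ`; orbitals are
split at the largest gap in the singular values (ties resolve to the
smaller active set; an all-equal spectrum raises an error). For a
single orbital the assignment follows majority weight.

**Boys + Mulliken.** Foster–Boys localization by Jacobi sweeps on the
dipole matrices, then an orbital is active when its Mulliken
population on the active atoms exceeds a threshold (default 0.3).

Open-shell orbitals are always assigned to the active subsystem; the
closed shells are partitioned. Partition invariants (density
additivity, integer traces, idempotency `D_c S D_c = 2 D_c`,
`D_o S D_o = D_o`) are tested on every converged partition.

## 6. Mixed ansatz combinations

*UKS-in-ROKS*: the restricted open-shell supersystem solution is
presented through its spin views (`alpha` occupies closed + open,
`beta` closed only) and the standard unrestricted embedding runs on
top.

*ROKS-in-UKS*: natural orbitals of the unrestricted total density
(eigenvectors of `S D S` in the S-metric, descending occupation) are
classified as doubly/singly/virtual by the electron counts — the
quasi-restricted orbital construction. The doubly occupied set is
partitioned, the restricted open-shell embedding machinery
reoptimizes the subsystem, and the unrestricted supersystem/subsystem
energies enter the low-level terms. A warning is emitted when the
doubly/singly occupation split is ambiguous.

## 7. Correlation and dispersion

MP2 uses one semicanonical spin-unrestricted kernel: occupied and
virtual blocks of the per-spin Fock matrices are diagonalized
separately (exact for canonical orbitals; the standard semicanonical
treatment for restricted open-shell and embedded references). In
embedded calculations the occupied space is the active occupied set,
and the virtual space is the full supersystem virtual space with
environment-occupied directions excluded; the per-spin Fock includes
the embedding potential. Dispersion is a pairwise C6/R^6 correction
with Fermi damping and per-functional `s6` scaling, assembled
subsystem-wise (low level on all pairs minus low level on active
pairs plus high level on active pairs).

## 8. Subtractive baselines

`E = E_low(AB) - E_low(model) + E_high(model)` with the model built
from the active atoms plus link hydrogens placed collinearly at
1.08 Å along each cut bond. The model inherits the parent's charge
and, when the radical lies in the active region, its multiplicity
(with a parity fallback). Electronic embedding (ONIOM-EE) surrounds
both model calculations with environment point charges derived from
intrinsic atomic orbital (IAO) populations of the low-level
supersystem density (Mulliken fallback with a warning); charges of
border environment atoms are zeroed and the residual is evenly
redistributed so the field total equals the parent-minus-model
charge. Placing the charges in both model calculations makes the
classical terms cancel in the subtraction and guarantees the exact
reduction to mechanical embedding as the charges scale to zero.

## 9. Numerical engine

Cartesian Gaussian integrals by McMurchie–Davidson recursion (s and p
shells), dipole integrals from the same Hermite expansion,
exchange-correlation on an atom-centered Becke-partitioned grid
(Mura–Knowles radial points, Gauss–Legendre × uniform angular product
rule, fixed grid levels), spherically averaged
atomic densities for the initial guess, DIIS acceleration, and
deterministic convergence thresholds (energy 1e-9, residual 1e-7).
Functionals: Hartree–Fock exchange, Slater, LDA (Slater +
Perdew–Wang), PBE, PBE0.
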