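# huzembed

Projection-based embedding for open-shell systems via the Huzinaga
equation: multilevel DFT-in-DFT and wavefunction-in-DFT simulations
with spin-unrestricted (UKS) and restricted open-shell (ROKS)
self-consistent field theory, in any combination of the two ansatz
choices, plus subtractive (ONIOM-style) baselines for comparison.

The package is a self-contained library: Gaussian integrals
(McMurchie–Davidson, s/p shells), exchange-correlation quadrature
(Slater, LDA, PBE, PBE0, plus pure Hartree–Fock), SCF with DIIS, and a
small click CLI. No external quantum-chemistry engine is required; the
integral/DFT backend sits behind a thin adapter (`AOBasisContext`) so
it can be swapped.

## Features

- **Huzinaga projection embedding** — an active subsystem is
  reoptimized at a high level inside the frozen potential of the
  low-level environment, with orthogonality enforced through the
  Huzinaga operator rather than level shifts. When both levels
  coincide the supersystem result is reproduced to numerical precision
  (tested to ~1e-13 hartree).
- **Open-shell ansatz freedom** — UKS-in-UKS, ROKS-in-ROKS, and the
  mixed UKS-in-ROKS / ROKS-in-UKS combinations (the latter via natural
  orbitals of the unrestricted total density, i.e. quasi-restricted
  orbitals).
- **Orbital partitioning** — SPADE (singular-value gap in the
  active-atom projection) or Foster–Boys localization with a Mulliken
  population threshold.
- **Correlation & dispersion** — semicanonical MP2 for plain and
  embedded references; pairwise dispersion correction with
  subsystem-resolved assembly.
- **Baselines** — vacuum model, ONIOM-ME, and ONIOM-EE with link-atom
  capping at 1.08 Å and IAO (or Mulliken) environment point charges
  with border zeroing and charge redistribution.
- **Analysis** — reaction-energy error versus active-subsystem size
  curves against full high-level references.

## Quick start (library)

```python
from huzembed import (XCFunctionalSpec, build_context, get_fixture,
                      run_uks_embedding)

mol = get_fixture("water_dimer")
ctx = build_context(mol, "sto-3g", grid_level=1)
res = run_uks_embedding(mol, ctx,
                        XCFunctionalSpec.resolve("pbe"),    # low level
                        XCFunctionalSpec.resolve("pbe0"),   # high level
                        active_atoms=[0, 1, 2])
print(res.E_pbe, res.correction, res.orthogonality_residual)
```

See `examples/` for narrative walk-throughs: embedding basics, the
four open-shell ansatz combinations, MP2-in-DFT, baseline comparison,
and the error-versus-subsystem-size curve.

## Quick start (CLI)

```yaml
# run.yaml
fixture: water_dimer          # or xyz: path/to/file.xyz
basis: sto-3g
scheme: pbe                   # pbe | oniom_me | oniom_ee | vacuum | supersystem
high: {functional: pbe0}
low: {functional: pbe}
active_atoms: [0, 1, 2]
```

```bash
huzembed run run.yaml -o result.json
huzembed curve reaction.yaml          # error-vs-subsystem table
```

Reports are JSON key-value files with every energy term in hartree;
reaction energies are reported in kcal/mol (627.509474 kcal/mol per
hartree).

## Testing

```bash
pytest -q               # unit + acceptance tests
python scripts/acceptance.py --seed 0 --out report.json
```

`tests/test_acceptance.py` holds one test per headline requirement:
same-level exactness across all ansatz combinations, restricted
open-shell oracle equivalence, the one-electron self-interaction-free
limit, embedded-orbital orthogonality, subsystem density algebra,
ONIOM identities, finite-difference validation of both embedding
potentials, and the error-versus-subsystem-size trend.

## Layout

- `src/huzembed/` — `integrals`, `basis`, `grid`, `xc`, `adapter`
  (engine); `uks`, `ro` (SCF); `partition`, `embed_uks`, `embed_roks`,
  `combine` (embedding); `mp2`, `dispersion`; `baselines` (ONIOM);
  `config`, `cli`, `fixtures` (drivers).
- `docs/methods.md` — the working equations and conventions.
- `examples/` — runnable narrative scripts.

## Limitations

Cartesian s/p Gaussian shells only (bundled minimal and
split-valence bases cover H, He, C, N, O, F, S, Cl; no d functions);
moderate fixed-size xc grids; MP2 with full integral
transformation (small systems). These bounds keep the package fully
self-contained and deterministic.
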