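"""Projection-based embedding basics on the water dimer.

We treat one water molecule of the dimer at the PBE0 level while the
other stays at PBE, then verify the method's defining property: when
both levels are the same, the embedding reproduces the supersystem
energy essentially exactly.
"""

from huzembed import (XCFunctionalSpec, build_context, get_fixture,
                      run_uks_embedding, solve_uks)

mol = get_fixture("water_dimer")
ctx = build_context(mol, "sto-3g", grid_level=1)
pbe = XCFunctionalSpec.resolve("pbe")
pbe0 = XCFunctionalSpec.resolve("pbe0")

# --- PBE0-in-PBE: the first three atoms (one water) are active --------
res = run_uks_embedding(mol, ctx, pbe, pbe0, active_atoms=[0, 1, 2])
print("PBE0-in-PBE on the water dimer")
print(f"  E_low(AB)   = {res.E_low_AB:+.8f}  (supersystem, low level)")
print(f"  E_low(A)    = {res.E_low_A:+.8f}  (subsystem, low level)")
print(f"  E_high(A~)  = {res.E_high_A:+.8f}  (reoptimized subsystem)")
print(f"  correction  = {res.correction:+.2e}  (first-order trace)")
print(f"  V_nn        = {res.V_nn:+.8f}")
print(f"  E_total     = {res.E_pbe:+.8f}")
print(f"  orthogonality residual = {res.orthogonality_residual:.1e}")

# --- same level on both sides: exact by construction ------------------
sup = solve_uks(mol, ctx, pbe)
same = run_uks_embedding(mol, ctx, pbe, pbe, [0, 1, 2], supersystem=sup)
print("\nPBE-in-PBE sanity check")
print(f"  supersystem energy  = {sup.energy:+.10f}")
print(f"  embedded energy     = {same.E_pbe:+.10f}")
print(f"  deviation           = {same.E_pbe - sup.energy:+.2e} hartree")
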