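"""Competing focused models on a covalently cut radical.

The radical end of the propyl radical is the active region; the cut
C-C bond is saturated with a link hydrogen.  We compare the
projection-based embedding against vacuum, mechanically embedded
(ONIOM-ME), and electronically embedded (ONIOM-EE) baselines.
"""

from huzembed import RunConfig, run_scheme

base = {
    "fixture": "propyl_radical",
    "basis": "sto-3g",
    "high": {"functional": "pbe0"},
    "low": {"functional": "pbe"},
    "active_atoms": [2, 7, 8],            # radical CH2 group
    "border_pairs": [[2, 1]],             # the broken C-C bond
}

print("Focused models of the propyl radical (PBE0 high, PBE low)")
for scheme in ("vacuum", "oniom_me", "oniom_ee", "pbe"):
    cfg = RunConfig.from_dict({**base, "scheme": scheme})
    _, rep = run_scheme(cfg)
    label = {"pbe": "projection-based"}.get(scheme, scheme)
    print(f"  {label:18s} E_total = {rep['E_total']:+.8f}")
print("\nThe vacuum model lacks the environment entirely; the two ONIOM")
print("variants add it subtractively (EE also polarizes the model with")
print("environment point charges); projection-based embedding keeps the")
print("full supersystem density and needs no link atoms.")
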