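"""Link-atom capping, charge fields, population analysis, and ONIOM."""

import numpy as np
import pytest

from huzembed import (MoleculeSpec, XCFunctionalSpec, build_charge_field,
                      build_context, cap_with_link_atoms, get_fixture,
                      iao_charges, mulliken_charges, oniom_ee, oniom_me,
                      solve_uks, vacuum_embedding_energy)
from huzembed.baselines import iao_or_mulliken_charges
from huzembed.molecule import ConfigurationError

HF = XCFunctionalSpec.resolve("hf")
PBE = XCFunctionalSpec.resolve("pbe")


def test_link_atom_distance_and_direction():
    mol = get_fixture("propyl_radical")
    ms = cap_with_link_atoms(mol, [2, 7, 8], [(2, 1)])
    assert len(ms.link_positions) == 1
    c = mol.coords_angstrom
    h = np.asarray(ms.link_positions[0])
    d = np.linalg.norm(h - c[2])
    assert d == pytest.approx(1.08, abs=1e-12)
    # collinear with the broken bond
    u = (h - c[2]) / d
    v = (c[1] - c[2]) / np.linalg.norm(c[1] - c[2])
    assert np.allclose(u, v, atol=1e-12)


def test_cap_no_border_pairs_is_plain_cut():
    mol = get_fixture("water_dimer")
    ms = cap_with_link_atoms(mol, [0, 1, 2])
    assert ms.model.n_atoms == 3
    assert tuple(ms.model.symbols) == ("O", "H", "H")


def test_cap_rejects_bad_border_pair():
    mol = get_fixture("water_dimer")
    with pytest.raises(ConfigurationError):
        cap_with_link_atoms(mol, [0, 1, 2], [(0, 1)])   # both active


def test_cap_multiplicity_inheritance():
    mol = get_fixture("propyl_radical")     # doublet, radical on C2
    ms = cap_with_link_atoms(mol, [2, 7, 8], [(2, 1)])
    assert ms.model.multiplicity == 2       # CH3-like radical model


def test_charge_field_redistribution():
    mol = get_fixture("propyl_radical")
    ms = cap_with_link_atoms(mol, [2, 7, 8], [(2, 1)])
    q = 0.1 * np.arange(mol.n_atoms)
    field = build_charge_field(ms, q)
    # border environment atom zeroed; total equals parent - model charge
    assert field.total == pytest.approx(0.0, abs=1e-12)
    k = field.atom_indices.index(1)
    assert field.charges[k] == 0.0


def test_population_sums_and_signs():
    mol = MoleculeSpec.from_lists(["H", "F"], [[0, 0, 0], [0, 0, 0.92]], 0, 1)
    ctx = build_context(mol, "6-31g")
    r = solve_uks(mol, ctx, HF)
    for scheme in ("iao", "mulliken"):
        q = iao_or_mulliken_charges(r.densities.total, ctx, scheme)
        assert q.sum() == pytest.approx(0.0, abs=1e-8)
        assert q[0] > 0 and q[1] < 0        # H positive, F negative


def test_h2_charges_zero_by_symmetry():
    mol = MoleculeSpec.from_lists(["H", "H"], [[0, 0, 0], [0, 0, 0.74]], 0, 1)
    ctx = build_context(mol, "sto-3g")
    r = solve_uks(mol, ctx, HF)
    assert np.allclose(iao_charges(r.densities.total, ctx), 0.0, atol=1e-10)
    assert np.allclose(mulliken_charges(r.densities.total, ctx), 0.0,
                       atol=1e-10)


def test_vacuum_model_noncovalent():
    mol = get_fixture("water_dimer")
    ms = cap_with_link_atoms(mol, [0, 1, 2])
    e = vacuum_embedding_energy(ms, HF, "sto-3g")
    # equals a direct calculation of the monomer at the dimer geometry
    frag = MoleculeSpec.from_lists(
        [mol.symbols[i] for i in range(3)],
        mol.coords_angstrom[:3].tolist(), 0, 1)
    ctx = build_context(frag, "sto-3g")
    direct = solve_uks(frag, ctx, HF).energy
    assert e == pytest.approx(direct, abs=1e-10)


def test_oniom_me_three_term_assembly():
    mol = get_fixture("water_dimer")
    ms = cap_with_link_atoms(mol, [0, 1, 2])
    e = oniom_me(ms, PBE, HF, "sto-3g", grid_level=1)
    parts = []
    for m, xc in ((ms.parent, HF), (ms.model, HF), (ms.model, PBE)):
        ctx = build_context(m, "sto-3g", grid_level=1)
        parts.append(solve_uks(m, ctx, xc).energy)
    assert e == pytest.approx(parts[0] - parts[1] + parts[2], abs=1e-12)


def test_oniom_ee_total_charge_consistency():
    mol = get_fixture("hydroxyl_water")
    ms = cap_with_link_atoms(mol, [0, 1])
    ctx = build_context(mol, "sto-3g")
    r = solve_uks(mol, ctx, HF)
    q = mulliken_charges(r.densities.total, ctx)
    field = build_charge_field(ms, q)
    assert field.total == pytest.approx(0.0, abs=1e-10)
    assert len(field.charges) == 3          # the three water atoms
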