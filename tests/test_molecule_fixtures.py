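"""Molecule bookkeeping and programmatic fixture sanity."""

import numpy as np
import pytest

from huzembed import ConfigurationError, FIXTURES, MoleculeSpec, get_fixture
from huzembed.molecule import read_xyz


def test_electron_counting():
    m = MoleculeSpec.from_lists(["O", "H"], [[0, 0, 0], [0, 0, 0.97]], 0, 2)
    assert m.n_electrons == 9
    assert (m.n_alpha, m.n_beta) == (5, 4)


def test_charge_shifts_counts():
    m = MoleculeSpec.from_lists(
        ["O", "H", "H"], [[0, 0, 0], [0, 0, 1], [0, 1, 0]], 1, 2)
    assert m.n_electrons == 9


def test_parity_mismatch_rejected():
    with pytest.raises(ConfigurationError):
        MoleculeSpec.from_lists(["H", "H"], [[0, 0, 0], [0, 0, 0.7]], 0, 2)


def test_xyz_round_trip(tmp_path):
    p = tmp_path / "oh.xyz"
    p.write_text("2\ncomment\nO 0.0 0.0 0.0\nH 0.0 0.0 0.97\n")
    m = read_xyz(str(p), 0, 2)
    assert tuple(m.symbols) == ("O", "H")
    assert m.coords_angstrom[1, 2] == pytest.approx(0.97)


@pytest.mark.parametrize("name", sorted(FIXTURES))
def test_fixture_sanity(name):
    mol = get_fixture(name)
    # parity-consistent multiplicity
    assert (mol.n_electrons - (mol.multiplicity - 1)) % 2 == 0
    # no atom collisions: minimum separation above 0.9 A
    c = mol.coords_angstrom
    if mol.n_atoms > 1:
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        assert d.min() > 0.9


def test_fixture_catalog_covers_radicals():
    for name in ("pentenyl_radical", "propyl_radical",
                 "methyl_propanoate_radical", "ethanethiol_oh"):
        assert get_fixture(name).multiplicity == 2
    assert get_fixture("imidazol_2_ylidene").multiplicity == 1
    assert get_fixture("imidazol_2_ylidene", triplet=True).multiplicity == 3


def test_parametric_fixtures():
    assert get_fixture("he_dimer", separation=4.0).coords_angstrom[1, 2] == 4.0
    with pytest.raises(KeyError):
        get_fixture("nope")
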