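"""Coordinate I/O: identity reads, round trips, altloc and hydrogen policy."""

from __future__ import annotations

import numpy as np
import pytest

from npfsite.structure_io import (
    Atom,
    Residue,
    Selection,
    StructureModel,
    read_structure,
    resolve_selection,
    write_minipdb,
)
from npfsite.synthetic import HelixSpec, make_ideal_helix

from conftest import make_residue

TWO_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134   2.000  1.00 10.00           N
ATOM      2  CA  ALA A   1      12.560   6.351   2.111  1.00 10.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  CA AALA A   1       1.000   2.000   3.000  0.60 10.00           C
ATOM      2  CA BALA A   1       4.000   5.000   6.000  0.40 10.00           C
ATOM      3  CB  ALA A   1       2.500   2.000   3.000  1.00 10.00           C
END
"""

HYDROGEN_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C
ATOM      2  HA  ALA A   1       1.000   0.000   0.000  1.00 10.00           H
ATOM      3  CA  ALA B   2       6.000   0.000   0.000  1.00 10.00           C
ATOM      4  HA  ALA B   2       4.500   0.000   0.000  1.00 10.00           H
END
"""


def test_identity_read_of_handwritten_file(tmp_path):
    path = tmp_path / "two.pdb"
    path.write_text(TWO_ATOM_PDB)
    model = read_structure(path, format="pdb")
    res = model.residue("A", 1)
    assert [a.name for a in res.atoms] == ["N", "CA"]
    assert res.atom("N").coords == (11.104, 6.134, 2.0)
    assert res.atom("CA").coords == (12.560, 6.351, 2.111)


def test_altloc_keeps_highest_occupancy_conformer(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    model = read_structure(path, format="pdb")
    res = model.residue("A", 1)
    ca = [a for a in res.atoms if a.name == "CA"]
    assert len(ca) == 1, "exactly one conformer per (residue, atom name)"
    assert ca[0].coords == (1.0, 2.0, 3.0)  # occupancy 0.60 conformer A


def test_helix_roundtrip_atom_by_atom(tmp_path):
    helix = make_ideal_helix(HelixSpec(n_residues=18))
    path = tmp_path / "helix.pdb"
    write_minipdb(helix, path)
    back = read_structure(path, format="pdb")
    orig = [(r.key, r.name, a.name, a.coords) for r in helix.iter_residues() for a in r.atoms]
    got = [(r.key, r.name, a.name, a.coords) for r in back.iter_residues() for a in r.atoms]
    assert len(orig) == len(got)
    for (k1, n1, a1, c1), (k2, n2, a2, c2) in zip(orig, got):
        assert (k1, n1, a1) == (k2, n2, a2)
        assert np.allclose(c1, c2, atol=1e-3)


def test_random_model_roundtrip(tmp_path):
    rng = np.random.default_rng(5)
    residues = [
        make_residue("A", i + 1, "GLY", {"CA": ("C", tuple(rng.uniform(0, 30, 3).tolist()))})
        for i in range(50)
    ]
    model = StructureModel("rand", {"A": residues})
    path = tmp_path / "rand.pdb"
    write_minipdb(model, path)
    back = read_structure(path)
    orig = np.array([r.atoms[0].coords for r in model.chains["A"]])
    got = np.array([r.atoms[0].coords for r in back.chains["A"]])
    assert np.allclose(orig, got, atol=1e-3)


def test_hydrogen_stripping_is_default_and_idempotent(tmp_path):
    path = tmp_path / "h.pdb"
    path.write_text(HYDROGEN_PDB)
    with_h = read_structure(path, keep_hydrogens=True)
    without = read_structure(path, keep_hydrogens=False)
    assert with_h.n_atoms == 4 and without.n_atoms == 2
    stripped = with_h.strip_hydrogens()
    assert stripped.n_atoms == 2
    again = stripped.strip_hydrogens()
    heavy = [a.coords for r in stripped.iter_residues() for a in r.atoms]
    heavy2 = [a.coords for r in again.iter_residues() for a in r.atoms]
    assert heavy == heavy2


def test_model_index_out_of_range(tmp_path):
    path = tmp_path / "two.pdb"
    path.write_text(TWO_ATOM_PDB)
    with pytest.raises(IndexError):
        read_structure(path, model_index=3)


def test_unparseable_file_raises_named_error(tmp_path):
    path = tmp_path / "bad.cif"
    path.write_text("this is not a structure file\n")
    with pytest.raises((ValueError, FileNotFoundError)):
        read_structure(path, format="mmcif")


def test_write_requires_atoms():
    with pytest.raises(ValueError):
        StructureModel("empty", {})


def test_selection_order_and_side_chains():
    res1 = make_residue(
        "A", 1, "LEU",
        {"N": ("N", (0, 0, 0)), "CA": ("C", (1, 0, 0)), "C": ("C", (2, 0, 0)),
         "O": ("O", (3, 0, 0)), "CB": ("C", (1, 1, 0)), "CD1": ("C", (1, 2, 0))},
    )
    res2 = make_residue("A", 2, "GLY", {"N": ("N", (4, 0, 0)), "CA": ("C", (5, 0, 0)),
                                        "C": ("C", (6, 0, 0)), "O": ("O", (7, 0, 0))})
    res3 = make_residue("A", 3, "ALA", {"CA": ("C", (8, 0, 0)), "CB": ("C", (8, 1, 0))})
    model = StructureModel("sel", {"A": [res3, res1, res2]})  # deliberately unordered

    whole = resolve_selection(Selection(model, "A"))
    order = [(r.number, a.name) for r, a in whole]
    assert order == sorted(order), "deterministic (residue, atom-name) order"
    assert len(whole) == 12

    gly_side = resolve_selection(Selection(model, "A", residue_range=(2, 2), side_chain_only=True))
    assert gly_side == []

    leu_side = resolve_selection(Selection(model, "A", residue_range=(1, 1), side_chain_only=True))
    assert {a.name for _, a in leu_side} == {"CB", "CD1"}, "CB counts as side chain"


def test_range_selection_on_gamma_like_helix():
    helix = make_ideal_helix(HelixSpec(n_residues=20, chain_id="G", start_number=55))
    sel = resolve_selection(Selection(helix, "G", residue_range=(60, 64)))
    assert sorted({r.number for r, _ in sel}) == [60, 61, 62, 63, 64]


def test_duplicate_residue_keys_rejected():
    res = make_residue("A", 1, "ALA", {"CA": ("C", (0, 0, 0))})
    with pytest.raises(ValueError):
        StructureModel("dup", {"A": [res, res]})
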