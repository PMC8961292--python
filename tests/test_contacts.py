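"""Contact engine: strict cutoff, oracle equivalence, typology rules, persistence."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npfsite.contacts import (
    contact_persistence,
    interchain_contacts,
    intrachain_interactions,
    min_distance,
)
from npfsite.structure_io import Selection, StructureModel

from conftest import make_residue, random_two_chain_model


def _pair_model(distance: float) -> StructureModel:
    a = make_residue("A", 1, "ALA", {"CA": ("C", (0.0, 0.0, 0.0))})
    b = make_residue("B", 1, "ALA", {"CA": ("C", (distance, 0.0, 0.0))})
    return StructureModel("pair", {"A": [a], "B": [b]})


def _sel(model, chain):
    return Selection(model, chain)


def test_pair_below_cutoff_is_one_record():
    model = _pair_model(3.90)
    table = interchain_contacts(model, _sel(model, "A"), _sel(model, "B"))
    assert len(table) == 1
    assert table.records[0].distance == pytest.approx(3.90)


def test_exact_cutoff_is_excluded():
    model = _pair_model(4.00)
    table = interchain_contacts(model, _sel(model, "A"), _sel(model, "B"))
    assert len(table) == 0, "strictly-less-than cutoff"


def brute_force_pairs(model: StructureModel, cutoff: float) -> set:
    out = set()
    for ra in model.chains["A"]:
        for aa in ra.atoms:
            for rb in model.chains["B"]:
                for ab in rb.atoms:
                    d = float(np.linalg.norm(np.array(aa.coords) - np.array(ab.coords)))
                    if d < cutoff:
                        out.add((ra.key, aa.name, rb.key, ab.name))
    return out


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_engine_equals_exhaustive_double_loop(seed):
    model = random_two_chain_model(seed, n_atoms=300)
    table = interchain_contacts(model, _sel(model, "A"), _sel(model, "B"))
    got = {(r.residue_a, r.atom_a, r.residue_b, r.atom_b) for r in table.records}
    assert got == brute_force_pairs(model, 4.0)


def test_symmetry_of_residue_pair_summary():
    model = random_two_chain_model(7, n_atoms=200)
    ab = interchain_contacts(model, _sel(model, "A"), _sel(model, "B"))
    ba = interchain_contacts(model, _sel(model, "B"), _sel(model, "A"))
    assert ab.residue_pair_summary() == ba.residue_pair_summary()


@settings(deadline=None, max_examples=20, derandomize=True)
@given(
    seed=st.integers(0, 50),
    cut_lo=st.floats(1.0, 5.0),
    cut_hi=st.floats(5.0, 9.0),
)
def test_record_count_monotone_in_cutoff(seed, cut_lo, cut_hi):
    model = random_two_chain_model(seed, n_atoms=80)
    lo = interchain_contacts(model, _sel(model, "A"), _sel(model, "B"), cutoff=cut_lo)
    hi = interchain_contacts(model, _sel(model, "A"), _sel(model, "B"), cutoff=cut_hi)
    assert len(lo) <= len(hi)


def test_overlapping_selections_rejected():
    model = _pair_model(3.0)
    with pytest.raises(ValueError, match="overlap"):
        interchain_contacts(model, _sel(model, "A"), _sel(model, "A"))


def test_hydrogen_inflation():
    """Keeping hydrogens can only add contact records, never remove them."""
    a = make_residue("A", 1, "ALA", {"CA": ("C", (0, 0, 0)), "HA": ("H", (1.0, 0, 0))})
    b = make_residue("B", 1, "ALA", {"CA": ("C", (4.5, 0, 0)), "HA": ("H", (3.4, 0, 0))})
    with_h = StructureModel("h", {"A": [a], "B": [b]})
    heavy = with_h.strip_hydrogens()
    n_h = len(interchain_contacts(with_h, _sel(with_h, "A"), _sel(with_h, "B")))
    n_heavy = len(interchain_contacts(heavy, _sel(heavy, "A"), _sel(heavy, "B")))
    assert n_h >= n_heavy
    assert n_h == 3 and n_heavy == 0  # HA-HA 2.4, CA-HA 3.4, HA-CA 3.5 vs CA-CA 4.5


def test_min_distance_commutative_and_exact():
    model = _pair_model(7.25)
    d1 = min_distance(_sel(model, "A"), _sel(model, "B"))
    d2 = min_distance(_sel(model, "B"), _sel(model, "A"))
    assert d1 == d2 == pytest.approx(7.25)
    assert min_distance(_sel(model, "A"), _sel(model, "A")) == 0.0


def test_min_distance_empty_selection_errors():
    model = _pair_model(3.0)
    empty = Selection(model, "A", residue_range=(99, 99))
    with pytest.raises(ValueError):
        min_distance(empty, _sel(model, "B"))


# ---------------------------------------------------------------------------
# typology


def test_ionic_rule():
    lys = make_residue("A", 1, "LYS", {"CA": ("C", (0, 0, 0)), "NZ": ("N", (1, 0, 0))})
    asp = make_residue("A", 10, "ASP", {"CA": ("C", (5, 0, 0)), "OD1": ("O", (4.0, 0, 0))})
    model = StructureModel("ionic", {"A": [lys, asp]})
    recs = intrachain_interactions(model, "A")
    assert any(r.type == "ionic" and r.distance == pytest.approx(3.0) for r in recs)


def test_hydrophobic_rule():
    l1 = make_residue("A", 1, "LEU", {"CA": ("C", (0, 0, 0)), "CD1": ("C", (1, 0, 0))})
    l2 = make_residue("A", 5, "LEU", {"CA": ("C", (7, 0, 0)), "CD1": ("C", (5.5, 0, 0))})
    model = StructureModel("phob", {"A": [l1, l2]})
    recs = intrachain_interactions(model, "A")
    assert [r.type for r in recs] == ["hydrophobic"]
    assert recs[0].distance == pytest.approx(4.5)


def test_isolated_residue_yields_nothing():
    solo = make_residue("A", 1, "TRP", {"CA": ("C", (0, 0, 0))})
    model = StructureModel("solo", {"A": [solo]})
    assert intrachain_interactions(model, "A") == []


def test_unknown_residue_skipped_with_warning():
    odd = make_residue("A", 1, "XYZ", {"CA": ("C", (0, 0, 0))})
    leu = make_residue("A", 5, "LEU", {"CA": ("C", (2, 0, 0)), "CB": ("C", (3, 0, 0))})
    model = StructureModel("odd", {"A": [odd, leu]})
    with pytest.warns(UserWarning, match="XYZ"):
        recs = intrachain_interactions(model, "A")
    assert recs == []


# ---------------------------------------------------------------------------
# persistence


def test_persistence_identity_keeps_all_contacts(toy_complex):
    model, truth = toy_complex
    records = contact_persistence(truth, model)
    assert records and not any(r.broken for r in records)


def test_persistence_translated_chain_breaks_all(toy_complex):
    model, truth = toy_complex
    moved = model.transformed(np.eye(3), np.array([50.0, 0.0, 0.0]))
    # translate only the probe chain: rebuild with original pocket + moved probe
    hybrid = StructureModel(
        "hybrid",
        {"A": model.chains["A"], "B": model.chains["B"], "P": moved.chains["P"]},
    )
    records = contact_persistence(truth, hybrid)
    assert records and all(r.broken for r in records)


def test_persistence_missing_residue_lists_keys(toy_complex):
    model, truth = toy_complex
    smaller = StructureModel("small", {"A": model.chains["A"], "B": model.chains["B"]})
    with pytest.raises(KeyError, match="unmapped"):
        contact_persistence(truth, smaller)
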