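"""Shared fixtures: all structural inputs are generated, none downloaded."""

from __future__ import annotations

import numpy as np
import pytest

from npfsite.structure_io import Atom, Residue, StructureModel


def make_residue(
    chain: str,
    number: int,
    name: str,
    atoms: dict[str, tuple[str, tuple[float, float, float]]],
) -> Residue:
    """Residue from {atom_name: (element, xyz)}."""
    return Residue(
        chain_id=chain,
        number=number,
        name=name,
        atoms=tuple(
            Atom(name=an, element=el, coords=xyz) for an, (el, xyz) in atoms.items()
        ),
    )


def random_two_chain_model(seed: int, n_atoms: int = 300, box: float = 12.0) -> StructureModel:
    """Random point cloud split into two chains of single-atom 'residues'."""
    rng = np.random.default_rng(seed)
    xyz = rng.uniform(0.0, box, size=(n_atoms, 3))
    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    for i, p in enumerate(xyz):
        chain = "A" if i < n_atoms // 2 else "B"
        chains[chain].append(
            make_residue(chain, i + 1, "ALA", {"CA": ("C", tuple(p.tolist()))})
        )
    return StructureModel("random", chains)


@pytest.fixture(scope="session")
def toy_complex():
    from npfsite.synthetic import ToyComplexSpec, make_toy_pocket_complex

    return make_toy_pocket_complex(ToyComplexSpec(seed=11))


@pytest.fixture(scope="session")
def reference():
    from npfsite.cggn import build_reference

    return build_reference()


@pytest.fixture(scope="session")
def rhodopsin_numbered():
    from npfsite.gpcr_numbering import assign_bw, rhodopsin_reference

    return assign_bw(rhodopsin_reference().sequence)
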