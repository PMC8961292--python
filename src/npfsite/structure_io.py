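"""Macromolecular coordinate I/O and atom selection.

Structures are held in a small, explicit object model (:class:`Atom`,
:class:`Residue`, :class:`StructureModel`) keyed by *author* residue numbers,
since every residue cited in the accompanying analyses (Cys316 of rhodopsin,
Trp54 of the Eps15 EH2 domain, ...) is an author number.  Parsing and PDB
writing are delegated to :mod:`gemmi`; this module only normalizes the result:
one model per :class:`StructureModel`, optional hydrogen stripping, and
single-conformer alternate-location resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Selection",
    "read_structure",
    "write_minipdb",
    "resolve_selection",
]

#: Backbone atom names excluded by side-chain-only selections (CB is a side-chain atom).
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})

_WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

_STANDARD_AA = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL "
    "MSE".split()
)


@dataclass(frozen=True)
class Atom:
    """A single atom with Cartesian coordinates in Å."""

    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def __post_init__(self) -> None:
        if not all(math.isfinite(c) for c in self.coords):
            raise ValueError(f"non-finite coordinates for atom {self.name!r}: {self.coords}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class Residue:
    """One residue identified by (chain_id, author number, insertion code)."""

    chain_id: str
    number: int
    name: str
    atoms: tuple[Atom, ...]
    icode: str = ""

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.key} has no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.name}{self.number} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    @property
    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if not a.is_hydrogen)

    @property
    def side_chain_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.name not in BACKBONE_ATOMS)


@dataclass
class StructureModel:
    """One model of a macromolecular structure: ordered residues grouped by chain."""

    identifier: str
    chains: dict[str, list[Residue]]
    model_index: int = 0

    def __post_init__(self) -> None:
        if not self.chains:
            raise ValueError(f"structure {self.identifier!r} has no chains")
        seen: set[tuple[str, int, str]] = set()
        for chain_id, residues in self.chains.items():
            for res in residues:
                if res.chain_id != chain_id:
                    raise ValueError(f"residue {res.key} filed under chain {chain_id!r}")
                if res.key in seen:
                    raise ValueError(f"duplicate residue key {res.key}")
                seen.add(res.key)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"no chain {chain_id!r} in {self.identifier!r}; have {sorted(self.chains)}"
            ) from None

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for res in self.chain(chain_id):
            if res.number == number and res.icode == icode:
                return res
        raise KeyError(f"no residue ({chain_id!r}, {number}, {icode!r}) in {self.identifier!r}")

    def iter_residues(self) -> Iterable[Residue]:
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def strip_hydrogens(self) -> "StructureModel":
        """Return a copy without H/D atoms (idempotent; heavy atoms untouched)."""
        chains: dict[str, list[Residue]] = {}
        for chain_id, residues in self.chains.items():
            kept = []
            for res in residues:
                heavy = res.heavy_atoms
                if heavy:
                    kept.append(replace(res, atoms=heavy))
            if kept:
                chains[chain_id] = kept
        return StructureModel(self.identifier, chains, self.model_index)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        chains: dict[str, list[Residue]] = {}
        for chain_id, residues in self.chains.items():
            out = []
            for res in residues:
                atoms = tuple(
                    replace(a, coords=tuple((R @ a.xyz + t).tolist())) for a in res.atoms
                )
                out.append(replace(res, atoms=atoms))
            chains[chain_id] = out
        return StructureModel(self.identifier, chains, self.model_index)


@dataclass(frozen=True)
class Selection:
    """A deterministic atom selection: chain, optional residue range / atom names.

    ``resolve_selection`` orders atoms by (chain, residue number, insertion code,
    atom name), so an identical selection always yields the identical list.
    """

    model: StructureModel
    chain_id: str
    residue_range: tuple[int, int] | None = None
    residue_numbers: frozenset[int] | None = None
    atom_names: frozenset[str] | None = None
    side_chain_only: bool = False


def resolve_selection(sel: Selection) -> list[tuple[Residue, Atom]]:
    """Resolve a :class:`Selection` to an ordered list of (residue, atom) pairs."""
    residues = sel.model.chain(sel.chain_id)
    pairs: list[tuple[Residue, Atom]] = []
    for res in sorted(residues, key=lambda r: (r.number, r.icode)):
        if sel.residue_range is not None:
            lo, hi = sel.residue_range
            if not (lo <= res.number <= hi):
                continue
        if sel.residue_numbers is not None and res.number not in sel.residue_numbers:
            continue
        atoms = res.side_chain_atoms if sel.side_chain_only else res.atoms
        for atom in sorted(atoms, key=lambda a: a.name):
            if sel.atom_names is not None and atom.name not in sel.atom_names:
                continue
            pairs.append((res, atom))
    return pairs


# ---------------------------------------------------------------------------
# reading


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties go to the alphabetically first altloc ('A' first)
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def read_structure(
    path: str | Path,
    format: str = "auto",
    model_index: int = 0,
    keep_hydrogens: bool = False,
    keep_hetero: bool = False,
    keep_waters: bool = False,
) -> StructureModel:
    """Read one model from a PDB or mmCIF file.

    Parameters
    ----------
    path
        Coordinate file.
    format
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension/content).
    model_index
        0-based index into a multi-model (e.g. NMR) file.
    keep_hydrogens
        When false (default), all H/D atoms are dropped.  Solution NMR entries
        deposit hydrogens while most crystal structures do not, which inflates
        contact counts; the default makes heavy-atom-only the baseline and
        hydrogen inclusion an explicit choice.
    keep_hetero, keep_waters
        Non-polymer heteroatoms and waters are excluded by default.

    For alternate-location duplicates only the highest-occupancy conformer is
    retained (ties resolved toward altloc 'A').
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format.lower()
    try:
        if fmt == "pdb":
            st = gemmi.read_pdb(str(path))
        elif fmt in ("mmcif", "cif"):
            st = gemmi.make_structure_from_block(gemmi.cif.read(str(path)).sole_block())
        elif fmt == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}; use 'pdb', 'mmcif' or 'auto'")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ValueError(f"cannot parse {path.name}: {exc}") from exc

    if not 0 <= model_index < len(st):
        raise IndexError(
            f"model_index {model_index} out of range: {path.name} has {len(st)} model(s)"
        )
    st.setup_entities()
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.name in _WATER_NAMES:
                if not keep_waters:
                    continue
            elif res.name not in _STANDARD_AA and res.het_flag == "H" and not keep_hetero:
                # amino acids always count as polymer, however short the chain
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            atoms: list[Atom] = []
            for name in by_name:
                ga = _pick_altloc(by_name[name])
                atom = Atom(
                    name=name,
                    element=ga.element.name,
                    coords=(ga.pos.x, ga.pos.y, ga.pos.z),
                    occupancy=ga.occ,
                    altloc=ga.altloc or "",
                )
                if atom.is_hydrogen and not keep_hydrogens:
                    continue
                atoms.append(atom)
            if atoms:
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        number=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        name=res.name,
                        atoms=tuple(atoms),
                    )
                )
        if residues:
            chains[chain.name] = residues
    if not chains:
        raise ValueError(f"{path.name}: no residues left after filtering")
    return StructureModel(identifier=st.name or path.stem, chains=chains, model_index=model_index)


# ---------------------------------------------------------------------------
# writing


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.identifier
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.number, res.icode or " ")
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.altloc = "\0"
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_minipdb(model: StructureModel, path: str | Path) -> None:
    """Write fixed-column PDB ATOM records; round-trips coordinates to 3 decimals."""
    if model.n_atoms == 0:
        raise ValueError("refusing to write a structure with no atoms")
    st = _to_gemmi(model)
    try:
        st.write_minimal_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write PDB to {path}: {exc}") from exc


def coords_of(pairs: Sequence[tuple[Residue, Atom]]) -> np.ndarray:
    """Coordinate array (n, 3) of a resolved selection."""
    if not pairs:
        return np.empty((0, 3), dtype=float)
    return np.array([a.xyz for _, a in pairs], dtype=float)
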