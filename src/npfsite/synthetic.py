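"""Deterministic synthetic fixtures: ideal helices, toy pocket–peptide
complexes with ground-truth contact lists, and Gγ-like sequences with known
CGγN labels.

Every generator is a pure function of its spec (seed included), so fixtures
are bit-reproducible and no coordinate or sequence files need to be shipped.
The helix builder uses textbook α-helix parameters (1.5 Å rise and 100°
twist per residue, 2.3 Å Cα radius); backbone and Cβ atoms are placed by an
idealized cylindrical geometry — good enough for contact counting and axis
fitting, with no claim of stereochemical realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .cggn import CGammaNLabel, build_reference
from .contacts import ContactTable, interchain_contacts
from .structure_io import Atom, Residue, Selection, StructureModel

__all__ = [
    "HelixSpec",
    "ToyComplexSpec",
    "GammaSeqSpec",
    "make_ideal_helix",
    "make_toy_pocket_complex",
    "make_gamma_like_sequence",
    "make_rotated_pocket_pair",
    "AA_3LETTER",
]

AA_3LETTER = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

# idealized cylindrical placement of backbone atoms relative to the Cα lattice:
# (radius Å, phase offset °, axial offset Å) per atom name
_BACKBONE_CYLINDER = {
    "N": (1.56, -28.0, -0.90),
    "C": (1.65, 26.0, 0.75),
    "O": (2.00, 24.0, 2.00),
}
_CB_LENGTH = 1.53  # Cβ placed radially outward from the axis through Cα


@dataclass(frozen=True)
class HelixSpec:
    """Geometry and sequence of one ideal α helix."""

    n_residues: int
    rise: float = 1.5
    twist: float = 100.0
    ca_radius: float = 2.3
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase0: float = 0.0
    sequence: str | None = None  # default poly-Ala
    chain_id: str = "A"
    start_number: int = 1

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be ≥ 1")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise ValueError(
                f"sequence length {len(self.sequence)} != n_residues {self.n_residues}"
            )


def _axis_frame(axis: tuple[float, float, float]) -> np.ndarray:
    """Rotation matrix carrying the z axis onto *axis*."""
    u = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("axis must be a non-zero vector")
    u = u / norm
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, u)
    s, c = np.linalg.norm(v), float(np.dot(z, u))
    if s < 1e-12:
        return np.eye(3) if c > 0 else Rotation.from_rotvec([math.pi, 0, 0]).as_matrix()
    return Rotation.from_rotvec(v / s * math.atan2(s, c)).as_matrix()


def make_ideal_helix(spec: HelixSpec) -> StructureModel:
    """Build an ideal α helix as a :class:`StructureModel`.

    Cα atoms sit on a cylinder of ``ca_radius`` about the axis with angular
    step ``twist`` and axial step ``rise``; N, C, O and Cβ are placed by the
    idealized cylindrical offsets above (Cβ radially outward, so its azimuth
    equals the Cα azimuth).  Glycine gets no Cβ.
    """
    seq = spec.sequence or "A" * spec.n_residues
    R = _axis_frame(spec.axis)
    origin = np.asarray(spec.origin, dtype=float)

    def place(radius: float, phase_deg: float, z: float) -> tuple[float, float, float]:
        phi = math.radians(phase_deg)
        local = np.array([radius * math.cos(phi), radius * math.sin(phi), z])
        return tuple((R @ local + origin).tolist())

    residues = []
    for i, aa in enumerate(seq.upper()):
        phase = spec.phase0 + i * spec.twist
        z = i * spec.rise
        atoms = [Atom(name="CA", element="C", coords=place(spec.ca_radius, phase, z))]
        for name, (radius, dphi, dz) in _BACKBONE_CYLINDER.items():
            atoms.append(
                Atom(name=name, element=name[0], coords=place(radius, phase + dphi, z + dz))
            )
        if aa != "G":
            atoms.append(
                Atom(
                    name="CB",
                    element="C",
                    coords=place(spec.ca_radius + _CB_LENGTH, phase, z),
                )
            )
        residues.append(
            Residue(
                chain_id=spec.chain_id,
                number=spec.start_number + i,
                name=AA_3LETTER.get(aa, "UNK"),
                atoms=tuple(atoms),
            )
        )
    return StructureModel(
        identifier=f"ideal-helix-{spec.chain_id}",
        chains={spec.chain_id: residues},
    )


# ---------------------------------------------------------------------------
# toy pocket + probe complex


@dataclass(frozen=True)
class ToyComplexSpec:
    """Two crossing pocket helices plus a placed tripeptide probe.

    ``distance_targets`` are ((pocket_chain, pocket_residue), probe_residue,
    distance) triples measured between Cα atoms; each probe residue is placed
    so its target holds exactly, pointing outward from the pocket center.
    """

    seed: int = 0
    probe_sequence: str = "NPF"
    crossing_angle: float = 60.0
    helix_length: int = 12
    distance_targets: tuple[tuple[tuple[str, int], int, float], ...] = (
        (("A", 6), 1, 3.8),
        (("B", 6), 2, 3.6),
        (("A", 7), 3, 3.5),
    )

    def __post_init__(self) -> None:
        for (_, _), probe_res, d in self.distance_targets:
            if not 1 <= probe_res <= len(self.probe_sequence):
                raise ValueError(f"probe residue {probe_res} outside probe sequence")
            if d <= 0:
                raise ValueError("distance targets must be positive")


# local template of a probe residue around its Cα (rough amino-acid footprint)
_PROBE_TEMPLATE = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.15, 1.05, 0.0]),
    "CB": np.array([-0.50, 1.40, 0.0]),
}


def make_toy_pocket_complex(spec: ToyComplexSpec) -> tuple[StructureModel, ContactTable]:
    """Build the pocket–probe complex and its ground-truth <4 Å contact table.

    The truth table is enumerated by exhaustive pairwise search at build time,
    independent of the fast contact engine, so the pair (model, truth) can
    serve as an oracle for it.
    """
    rng = np.random.default_rng(spec.seed)
    theta = math.radians(spec.crossing_angle)
    helix_a = HelixSpec(n_residues=spec.helix_length, chain_id="A",
                        phase0=float(rng.uniform(0, 360)))
    helix_b = HelixSpec(
        n_residues=spec.helix_length,
        chain_id="B",
        axis=(math.sin(theta), 0.0, math.cos(theta)),
        origin=(9.0, 0.0, 0.0),
        phase0=float(rng.uniform(0, 360)),
    )
    model_a = make_ideal_helix(helix_a)
    model_b = make_ideal_helix(helix_b)
    pocket_center = np.array([4.5, 0.0, spec.helix_length * helix_a.rise / 2.0])

    pocket = StructureModel(
        identifier=f"toy-pocket-{spec.seed}",
        chains={"A": model_a.chains["A"], "B": model_b.chains["B"]},
    )

    targets_by_probe: dict[int, tuple[tuple[str, int], float]] = {}
    for pocket_res, probe_res, d in spec.distance_targets:
        if probe_res in targets_by_probe:
            raise ValueError(f"multiple distance targets for probe residue {probe_res}")
        targets_by_probe[probe_res] = (pocket_res, d)

    probe_residues = []
    for i, aa in enumerate(spec.probe_sequence.upper(), start=1):
        if i in targets_by_probe:
            (chain_id, resnum), d = targets_by_probe[i]
            anchor = pocket.residue(chain_id, resnum).atom("CA").xyz
            direction = anchor - pocket_center
            direction = direction / np.linalg.norm(direction)
            ca = anchor + d * direction
        else:
            # park unconstrained probe residues well away from the pocket
            ca = pocket_center + np.array([0.0, 25.0 + 5.0 * i, 0.0])
        frame = Rotation.random(random_state=int(rng.integers(2**31))).as_matrix()
        atoms = [Atom(name="CA", element="C", coords=tuple(ca.tolist()))]
        for name, local in _PROBE_TEMPLATE.items():
            if name == "CB" and aa == "G":
                continue
            atoms.append(
                Atom(name=name, element=name[0], coords=tuple((ca + frame @ local).tolist()))
            )
        probe_residues.append(
            Residue(chain_id="P", number=i, name=AA_3LETTER.get(aa, "UNK"), atoms=tuple(atoms))
        )

    model = StructureModel(
        identifier=f"toy-complex-{spec.seed}",
        chains={"A": model_a.chains["A"], "B": model_b.chains["B"], "P": probe_residues},
    )

    # verify the placement honoured every target
    for pocket_res, probe_res, d in spec.distance_targets:
        got = float(
            np.linalg.norm(
                model.residue("P", probe_res).atom("CA").xyz
                - model.residue(*pocket_res).atom("CA").xyz
            )
        )
        if abs(got - d) > 0.05:
            raise RuntimeError(
                f"unsatisfiable distance target {pocket_res}↔probe {probe_res}: "
                f"wanted {d}, placed at {got:.3f}"
            )

    truth = _exhaustive_contacts(model, cutoff=4.0)
    return model, truth


def _exhaustive_contacts(model: StructureModel, cutoff: float) -> ContactTable:
    """Ground-truth pocket↔probe contacts by brute-force double loop."""
    from .contacts import ContactRecord

    records = []
    probe = model.chains["P"]
    pocket = [r for cid in ("A", "B") for r in model.chains[cid]]
    for res_a in pocket:
        for atom_a in res_a.atoms:
            for res_b in probe:
                for atom_b in res_b.atoms:
                    d = float(np.linalg.norm(atom_a.xyz - atom_b.xyz))
                    if 0.0 < d < cutoff:
                        records.append(
                            ContactRecord(
                                residue_a=res_a.key,
                                residue_b=res_b.key,
                                resname_a=res_a.name,
                                resname_b=res_b.name,
                                atom_a=atom_a.name,
                                atom_b=atom_b.name,
                                distance=d,
                                involves_hydrogen=atom_a.is_hydrogen or atom_b.is_hydrogen,
                            )
                        )
    records.sort(key=lambda r: (r.residue_a, r.atom_a, r.residue_b, r.atom_b))
    return ContactTable(cutoff=cutoff, records=records)


# ---------------------------------------------------------------------------
# synthetic GPCR / EH2-like pair with a known helix-8 rotation


def make_rotated_pocket_pair(
    rotation_deg: float, seed: int = 0
) -> tuple[StructureModel, StructureModel]:
    """Build a (GPCR-like, EH2-like) structure pair with a known H8 rotation.

    The GPCR-like model (chain ``R``, rhodopsin author numbering) carries a
    TM1/ICL1-like helix over residues 52–69 and an H8-like helix over
    310–323.  The EH2-like model (chain ``E``) holds exact copies of the four
    αB correspondence residues (33/37/40/41 on the TM1 partners, so the αB
    superposition is the identity) and copies of the four αC partners rotated
    about the H8 axis by *rotation_deg*, clockwise as viewed from the distal
    end of H8.  Recovering *rotation_deg* from this pair closes the loop
    between the generator and the rotation estimator.
    """
    from .site_mapping import clockwise_rotation_matrix, fit_helix_axis

    rng = np.random.default_rng(seed)
    tm1 = make_ideal_helix(
        HelixSpec(n_residues=18, chain_id="R", start_number=52,
                  phase0=float(rng.uniform(0, 360)))
    )
    h8 = make_ideal_helix(
        HelixSpec(
            n_residues=14,
            chain_id="R",
            start_number=310,
            axis=(1.0, 0.0, 0.0),
            origin=(6.0, 8.0, 0.0),
            phase0=float(rng.uniform(0, 360)),
        )
    )
    gpcr = StructureModel(
        identifier=f"synthetic-gpcr-{seed}",
        chains={"R": tm1.chains["R"] + h8.chains["R"]},
    )

    h8_ca = np.array([gpcr.residue("R", n).atom("CA").xyz for n in range(310, 324)])
    axis = fit_helix_axis(h8_ca)
    R = clockwise_rotation_matrix(axis.direction, rotation_deg)

    def copy_as(author: int, new_number: int, rotate: bool) -> Residue:
        res = gpcr.residue("R", author)
        atoms = []
        for atom in res.atoms:
            xyz = atom.xyz
            if rotate:
                xyz = axis.centroid + R @ (xyz - axis.centroid)
            atoms.append(replace(atom, coords=tuple(xyz.tolist())))
        return replace(res, chain_id="E", number=new_number, atoms=tuple(atoms))

    # αB pairs 33↔12.50(68), 37↔1.59(64), 40↔1.56(61), 41↔1.55(60): plain copies
    # αC pairs 47↔8.57(320), 50↔8.50(313), 54↔8.54(317), 55↔8.49(312): rotated copies
    eh2_residues = [
        copy_as(68, 33, rotate=False),
        copy_as(64, 37, rotate=False),
        copy_as(61, 40, rotate=False),
        copy_as(60, 41, rotate=False),
        copy_as(320, 47, rotate=True),
        copy_as(313, 50, rotate=True),
        copy_as(317, 54, rotate=True),
        copy_as(312, 55, rotate=True),
    ]
    eh2_residues.sort(key=lambda r: r.number)
    eh2 = StructureModel(
        identifier=f"synthetic-eh2-{seed}", chains={"E": eh2_residues}
    )
    return gpcr, eh2


# ---------------------------------------------------------------------------
# Gγ-like sequences with ground-truth labels


@dataclass(frozen=True)
class GammaSeqSpec:
    """A mutated/indel-bearing variant of a reference Gγ isoform.

    Point mutations and indels are drawn deterministically from *seed* and
    kept outside the protected windows (NPF ± 2 and the CAAX cysteine), so
    the ground-truth CGγN labels of the retained positions follow from the
    base isoform by position bookkeeping.
    """

    seed: int = 0
    base_isoform: str | None = None  # default: seed-chosen among the 12
    n_mutations: int = 5
    n_indels: int = 0
    protect_window: int = 2  # residues around NPF kept untouched


def make_gamma_like_sequence(
    spec: GammaSeqSpec,
) -> tuple[str, dict[int, CGammaNLabel]]:
    """Generate a Gγ-like sequence and its ground-truth position→label map.

    Deterministic in the spec (seed included).  The result always contains
    exactly one NPF trimer, with ground-truth labels h2.8–h2.10, and the
    terminal CAAX cysteine keeps ground truth h2.17.
    """
    rng = np.random.default_rng(spec.seed)
    reference = build_reference()
    names = [iso.name for iso in reference.isoforms]
    base_name = spec.base_isoform or names[int(rng.integers(len(names)))]
    iso = reference.isoform(base_name)
    seq = list(iso.sequence)
    labels: dict[int, CGammaNLabel] = dict(iso.numbering)

    npf_start = iso.sequence.rfind("NPF") + 1
    protected = set(
        range(npf_start - spec.protect_window, npf_start + 3 + spec.protect_window)
    )
    protected.add(len(seq) - 3)  # CAAX cysteine (1-based: len-3)
    alphabet = "ACDEFGHIKLMNPQRSTVWY"

    def has_single_npf(s: Sequence[str]) -> bool:
        return "".join(s).count("NPF") == 1

    placed = 0
    attempts = 0
    while placed < spec.n_mutations and attempts < 200:
        attempts += 1
        pos = int(rng.integers(1, len(seq) + 1))
        if pos in protected:
            continue
        new = alphabet[int(rng.integers(len(alphabet)))]
        old = seq[pos - 1]
        if new == old:
            continue
        seq[pos - 1] = new
        if not has_single_npf(seq):
            seq[pos - 1] = old
            continue
        placed += 1

    applied = 0
    attempts = 0
    while applied < spec.n_indels and attempts < 200:
        attempts += 1
        pos = int(rng.integers(2, len(seq)))
        if pos in protected or (pos + 1) in protected:
            continue
        if rng.random() < 0.5:  # insertion before pos
            aa = alphabet[int(rng.integers(len(alphabet)))]
            candidate = seq[: pos - 1] + [aa] + seq[pos - 1 :]
            if not has_single_npf(candidate):
                continue
            seq = candidate
            labels = {(p if p < pos else p + 1): lab for p, lab in labels.items()}
            protected = {p if p < pos else p + 1 for p in protected}
        else:  # deletion of pos
            candidate = seq[: pos - 1] + seq[pos:]
            if not has_single_npf(candidate):
                continue
            seq = candidate
            labels = {
                (p if p < pos else p - 1): lab for p, lab in labels.items() if p != pos
            }
            protected = {p if p < pos else p - 1 for p in protected}
        applied += 1

    sequence = "".join(seq)
    assert sequence.count("NPF") == 1
    npf = sequence.find("NPF") + 1
    for off, idx in enumerate((8, 9, 10)):
        assert labels[npf + off] == CGammaNLabel(segment="h2", index=idx)
    return sequence, labels
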