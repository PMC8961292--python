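"""EH2 ↔ GPCR structural correspondence and NPF-site plausibility.

This module carries the geometric core of the analysis: least-squares rigid
superposition (Kabsch), α-helix axis fitting with per-residue azimuthal
phases, the helix-8 rotation angle that maps the receptor's TM1/ICL1/H8
pocket onto the NPF-binding αB/αC cleft of an EH domain, a chemical-class
conservation profile over a user-supplied alignment, the aggregate NPF-site
plausibility score, and the TM7–H8 "lock" classifier (the Tyr7.53–Phe8.50
contact that marks an inactive class A receptor).

Angle convention: helix phases and rotation angles are reported in
[0°, 360°), positive clockwise as viewed from the distal (C-terminal) end of
helix 8 — the viewpoint in which the pocket rotation is ~115°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .contacts import _min_atom_distance
from .gpcr_numbering import BWLabel, NumberedGPCR, rhodopsin_reference
from .structure_io import Residue, StructureModel

__all__ = [
    "CHEMICAL_CLASSES",
    "chemical_class",
    "CorrespondencePair",
    "CorrespondenceMap",
    "default_correspondence",
    "HelixAxis",
    "SitePositionProfile",
    "SiteProfile",
    "kabsch_superpose",
    "SuperpositionResult",
    "fit_helix_axis",
    "clockwise_rotation_matrix",
    "h8_rotation_angle",
    "npf_site_score",
    "conservation_profile",
    "tm7_h8_lock",
]


# ---------------------------------------------------------------------------
# chemical classes (exact partition of the 20 amino acids)

CHEMICAL_CLASSES: dict[str, frozenset[str]] = {
    "polar": frozenset("GSTYC"),
    "neutral": frozenset("QN"),
    "basic": frozenset("KRH"),
    "acidic": frozenset("DE"),
    "hydrophobic": frozenset("AVLIPWFM"),
}


def chemical_class(aa: str) -> str:
    """Class of a one-letter amino acid under the five-way partition."""
    aa = aa.upper()
    for name, members in CHEMICAL_CLASSES.items():
        if aa in members:
            return name
    raise KeyError(f"not a standard amino acid: {aa!r}")


# expected chemistry of the eight pocket positions: a hydrophobic floor with
# two charged/polar rims.  Tyr is additionally accepted at the hydrophobic
# positions: its ring packs like a hydrophobic side chain there (rhodopsin
# itself presents Tyr at 1.55), even though the five-way partition files Tyr
# as polar.
_HYDROPHOBIC_POSITIONS = frozenset(
    BWLabel.parse(t) for t in ("1.55", "1.56", "12.50", "8.50", "8.54", "8.57")
)
_POLAR_OR_CHARGED_POSITIONS = frozenset(BWLabel.parse(t) for t in ("1.59", "8.49"))


def _position_matches(label: BWLabel, aa: str) -> bool:
    cls = chemical_class(aa)
    if label in _HYDROPHOBIC_POSITIONS:
        return cls == "hydrophobic" or aa.upper() == "Y"
    if label in _POLAR_OR_CHARGED_POSITIONS:
        return cls != "hydrophobic"
    raise KeyError(f"{label} is not an NPF-site position")


# ---------------------------------------------------------------------------
# correspondence map


@dataclass(frozen=True)
class CorrespondencePair:
    """One EH2-residue ↔ GPCR-position equivalence."""

    eh2_residue: int
    gpcr_label: BWLabel
    helix: str  # "aB" (vs TM1/ICL1) or "aC" (vs H8)
    verified: bool = True


@dataclass(frozen=True)
class CorrespondenceMap:
    """Ordered EH2↔GPCR pairs anchoring superposition and rotation."""

    pairs: tuple[CorrespondencePair, ...]

    def __post_init__(self) -> None:
        eh2 = [p.eh2_residue for p in self.pairs]
        gpcr = [p.gpcr_label for p in self.pairs]
        if len(set(eh2)) != len(eh2) or len(set(gpcr)) != len(gpcr):
            raise ValueError("correspondence must be one-to-one on both sides")

    def side(self, helix: str, verified_only: bool = True) -> tuple[CorrespondencePair, ...]:
        return tuple(
            p for p in self.pairs if p.helix == helix and (p.verified or not verified_only)
        )


def default_correspondence(include_sle: bool = False,
                           sle_residues: tuple[int, int] | None = None) -> CorrespondenceMap:
    """The canonical eight EH2↔GPCR pairs.

    αB↔TM1/ICL1: Gly33↔12.50, Lys37↔1.59, Leu40↔1.56, Leu41↔1.55;
    αC↔H8: Val47↔8.57, Leu50↔8.50, Trp54↔8.54, Glu55↔8.49.

    The αC "SLE" ↔ H8 "NKQ" triple shares only its glutamate (Glu55↔8.49)
    with the canonical set; the serine/leucine partner numbers are not
    text-anchored, so they are included only on request, as unverified pairs
    with caller-supplied residue numbers.
    """
    pairs = [
        CorrespondencePair(33, BWLabel(12, 50), "aB"),
        CorrespondencePair(37, BWLabel(1, 59), "aB"),
        CorrespondencePair(40, BWLabel(1, 56), "aB"),
        CorrespondencePair(41, BWLabel(1, 55), "aB"),
        CorrespondencePair(47, BWLabel(8, 57), "aC"),
        CorrespondencePair(50, BWLabel(8, 50), "aC"),
        CorrespondencePair(54, BWLabel(8, 54), "aC"),
        CorrespondencePair(55, BWLabel(8, 49), "aC"),
    ]
    if include_sle:
        if sle_residues is None:
            raise ValueError("include_sle requires sle_residues=(ser_number, leu_number)")
        s, l = sle_residues
        pairs += [
            CorrespondencePair(s, BWLabel(8, 47), "aC", verified=False),
            CorrespondencePair(l, BWLabel(8, 48), "aC", verified=False),
        ]
    return CorrespondenceMap(pairs=tuple(pairs))


# ---------------------------------------------------------------------------
# rigid superposition


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3), proper (det = +1)
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> SuperpositionResult:
    """Least-squares optimal rigid transform mapping *mobile* onto *target*.

    Both inputs are paired (n, 3) coordinate arrays with n ≥ 3 and
    non-collinear points; the returned rotation is proper (no reflection) and
    the RMSD is evaluated after applying the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape != target.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(f"need paired (n, 3) arrays, got {mobile.shape} vs {target.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 paired points, got {n}")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    a, b = mobile - cm, target - ct
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ValueError("points are collinear; rotation is underdetermined")
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    t = ct - R @ cm
    rmsd = float(np.sqrt(np.mean(np.sum((a @ R.T - b) ** 2, axis=1))))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


# ---------------------------------------------------------------------------
# helix axis and phases


@dataclass(frozen=True)
class HelixAxis:
    """A fitted helix axis with per-residue azimuthal phases.

    ``direction`` is a unit vector pointing N→C; ``phases`` are azimuths of
    the fitted positions about the axis in [0°, 360°), clockwise-positive as
    viewed from the distal (C-terminal) end.
    """

    direction: np.ndarray
    centroid: np.ndarray
    phases: tuple[float, ...]

    def phase_of(self, point: np.ndarray) -> float:
        return _azimuth(point, self.centroid, self.direction)


def _reference_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # deterministic in-plane frame: global x (fallback y) projected ⊥ axis
    for ref in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])):
        e1 = ref - np.dot(ref, direction) * direction
        norm = np.linalg.norm(e1)
        if norm > 1e-6:
            e1 /= norm
            return e1, np.cross(direction, e1)
    raise AssertionError("unreachable: axis cannot be parallel to both x and y")


def _azimuth(point: np.ndarray, origin: np.ndarray, direction: np.ndarray) -> float:
    e1, e2 = _reference_frame(direction)
    v = point - origin
    v = v - np.dot(v, direction) * direction
    # right-handed angle about `direction`, negated: clockwise from the distal end
    angle = -math.degrees(math.atan2(np.dot(v, e2), np.dot(v, e1)))
    return angle % 360.0


def clockwise_rotation_matrix(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation by *angle_deg* about *direction*, clockwise viewed from the distal end."""
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    return Rotation.from_rotvec(-math.radians(angle_deg) * direction).as_matrix()


def fit_helix_axis(ca_coords: np.ndarray, window: int = 4) -> HelixAxis:
    """Fit a helix axis through sliding-window centroids of consecutive Cα.

    Requires at least 6 consecutive Cα positions.  Window centroids of an
    α helix fall close to the axis; a least-squares 3-D line (principal
    component of the centroids) gives the direction, oriented N→C.
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3:
        raise ValueError(f"expected (n, 3) Cα coordinates, got {ca.shape}")
    if ca.shape[0] < 6:
        raise ValueError(f"helix-axis fit needs ≥ 6 residues, got {ca.shape[0]}")
    centroids = np.array(
        [ca[i : i + window].mean(axis=0) for i in range(len(ca) - window + 1)]
    )
    mean = centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centroids - mean)
    direction = vt[0]
    if np.dot(direction, centroids[-1] - centroids[0]) < 0:
        direction = -direction
    direction = direction / np.linalg.norm(direction)
    axis = HelixAxis(direction=direction, centroid=mean, phases=())
    phases = tuple(axis.phase_of(p) for p in ca)
    return HelixAxis(direction=direction, centroid=mean, phases=phases)


def _side_chain_reference_atom(res: Residue) -> np.ndarray:
    """Cβ position (Cα for glycine) — the side-chain facing proxy used for phases."""
    if res.has_atom("CB"):
        return res.atom("CB").xyz
    return res.atom("CA").xyz


def _circular_mean_deg(angles: Sequence[float]) -> float:
    z = np.mean(np.exp(1j * np.radians(np.asarray(angles))))
    return float(np.degrees(np.angle(z))) % 360.0


def h8_rotation_angle(
    gpcr: StructureModel,
    eh2: StructureModel,
    cmap: CorrespondenceMap | None = None,
    gpcr_chain: str | None = None,
    eh2_chain: str | None = None,
    bw_to_author: Mapping[BWLabel, int] | None = None,
    h8_span: tuple[int, int] = (47, 57),
) -> float:
    """Rotation of helix 8 that maps its pocket residues onto the EH2 αC helix.

    After superposing the EH2 αB Cα onto the receptor TM1/ICL1 Cα through the
    αB-side correspondence pairs, the helix-8 axis is fitted from the
    receptor's H8 Cα trace and the azimuthal offsets between the H8-side
    positions (8.49, 8.50, 8.54, 8.57; Cβ proxy, Cα for Gly) and their αC
    partners are averaged on the circle.  Returned in degrees in [0°, 360°),
    clockwise-positive viewed from the distal end of H8.

    ``bw_to_author`` maps BW labels to author residue numbers in *gpcr*
    (default: the rhodopsin reference numbering, where both coincide).
    """
    cmap = cmap or default_correspondence()
    gpcr_chain = gpcr_chain or next(iter(gpcr.chains))
    eh2_chain = eh2_chain or next(iter(eh2.chains))
    ref = rhodopsin_reference()
    to_author = dict(bw_to_author) if bw_to_author else {
        lab: pos for pos, lab in ref.numbering.items()
    }

    def gpcr_res(label: BWLabel) -> Residue:
        if label not in to_author:
            raise KeyError(f"no author residue number for GPCR position {label}")
        return gpcr.residue(gpcr_chain, to_author[label])

    missing = []
    for pair in cmap.pairs:
        try:
            gpcr_res(pair.gpcr_label)
        except KeyError:
            missing.append(str(pair.gpcr_label))
        try:
            eh2.residue(eh2_chain, pair.eh2_residue)
        except KeyError:
            missing.append(f"EH2 {pair.eh2_residue}")
    if missing:
        raise KeyError(f"correspondence residues missing from structures: {missing}")

    ab = cmap.side("aB")
    mobile = np.array([eh2.residue(eh2_chain, p.eh2_residue).atom("CA").xyz for p in ab])
    target = np.array([gpcr_res(p.gpcr_label).atom("CA").xyz for p in ab])
    sup = kabsch_superpose(mobile, target)
    eh2_sup = eh2.transformed(sup.rotation, sup.translation)

    h8_ca = np.array(
        [
            gpcr_res(BWLabel(8, i)).atom("CA").xyz
            for i in range(h8_span[0], h8_span[1] + 1)
            if BWLabel(8, i) in to_author
        ]
    )
    axis = fit_helix_axis(h8_ca)

    deltas = []
    for pair in cmap.side("aC"):
        phase_h8 = axis.phase_of(_side_chain_reference_atom(gpcr_res(pair.gpcr_label)))
        phase_ac = axis.phase_of(
            _side_chain_reference_atom(eh2_sup.residue(eh2_chain, pair.eh2_residue))
        )
        # clockwise rotation of H8 by delta carries its phase onto the αC partner
        # (phases are clockwise-measured, so the offset is αC minus H8)
        deltas.append(phase_ac - phase_h8)
    return _circular_mean_deg(deltas)


# ---------------------------------------------------------------------------
# site profile and score


@dataclass(frozen=True)
class SitePositionProfile:
    label: BWLabel
    frequencies: Mapping[str, float]  # residue -> frequency (gaps excluded)
    dominant_class: str
    matches_expected: bool


@dataclass(frozen=True)
class SiteProfile:
    positions: tuple[SitePositionProfile, ...]
    score: float  # fraction of evaluated positions matching the expected chemistry


def npf_site_score(residues: Mapping[BWLabel | str, str]) -> SiteProfile:
    """Score a residue set at the eight pocket positions against expected chemistry.

    Expected: hydrophobic side chains at 1.55, 1.56, 12.50, 8.50, 8.54 and
    8.57 (Tyr accepted); charged-or-polar (anything non-hydrophobic) at 1.59
    and 8.49.  The score is the fraction of *present* positions that match;
    absent positions are excluded from the denominator.
    """
    entries = []
    for label, aa in residues.items():
        if isinstance(label, str):
            label = BWLabel.parse(label)
        entries.append(
            SitePositionProfile(
                label=label,
                frequencies={aa.upper(): 1.0},
                dominant_class=chemical_class(aa),
                matches_expected=_position_matches(label, aa),
            )
        )
    if not entries:
        raise ValueError("no NPF-site positions supplied")
    entries.sort(key=lambda e: e.label)
    score = sum(e.matches_expected for e in entries) / len(entries)
    return SiteProfile(positions=tuple(entries), score=score)


def conservation_profile(
    msa: Sequence[str],
    positions: Sequence[BWLabel | str] | None = None,
    reference_row: int = 0,
    numbered_reference: NumberedGPCR | None = None,
) -> SiteProfile:
    """Per-position residue frequencies and chemistry over a class A alignment.

    The reference row (default the first) is numbered through
    :func:`npfsite.gpcr_numbering.assign_bw` — or supplied pre-numbered — and
    its labels are pushed onto the alignment columns; frequencies at each
    requested position are counted over all rows with gaps excluded.
    Positions absent from every row are reported with empty frequencies.
    """
    from .gpcr_numbering import NPF_SITE_POSITIONS, assign_bw

    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("alignment rows have unequal lengths")
    wanted = [
        BWLabel.parse(p) if isinstance(p, str) else p
        for p in (positions if positions is not None else NPF_SITE_POSITIONS)
    ]
    ref_row = msa[reference_row]
    ungapped = ref_row.replace("-", "").replace(".", "")
    numbered = numbered_reference or assign_bw(ungapped)

    # alignment column of each reference residue position
    col_of: dict[int, int] = {}
    pos = 0
    for col, char in enumerate(ref_row):
        if char not in "-.":
            pos += 1
            col_of[pos] = col

    entries = []
    for label in wanted:
        try:
            col = col_of[numbered.position_of(label)]
        except KeyError:
            entries.append(
                SitePositionProfile(
                    label=label, frequencies={}, dominant_class="", matches_expected=False
                )
            )
            continue
        counts: dict[str, int] = {}
        for row in msa:
            aa = row[col].upper()
            if aa in "-.":
                continue
            counts[aa] = counts.get(aa, 0) + 1
        total = sum(counts.values())
        freqs = {aa: c / total for aa, c in sorted(counts.items())}
        class_weight: dict[str, float] = {}
        for aa, f in freqs.items():
            cls = chemical_class(aa)
            class_weight[cls] = class_weight.get(cls, 0.0) + f
        dominant = max(sorted(class_weight), key=lambda c: class_weight[c])
        dominant_aa = max(sorted(freqs), key=lambda a: freqs[a])
        entries.append(
            SitePositionProfile(
                label=label,
                frequencies=freqs,
                dominant_class=dominant,
                matches_expected=_position_matches(label, dominant_aa),
            )
        )
    evaluated = [e for e in entries if e.frequencies]
    score = (
        sum(e.matches_expected for e in evaluated) / len(evaluated) if evaluated else 0.0
    )
    return SiteProfile(positions=tuple(entries), score=score)


# ---------------------------------------------------------------------------
# TM7–H8 lock


def tm7_h8_lock(
    model: StructureModel,
    chain: str | None = None,
    bw_to_author: Mapping[BWLabel, int] | None = None,
    cutoff: float = 4.0,
) -> dict:
    """Classify the Tyr7.53–Phe8.50 side-chain contact (inactive-state hallmark).

    ``locked`` is true when the minimum side-chain heavy-atom distance between
    the residues at 7.53 and 8.50 is strictly below *cutoff* Å.
    """
    chain = chain or next(iter(model.chains))
    ref = rhodopsin_reference()
    to_author = dict(bw_to_author) if bw_to_author else {
        lab: pos for pos, lab in ref.numbering.items()
    }
    resolved = {}
    for text in ("7.53", "8.50"):
        label = BWLabel.parse(text)
        try:
            resolved[text] = model.residue(chain, to_author[label])
        except KeyError as exc:
            raise KeyError(f"residue at {label} not present in chain {chain!r}") from exc
    sc_a = [a for a in resolved["7.53"].side_chain_atoms if not a.is_hydrogen]
    sc_b = [a for a in resolved["8.50"].side_chain_atoms if not a.is_hydrogen]
    if not sc_a or not sc_b:
        raise ValueError("7.53/8.50 residues lack side-chain atoms")
    d = _min_atom_distance(sc_a, sc_b)
    assert d is not None
    return {"locked": d < cutoff, "distance": round(d, 3)}
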