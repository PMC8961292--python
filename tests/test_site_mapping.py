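"""Geometry and scoring: Kabsch, helix axes, H8 rotation, site score, profiles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from npfsite.gpcr_numbering import BWLabel
from npfsite.site_mapping import (
    CHEMICAL_CLASSES,
    chemical_class,
    clockwise_rotation_matrix,
    conservation_profile,
    default_correspondence,
    fit_helix_axis,
    h8_rotation_angle,
    kabsch_superpose,
    npf_site_score,
    tm7_h8_lock,
)
from npfsite.structure_io import StructureModel
from npfsite.synthetic import HelixSpec, make_ideal_helix, make_rotated_pocket_pair

from conftest import make_residue


# ---------------------------------------------------------------------------
# Kabsch


def _random_cloud(seed, n=20):
    return np.random.default_rng(seed).normal(size=(n, 3)) * 5.0


def test_kabsch_recovers_exact_rigid_transform():
    cloud = _random_cloud(0)
    R_true = Rotation.from_euler("zyx", [40, -25, 70], degrees=True).as_matrix()
    t_true = np.array([3.0, -7.0, 11.0])
    moved = cloud @ R_true.T + t_true
    sup = kabsch_superpose(cloud, moved)
    assert sup.rmsd < 1e-6
    assert np.allclose(sup.rotation, R_true, atol=1e-8)
    assert np.allclose(sup.translation, t_true, atol=1e-8)
    assert np.isclose(np.linalg.det(sup.rotation), 1.0)


def test_kabsch_matches_rotation_grid_search_on_three_points():
    """Independent oracle: coarse-to-fine search over rotation space."""
    mobile = np.array([[1.0, 0.0, 0.0], [0.0, 2.0, 0.0], [0.0, 0.0, 3.0]])
    rng = np.random.default_rng(4)
    R_true = Rotation.random(random_state=7).as_matrix()
    target = mobile @ R_true.T + np.array([1.0, 2.0, 3.0])

    def rmsd_for(rot: Rotation) -> float:
        a = mobile - mobile.mean(axis=0)
        b = target - target.mean(axis=0)
        return float(np.sqrt(np.mean(np.sum((a @ rot.as_matrix().T - b) ** 2, axis=1))))

    best = min(
        (Rotation.from_euler("zyx", e, degrees=True)
         for e in itertools.product(range(0, 360, 12), range(-90, 91, 12), range(0, 360, 12))),
        key=rmsd_for,
    )
    for step in (4.0, 1.0, 0.25, 0.05, 0.01):
        candidates = [best]
        for axis in np.vstack([np.eye(3), -np.eye(3)]):
            candidates.append(Rotation.from_rotvec(np.radians(step) * axis) * best)
        best = min(candidates, key=rmsd_for)
        while True:
            improved = min(
                [best] + [
                    Rotation.from_rotvec(np.radians(step) * axis) * best
                    for axis in np.vstack([np.eye(3), -np.eye(3)])
                ],
                key=rmsd_for,
            )
            if rmsd_for(improved) >= rmsd_for(best) - 1e-12:
                break
            best = improved
    sup = kabsch_superpose(mobile, target)
    assert sup.rmsd <= rmsd_for(best) + 1e-3


def test_kabsch_rmsd_monotone_in_noise():
    cloud = _random_cloud(1, n=40)
    rng = np.random.default_rng(2)
    R = Rotation.random(random_state=3).as_matrix()
    rmsds = []
    for sigma in (0.1, 0.5, 1.0):
        noisy = cloud @ R.T + rng.normal(scale=sigma, size=cloud.shape)
        rmsds.append(kabsch_superpose(cloud, noisy).rmsd)
    assert rmsds[0] < rmsds[1] < rmsds[2]


def test_kabsch_rejects_degenerate_input():
    line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0]], dtype=float)
    with pytest.raises(ValueError, match="collinear"):
        kabsch_superpose(line, line + 1.0)
    with pytest.raises(ValueError):
        kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


# ---------------------------------------------------------------------------
# helix axis


def _ca(model, chain="A"):
    return np.array([r.atom("CA").xyz for r in model.chains[chain]])


def test_axis_of_z_helix_within_one_degree():
    helix = make_ideal_helix(HelixSpec(n_residues=18))
    axis = fit_helix_axis(_ca(helix))
    angle = math.degrees(math.acos(abs(float(axis.direction @ [0, 0, 1]))))
    assert angle < 1.0
    assert all(0.0 <= p < 360.0 for p in axis.phases)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_axis_follows_applied_rotation(seed):
    R = Rotation.random(random_state=seed).as_matrix()
    u = R @ np.array([0.0, 0.0, 1.0])
    helix = make_ideal_helix(HelixSpec(n_residues=15, axis=tuple(u.tolist())))
    axis = fit_helix_axis(_ca(helix))
    angle = math.degrees(math.acos(np.clip(abs(float(axis.direction @ u)), 0, 1)))
    assert angle < 1.0


def test_short_fragment_rejected():
    helix = make_ideal_helix(HelixSpec(n_residues=4))
    with pytest.raises(ValueError, match="6"):
        fit_helix_axis(_ca(helix))


def test_phase_differences_match_twist():
    helix = make_ideal_helix(HelixSpec(n_residues=18, twist=100.0))
    axis = fit_helix_axis(_ca(helix))
    steps = np.diff(axis.phases) % 360.0
    # clockwise-measured phases of a right-handed helix step by 360-100; the
    # slight wobble comes from the sliding-window axis fit
    assert np.allclose(steps, 260.0, atol=4.0)


# ---------------------------------------------------------------------------
# H8 rotation


@pytest.mark.parametrize("theta", [0.0, 30.0, 115.0, 180.0, 245.0])
def test_rotation_angle_parameter_recovery(theta):
    for seed in (0, 1, 2):
        gpcr, eh2 = make_rotated_pocket_pair(theta, seed=seed)
        got = h8_rotation_angle(gpcr, eh2)
        err = min(abs(got - theta), 360.0 - abs(got - theta))
        assert err < 2.0, (theta, seed, got)


def test_rotation_missing_residue_reported():
    gpcr, eh2 = make_rotated_pocket_pair(115.0)
    without = StructureModel("cut", {"E": [r for r in eh2.chains["E"] if r.number != 54]})
    with pytest.raises(KeyError, match="54"):
        h8_rotation_angle(gpcr, without)


def test_correspondence_map_is_one_to_one():
    cmap = default_correspondence()
    assert len(cmap.pairs) == 8
    with pytest.raises(ValueError, match="include_sle"):
        default_correspondence(include_sle=True)


# ---------------------------------------------------------------------------
# chemical classes & score


def test_chemical_classes_partition_all_twenty():
    union = set().union(*CHEMICAL_CLASSES.values())
    assert len(union) == 20
    total = sum(len(v) for v in CHEMICAL_CLASSES.values())
    assert total == 20, "classes are disjoint"
    assert chemical_class("G") == "polar" and chemical_class("K") == "basic"


def test_rhodopsin_site_scores_seven_of_eight():
    residues = {
        "1.55": "Y", "1.56": "V", "1.59": "Q", "12.50": "L",
        "8.49": "Q", "8.50": "F", "8.54": "M", "8.57": "T",
    }
    profile = npf_site_score(residues)
    assert profile.score == pytest.approx(7 / 8)
    failing = [str(p.label) for p in profile.positions if not p.matches_expected]
    assert failing == ["8.57"], "only the threonine misses the hydrophobic floor"


def test_perfect_and_minimal_scores():
    perfect = {t: "L" for t in ("1.55", "1.56", "12.50", "8.50", "8.54", "8.57")}
    perfect |= {"1.59": "R", "8.49": "Q"}
    assert npf_site_score(perfect).score == pytest.approx(1.0)
    all_gly = {t: "G" for t in ("1.55", "1.56", "1.59", "12.50", "8.49", "8.50", "8.54", "8.57")}
    assert npf_site_score(all_gly).score == pytest.approx(0.25)


def test_score_permutation_invariant_and_partial():
    residues = {"8.50": "F", "1.59": "K"}
    reversed_order = dict(reversed(list(residues.items())))
    assert npf_site_score(residues).score == npf_site_score(reversed_order).score == 1.0


# ---------------------------------------------------------------------------
# conservation profile


def test_identical_rows_give_unit_frequencies(rhodopsin_numbered):
    row = rhodopsin_numbered.sequence
    profile = conservation_profile([row] * 5, numbered_reference=rhodopsin_numbered)
    for entry in profile.positions:
        assert sum(entry.frequencies.values()) == pytest.approx(1.0)
        assert max(entry.frequencies.values()) == pytest.approx(1.0)


def test_two_rows_split_frequency(rhodopsin_numbered):
    ref = rhodopsin_numbered
    row = ref.sequence
    pos850 = ref.position_of(BWLabel.parse("8.50"))
    variant = row[: pos850 - 1] + "L" + row[pos850:]
    profile = conservation_profile([row, variant], positions=["8.50"], numbered_reference=ref)
    assert profile.positions[0].frequencies == {"F": 0.5, "L": 0.5}


def test_frequencies_equal_brute_force_counts(rhodopsin_numbered):
    rng = np.random.default_rng(9)
    ref = rhodopsin_numbered
    base = ref.sequence
    rows = [base]
    for _ in range(49):
        seq = list(base)
        for _ in range(rng.integers(0, 12)):
            seq[int(rng.integers(len(seq)))] = "ACDEFGHIKLMNPQRSTVWY"[int(rng.integers(20))]
        rows.append("".join(seq))
    profile = conservation_profile(rows, numbered_reference=ref)
    for entry in profile.positions:
        col = ref.position_of(entry.label) - 1
        counts: dict[str, int] = {}
        for row in rows:
            counts[row[col]] = counts.get(row[col], 0) + 1
        expected = {aa: c / len(rows) for aa, c in counts.items()}
        assert entry.frequencies == pytest.approx(expected)


def test_gapped_position_excluded_from_frequencies(rhodopsin_numbered):
    ref = rhodopsin_numbered
    row = ref.sequence
    pos = ref.position_of(BWLabel.parse("8.50"))
    gapped = row[: pos - 1] + "-" + row[pos:]
    profile = conservation_profile([row, gapped], positions=["8.50"], numbered_reference=ref)
    assert profile.positions[0].frequencies == {"F": 1.0}


# ---------------------------------------------------------------------------
# TM7–H8 lock


def _lock_model(cb_separation: float) -> StructureModel:
    tyr = make_residue("R", 306, "TYR", {"CA": ("C", (0, 0, 0)), "CB": ("C", (1.5, 0, 0))})
    phe = make_residue(
        "R", 313, "PHE",
        {"CA": ("C", (1.5 + cb_separation + 1.5, 0, 0)),
         "CB": ("C", (1.5 + cb_separation, 0, 0))},
    )
    return StructureModel("lock", {"R": [tyr, phe]})


def test_lock_detected_below_cutoff():
    result = tm7_h8_lock(_lock_model(3.5))
    assert result == {"locked": True, "distance": 3.5}


def test_lock_open_above_cutoff():
    result = tm7_h8_lock(_lock_model(9.0))
    assert result["locked"] is False


def test_lock_missing_residue_errors():
    model = StructureModel(
        "only-tyr", {"R": [make_residue("R", 306, "TYR", {"CB": ("C", (0, 0, 0))})]}
    )
    with pytest.raises(KeyError):
        tm7_h8_lock(model)
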