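import numpy as np
import pytest

from ligpocket import (
    FocusSpec,
    HBondCriteria,
    build_toy_pocket,
    compute_angle,
    detect_hbonds,
    focus_interactions,
    plant_hbond,
    summarize_ligand,
)
from ligpocket.errors import DegenerateGeometryError, SelectorError
from ligpocket.hbond import HBond

from conftest import random_rotation, rigid_transform


# ---------------------------------------------------------------------------
# Independent brute-force oracle: re-derives hydrogen attachment and scans
# every (donor-H, acceptor) pair with no shared code path.
# ---------------------------------------------------------------------------

def oracle_hbonds(cplx, cutoff=3.5, angle_min=120.0, angle_max=170.0,
                  include_water=True):
    atoms = cplx.atoms
    n = len(atoms)
    found = set()
    for hi in range(n):
        if atoms[hi].element != "H":
            continue
        # nearest heavy atom (naive scan)
        best, best_d = None, np.inf
        for j in range(n):
            if j == hi or atoms[j].element == "H" or atoms[j].role == "ion":
                continue
            d = np.linalg.norm(atoms[hi].coords - atoms[j].coords)
            if d < best_d:
                best, best_d = j, d
        lim = 1.5 if atoms[best].element == "S" else 1.2
        if best_d > lim or atoms[best].element not in ("N", "O", "S"):
            continue
        donor = best
        for ai in range(n):
            if ai == donor or atoms[ai].element not in ("N", "O"):
                continue
            if atoms[ai].role == "ion" or atoms[ai].element == "H":
                continue
            lig_d = atoms[donor].role == "ligand"
            lig_a = atoms[ai].role == "ligand"
            if lig_d == lig_a:
                continue
            partner_role = atoms[ai].role if lig_d else atoms[donor].role
            if partner_role == "water" and not include_water:
                continue
            dist = np.linalg.norm(atoms[hi].coords - atoms[ai].coords)
            if dist >= cutoff:
                continue
            v1 = atoms[donor].coords - atoms[hi].coords
            v2 = atoms[ai].coords - atoms[hi].coords
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if angle_min <= angle <= angle_max:
                found.add((atoms[hi].serial, atoms[ai].serial))
    return found


def randomized_pocket(seed):
    """Toy pocket with every water rigidly re-placed at random near the
    ligand, rejecting placements that overlap other molecules (which would
    make hydrogen attachment ambiguous)."""
    rng = np.random.default_rng(seed)
    pocket = build_toy_pocket(seed=0)
    coords = pocket.coords.copy()
    oac = next(a.coords for a in pocket.atoms if a.name == "OAC")
    water_groups = {}
    non_water = [i for i, a in enumerate(pocket.atoms) if a.role != "water"]
    for i, a in enumerate(pocket.atoms):
        if a.role == "water":
            water_groups.setdefault(a.residue_seq, []).append(i)
    placed = [coords[i] for i in non_water]
    for members in water_groups.values():
        center = np.mean([coords[i] for i in members], axis=0)
        for _attempt in range(200):
            rot = random_rotation(rng)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            new_center = oac + direction * rng.uniform(2.2, 6.5)
            candidate = [
                (coords[i] - center) @ rot.T + new_center for i in members
            ]
            others = np.array(placed)
            if all(
                np.min(np.linalg.norm(others - c, axis=1)) >= 1.7
                for c in candidate
            ):
                break
        for i, c in zip(members, candidate):
            coords[i] = c
        placed.extend(candidate)
    return pocket.with_coords(coords)


class TestComputeAngle:
    def test_collinear(self):
        assert compute_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == pytest.approx(180.0)

    def test_right_angle(self):
        assert compute_angle((0, 0, 0), (1, 0, 0), (1, 1, 0)) == pytest.approx(90.0)

    def test_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            compute_angle((1, 0, 0), (1, 0, 0), (2, 0, 0))

    def test_closed_form_oracle(self, rng):
        for _ in range(1000):
            d, h, a = rng.normal(size=(3, 3)) * 5
            if min(np.linalg.norm(d - h), np.linalg.norm(a - h)) < 1e-6:
                continue
            v1, v2 = d - h, a - h
            expected = np.degrees(
                np.arccos(
                    np.clip(
                        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                        -1, 1,
                    )
                )
            )
            assert compute_angle(d, h, a) == pytest.approx(expected, abs=1e-9)


class TestCriteria:
    def test_defaults(self):
        c = HBondCriteria()
        assert c.max_h_acceptor_distance == 3.5
        assert (c.angle_min, c.angle_max) == (120.0, 170.0)

    @pytest.mark.parametrize(
        "kwargs", [
            {"max_h_acceptor_distance": 0.0},
            {"angle_min": -1.0},
            {"angle_min": 150.0, "angle_max": 120.0},
            {"angle_max": 190.0},
        ],
    )
    def test_validation(self, kwargs):
        with pytest.raises(ValueError):
            HBondCriteria(**kwargs)


class TestDetection:
    def plant(self, distance, angle):
        """Planted SOL1-HW1 -> OAC bond; returns (complex, planted pair)."""
        pocket = build_toy_pocket(seed=0)
        planted = plant_hbond(
            pocket, ("SOL", 1, "OW"), ("LIG", 900, "OAC"), distance, angle
        )
        h_serial = next(
            a.serial for a in planted.atoms
            if a.name == "HW1" and a.residue_seq == 1 and a.role == "water"
        )
        a_serial = next(a.serial for a in planted.atoms if a.name == "OAC")
        return planted, (h_serial, a_serial)

    def _planted_bond(self, distance, angle, **kwargs):
        cplx, pair = self.plant(distance, angle)
        hits = [
            b for b in detect_hbonds(cplx, **kwargs)
            if (b.hydrogen.serial, b.acceptor.serial) == pair
        ]
        assert len(hits) <= 1
        return hits[0] if hits else None

    def test_planted_bond_detected_exactly(self):
        bond = self._planted_bond(2.50, 150.0)
        assert bond is not None
        assert bond.h_a_distance == pytest.approx(2.50, abs=1e-6)
        assert bond.dha_angle == pytest.approx(150.0, abs=1e-6)
        assert bond.partner == "water"
        assert bond.direction == "ligand-accepts"

    def test_distance_boundary_strict(self):
        assert self._planted_bond(3.5, 150.0) is None
        assert self._planted_bond(3.4999, 150.0) is not None

    def test_angle_above_upper_bound(self):
        assert self._planted_bond(2.5, 175.0) is None

    @pytest.mark.parametrize("angle", [120.0001, 169.9999])
    def test_angle_just_inside_bounds(self, angle):
        bond = self._planted_bond(2.5, angle)
        assert bond is not None
        assert bond.dha_angle == pytest.approx(angle, abs=1e-6)

    @pytest.mark.parametrize("angle", [119.9999, 170.0001])
    def test_angle_just_outside_bounds(self, angle):
        assert self._planted_bond(2.5, angle) is None

    def test_angle_bounds_inclusive_in_criteria(self):
        c = HBondCriteria()
        assert c.accepts(2.5, 120.0) and c.accepts(2.5, 170.0)
        assert not c.accepts(3.5, 150.0)  # strict distance
        assert not c.accepts(2.5, 119.999999) and not c.accepts(2.5, 170.000001)

    def test_vacuum_drops_water_bonds(self):
        cplx, pair = self.plant(2.5, 150.0)
        assert detect_hbonds(cplx, include_water=False) == []
        assert self._planted_bond(2.5, 150.0) is not None

    def test_vacuum_subset_of_with_water(self):
        for seed in range(10):
            cplx = randomized_pocket(seed)
            vac = {
                (b.hydrogen.serial, b.acceptor.serial)
                for b in detect_hbonds(cplx, include_water=False)
            }
            wet = {
                (b.hydrogen.serial, b.acceptor.serial)
                for b in detect_hbonds(cplx, include_water=True)
            }
            assert vac <= wet

    def test_every_bond_revalidates(self):
        criteria = HBondCriteria()
        for seed in range(20):
            for bond in detect_hbonds(randomized_pocket(seed), criteria):
                assert criteria.accepts(bond.h_a_distance, bond.dha_angle)
                assert compute_angle(
                    bond.donor.coords, bond.hydrogen.coords, bond.acceptor.coords
                ) == pytest.approx(bond.dha_angle, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        for seed in range(30):
            cplx = randomized_pocket(seed)
            got = {
                (b.hydrogen.serial, b.acceptor.serial) for b in detect_hbonds(cplx)
            }
            assert got == oracle_hbonds(cplx), f"seed {seed}"

    def test_deterministic_ordering(self):
        cplx = randomized_pocket(3)
        bonds = detect_hbonds(cplx)
        keys = [(b.donor.serial, b.acceptor.serial) for b in bonds]
        assert keys == sorted(keys)

    def test_invariant_under_rigid_transform(self, rng):
        cplx = randomized_pocket(5)
        before = [
            (b.hydrogen.serial, b.acceptor.serial, round(b.h_a_distance, 9),
             round(b.dha_angle, 9))
            for b in detect_hbonds(cplx)
        ]
        moved = rigid_transform(cplx, random_rotation(rng), rng.normal(size=3) * 20)
        after = [
            (b.hydrogen.serial, b.acceptor.serial, round(b.h_a_distance, 9),
             round(b.dha_angle, 9))
            for b in detect_hbonds(moved)
        ]
        assert before == after


class TestFocus:
    def test_planted_amide_bond(self):
        pocket = build_toy_pocket(seed=0)
        planted = plant_hbond(
            pocket, ("GLN", 443, "NE2"), ("LIG", 900, "OAC"), 2.77, 150.0
        )
        result = focus_interactions(planted)
        assert len(result) == 1
        assert result[0].partner == "amino_acid"
        assert result[0].partner_label() == "GLN443"
        assert result[0].h_a_distance == pytest.approx(2.77, abs=1e-6)

    def test_empty_when_no_partner_in_range(self, toy_pocket):
        assert focus_interactions(toy_pocket) == []

    def test_unresolvable_ligand_selector(self, toy_pocket):
        with pytest.raises(SelectorError, match="NOPE"):
            focus_interactions(toy_pocket, spec=FocusSpec(ligand_atom_selector="NOPE"))

    def test_unresolvable_residue_partner(self, toy_pocket):
        with pytest.raises(SelectorError, match="GLN999"):
            focus_interactions(
                toy_pocket, spec=FocusSpec(residue_partners=[("GLN", 999)])
            )

    def test_unresolvable_water_partner(self, toy_pocket):
        with pytest.raises(SelectorError, match="99"):
            focus_interactions(toy_pocket, spec=FocusSpec(water_partners=[99]))

    def test_subset_of_full_detection(self):
        spec = FocusSpec()
        for seed in range(15):
            cplx = randomized_pocket(seed)
            full = {
                (b.hydrogen.serial, b.acceptor.serial) for b in detect_hbonds(cplx)
            }
            focus = {
                (b.hydrogen.serial, b.acceptor.serial)
                for b in focus_interactions(cplx, spec=spec)
            }
            assert focus <= full

    def test_equals_filtered_full_set(self):
        # focus = full detection intersected with the selector sets
        for seed in range(15):
            cplx = randomized_pocket(seed)
            oac_serial = next(a.serial for a in cplx.atoms if a.name == "OAC")
            allowed_partners = {
                a.serial for a in cplx.atoms
                if (a.residue_name == "GLN" and a.residue_seq == 443
                    and a.name not in ("N", "CA", "C", "O", "H"))
                or (a.role == "water" and a.residue_seq in (1, 13))
            }
            expected = set()
            for b in detect_hbonds(cplx):
                ends = {b.donor.serial, b.hydrogen.serial, b.acceptor.serial}
                if oac_serial in ends and (ends - {oac_serial}) & allowed_partners:
                    expected.add((b.hydrogen.serial, b.acceptor.serial))
            got = {
                (b.hydrogen.serial, b.acceptor.serial)
                for b in focus_interactions(cplx)
            }
            assert got == expected


def _mkbond(distance, pocket=None):
    pocket = pocket or build_toy_pocket(seed=0)
    planted = plant_hbond(
        pocket, ("SOL", 1, "OW"), ("LIG", 900, "OAC"), distance, 150.0
    )
    bonds = detect_hbonds(planted)
    assert len(bonds) == 1
    return bonds[0]


class TestSummarize:
    def _bonds(self, n, distance=2.5):
        bond = _mkbond(distance)
        return [bond] * n

    def test_bonds_per_pose(self):
        summary = summarize_ligand([self._bonds(3), self._bonds(5)], ligand_id="x")
        assert summary.bonds_per_pose == pytest.approx(4.0)
        assert summary.n_poses == 2

    def test_mean_distance(self):
        poses = [[_mkbond(2.0)], [_mkbond(3.0)]]
        summary = summarize_ligand(poses)
        assert summary.mean_h_a_distance == pytest.approx(2.5, abs=1e-6)

    def test_no_bonds_mean_undefined(self):
        summary = summarize_ligand([[], []])
        assert summary.bonds_per_pose == 0.0
        assert summary.mean_h_a_distance is None

    def test_zero_poses_error(self):
        with pytest.raises(ValueError):
            summarize_ligand([])

    def test_focus_fields(self):
        b1, b2 = _mkbond(2.0), _mkbond(3.0)
        summary = summarize_ligand(
            [[b1, b2], [b1]], focus_per_pose=[[b1], []]
        )
        assert summary.focus_bonds_per_pose == pytest.approx(0.5)
        assert summary.focus_mean_distance == pytest.approx(2.0, abs=1e-6)
        assert summary.focus_partner_breakdown == {"SOL1": 1}

    def test_hand_summed_fixture(self, rng):
        # spreadsheet-style recomputation on 10 poses of planted bonds
        distances = [[2.1, 2.9], [2.4], [], [3.0, 2.2, 2.6], [2.8],
                     [2.0], [], [2.5], [3.1], [1.9]]
        pocket = build_toy_pocket(seed=0)
        poses = [[_mkbond(d, pocket) for d in pose] for pose in distances]
        summary = summarize_ligand(poses)
        flat = [d for pose in distances for d in pose]
        assert summary.bonds_per_pose == pytest.approx(len(flat) / 10)
        assert summary.mean_h_a_distance == pytest.approx(np.mean(flat), abs=1e-6)

    def test_focus_pose_count_mismatch(self):
        with pytest.raises(ValueError):
            summarize_ligand([[], []], focus_per_pose=[[]])
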