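"""Trp-pair geometry statistics: constructed cases and rigid-motion checks."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from holebif.trp_geometry import (
    INDOLE_RING_ATOMS,
    TrpPairGeometry,
    closest_hh_distance,
    interplane_angle,
    load_trp_pair,
    pair_statistics,
    ring_overlap_area,
)


def planar_ring(radius=1.4, z=0.0, center=(0.0, 0.0)):
    """Nine ring atoms on a planar circle (a convex stand-in for indole)."""
    angles = np.linspace(0.0, 2 * np.pi, 9, endpoint=False)
    return {
        name: np.array(
            [center[0] + radius * np.cos(a), center[1] + radius * np.sin(a), z]
        )
        for name, a in zip(INDOLE_RING_ATOMS, angles)
    }


def square_ring(side=1.0, z=0.0, center=(0.0, 0.0)):
    """Nine atoms outlining a unit square (corners + edge midpoints + center)."""
    cx, cy = center
    h = side / 2.0
    outline = [
        (-h, -h), (0, -h), (h, -h), (h, 0), (h, h), (0, h), (-h, h), (-h, 0),
        (0.0, 0.0),
    ]
    return {
        name: np.array([cx + x, cy + y, z])
        for name, (x, y) in zip(INDOLE_RING_ATOMS, outline)
    }


def with_hydrogen(atoms, name, xyz):
    atoms = dict(atoms)
    atoms[name] = np.array(xyz, dtype=float)
    return atoms


def random_rigid_motion(rng):
    rotation = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    return rotation.as_matrix(), rng.normal(scale=20.0, size=3)


def mc_overlap_oracle(pair, n_samples=200_000, seed=42):
    """Rejection-sampling estimate of the projected hull intersection area."""
    from scipy.spatial import ConvexHull, Delaunay

    ring_a = pair.ring("a")
    centroid = ring_a.mean(axis=0)
    _, _, vt = np.linalg.svd(ring_a - centroid)
    basis = vt[:2]

    def project(ring):
        return (ring - centroid) @ basis.T

    pa, pb = project(pair.ring("a")), project(pair.ring("b"))
    hull_a, hull_b = Delaunay(pa[ConvexHull(pa).vertices]), Delaunay(pb[ConvexHull(pb).vertices])
    points = np.vstack([pa, pb])
    lo, hi = points.min(axis=0), points.max(axis=0)
    rng = np.random.default_rng(seed)
    samples = rng.uniform(lo, hi, size=(n_samples, 2))
    inside = (hull_a.find_simplex(samples) >= 0) & (hull_b.find_simplex(samples) >= 0)
    box_area = np.prod(hi - lo)
    return box_area * inside.mean()


class TestClosestHH:
    def test_two_single_hydrogen_constructs(self):
        a = with_hydrogen(planar_ring(z=0.0), "HE1", (0.0, 0.0, 0.0))
        b = with_hydrogen(planar_ring(z=3.0), "HE1", (0.0, 0.0, 3.1))
        assert closest_hh_distance(TrpPairGeometry(a, b)) == pytest.approx(3.1)

    def test_designed_minimum_among_many_hydrogens(self):
        a = planar_ring(z=0.0)
        a = with_hydrogen(a, "HD1", (1.0, 0.0, 0.0))
        a = with_hydrogen(a, "HZ2", (0.0, 1.0, 0.0))
        b = planar_ring(z=4.0)
        b = with_hydrogen(b, "HD1", (1.0, 0.0, 2.75))  # closest pair: 2.75
        b = with_hydrogen(b, "HZ3", (5.0, 5.0, 4.0))
        assert closest_hh_distance(TrpPairGeometry(a, b)) == pytest.approx(2.75)

    def test_no_hydrogens_rejected(self):
        pair = TrpPairGeometry(planar_ring(), planar_ring(z=3.0))
        with pytest.raises(ValueError, match="hydrogen"):
            closest_hh_distance(pair)


class TestInterplaneAngle:
    def test_coplanar_rings_are_zero_degrees(self):
        pair = TrpPairGeometry(planar_ring(z=0.0), planar_ring(z=0.0, center=(5.0, 0.0)))
        assert interplane_angle(pair) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_rings(self):
        rot = Rotation.from_euler("x", 90, degrees=True).as_matrix()
        b = {n: rot @ xyz + np.array([4.0, 0, 0]) for n, xyz in planar_ring().items()}
        pair = TrpPairGeometry(planar_ring(), b)
        assert interplane_angle(pair) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [10.0, 45.0, 80.0])
    def test_constructed_rotation_recovered(self, angle):
        rot = Rotation.from_euler("y", angle, degrees=True).as_matrix()
        b = {n: rot @ xyz + np.array([0, 0, 3.5]) for n, xyz in planar_ring().items()}
        pair = TrpPairGeometry(planar_ring(), b)
        assert interplane_angle(pair) == pytest.approx(angle, abs=1e-7)

    def test_angle_folded_into_first_quadrant(self):
        rot = Rotation.from_euler("y", 135, degrees=True).as_matrix()
        b = {n: rot @ xyz + np.array([0, 0, 3.5]) for n, xyz in planar_ring().items()}
        assert interplane_angle(TrpPairGeometry(planar_ring(), b)) == pytest.approx(45.0, abs=1e-7)

    def test_degenerate_ring_rejected(self):
        collinear = {
            name: np.array([float(i), 0.0, 0.0])
            for i, name in enumerate(INDOLE_RING_ATOMS)
        }
        with pytest.raises(ValueError, match="degenerate|collinear"):
            interplane_angle(TrpPairGeometry(collinear, planar_ring()))


class TestRingOverlap:
    def test_identical_stacked_rings_give_full_outline_area(self):
        from scipy.spatial import ConvexHull

        a = planar_ring(z=0.0)
        b = planar_ring(z=3.4)
        area = ring_overlap_area(TrpPairGeometry(a, b))
        hull = ConvexHull(np.array([xyz[:2] for xyz in a.values()]))
        assert area == pytest.approx(hull.volume, rel=1e-9)  # 2-D hull volume = area

    def test_disjoint_projections_give_zero(self):
        pair = TrpPairGeometry(planar_ring(), planar_ring(z=3.4, center=(10.0, 0.0)))
        assert ring_overlap_area(pair) == 0.0

    def test_half_overlapping_unit_squares(self):
        pair = TrpPairGeometry(
            square_ring(z=0.0), square_ring(z=3.0, center=(0.5, 0.0))
        )
        assert ring_overlap_area(pair) == pytest.approx(0.5, rel=1e-9)

    @pytest.mark.parametrize("shift", [(0.5, 0.0), (0.3, 0.4), (0.9, 0.9)])
    def test_matches_monte_carlo_oracle(self, shift):
        pair = TrpPairGeometry(
            square_ring(z=0.0), square_ring(z=2.0, center=shift)
        )
        area = ring_overlap_area(pair)
        oracle = mc_overlap_oracle(pair)
        assert area == pytest.approx(oracle, rel=0.01, abs=0.002)

    def test_overlap_bounded_by_smaller_outline(self):
        pair = TrpPairGeometry(
            planar_ring(radius=1.4), square_ring(side=1.0, z=2.0, center=(0.4, 0.1))
        )
        assert ring_overlap_area(pair) <= 1.0 + 1e-12


class TestRigidInvariance:
    def test_all_statistics_invariant_under_rigid_motion(self, rng):
        a = with_hydrogen(planar_ring(z=0.0), "HE1", (1.2, 0.3, 0.1))
        rot_b = Rotation.from_euler("y", 35, degrees=True).as_matrix()
        b = {n: rot_b @ xyz + np.array([1.0, 0.5, 3.4]) for n, xyz in planar_ring().items()}
        b = with_hydrogen(b, "HZ2", (0.8, -0.2, 3.0))
        pair = TrpPairGeometry(a, b)
        reference = pair_statistics(pair)
        for _ in range(5):
            rotation, translation = random_rigid_motion(rng)
            moved = pair.transformed(rotation, translation)
            stats = pair_statistics(moved)
            for key in reference:
                assert stats[key] == pytest.approx(reference[key], abs=1e-8)


def _format_pdb(models):
    """Minimal multi-model PDB text for two TRP residues per model."""
    lines = []
    for model_index, (atoms_a, atoms_b) in enumerate(models, start=1):
        lines.append(f"MODEL     {model_index:4d}")
        serial = 1
        for chain, resseq, atoms in (("A", 306, atoms_a), ("A", 359, atoms_b)):
            for name, xyz in atoms.items():
                element = name[0]
                padded = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    f"ATOM  {serial:5d} {padded:<4s} TRP {chain}{resseq:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                    f"          {element:>2s}"
                )
                serial += 1
        lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"


class TestPdbInput:
    def test_round_trip_through_pdb(self, tmp_path):
        a = with_hydrogen(planar_ring(z=0.0), "HE1", (1.2, 0.3, 0.1))
        b = with_hydrogen(planar_ring(z=3.4), "HE1", (0.8, -0.2, 3.0))
        path = tmp_path / "pair.pdb"
        path.write_text(_format_pdb([(a, b)]))
        pair = load_trp_pair(path, ("A", 306), ("A", 359))
        direct = pair_statistics(TrpPairGeometry(a, b))
        from_pdb = pair_statistics(pair)
        for key in direct:
            assert from_pdb[key] == pytest.approx(direct[key], abs=1e-3)

    def test_model_index_selects_frame(self, tmp_path):
        a0 = with_hydrogen(planar_ring(z=0.0), "HE1", (0.0, 0.0, 0.0))
        b0 = with_hydrogen(planar_ring(z=3.0), "HE1", (0.0, 0.0, 3.0))
        b1 = with_hydrogen(planar_ring(z=4.0), "HE1", (0.0, 0.0, 4.0))
        path = tmp_path / "frames.pdb"
        path.write_text(_format_pdb([(a0, b0), (a0, b1)]))
        first = load_trp_pair(path, ("A", 306), ("A", 359), model_index=0)
        second = load_trp_pair(path, ("A", 306), ("A", 359), model_index=1)
        assert closest_hh_distance(first) == pytest.approx(3.0, abs=1e-3)
        assert closest_hh_distance(second) == pytest.approx(4.0, abs=1e-3)

    def test_missing_model_rejected(self, tmp_path):
        a = with_hydrogen(planar_ring(), "HE1", (0, 0, 0))
        b = with_hydrogen(planar_ring(z=3.0), "HE1", (0, 0, 3))
        path = tmp_path / "one.pdb"
        path.write_text(_format_pdb([(a, b)]))
        with pytest.raises(ValueError, match="model"):
            load_trp_pair(path, ("A", 306), ("A", 359), model_index=5)
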