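"""Geometric monitors: distances, reaction coordinates, H-bonds, RMSD."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from glycopmf import (
    Frame,
    RCSpec,
    distance,
    evaluate_rc,
    hbond_present,
    kabsch_rmsd,
    ring_plane_angle,
)
from glycopmf.errors import GeometryError, LabelError


def make_frame(labels, coords, elements=None):
    elements = elements or tuple("X" for _ in labels)
    return Frame(labels=tuple(labels), elements=tuple(elements), coords=np.asarray(coords, float))


def hexagon_frame(radius=1.45, extra=None):
    ang = 2 * np.pi * np.arange(6) / 6
    coords = np.column_stack([radius * np.cos(ang), -radius * np.sin(ang), np.zeros(6)])
    labels = ["O5", "C1", "C2", "C3", "C4", "C5"]
    if extra:
        for lab, xyz in extra.items():
            labels.append(lab)
            coords = np.vstack([coords, xyz])
    return make_frame(labels, coords)


class TestDistance:
    @pytest.mark.parametrize(
        "pa, pb, expected",
        [
            ((0, 0, 0), (3, 4, 0), 5.0),                      # 3-4-5 triangle
            ((1.2, -0.7, 9.0), (1.2, -0.7, 9.0), 0.0),        # identical positions
            ((1, 1, 1), (2, 3, 4), math.sqrt(14.0)),          # hand-evaluated sqrt(14)
        ],
    )
    def test_known_distances(self, pa, pb, expected):
        fr = make_frame(["a", "b"], [pa, pb])
        assert distance(fr, "a", "b") == pytest.approx(expected, abs=1e-12)

    def test_unknown_label_names_the_label(self):
        fr = make_frame(["a", "b"], [(0, 0, 0), (1, 0, 0)])
        with pytest.raises(LabelError, match="missing"):
            distance(fr, "a", "missing")

    @given(st.integers(0, 10_000))
    def test_symmetry_and_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        fr = make_frame(["a", "b", "c"], rng.normal(size=(3, 3)) * 5)
        dab = distance(fr, "a", "b")
        assert dab == distance(fr, "b", "a")
        assert dab >= 0
        assert dab <= distance(fr, "a", "c") + distance(fr, "c", "b") + 1e-12


class TestEvaluateRC:
    def test_single_term_equals_distance(self):
        fr = make_frame(["C1", "O4"], [(0, 0, 0), (0, 1.5, 0)])
        spec = RCSpec(name="rc2", terms=(("C1", "O4", 1.0),))
        assert evaluate_rc(fr, spec) == pytest.approx(distance(fr, "C1", "O4"))

    def test_difference_coordinate_vanishes_for_equidistant_pairs(self):
        fr = make_frame(["h", "d", "a"], [(0, 0, 0), (-1.0, 0, 0), (1.0, 0, 0)])
        spec = RCSpec(name="pt", terms=(("h", "d", 1.0), ("h", "a", -1.0)))
        assert evaluate_rc(fr, spec) == pytest.approx(0.0, abs=1e-12)

    def test_three_term_sum(self):
        fr = make_frame(
            ["p", "q", "r", "s"],
            [(0, 0, 0), (1.0, 0, 0), (1.0, 2.0, 0), (1.0, 2.0, 0.5)],
        )
        spec = RCSpec(
            name="sum",
            terms=(("p", "q", 1.0), ("q", "r", 1.0), ("r", "s", 1.0)),
        )
        assert evaluate_rc(fr, spec) == pytest.approx(3.5, abs=1e-12)

    @given(st.integers(0, 10_000), st.floats(-3, 3).filter(lambda w: abs(w) > 1e-3))
    def test_linear_in_weights(self, seed, scale):
        rng = np.random.default_rng(seed)
        fr = make_frame(["a", "b", "c"], rng.normal(size=(3, 3)))
        spec = RCSpec(name="rc", terms=(("a", "b", 1.0), ("b", "c", -0.5)))
        scaled = RCSpec(name="rc", terms=(("a", "b", scale), ("b", "c", -0.5 * scale)))
        assert evaluate_rc(fr, scaled) == pytest.approx(scale * evaluate_rc(fr, spec), rel=1e-10)

    def test_rejects_zero_weight(self):
        with pytest.raises(ValueError, match="weight"):
            RCSpec(name="bad", terms=(("a", "b", 0.0),))


class TestRingPlaneAngle:
    def test_bond_along_normal_is_axial(self):
        fr = hexagon_frame(extra={"O4": (0, 0, 2.0), "c": (0, 0, 0)})
        assert ring_plane_angle(fr, ["O5", "C1", "C2", "C3", "C4", "C5"], ("c", "O4")) == pytest.approx(90.0)

    def test_bond_in_plane_is_equatorial(self):
        fr = hexagon_frame(extra={"O4": (2.5, 0.3, 0.0), "c": (0, 0, 0)})
        assert ring_plane_angle(fr, ["O5", "C1", "C2", "C3", "C4", "C5"], ("c", "O4")) == pytest.approx(0.0, abs=1e-10)

    def test_45_degree_elevation(self):
        fr = hexagon_frame(extra={"O4": (1.0, 0.0, 1.0), "c": (0, 0, 0)})
        assert ring_plane_angle(fr, ["O5", "C1", "C2", "C3", "C4", "C5"], ("c", "O4")) == pytest.approx(45.0)

    @given(st.integers(0, 10_000))
    def test_invariant_under_global_rotation(self, seed):
        rng = np.random.default_rng(seed)
        fr = hexagon_frame(extra={"O4": (0.8, -0.2, 1.1), "c": (0.1, 0.0, 0.2)})
        ring = ["O5", "C1", "C2", "C3", "C4", "C5"]
        before = ring_plane_angle(fr, ring, ("c", "O4"))
        rot = Rotation.random(rng=rng)
        fr2 = make_frame(fr.labels, rot.apply(fr.coords) + rng.normal(size=3))
        assert ring_plane_angle(fr2, ring, ("c", "O4")) == pytest.approx(before, abs=1e-8)

    def test_collinear_ring_raises(self):
        coords = np.column_stack([np.arange(6), np.zeros(6), np.zeros(6)])
        fr = make_frame(["O5", "C1", "C2", "C3", "C4", "C5", "x"],
                        np.vstack([coords, [0, 1, 0]]))
        with pytest.raises(GeometryError):
            ring_plane_angle(fr, ["O5", "C1", "C2", "C3", "C4", "C5"], ("O5", "x"))


class TestHBond:
    def setup_method(self):
        # linear D-H...A along x, tunable H...A separation
        self.make = lambda dha: make_frame(
            ["D", "H", "A"], [(-1.0, 0, 0), (0, 0, 0), (dha, 0, 0)]
        )

    def test_well_inside_cutoffs(self):
        res = hbond_present(self.make(1.8), "D", "H", "A")
        assert res.present
        assert res.h_acceptor_distance == pytest.approx(1.8)
        assert res.dha_angle == pytest.approx(180.0)

    def test_beyond_distance_cutoff(self):
        res = hbond_present(self.make(3.5), "D", "H", "A")
        assert not res.present
        assert res.h_acceptor_distance == pytest.approx(3.5)

    def test_fails_angle_test_only(self):
        # acceptor at 100 degrees from the donor direction, H...A = 2.0
        ang = math.radians(100.0)
        fr = make_frame(
            ["D", "H", "A"],
            [(-1.0, 0, 0), (0, 0, 0), (2.0 * -math.cos(ang), 2.0 * math.sin(ang), 0)],
        )
        res = hbond_present(fr, "D", "H", "A", d_cut=2.5, angle_cut=120.0)
        assert not res.present
        assert res.h_acceptor_distance == pytest.approx(2.0)
        assert res.dha_angle == pytest.approx(100.0)

    def test_distinct_labels_required(self):
        with pytest.raises(ValueError):
            hbond_present(self.make(1.8), "D", "H", "H")


class TestKabschRMSD:
    square = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)
    labels = ("p0", "p1", "p2", "p3")

    def test_identical_frames(self):
        fr = make_frame(self.labels, self.square)
        assert kabsch_rmsd(fr, fr, self.labels) == pytest.approx(0.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(5, 3)) * 3
        labels = tuple(f"a{i}" for i in range(5))
        fa = make_frame(labels, coords)
        rot = Rotation.random(rng=rng)
        fb = make_frame(labels, rot.apply(coords) + rng.normal(size=3) * 10)
        assert kabsch_rmsd(fa, fb, labels) == pytest.approx(0.0, abs=1e-8)

    def test_matches_brute_force_rotation_search(self):
        # square with one corner displaced 0.4 A out of plane
        displaced = self.square.copy()
        displaced[0, 2] = 0.4
        fa = make_frame(self.labels, self.square)
        fb = make_frame(self.labels, displaced)
        result = kabsch_rmsd(fa, fb, self.labels)

        ac = self.square - self.square.mean(axis=0)
        bc = displaced - displaced.mean(axis=0)

        def rmsd_of_rotvec(v):
            rb = Rotation.from_rotvec(v).apply(bc)
            return float(np.sqrt(np.mean(np.sum((ac - rb) ** 2, axis=1))))

        rng = np.random.default_rng(0)
        best = min(
            (rmsd_of_rotvec(r.as_rotvec()) for r in Rotation.random(2000, rng=rng)),
        )
        for r in Rotation.random(200, rng=rng):
            res = minimize(rmsd_of_rotvec, r.as_rotvec(), method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-12})
            best = min(best, float(res.fun))
        assert result == pytest.approx(best, abs=1e-3)
        assert result > 0.05  # genuinely nonzero deformation

    def test_too_few_atoms(self):
        fr = make_frame(self.labels, self.square)
        with pytest.raises(GeometryError):
            kabsch_rmsd(fr, fr, ("p0", "p1"))

    def test_collinear_selection(self):
        coords = np.column_stack([np.arange(4), np.zeros(4), np.zeros(4)])
        fr = make_frame(self.labels, coords)
        with pytest.raises(GeometryError):
            kabsch_rmsd(fr, fr, self.labels)


class TestFrameInvariants:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            make_frame(["a", "a"], [(0, 0, 0), (1, 0, 0)])

    def test_nonfinite_coords_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            make_frame(["a", "b"], [(0, 0, 0), (np.inf, 0, 0)])

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            make_frame([], np.zeros((0, 3)))
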