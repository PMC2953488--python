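"""Coordinate frames and geometric monitors for reaction trajectories.

A :class:`Frame` is one time point of a labelled atom set.  On top of it this
module evaluates the monitors used to follow a glycosidase reaction: plain
interatomic distances, signed linear combinations of distances (reaction
coordinates such as the glycosidic C1-O4 cleavage distance or
proton-transfer distance differences), hydrogen-bond geometry, the axiality
angle of a bond relative to the sugar-ring mean plane, and least-squares
superposition RMSD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import GeometryError, LabelError
from .puckering import _mean_plane_normal

__all__ = [
    "Frame",
    "RCSpec",
    "RCTerm",
    "HBondGeometry",
    "distance",
    "evaluate_rc",
    "ring_plane_angle",
    "hbond_present",
    "kabsch_rmsd",
]


@dataclass(frozen=True)
class Frame:
    """Labelled atoms with 3-D coordinates (Å) at one time point (ps, optional).

    Labels are free strings matched exactly (no PDB-name normalization) and
    must be unique within a frame.
    """

    labels: tuple[str, ...]
    elements: tuple[str, ...]
    coords: np.ndarray
    time: float | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        if len(self.labels) == 0:
            raise ValueError("a frame must contain at least one atom")
        if coords.shape != (len(self.labels), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match {len(self.labels)} labels"
            )
        if len(self.elements) != len(self.labels):
            raise ValueError("elements and labels must have equal length")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        index = {}
        for i, lab in enumerate(self.labels):
            if lab in index:
                raise ValueError(f"duplicate atom label {lab!r}")
            index[lab] = i
        object.__setattr__(self, "_index", index)

    def __len__(self) -> int:
        return len(self.labels)

    def position(self, label: str) -> np.ndarray:
        try:
            return self.coords[self._index[label]]
        except KeyError:
            raise LabelError(f"atom label {label!r} not present in frame") from None

    def positions(self, labels: Sequence[str]) -> np.ndarray:
        return np.array([self.position(lab) for lab in labels])


class RCTerm(NamedTuple):
    """One weighted distance term of a reaction coordinate."""

    a: str
    b: str
    w: float


@dataclass(frozen=True)
class RCSpec:
    """A named signed linear combination of interatomic distances.

    Examples: a single +1 term is a plain bond/contact distance (the
    glycosidic C1-O4 cleavage coordinate); a (+1, -1) pair of terms is a
    proton-transfer coordinate (donor-H distance minus acceptor-H distance).
    """

    name: str
    terms: tuple[RCTerm, ...]

    def __post_init__(self):
        terms = tuple(RCTerm(*t) for t in self.terms)
        object.__setattr__(self, "terms", terms)
        if len(terms) == 0:
            raise ValueError(f"RC spec {self.name!r} must have at least one term")
        for t in terms:
            if t.w == 0 or not math.isfinite(t.w):
                raise ValueError(f"RC spec {self.name!r}: weight must be nonzero and finite")

    @classmethod
    def from_dict(cls, d: dict) -> "RCSpec":
        return cls(
            name=d["name"],
            terms=tuple(RCTerm(t["a"], t["b"], float(t["w"])) for t in d["terms"]),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "terms": [{"a": t.a, "b": t.b, "w": t.w} for t in self.terms],
        }


def distance(frame: Frame, a: str, b: str) -> float:
    """Euclidean distance (Å) between two labelled atoms."""
    return float(np.linalg.norm(frame.position(a) - frame.position(b)))


def evaluate_rc(frame: Frame, spec: RCSpec) -> float:
    """Evaluate a reaction coordinate: sum of weight_i * distance(a_i, b_i)."""
    return float(sum(t.w * distance(frame, t.a, t.b) for t in spec.terms))


def ring_plane_angle(
    frame: Frame, ring: Sequence[str], bond: tuple[str, str]
) -> float:
    """Angle (degrees, in [0, 90]) between a bond and the ring mean plane.

    90 means perpendicular to the plane (axial), 0 means in-plane
    (equatorial).  The plane is the Cremer–Pople mean plane of the six ring
    atoms — the same construction the puckering analysis uses — not a
    least-squares fit.
    """
    if len(ring) != 6:
        raise ValueError(f"expected 6 ring labels, got {len(ring)}")
    ring_xyz = frame.positions(ring)
    centered = ring_xyz - ring_xyz.mean(axis=0)
    normal = _mean_plane_normal(centered)
    v = frame.position(bond[1]) - frame.position(bond[0])
    nv = np.linalg.norm(v)
    if nv < 1e-12:
        raise GeometryError(f"bond {bond[0]!r}-{bond[1]!r} has zero length")
    s = abs(float(np.dot(v, normal))) / nv
    return math.degrees(math.asin(min(1.0, s)))


class HBondGeometry(NamedTuple):
    """Hydrogen-bond test outcome plus the measured geometry."""

    present: bool
    h_acceptor_distance: float  # Å
    dha_angle: float            # donor-H...acceptor angle, degrees


def hbond_present(
    frame: Frame,
    donor: str,
    hydrogen: str,
    acceptor: str,
    d_cut: float = 2.5,
    angle_cut: float = 120.0,
) -> HBondGeometry:
    """Geometric hydrogen-bond criterion.

    True iff the H...acceptor distance is <= ``d_cut`` (default 2.5 Å) and the
    donor-H...acceptor angle is >= ``angle_cut`` (default 120 degrees).  The
    measured geometry is returned regardless of the verdict.
    """
    if len({donor, hydrogen, acceptor}) != 3:
        raise ValueError("donor, hydrogen and acceptor labels must be distinct")
    h = frame.position(hydrogen)
    vd = frame.position(donor) - h
    va = frame.position(acceptor) - h
    d_ha = float(np.linalg.norm(va))
    nd, na = np.linalg.norm(vd), d_ha
    if nd < 1e-12 or na < 1e-12:
        raise GeometryError("coincident atoms in hydrogen-bond triple")
    cosang = float(np.dot(vd, va) / (nd * na))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return HBondGeometry(
        present=(d_ha <= d_cut and angle >= angle_cut),
        h_acceptor_distance=d_ha,
        dha_angle=angle,
    )


def kabsch_rmsd(frame_a: Frame, frame_b: Frame, selection: Sequence[str]) -> float:
    """Minimum RMSD (Å) of ``frame_b`` onto ``frame_a`` over rigid motions.

    Optimal least-squares superposition (Kabsch); invariant to any rigid
    transform applied to either input.  Requires >= 3 non-collinear selected
    atoms, matched by label in the given order.
    """
    if len(selection) < 3:
        raise GeometryError("superposition requires at least 3 atoms")
    a = frame_a.positions(selection)
    b = frame_b.positions(selection)
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    # collinear selections leave the rotation underdetermined
    if np.linalg.matrix_rank(ac, tol=1e-8) < 2 or np.linalg.matrix_rank(bc, tol=1e-8) < 2:
        raise GeometryError("selection atoms are collinear; superposition underdetermined")
    rot, _ = Rotation.align_vectors(ac, bc)
    # recompute residuals directly: the rssd reported by align_vectors is
    # obtained by cancellation of large norms and loses ~7 digits near zero
    res = ac - rot.apply(bc)
    return float(np.sqrt(np.mean(np.sum(res * res, axis=1))))
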