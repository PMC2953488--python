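"""Cremer–Pople puckering coordinates and conformer classification for pyranose rings.

A six-membered ring is reduced to an amplitude ``Q`` (Å) and two angles
``(theta, phi)`` on the puckering sphere.  The ring atoms must be supplied in
the order O5, C1, C2, C3, C4, C5 (j = 1..6), the common carbohydrate
convention, under which ``theta = 0`` is the undistorted 4C1 chair of
D-pyranoses and ``theta = 180`` is 1C4.  The planar projections used in
Stoddart-style itinerary diagrams are

    q_x = Q sin(theta) sin(phi),   q_y = Q sin(theta) cos(phi),

so the chair sits at the origin of the (q_x, q_y) plane and boats/skew-boats
lie on the outer circle.

Canonical conformers are classified by great-circle (geodesic) distance to a
fixed 38-vertex table on the puckering sphere: 2 chairs, 6 boats and 6
skew-boats on the equator (every 30 degrees in phi), 12 envelopes at
theta = 54.74 / 125.26 degrees and 12 half-chairs at theta = 50.84 / 129.16
degrees.  Absolute phi depends on the atom-ordering origin; conformer names,
not raw phi, are the stable comparison surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError

__all__ = [
    "PuckerCoords",
    "ConformerLabel",
    "CANONICAL_CONFORMERS",
    "cremer_pople",
    "inverse_cremer_pople",
    "classify_conformer",
    "itinerary",
    "ItineraryResult",
    "DEFAULT_REGIONS",
]

_J = np.arange(6)
_ANG = 2.0 * np.pi * _J / 6.0          # 2*pi*(j-1)/6
_SIGN = (-1.0) ** _J                    # (-1)**(j-1)
_SQ13 = math.sqrt(1.0 / 3.0)
_SQ16 = math.sqrt(1.0 / 6.0)

#: Ideal theta of envelope (E) and half-chair (H) forms on the sphere, degrees.
THETA_ENVELOPE = math.degrees(math.acos(1.0 / math.sqrt(3.0)))  # 54.7356...
THETA_HALFCHAIR = 50.84


@dataclass(frozen=True)
class PuckerCoords:
    """Cremer–Pople coordinates of one six-membered ring.

    ``theta`` and ``phi`` are NaN for an exactly planar ring (Q = 0), where
    they are undefined.
    """

    Q: float            # total puckering amplitude, Å
    theta: float        # polar angle, degrees in [0, 180]
    phi: float          # azimuth, degrees in [0, 360)
    q_x: float          # Q sin(theta) sin(phi), Å
    q_y: float          # Q sin(theta) cos(phi), Å
    q3: float           # Q cos(theta), Å

    @property
    def is_planar(self) -> bool:
        return not math.isfinite(self.theta)


@dataclass(frozen=True)
class ConformerLabel:
    """Nearest canonical conformer and the geodesic distance to it (degrees)."""

    name: str
    geodesic_dist: float


def _build_canonical_table() -> tuple[tuple[str, float, float], ...]:
    """The 38 canonical vertices as (name, theta, phi) in degrees.

    Names follow the usual carbohydrate notation with superscripts before the
    ring-shape letter and subscripts after, comma-separated (e.g. ``2,5B`` has
    C2 and C5 above the reference plane, ``B2,5`` below).  The table is
    internally consistent with :func:`inverse_cremer_pople`: generating a ring
    at a vertex and transforming it back lands on that vertex.
    """
    boats = {0: "3,OB", 60: "B1,4", 120: "2,5B", 180: "B3,O", 240: "1,4B", 300: "B2,5"}
    skews = {30: "3S1", 90: "5S1", 150: "2SO", 210: "1S3", 270: "1S5", 330: "OS2"}
    north_e = {0: "OE", 60: "E1", 120: "2E", 180: "E3", 240: "4E", 300: "E5"}
    north_h = {30: "OH1", 90: "2H1", 150: "2H3", 210: "4H3", 270: "4H5", 330: "OH5"}
    south_e = {0: "3E", 60: "E4", 120: "5E", 180: "EO", 240: "1E", 300: "E2"}
    south_h = {30: "3H4", 90: "5H4", 150: "5HO", 210: "1HO", 270: "1H2", 330: "3H2"}

    table: list[tuple[str, float, float]] = [("4C1", 0.0, 0.0), ("1C4", 180.0, 0.0)]
    for phi, name in sorted(north_h.items()):
        table.append((name, THETA_HALFCHAIR, float(phi)))
    for phi, name in sorted(north_e.items()):
        table.append((name, THETA_ENVELOPE, float(phi)))
    for phi, name in sorted(boats.items()):
        table.append((name, 90.0, float(phi)))
    for phi, name in sorted(skews.items()):
        table.append((name, 90.0, float(phi)))
    for phi, name in sorted(south_e.items()):
        table.append((name, 180.0 - THETA_ENVELOPE, float(phi)))
    for phi, name in sorted(south_h.items()):
        table.append((name, 180.0 - THETA_HALFCHAIR, float(phi)))
    return tuple(table)


CANONICAL_CONFORMERS: tuple[tuple[str, float, float], ...] = _build_canonical_table()


def sphere_vector(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit vector for sphere angles, axes chosen so (x, y, z) = (q_x, q_y, q3)/Q."""
    t = math.radians(theta_deg)
    p = math.radians(phi_deg)
    return np.array([math.sin(t) * math.sin(p), math.sin(t) * math.cos(p), math.cos(t)])


def sphere_angles(u: np.ndarray) -> tuple[float, float]:
    """Inverse of :func:`sphere_vector`; phi is 0 at the pole by convention."""
    z = min(1.0, max(-1.0, float(u[2])))
    theta = math.degrees(math.acos(z))
    if abs(u[0]) < 1e-15 and abs(u[1]) < 1e-15:
        return theta, 0.0
    phi = math.degrees(math.atan2(u[0], u[1])) % 360.0
    return theta, phi


_VERTEX_VECTORS = np.array([sphere_vector(t, p) for _, t, p in CANONICAL_CONFORMERS])


def _mean_plane_normal(centered: np.ndarray) -> np.ndarray:
    """Unit normal of the Cremer–Pople mean plane of centered ring coordinates."""
    rp = (centered * np.sin(_ANG)[:, None]).sum(axis=0)
    rpp = (centered * np.cos(_ANG)[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("degenerate ring: atoms are collinear, mean plane undefined")
    return n / nn


def ring_displacements(ring_coords: np.ndarray) -> np.ndarray:
    """Out-of-plane displacements z_j relative to the CP mean plane (sum to 0)."""
    c = np.asarray(ring_coords, dtype=float)
    if c.shape != (6, 3):
        raise ValueError(f"expected 6 ring atoms with 3-D coordinates, got shape {c.shape}")
    centered = c - c.mean(axis=0)
    return centered @ _mean_plane_normal(centered)


def cremer_pople(ring_coords: np.ndarray) -> PuckerCoords:
    """Puckering coordinates of a ring given as 6 ordered 3-vectors (O5, C1..C5).

    Follows the standard construction: translate to the geometric centre,
    build the unique mean plane from the two trigonometrically weighted sum
    vectors, project out-of-plane displacements z_j (which sum to zero by
    construction), and form

        q2 cos(phi) =  sqrt(1/3) sum z_j cos(4 pi (j-1)/6)
        q2 sin(phi) = -sqrt(1/3) sum z_j sin(4 pi (j-1)/6)
        q3          =  sqrt(1/6) sum (-1)^(j-1) z_j

    with Q = sqrt(q2^2 + q3^2) and cos(theta) = q3 / Q.
    """
    z = ring_displacements(ring_coords)
    q2c = _SQ13 * float(np.dot(z, np.cos(2.0 * _ANG)))
    q2s = -_SQ13 * float(np.dot(z, np.sin(2.0 * _ANG)))
    q3 = _SQ16 * float(np.dot(z, _SIGN))
    q2 = math.hypot(q2c, q2s)
    Q = math.hypot(q2, q3)
    if Q < 1e-10:
        return PuckerCoords(Q=Q, theta=math.nan, phi=math.nan, q_x=0.0, q_y=0.0, q3=0.0)
    theta = math.degrees(math.atan2(q2, q3))
    phi = math.degrees(math.atan2(q2s, q2c)) % 360.0 if q2 > 1e-12 else 0.0
    # q_x = Q sin(theta) sin(phi) = q2 sin(phi); q_y = Q sin(theta) cos(phi) = q2 cos(phi)
    return PuckerCoords(Q=Q, theta=theta, phi=phi, q_x=q2s, q_y=q2c, q3=q3)


def inverse_cremer_pople(
    Q: float, theta: float, phi: float, ring_radius: float = 1.45
) -> np.ndarray:
    """Build an ideal six-ring with prescribed puckering coordinates.

    Atoms are placed at angles 2 pi (j-1)/6 on a circle of ``ring_radius`` in
    the xy-plane (traversed so that the CP mean-plane normal is +z) with

        z_j = sqrt(1/3) q2 cos(phi + 4 pi (j-1)/6) + sqrt(1/6) q3 (-1)^(j-1),

    q2 = Q sin(theta), q3 = Q cos(theta).  For Q > 0, :func:`cremer_pople` of
    the result recovers (Q, theta, phi).
    """
    if Q < 0:
        raise ValueError(f"puckering amplitude Q must be non-negative, got {Q}")
    if ring_radius <= 0:
        raise ValueError(f"ring_radius must be positive, got {ring_radius}")
    t = math.radians(theta)
    p = math.radians(phi)
    q2 = Q * math.sin(t)
    q3 = Q * math.cos(t)
    z = _SQ13 * q2 * np.cos(p + 2.0 * _ANG) + _SQ16 * q3 * _SIGN
    # clockwise placement in xy so that the CP normal points along +z
    x = ring_radius * np.cos(_ANG)
    y = -ring_radius * np.sin(_ANG)
    return np.column_stack([x, y, z])


def classify_conformer(p: PuckerCoords, planarity_threshold: float = 0.1) -> ConformerLabel:
    """Nearest canonical conformer by great-circle distance on the sphere.

    Rings with ``Q`` below ``planarity_threshold`` (default 0.1 Å) are labelled
    ``"planar"`` because theta/phi are numerically unstable near Q = 0.  Ties
    are broken by table order.
    """
    if p.Q < planarity_threshold or p.is_planar:
        return ConformerLabel(name="planar", geodesic_dist=math.nan)
    u = sphere_vector(p.theta, p.phi)
    cosd = np.clip(_VERTEX_VECTORS @ u, -1.0, 1.0)
    idx = int(np.argmax(cosd))  # first maximum == smallest distance, table order
    return ConformerLabel(
        name=CANONICAL_CONFORMERS[idx][0],
        geodesic_dist=math.degrees(math.acos(float(cosd[idx]))),
    )


#: RC2 intervals (Å) bracketing the reactant, transition and product ensembles.
DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "reactant": (1.5, 1.8),
    "ts": (2.0, 2.3),
    "product": (2.4, 3.2),
}


@dataclass(frozen=True)
class ItineraryResult:
    """Per-region conformer populations and Stoddart-projection statistics.

    ``populations``: DataFrame indexed by region, columns = conformer names,
    values = frame fractions (each nonempty region row sums to 1; empty
    regions carry NaN).  ``stats``: frame count and mean/SD of (q_x, q_y) per
    region.  ``majority``: most populated conformer per nonempty region.
    """

    populations: pd.DataFrame
    stats: pd.DataFrame
    majority: dict[str, str]


def itinerary(
    pucker_series: Sequence[PuckerCoords],
    rc2_series: Iterable[float],
    regions: Mapping[str, tuple[float, float]] = DEFAULT_REGIONS,
    planarity_threshold: float = 0.1,
) -> ItineraryResult:
    """Summarize the ring-conformational itinerary along the RC2 coordinate.

    Frames are assigned to the named, non-overlapping RC2 intervals
    (inclusive); frames outside all regions are ignored.
    """
    rc2 = np.asarray(list(rc2_series), dtype=float)
    if len(pucker_series) != rc2.size:
        raise ValueError(
            f"length mismatch: {len(pucker_series)} pucker frames vs {rc2.size} rc2 values"
        )
    items = sorted(regions.items(), key=lambda kv: kv[1][0])
    for (na, (la, ha)), (nb, (lb, hb)) in zip(items, items[1:]):
        if hb < lb or ha < la:
            raise ValueError("region intervals must satisfy lo <= hi")
        if lb < ha:
            raise ValueError(f"regions {na!r} and {nb!r} overlap")

    labels = [classify_conformer(p, planarity_threshold).name for p in pucker_series]
    labels = np.array(labels)
    qx = np.array([p.q_x for p in pucker_series])
    qy = np.array([p.q_y for p in pucker_series])

    pop_rows: dict[str, dict[str, float]] = {}
    stat_rows: dict[str, dict[str, float]] = {}
    majority: dict[str, str] = {}
    for name, (lo, hi) in regions.items():
        mask = (rc2 >= lo) & (rc2 <= hi)
        n = int(mask.sum())
        if n == 0:
            pop_rows[name] = {}
            stat_rows[name] = {
                "count": 0, "qx_mean": math.nan, "qx_sd": math.nan,
                "qy_mean": math.nan, "qy_sd": math.nan,
            }
            continue
        uniq, counts = np.unique(labels[mask], return_counts=True)
        fracs = {str(u): c / n for u, c in zip(uniq, counts)}
        pop_rows[name] = fracs
        majority[name] = max(fracs, key=fracs.get)
        stat_rows[name] = {
            "count": n,
            "qx_mean": float(qx[mask].mean()),
            "qx_sd": float(qx[mask].std(ddof=0)),
            "qy_mean": float(qy[mask].mean()),
            "qy_sd": float(qy[mask].std(ddof=0)),
        }

    populations = pd.DataFrame.from_dict(pop_rows, orient="index").reindex(regions.keys())
    stats = pd.DataFrame.from_dict(stat_rows, orient="index").reindex(regions.keys())
    stats["count"] = stats["count"].astype(int)
    return ItineraryResult(populations=populations, stats=stats, majority=majority)
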