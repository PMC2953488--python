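"""Synthetic surrogate of a glycosidase free-energy landscape and ring itinerary.

The real observable — a QM/MM free-energy surface along the glycosidic-bond
cleavage coordinate RC2 — is stood in for by an analytic 1-D potential: a C1
cubic-Hermite curve through landmark nodes (reactant minimum, transition
state, product minimum) with zero slope at stationary nodes and harmonic
walls beyond the outer nodes.  The default nodes are the published landmark
values of the CelS hydrolysis profile: (1.5 Å, 0), (2.17 Å, 19 kcal/mol),
(3.2 Å, 5 kcal/mol).

Umbrella-sampling data are generated by overdamped Langevin dynamics in each
harmonic window (a Heun predictor–corrector discretization of
dx = -(D/kBT) dU dt + sqrt(2 D dt) dW; see docs/methods.md for the
discretization choice).  One integration step corresponds nominally to
0.001 ps, so the default 10,000 + 10,000 steps mirror a 10 ps equilibration
plus 10 ps production protocol per window; only the stationary distribution
matters for the PMF reconstruction.

The ring-conformational itinerary (skew-boat reactant -> boat transition
state -> relaxed chair product) is emulated by geodesic interpolation between
anchor points on the Cremer–Pople sphere as a function of RC2, with Gaussian
noise, and turned into explicit ring geometries via the inverse puckering
transform.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import DEFAULT_TEMPERATURE, KB
from .errors import StabilityError
from .frames import Frame
from .pmf import UmbrellaWindow
from .puckering import inverse_cremer_pople, sphere_angles, sphere_vector

__all__ = [
    "SurrogatePotential",
    "DEFAULT_POTENTIAL",
    "surrogate_energy",
    "langevin_sample",
    "generate_umbrella_dataset",
    "PuckerPath",
    "DEFAULT_PUCKER_PATH",
    "pucker_path_state",
    "generate_ring_trajectory",
]


@dataclass(frozen=True)
class SurrogatePotential:
    """Analytic 1-D free-energy surface through landmark nodes.

    ``nodes`` are (position Å, energy kcal/mol) pairs with strictly increasing
    positions.  Flagged stationary nodes get zero slope; other nodes get the
    mean of adjacent secant slopes (end nodes: the single secant).  Beyond the
    outer nodes the surface continues as a harmonic wall of stiffness
    ``wall_k`` (kcal/mol/Å²) matched in value and slope, so the energy and its
    first derivative are continuous everywhere.
    """

    nodes: tuple[tuple[float, float], ...]
    stationary: tuple[bool, ...] | None = None
    wall_k: float = 100.0

    def __post_init__(self):
        nodes = tuple((float(x), float(e)) for x, e in self.nodes)
        object.__setattr__(self, "nodes", nodes)
        if len(nodes) < 2:
            raise ValueError("at least two nodes are required")
        xs = [x for x, _ in nodes]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ValueError("node positions must be strictly increasing")
        stat = self.stationary if self.stationary is not None else tuple(True for _ in nodes)
        stat = tuple(bool(s) for s in stat)
        if len(stat) != len(nodes):
            raise ValueError("stationary flags must match the number of nodes")
        object.__setattr__(self, "stationary", stat)
        if self.wall_k <= 0:
            raise ValueError("wall stiffness must be positive")

        ys = [e for _, e in nodes]
        slopes = []
        for i in range(len(nodes)):
            if stat[i]:
                slopes.append(0.0)
                continue
            if i == 0:
                slopes.append((ys[1] - ys[0]) / (xs[1] - xs[0]))
            elif i == len(nodes) - 1:
                slopes.append((ys[-1] - ys[-2]) / (xs[-1] - xs[-2]))
            else:
                sl = (ys[i] - ys[i - 1]) / (xs[i] - xs[i - 1])
                sr = (ys[i + 1] - ys[i]) / (xs[i + 1] - xs[i])
                slopes.append(0.5 * (sl + sr))
        # per-segment cubic coefficients in u = x - x_i: a + b u + c u^2 + d u^3
        coeffs = []
        for i in range(len(nodes) - 1):
            h = xs[i + 1] - xs[i]
            dy = ys[i + 1] - ys[i]
            m0, m1 = slopes[i], slopes[i + 1]
            c = (3.0 * dy / h - 2.0 * m0 - m1) / h
            d = (-2.0 * dy / h + m0 + m1) / (h * h)
            coeffs.append((ys[i], m0, c, d))
        object.__setattr__(self, "_xs", tuple(xs))
        object.__setattr__(self, "_ys", tuple(ys))
        object.__setattr__(self, "_slopes", tuple(slopes))
        object.__setattr__(self, "_coeffs", tuple(coeffs))

    # -- scalar fast path (used inside the Langevin loop) --------------------

    def value_and_grad(self, x: float) -> tuple[float, float]:
        xs = self._xs
        if x <= xs[0]:
            u = x - xs[0]
            m = self._slopes[0]
            return (self._ys[0] + m * u + 0.5 * self.wall_k * u * u,
                    m + self.wall_k * u)
        if x >= xs[-1]:
            u = x - xs[-1]
            m = self._slopes[-1]
            return (self._ys[-1] + m * u + 0.5 * self.wall_k * u * u,
                    m + self.wall_k * u)
        i = bisect_right(xs, x) - 1
        a, b, c, d = self._coeffs[i]
        u = x - xs[i]
        return (a + u * (b + u * (c + u * d)), b + u * (2.0 * c + 3.0 * d * u))

    def energy(self, x) -> np.ndarray | float:
        xv = np.asarray(x, dtype=float)
        if xv.ndim == 0:
            return self.value_and_grad(float(xv))[0]
        return np.array([self.value_and_grad(v)[0] for v in xv.ravel()]).reshape(xv.shape)

    def gradient(self, x) -> np.ndarray | float:
        xv = np.asarray(x, dtype=float)
        if xv.ndim == 0:
            return self.value_and_grad(float(xv))[1]
        return np.array([self.value_and_grad(v)[1] for v in xv.ravel()]).reshape(xv.shape)

    def max_curvature(self) -> float:
        """Largest |d2U/dx2| over the node range and walls (for stability checks)."""
        best = self.wall_k
        for (x0, _), (x1, _), (_, _, c, d) in zip(self.nodes, self.nodes[1:], self._coeffs):
            h = x1 - x0
            best = max(best, abs(2.0 * c), abs(2.0 * c + 6.0 * d * h))
        return best


#: Landmark surrogate for the published CelS hydrolysis profile:
#: reactant minimum (1.5 Å, 0), barrier top (2.17 Å, 19), product (3.2 Å, 5).
DEFAULT_POTENTIAL = SurrogatePotential(
    nodes=((1.5, 0.0), (2.17, 19.0), (3.2, 5.0)),
    stationary=(True, True, True),
)


def surrogate_energy(potential: SurrogatePotential, x: float) -> tuple[float, float]:
    """Energy (kcal/mol) and analytic gradient (kcal/mol/Å) at ``x``."""
    if not math.isfinite(x):
        raise ValueError("x must be finite")
    return potential.value_and_grad(float(x))


def langevin_sample(
    potential: SurrogatePotential,
    window: tuple[float, float],
    temperature: float = DEFAULT_TEMPERATURE,
    dt: float = 0.1,
    D: float = 0.001,
    n_equil: int = 10_000,
    n_prod: int = 10_000,
    seed: int = 0,
    x0: float | None = None,
    noise_scale: float = 1.0,
    bias_factor: float = 0.5,
) -> np.ndarray:
    """Overdamped Langevin samples of the biased coordinate in one window.

    ``window`` is (center Å, k kcal/mol/Å²); the total potential is
    U(x) + bias_factor * k * (x - center)^2.  The update is a Heun
    predictor–corrector step of

        x <- x - (D / kB T) * dU_total(x) * dt + sqrt(2 D dt) * N(0, 1),

    bit-reproducible for a fixed ``seed``.  The first ``n_equil`` steps are
    discarded; ``n_prod`` samples are returned.  ``noise_scale`` rescales the
    thermal noise (0 gives the deterministic zero-temperature limit).

    Raises :class:`StabilityError` if
    dt * D * (k_bias'' + max |U''|) / kB T >= 0.5.
    """
    center, k = float(window[0]), float(window[1])
    kbt = KB * temperature
    k2 = 2.0 * bias_factor * k  # second derivative of the bias
    a = dt * D * (k2 + potential.max_curvature()) / kbt
    if a >= 0.5:
        raise StabilityError(
            f"unstable integration parameters: dt*D*(k'' + max|U''|)/kBT = {a:.3f} >= 0.5 "
            f"(dt={dt}, D={D}, k={k}, T={temperature})"
        )
    mob_dt = D * dt / kbt
    sigma = math.sqrt(2.0 * D * dt) * noise_scale
    rng = np.random.default_rng(seed)
    n_total = n_equil + n_prod
    noise = rng.standard_normal(n_total)
    out = np.empty(n_prod)
    x = center if x0 is None else float(x0)
    vg = potential.value_and_grad
    for i in range(n_total):
        g0 = vg(x)[1] + k2 * (x - center)
        eta = sigma * noise[i]
        xp = x - mob_dt * g0 + eta
        g1 = vg(xp)[1] + k2 * (xp - center)
        x = x - 0.5 * mob_dt * (g0 + g1) + eta
        if i >= n_equil:
            out[i - n_equil] = x
    return out


def generate_umbrella_dataset(
    potential: SurrogatePotential = DEFAULT_POTENTIAL,
    n_windows: int = 42,
    rc_range: tuple[float, float] = (1.3, 3.5),
    k: float = 500.0,
    temperature: float = DEFAULT_TEMPERATURE,
    dt: float = 0.1,
    D: float = 0.001,
    n_equil: int = 10_000,
    n_prod: int = 10_000,
    seed: int = 0,
    bias_factor: float = 0.5,
) -> list[UmbrellaWindow]:
    """Biased samples from evenly spaced umbrella windows across ``rc_range``.

    Defaults mirror the reference protocol: 42 windows, k = 500 kcal/mol/Å²,
    10,000 equilibration + 10,000 production steps per window at 300 K.
    Per-window sub-seeds are ``seed + index``, so each window is reproducible
    independently of execution order.
    """
    if n_windows < 2:
        raise ValueError("at least two windows are required")
    centers = np.linspace(rc_range[0], rc_range[1], n_windows)
    windows = []
    for i, c in enumerate(centers):
        try:
            samples = langevin_sample(
                potential, (float(c), k), temperature=temperature, dt=dt, D=D,
                n_equil=n_equil, n_prod=n_prod, seed=seed + i,
                bias_factor=bias_factor,
            )
        except StabilityError as exc:
            raise StabilityError(f"window {i} (center {c:.4f} Å): {exc}") from exc
        windows.append(UmbrellaWindow(center=float(c), k=k, samples=samples, label=f"w{i:02d}"))
    return windows


@dataclass(frozen=True)
class PuckerPath:
    """Ring-puckering itinerary as anchors on the Cremer–Pople sphere vs RC2.

    Between consecutive anchors the (theta, phi) point moves along the great
    circle and Q interpolates linearly; Gaussian noise of the stated standard
    deviations is added on top (tangent-plane angular noise, additive
    amplitude noise).
    """

    anchors: tuple[tuple[float, float, float, float], ...]  # (rc2, Q, theta, phi)
    angle_noise_sd: float = 8.0   # degrees
    q_noise_sd: float = 0.03      # Å

    def __post_init__(self):
        anchors = tuple(tuple(float(v) for v in a) for a in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if len(anchors) < 2:
            raise ValueError("at least two anchors are required")
        rc = [a[0] for a in anchors]
        if any(b <= a for a, b in zip(rc, rc[1:])):
            raise ValueError("anchor rc2 positions must be strictly increasing")
        if any(a[1] <= 0 for a in anchors):
            raise ValueError("anchor amplitudes Q must be positive")


#: Reported itinerary of the catalytic-centre sugar: skew-boat 1S3 in the
#: reactant well, 2,5B boat at the oxocarbenium-like transition state,
#: relaxed 4C1 chair in the product.  The conformation plateaus at the
#: anchors and switches sharply approaching the barrier top (the q_x/q_y
#: projections change abruptly in the 2.0-2.3 Å window and oscillate around
#: zero past 2.4 Å); a single linear drift between the three vertices would
#: instead park most reactant frames near intermediate boat vertices.  TS
#: amplitude 0.45 Å reflects ring flattening from the C1-O5 partial double
#: bond (a modelling choice).
DEFAULT_PUCKER_PATH = PuckerPath(
    anchors=(
        (1.5, 0.57, 90.0, 210.0),   # 1S3 vertex, reactant plateau
        (2.0, 0.55, 90.0, 210.0),   # hold the skew-boat through the basin
        (2.1, 0.45, 90.0, 120.0),   # sharp switch to the 2,5B boat
        (2.3, 0.45, 90.0, 120.0),   # boat plateau around the barrier top
        (2.5, 0.57, 0.0, 0.0),      # relax to the 4C1 chair (clamped beyond)
    ),
)


def _slerp(u0: np.ndarray, u1: np.ndarray, t: float) -> np.ndarray:
    dot = float(np.clip(np.dot(u0, u1), -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        return u0
    s = math.sin(omega)
    return (math.sin((1.0 - t) * omega) * u0 + math.sin(t * omega) * u1) / s


def pucker_path_state(
    path: PuckerPath,
    rc2: float,
    rng: np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """(Q, theta, phi) on the itinerary at a given RC2, with optional noise.

    RC2 values outside the anchor span are clamped to the ends.  Noise is
    drawn from ``rng`` when given; with ``rng=None`` the state is exact.
    """
    anchors = path.anchors
    rcs = [a[0] for a in anchors]
    x = min(max(float(rc2), rcs[0]), rcs[-1])
    i = min(bisect_right(rcs, x) - 1, len(rcs) - 2)
    if x <= rcs[0]:
        i = 0
    t = (x - rcs[i]) / (rcs[i + 1] - rcs[i])
    q = (1.0 - t) * anchors[i][1] + t * anchors[i + 1][1]
    u = _slerp(
        sphere_vector(anchors[i][2], anchors[i][3]),
        sphere_vector(anchors[i + 1][2], anchors[i + 1][3]),
        t,
    )
    if rng is not None:
        # tangent-plane Gaussian step of sd angle_noise_sd degrees per component
        ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(u, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(u, e1)
        g = rng.standard_normal(2) * math.radians(path.angle_noise_sd)
        ang = math.hypot(g[0], g[1])
        if ang > 1e-12:
            d = (g[0] * e1 + g[1] * e2) / ang
            u = math.cos(ang) * u + math.sin(ang) * d
        q = max(q + rng.standard_normal() * path.q_noise_sd, 0.05)
    theta, phi = sphere_angles(u)
    return q, theta, phi


_RING_LABELS = ("O5", "C1", "C2", "C3", "C4", "C5")
_RING_ELEMENTS = ("O", "C", "C", "C", "C", "C")


def generate_ring_trajectory(
    path: PuckerPath,
    rc2_series: Sequence[float],
    ring_radius: float = 1.45,
    seed: int = 0,
) -> list[Frame]:
    """One idealized six-ring Frame per RC2 value, tracing the noisy itinerary.

    Frames carry the labels O5, C1..C5 in puckering order and are
    deterministic under a fixed seed.
    """
    if len(rc2_series) == 0:
        raise ValueError("rc2_series must be nonempty")
    rng = np.random.default_rng(seed)
    frames = []
    for rc2 in rc2_series:
        q, theta, phi = pucker_path_state(path, float(rc2), rng)
        coords = inverse_cremer_pople(q, theta, phi, ring_radius=ring_radius)
        frames.append(Frame(labels=_RING_LABELS, elements=_RING_ELEMENTS, coords=coords))
    return frames
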