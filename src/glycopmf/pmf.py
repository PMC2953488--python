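"""Potential-of-mean-force reconstruction from umbrella-sampling windows.

The free-energy profile G(x) along a 1-D reaction coordinate is recovered
from harmonically biased windows with the weighted histogram analysis method
(WHAM).  With windows j = 1..M, bias w_j(x) = f_b * k_j (x - c_j)^2
(f_b = 1/2 by default), N_j samples each and per-bin counts n_j(x), the
self-consistency equations are

    P(x) = sum_j n_j(x) / sum_j N_j exp[(F_j - w_j(x)) / kB T]
    F_j  = -kB T ln sum_x P(x) exp(-w_j(x) / kB T)

iterated until max_j |dF_j| < tol * kB T.  The unbiased profile is
G(x) = -kB T ln P(x), anchored to zero at its minimum.

A direct Boltzmann inversion of an unbiased histogram
(:func:`direct_histogram_pmf`) serves as an independent oracle: on unbiased
samples WHAM must reduce to it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .constants import DEFAULT_TEMPERATURE, KB
from .errors import ConnectivityError, ConvergenceError

__all__ = [
    "UmbrellaWindow",
    "PMFProfile",
    "Landmarks",
    "wham",
    "direct_histogram_pmf",
    "landmarks",
    "profile_sd",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One harmonic umbrella window: bias centre, force constant and samples.

    The bias is ``bias_factor * k * (x - center)**2`` with ``bias_factor``
    supplied at WHAM time (default 1/2); ``k`` is quoted in kcal/mol/Å².
    ``bias_offset`` adds a constant to the bias (a pure gauge; WHAM output is
    invariant to it).
    """

    center: float
    k: float
    samples: np.ndarray
    label: str = ""
    bias_offset: float = 0.0

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.k <= 0:
            raise ValueError(f"window {self.label!r}: force constant must be > 0, got {self.k}")
        if samples.size == 0:
            raise ValueError(f"window {self.label!r}: at least one sample required")
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"window {self.label!r}: samples must be finite")

    def bias(self, x: np.ndarray, bias_factor: float = 0.5) -> np.ndarray:
        return bias_factor * self.k * (np.asarray(x, dtype=float) - self.center) ** 2 + self.bias_offset


@dataclass(frozen=True)
class PMFProfile:
    """Binned free-energy curve; G is NaN on empty bins and zero at its minimum."""

    bin_centers: np.ndarray
    G: np.ndarray
    counts: np.ndarray
    temperature: float
    log_prob: np.ndarray | None = field(default=None, compare=False)
    n_iter: int | None = field(default=None, compare=False)
    residual: float | None = field(default=None, compare=False)

    def __post_init__(self):
        for name in ("bin_centers", "G", "counts"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.bin_centers.shape == self.G.shape == self.counts.shape):
            raise ValueError("bin_centers, G and counts must have matching shapes")

    @property
    def bin_width(self) -> float:
        return float(np.diff(self.bin_centers).mean()) if self.bin_centers.size > 1 else math.nan

    @property
    def populated(self) -> np.ndarray:
        return self.counts > 0


def _make_grid(samples: np.ndarray, bin_width: float) -> np.ndarray:
    """Bin edges aligned to integer multiples of the bin width (reproducible)."""
    lo = math.floor(samples.min() / bin_width)
    hi = math.ceil(samples.max() / bin_width)
    if hi == samples.max() / bin_width:
        hi += 1
    return np.arange(lo, hi + 1) * bin_width


def _check_connectivity(counts: np.ndarray, centers: np.ndarray) -> None:
    pop = np.flatnonzero(counts > 0)
    gaps = np.flatnonzero(np.diff(pop) > 1)
    if gaps.size:
        i = pop[gaps[0]]
        j = pop[gaps[0] + 1]
        raise ConnectivityError(
            "window histograms leave an empty gap on the reaction coordinate: "
            f"no samples in bins centred on [{centers[i + 1]:.4f}, {centers[j - 1]:.4f}] Å"
        )


def wham(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.02,
    temperature: float = DEFAULT_TEMPERATURE,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    bias_factor: float = 0.5,
) -> PMFProfile:
    """Reconstruct the unbiased free-energy profile from umbrella windows.

    Iterates the WHAM self-consistency equations (in log space, gauge-fixed to
    F_1 = 0) until the largest window free-energy change drops below
    ``tol * kB T``.  The probability density is normalized
    (sum P * bin_width = 1, exposed as ``log_prob``) before anchoring G at
    zero.  Raises :class:`ConnectivityError` if a histogram gap splits the
    sampled range and :class:`ConvergenceError` on iteration exhaustion.
    """
    if len(windows) == 0:
        raise ValueError("at least one umbrella window is required")
    if tol <= 0:
        raise ValueError("tol must be positive")
    kbt = KB * temperature
    all_samples = np.concatenate([w.samples for w in windows])
    edges = _make_grid(all_samples, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.array([np.histogram(w.samples, bins=edges)[0] for w in windows], dtype=float)
    n_b = counts.sum(axis=0)
    _check_connectivity(n_b, centers)

    pop = n_b > 0
    c_pop = centers[pop]
    ln_nb = np.log(n_b[pop])
    ln_N = np.log(np.array([w.samples.size for w in windows], dtype=float))
    w_bias = np.array([w.bias(c_pop, bias_factor) for w in windows]) / kbt  # (M, B)

    f = np.zeros(len(windows))  # window free energies in kBT units
    ln_p = None
    n_iter = 0
    delta = math.inf
    for n_iter in range(1, max_iter + 1):
        ln_den = logsumexp(ln_N[:, None] + f[:, None] - w_bias, axis=0)
        ln_p = ln_nb - ln_den
        f_new = -logsumexp(ln_p[None, :] - w_bias, axis=1)
        f_new -= f_new[0]
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last residual {delta:.3e} kBT, tol {tol:.3e})",
            residual=delta,
        )

    ln_p = ln_p - logsumexp(ln_p) - math.log(bin_width)  # sum P * bin_width = 1
    g = -kbt * ln_p
    g -= g.min()

    G = np.full(centers.shape, np.nan)
    G[pop] = g
    log_prob = np.full(centers.shape, -np.inf)
    log_prob[pop] = ln_p
    return PMFProfile(
        bin_centers=centers, G=G, counts=n_b, temperature=temperature,
        log_prob=log_prob, n_iter=n_iter, residual=delta,
    )


def direct_histogram_pmf(
    samples: np.ndarray,
    bin_width: float = 0.02,
    temperature: float = DEFAULT_TEMPERATURE,
) -> PMFProfile:
    """Boltzmann inversion of an unbiased sample histogram.

    G = -kB T ln(histogram density), anchored at zero.  This is the
    unbiased-limit oracle against which :func:`wham` is validated.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("at least one sample is required")
    kbt = KB * temperature
    edges = _make_grid(samples, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.histogram(samples, bins=edges)[0].astype(float)
    pop = counts > 0
    with np.errstate(divide="ignore"):
        ln_p = np.where(pop, np.log(counts), -np.inf)
    ln_p = ln_p - logsumexp(ln_p[pop]) - math.log(bin_width)
    G = np.full(centers.shape, np.nan)
    G[pop] = -kbt * ln_p[pop]
    G[pop] -= np.nanmin(G[pop])
    return PMFProfile(bin_centers=centers, G=G, counts=counts,
                      temperature=temperature, log_prob=ln_p)


@dataclass(frozen=True)
class Landmarks:
    """Stationary points of a reaction free-energy profile."""

    reactant_min: float   # Å
    ts_pos: float         # Å
    product_min: float    # Å
    barrier: float        # kcal/mol, G(ts) - G(reactant)
    delta_g: float        # kcal/mol, G(product) - G(reactant)

    def to_dict(self) -> dict:
        return {
            "reactant_min": self.reactant_min,
            "ts_pos": self.ts_pos,
            "product_min": self.product_min,
            "barrier": self.barrier,
            "delta_g": self.delta_g,
        }


def _refine_quadratic(x: np.ndarray, y: np.ndarray, idx: int, lo: int, hi: int) -> tuple[float, float]:
    """Vertex of the parabola through the extremal bin and its two neighbours.

    Falls back to the bin itself at the edge of the populated range or when
    the three points are degenerate.
    """
    if idx - 1 < lo or idx + 1 > hi:
        return float(x[idx]), float(y[idx])
    y0, y1, y2 = y[idx - 1], y[idx], y[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-14:
        return float(x[idx]), float(y[idx])
    h = 0.5 * (x[idx + 1] - x[idx - 1])
    shift = 0.5 * (y0 - y2) / denom * h
    if abs(shift) > h:  # neighbours do not bracket an extremum
        return float(x[idx]), float(y[idx])
    return float(x[idx] + shift), float(y1 - 0.125 * (y0 - y2) ** 2 / denom)


def landmarks(
    profile: PMFProfile,
    reactant_window: tuple[float, float],
    product_window: tuple[float, float],
) -> Landmarks:
    """Extract reactant/TS/product landmark positions and energies.

    The reactant (product) minimum is the argmin of G over populated bins in
    its window; the transition state is the argmax strictly between the two
    minima.  All three are refined by local quadratic interpolation through
    the extremal bin and its neighbours.
    """
    pop = np.flatnonzero(profile.populated & np.isfinite(profile.G))
    if pop.size == 0:
        raise ValueError("profile has no populated bins")
    x = profile.bin_centers
    g = profile.G
    lo_pop, hi_pop = int(pop[0]), int(pop[-1])

    def window_argmin(win: tuple[float, float], name: str) -> int:
        mask = (x >= win[0]) & (x <= win[1]) & profile.populated & np.isfinite(g)
        idxs = np.flatnonzero(mask)
        if idxs.size == 0:
            raise ValueError(f"{name} window [{win[0]}, {win[1]}] Å contains no populated bins")
        return int(idxs[np.argmin(g[idxs])])

    r_idx = window_argmin(reactant_window, "reactant")
    p_idx = window_argmin(product_window, "product")
    if r_idx >= p_idx:
        raise ValueError("reactant minimum must lie left of the product minimum")
    interior = np.arange(r_idx + 1, p_idx)
    if interior.size == 0:
        raise ValueError("no interior maximum: reactant and product bins are adjacent")
    t_idx = int(interior[np.argmax(g[interior])])
    if not (g[t_idx] >= g[t_idx - 1] and g[t_idx] >= g[t_idx + 1]):
        raise ValueError("no interior maximum between the reactant and product minima")

    r_pos, r_val = _refine_quadratic(x, g, r_idx, lo_pop, hi_pop)
    p_pos, p_val = _refine_quadratic(x, g, p_idx, lo_pop, hi_pop)
    t_pos, t_val = _refine_quadratic(x, g, t_idx, lo_pop, hi_pop)
    return Landmarks(
        reactant_min=r_pos,
        ts_pos=t_pos,
        product_min=p_pos,
        barrier=t_val - r_val,
        delta_g=p_val - r_val,
    )


def profile_sd(
    a: PMFProfile,
    b: PMFProfile,
    rc_range: tuple[float, float],
    anchor_window: tuple[float, float] | None = None,
) -> float:
    """Root-mean-square pointwise difference of two profiles over a range.

    Bins are matched by centre within half a bin width.  Both profiles are
    re-anchored to zero at their minimum inside ``anchor_window`` (the
    reactant well; defaults to each profile's global minimum) before the
    difference is taken, so constant offsets do not contribute.
    """
    tol = 0.5 * min(a.bin_width, b.bin_width)

    def anchored_g(p: PMFProfile) -> tuple[np.ndarray, np.ndarray]:
        mask = p.populated & np.isfinite(p.G)
        if anchor_window is not None:
            amask = mask & (p.bin_centers >= anchor_window[0]) & (p.bin_centers <= anchor_window[1])
            if not amask.any():
                raise ValueError("anchor window contains no populated bins")
            shift = p.G[amask].min()
        else:
            shift = p.G[mask].min()
        return p.bin_centers[mask], p.G[mask] - shift

    xa, ga = anchored_g(a)
    xb, gb = anchored_g(b)
    sel = (xa >= rc_range[0]) & (xa <= rc_range[1])
    diffs = []
    for xi, gi in zip(xa[sel], ga[sel]):
        j = np.argmin(np.abs(xb - xi))
        if abs(xb[j] - xi) <= tol:
            diffs.append(gi - gb[j])
    if not diffs:
        raise ValueError("profiles share no common populated bins in the requested range")
    d = np.asarray(diffs)
    return float(np.sqrt(np.mean(d * d)))
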