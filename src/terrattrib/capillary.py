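"""Maximum steady upward capillary flux from a water table (I_cap).

Steady one-dimensional Darcy–Buckingham (Richards) flow upward from a water
table gives, for a constant flux ``q`` (mm/day), the maximum height the
pressure profile can span:

    z_max(q) = ∫_{-inf}^{0} dh / (1 + q / K(h))        [h in meters, h <= 0]

``I_cap`` is the flux at which ``z_max(q)`` equals a prescribed height above
the water table (1 m by default): the largest steady evaporative/root-uptake
flux the soil column can deliver to that height.  ``z_max`` is strictly
decreasing in ``q``, so the root is found by Brent bracketing in log-flux.

The conductivity function is injected as a contract ``k_of_h(h) -> mm/day``
so the solver is independent of any particular soil model; a vectorised fast
path for the Brooks–Corey family used by the pedotransfer module is provided
for rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import integrate, optimize, special

#: relative level of K(h)/q below which the integrand is treated as zero
TRUNCATION_RATIO = 1e-9
#: head magnitude (m) beyond which a non-decaying K(h) is declared unbounded
UNBOUNDED_HEAD_M = 1e12


class UnboundedRiseError(RuntimeError):
    """K(h) does not decay with suction: capillary rise height diverges."""


@dataclass
class CapillarySetup:
    k_of_h: Callable[[float], float]
    height: float = 1.0
    q_bounds: tuple[float, float] = (1e-8, 1e8)
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height above the water table must be positive")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


def _truncation_head(q: float, k_of_h: Callable[[float], float]) -> float:
    """Suction magnitude s where K(-s)/q first drops below the truncation ratio."""
    target = TRUNCATION_RATIO * q
    s = 1.0
    while k_of_h(-s) > target:
        s *= 4.0
        if s > UNBOUNDED_HEAD_M or (
                s > 1e4 and k_of_h(-s) > 0.5 * k_of_h(-s / 16.0)):
            # not decaying (e.g. constant K): the rise integral diverges
            raise UnboundedRiseError(
                "conductivity does not decay with suction; rise height unbounded")
    return s


def max_rise_height(q: float, k_of_h: Callable[[float], float],
                    tol: float = 1e-9) -> float:
    """Height (m) spanned by the steady pressure profile at upward flux ``q``.

    Evaluates the head-space integral by adaptive quadrature, truncating the
    lower limit where ``K(h)/q < 1e-9`` (the integrand equals ``1/(1+q/K)``
    which is then below 1e-9).  Raises :class:`UnboundedRiseError` when the
    integral diverges (conductivity not decaying with suction).
    """
    if q <= 0:
        raise ValueError("flux must be positive")
    s_max = _truncation_head(q, k_of_h)

    def integrand(s: float) -> float:
        return 1.0 / (1.0 + q / k_of_h(-s))

    # piecewise over log-spaced segments: the integrand has a sharp shoulder
    # near the air-entry head and a long algebraic tail for power-law K
    edges = [0.0, 1.0]
    while edges[-1] < s_max:
        edges.append(min(edges[-1] * 10.0, s_max))
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(integrand, a, b, epsabs=tol, epsrel=tol,
                                limit=200)
        total += val
    return total


def icap(setup: CapillarySetup) -> float:
    """Flux (mm/day) whose maximum rise height equals ``setup.height``.

    Brent root of ``z_max(q) - height`` on a log-flux bracket, auto-expanded
    up to the configured bounds.  Returns 0.0 when even the smallest
    admissible flux cannot reach the height; raises
    :class:`UnboundedRiseError` when the rise height diverges for all fluxes.
    """
    q_lo, q_hi = setup.q_bounds
    z = lambda q: max_rise_height(q, setup.k_of_h, tol=setup.tol * 1e-3)

    # expand downward until z(q_lo) > height (or give up -> icap = 0)
    while z(q_lo) < setup.height:
        q_lo /= 10.0
        if q_lo < 1e-15:
            return 0.0
    # expand upward until z(q_hi) < height
    while z(q_hi) > setup.height:
        q_hi *= 10.0
        if q_hi > 1e15:
            raise RuntimeError(
                "could not bracket I_cap from above: rise height stays "
                f"> {setup.height} m even at q = {q_hi:g} mm/day")

    f = lambda lq: z(np.exp(lq)) - setup.height
    lq = optimize.brentq(f, np.log(q_lo), np.log(q_hi),
                         rtol=max(setup.tol, 4e-16))
    return float(np.exp(lq))


# ---------------------------------------------------------------------------
# Brooks-Corey fast path (vectorised over rasters)
# ---------------------------------------------------------------------------

def _bc_gfun(r: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Dimensionless rise height g(r, eta) = z_max / |h_b| for Brooks-Corey K.

    With K(h) = Ks (h_b/h)^eta below the bubbling head and Ks above it, and
    r = q/Ks, the head integral splits into a saturated segment and a
    closed-form tail:

        g = 1/(1+r) + (1/(r*(eta-1))) * 2F1(1, 1-1/eta; 2-1/eta; -1/r)
    """
    r = np.asarray(r, dtype=float)
    eta = np.asarray(eta, dtype=float)
    tail = special.hyp2f1(1.0, 1.0 - 1.0 / eta, 2.0 - 1.0 / eta, -1.0 / r)
    return 1.0 / (1.0 + r) + tail / (r * (eta - 1.0))


def icap_brooks_corey(ks: np.ndarray, h_b: np.ndarray, b_ret: np.ndarray,
                      height: float = 1.0, tol: float = 1e-10,
                      max_iter: int = 200) -> np.ndarray:
    """Vectorised I_cap (mm/day) for Brooks–Corey conductivity rasters.

    Solves g(r, eta) = height/|h_b| per cell by bisection in log r, where
    eta = 2 + 3/b is the head exponent.  Matches the generic quadrature
    solver (cross-checked in the test suite) but runs on whole rasters.
    """
    ks = np.asarray(ks, dtype=float)
    hb = np.abs(np.asarray(h_b, dtype=float))
    eta = 2.0 + 3.0 / np.asarray(b_ret, dtype=float)
    target = height / hb

    lo = np.full(ks.shape, np.log(1e-18))
    hi = np.full(ks.shape, np.log(1e12))
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        too_high = _bc_gfun(np.exp(mid), eta) > target  # rises past target -> flux can grow
        lo = np.where(too_high, mid, lo)
        hi = np.where(too_high, hi, mid)
        if np.max(hi - lo) < tol:
            break
    return ks * np.exp(0.5 * (lo + hi))
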