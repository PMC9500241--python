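"""Pedotransfer from soil composition to hydraulic parameters.

Implements the Saxton & Rawls (2006) regression equations: volumetric water
content at the wilting point (1500 kPa) and field capacity (33 kPa) with
organic-matter correction terms, saturation from texture, saturated
conductivity from the pore-size distribution, and coarse-fragment (gravel)
adjustments of both water content and conductivity.  Downstream predictors
are plant available water ``paw = theta_fc - theta_wp`` and the unsaturated
conductivity at field capacity ``k_fc``.

All functions are vectorised: scalar or array inputs of a common shape are
accepted and the outputs broadcast accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

# matric head equivalent of 33 kPa suction, in meters of water
H_FIELD_CAPACITY_M = 33.0 / 9.80665
#: weight-percent organic matter above which the regression is extrapolating
OM_ENVELOPE = 8.0


@dataclass
class SoilComposition:
    """Mass fractions of sand/clay/organic matter and volumetric gravel.

    ``sand``, ``clay``, ``om`` are mass fractions of the fine-earth
    (< 2 mm) fraction in [0, 1]; ``gravel_vol`` is the volumetric coarse
    fragment fraction of the bulk soil in [0, 1].
    """

    sand: np.ndarray | float
    clay: np.ndarray | float
    om: np.ndarray | float = 0.025
    gravel_vol: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        s, c, o, g = (np.asarray(v, dtype=float)
                      for v in (self.sand, self.clay, self.om, self.gravel_vol))
        for name, v in (("sand", s), ("clay", c), ("om", o), ("gravel_vol", g)):
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} outside [0, 1]")
        if np.any(s + c > 1.0 + 1e-12):
            raise ValueError("sand + clay exceeds 1")
        self.sand, self.clay, self.om, self.gravel_vol = s, c, o, g


@dataclass
class SoilHydraulics:
    """Hydraulic parameters per cell (volumetric fractions; mm/day)."""

    theta_wp: np.ndarray | float   # water content at 1500 kPa
    theta_fc: np.ndarray | float   # water content at 33 kPa
    theta_s: np.ndarray | float    # saturation
    ks: np.ndarray | float         # saturated conductivity, mm/day
    b_ret: np.ndarray | float      # Brooks-Corey retention exponent b
    paw: np.ndarray | float        # theta_fc - theta_wp
    k_fc: np.ndarray | float       # conductivity at field capacity, mm/day


def pedotransfer(comp: SoilComposition) -> SoilHydraulics:
    """Saxton–Rawls (2006) pedotransfer with OM and gravel corrections.

    Moisture regressions take sand/clay as decimal fractions and organic
    matter in percent by weight.  Gravel scales the water contents by the
    fine-earth bulk-volume fraction ``1 - gravel_vol`` and reduces saturated
    conductivity through the weight-fraction correction of the same
    reference.
    """
    s = np.asarray(comp.sand, dtype=float)
    c = np.asarray(comp.clay, dtype=float)
    om = np.asarray(comp.om, dtype=float) * 100.0  # percent by weight
    rv = np.asarray(comp.gravel_vol, dtype=float)

    if np.any(om > OM_ENVELOPE):
        warnings.warn(
            "organic matter above the Saxton-Rawls calibration envelope "
            f"({OM_ENVELOPE}% by weight); values are extrapolated",
            stacklevel=2)

    # moisture at 1500 kPa (wilting point)
    t1500 = (-0.024 * s + 0.487 * c + 0.006 * om
             + 0.005 * s * om - 0.013 * c * om + 0.068 * s * c + 0.031)
    theta_wp = t1500 + (0.14 * t1500 - 0.02)

    # moisture at 33 kPa (field capacity)
    t33 = (-0.251 * s + 0.195 * c + 0.011 * om
           + 0.006 * s * om - 0.027 * c * om + 0.452 * s * c + 0.299)
    theta_fc = t33 + (1.283 * t33 ** 2 - 0.374 * t33 - 0.015)

    # saturation-to-33 kPa drainable porosity
    ts33 = (0.278 * s + 0.034 * c + 0.022 * om
            - 0.018 * s * om - 0.027 * c * om - 0.584 * s * c + 0.078)
    theta_s33 = ts33 + (0.636 * ts33 - 0.107)

    theta_s = theta_fc + theta_s33 - 0.097 * s + 0.043

    # keep physical ordering even at extrapolated compositions
    eps = 1e-6
    theta_wp = np.clip(theta_wp, eps, 1 - 3 * eps)
    theta_fc = np.clip(theta_fc, theta_wp + eps, 1 - 2 * eps)
    theta_s = np.clip(theta_s, theta_fc + eps, 1 - eps)

    # retention exponent from the two fixed points of the curve
    b = (np.log(1500.0) - np.log(33.0)) / (np.log(theta_fc) - np.log(theta_wp))
    lam = 1.0 / b
    ks = 1930.0 * (theta_s - theta_fc) ** (3.0 - lam) * 24.0  # mm/h -> mm/day

    # gravel corrections: bulk-volume scaling of water contents, Saxton-Rawls
    # weight-fraction correction of conductivity
    alpha = 1.0 - theta_s  # matric density / particle density (2.65/2.65)
    rw = np.where(rv > 0,
                  2.65 * rv / (2.65 * rv + (1 - rv) * 2.65 * alpha), 0.0)
    kratio = (1.0 - rw) / (1.0 - rw * (1.0 - 1.5 * alpha))

    theta_wp_b = theta_wp * (1.0 - rv)
    theta_fc_b = theta_fc * (1.0 - rv)
    theta_s_b = theta_s * (1.0 - rv)
    ks_b = ks * kratio

    paw = theta_fc_b - theta_wp_b
    k_fc = ks_b * (theta_fc / theta_s) ** (3.0 + 2.0 * b)

    return SoilHydraulics(theta_wp=theta_wp_b, theta_fc=theta_fc_b,
                          theta_s=theta_s_b, ks=ks_b, b_ret=b,
                          paw=paw, k_fc=k_fc)


def bubbling_head(hyd: SoilHydraulics) -> np.ndarray | float:
    """Air-entry (bubbling) matric head in meters (negative).

    Anchored so that the Brooks–Corey retention curve passes exactly through
    the field-capacity point (33 kPa, theta_fc): ``|h_b| = h_33 *
    (theta_fc/theta_s)**b``.  This makes ``k_fc`` and ``unsat_conductivity``
    mutually consistent to machine precision.
    """
    ratio = np.asarray(hyd.theta_fc, dtype=float) / np.asarray(hyd.theta_s, dtype=float)
    return -H_FIELD_CAPACITY_M * ratio ** np.asarray(hyd.b_ret, dtype=float)


def unsat_conductivity(h: np.ndarray | float, hyd: SoilHydraulics) -> np.ndarray | float:
    """Campbell/Brooks–Corey unsaturated conductivity K(h), mm/day.

    ``K(h) = Ks * (h_b/h)**(2 + 3*lambda_p)`` for ``h < h_b`` and ``Ks``
    otherwise, with pore-size index ``lambda_p = 1/b``.  ``h`` is matric head
    in meters and must be <= 0; K is continuous and non-increasing in |h|.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h > 0):
        raise ValueError("matric head must be <= 0 (unsaturated or saturated)")
    hb = bubbling_head(hyd)
    ks = np.asarray(hyd.ks, dtype=float)
    # head exponent 2 + 3*lambda_p == (3 + 2b)/b, i.e. the head-space form of
    # K(theta) = Ks (theta/theta_s)^(3 + 2b) via theta/theta_s = (h_b/h)^(1/b)
    eta = 2.0 + 3.0 / np.asarray(hyd.b_ret, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(h < hb, hb / np.where(h == 0, -np.inf, h), 1.0)
    return ks * ratio ** eta
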