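"""Seasonal vegetation decay-rate estimation from daily FVC series.

The decay rate lambda is the e-folding timescale (days) of the asymptotic
exponential decay

    v(t) = v_min + (v0 - v_min) * exp(-t / lambda)

fitted per season by bounded nonlinear least squares over (v0, v_min,
lambda).  Because amplitude and asymptote are free parameters, lambda is
independent of the amplitude and timing of the decay event, making rates
comparable across climate zones.

Quality control mirrors the study-domain filters: a cell passes when the
relative standard error of lambda is at most 1 and at least 3 of its
seasonal fits converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

LAMBDA_BOUNDS_DAYS = (0.5, 5000.0)
MIN_POINTS = 8
MIN_CONVERGED = 3
MAX_RSE = 1.0


@dataclass
class DecayFit:
    lambda_est: float = np.nan
    se_lambda: float = np.nan
    rse: float = np.nan          # se_lambda / lambda_est
    converged: bool = False
    v0: float = np.nan
    v_min: float = np.nan


@dataclass
class CellDecaySummary:
    lambda_final: float
    n_converged: int
    n_seasons: int
    rse_summary: float
    pass_qc: bool


def _model(t: np.ndarray, v0: float, v_min: float, lam: float) -> np.ndarray:
    return v_min + (v0 - v_min) * np.exp(-t / lam)


def fit_decay(series: np.ndarray, t: np.ndarray | None = None) -> DecayFit:
    """Fit the asymptotic exponential to one decay event.

    Degenerate inputs (too few finite points, constant series, optimizer
    failure, lambda at the search bounds) yield ``converged=False`` rather
    than raising.
    """
    v = np.asarray(series, dtype=float)
    t = np.arange(v.size, dtype=float) if t is None else np.asarray(t, dtype=float)
    ok = np.isfinite(v) & np.isfinite(t)
    v, t = v[ok], t[ok]
    if v.size < MIN_POINTS or np.ptp(v) < 1e-9:
        return DecayFit()

    span = float(t.max() - t.min())
    p0 = (float(v[0]), float(v[-1]), max(span / 3.0, 1.0))
    lo = (-0.5, -0.5, LAMBDA_BOUNDS_DAYS[0])
    hi = (1.5, 1.5, LAMBDA_BOUNDS_DAYS[1])
    try:
        popt, pcov = curve_fit(_model, t, v, p0=p0, bounds=(lo, hi),
                               maxfev=2000)
    except (RuntimeError, ValueError):
        return DecayFit()
    lam = float(popt[2])
    se = float(np.sqrt(pcov[2, 2])) if np.all(np.isfinite(pcov)) else np.inf
    converged = (LAMBDA_BOUNDS_DAYS[0] < lam <= LAMBDA_BOUNDS_DAYS[1] * 0.999
                 and np.isfinite(se))
    return DecayFit(lambda_est=lam, se_lambda=se,
                    rse=se / lam if lam > 0 else np.inf,
                    converged=bool(converged),
                    v0=float(popt[0]), v_min=float(popt[1]))


def summarize_cell(fits: list[DecayFit]) -> CellDecaySummary:
    """Collapse the seasonal fits of one cell into its final lambda and QC flag.

    ``lambda_final`` and ``rse_summary`` are medians over converged seasons
    (robust to occasional bad fits); the cell passes QC when
    ``rse_summary <= 1`` (strictly greater than 1 is rejected) and at least
    3 seasons converged (or all of them, for records shorter than 3 seasons).
    """
    if not fits:
        raise ValueError("at least one seasonal fit is required")
    conv = [f for f in fits if f.converged]
    n_conv = len(conv)
    if n_conv == 0:
        return CellDecaySummary(np.nan, 0, len(fits), np.nan, False)
    lam = float(np.median([f.lambda_est for f in conv]))
    rse = float(np.median([f.rse for f in conv]))
    pass_qc = (rse <= MAX_RSE) and (n_conv >= min(MIN_CONVERGED, len(fits)))
    return CellDecaySummary(lam, n_conv, len(fits), rse, bool(pass_qc))


def fit_cube(fvc: np.ndarray, t: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Fit every pixel of a (season, time, y, x) or (time, y, x) FVC cube.

    Returns arrays ``lambda``, ``rse``, ``n_converged`` and the boolean
    ``qc`` mask on the (y, x) grid.
    """
    fvc = np.asarray(fvc, dtype=float)
    if fvc.ndim == 3:
        fvc = fvc[None]
    n_seasons, _, ny, nx = fvc.shape
    lam = np.full((ny, nx), np.nan)
    rse = np.full((ny, nx), np.nan)
    ncv = np.zeros((ny, nx), dtype=int)
    qc = np.zeros((ny, nx), dtype=bool)
    for iy in range(ny):
        for ix in range(nx):
            fits = [fit_decay(fvc[s, :, iy, ix], t) for s in range(n_seasons)]
            summ = summarize_cell(fits)
            lam[iy, ix] = summ.lambda_final
            rse[iy, ix] = summ.rse_summary
            ncv[iy, ix] = summ.n_converged
            qc[iy, ix] = summ.pass_qc
    return {"lambda": lam, "rse": rse, "n_converged": ncv, "qc": qc}
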