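"""Hyperbolic phase relation between nutrient uptake and biomass.

Cumulative uptake of a mineral element tracks cumulative biomass through a
rectangular hyperbola,

    N_u = N_um * Y / (K_y + Y),

where ``N_um`` is the potential maximum uptake at high biomass (kg/ha) and
``K_y`` the biomass at which uptake reaches half of it (Mg/ha).  Dividing
through gives the linear form Y/N_u = K_y/N_um + Y/N_um, so ordinary least
squares of Y/N_u on Y estimates both parameters exactly on noiseless data:
N_um = 1/slope, K_y = intercept/slope.  The linearized fit is canonical
here; a nonlinear least-squares refit (initialized from it) is provided for
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .series import NutrientObservation

__all__ = [
    "PhaseParams",
    "linearize",
    "fit_phase",
    "fit_phase_nonlinear",
    "predict_uptake",
    "predict_concentration",
    "efficiency_ratio",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PhaseParams:
    """Fitted hyperbolic phase relation for one element.

    Attributes
    ----------
    element : str
        Element label ("N", "P", "K", ...; labels are free-form).
    N_um : float
        Potential maximum uptake, kg/ha.
    K_y : float
        Biomass at half-maximal uptake, Mg/ha.
    slope, intercept : float
        Coefficients of the linearized regression Y/N_u on Y.
    r2_linear : float
        Coefficient of determination of that regression.
    n_points : int
        Observations used.
    """

    element: str
    N_um: float
    K_y: float
    slope: float = float("nan")
    intercept: float = float("nan")
    r2_linear: float = float("nan")
    n_points: int = 0

    def __post_init__(self) -> None:
        if not (self.N_um > 0):
            raise ValueError(f"N_um must be > 0, got {self.N_um}")
        if not (self.K_y > 0):
            raise ValueError(f"K_y must be > 0, got {self.K_y}")


def linearize(obs: list[NutrientObservation]) -> list[tuple[float, float]]:
    """Transform observations to (Y, Y/uptake) pairs, order preserved.

    Rows with uptake == 0 are non-physical for the phase relation and are
    dropped with a warning rather than poisoning the regression.
    """
    pairs: list[tuple[float, float]] = []
    for o in obs:
        if o.Y <= 0:
            raise ValueError(f"biomass must be > 0 to linearize, got Y={o.Y} at t={o.t}")
        if o.uptake <= 0:
            log.warning("dropping non-physical row at t=%s: uptake=%s", o.t, o.uptake)
            continue
        pairs.append((o.Y, o.Y / o.uptake))
    return pairs


def fit_phase(obs: list[NutrientObservation], element: str = "N") -> PhaseParams:
    """Estimate (N_um, K_y) by OLS on the linearized phase relation."""
    pairs = linearize(obs)
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 valid observations, got {len(pairs)}")
    y = np.array([p[0] for p in pairs])
    ratio = np.array([p[1] for p in pairs])
    if np.ptp(y) == 0:
        raise ValueError("zero variance in Y: phase relation not identifiable")
    res = stats.linregress(y, ratio)
    if res.slope <= 0 or res.intercept <= 0:
        raise ValueError(
            f"phase relation not supported by data for {element}: "
            f"slope={res.slope:.4g}, intercept={res.intercept:.4g}"
        )
    return PhaseParams(
        element=element,
        N_um=1.0 / res.slope,
        K_y=res.intercept / res.slope,
        slope=res.slope,
        intercept=res.intercept,
        r2_linear=res.rvalue**2,
        n_points=len(pairs),
    )


def fit_phase_nonlinear(obs: list[NutrientObservation], element: str = "N") -> PhaseParams:
    """Nonlinear least squares of uptake on Y, initialized from the linearized fit.

    Provided for comparison only; the linearized OLS is the canonical
    estimator for reproducing the published coefficients.
    """
    lin = fit_phase(obs, element)
    y = np.array([o.Y for o in obs if o.uptake > 0], dtype=float)
    u = np.array([o.uptake for o in obs if o.uptake > 0], dtype=float)
    popt, _ = optimize.curve_fit(
        lambda yy, num, ky: num * yy / (ky + yy), y, u, p0=[lin.N_um, lin.K_y]
    )
    resid = u - popt[0] * y / (popt[1] + y)
    ss_tot = float(np.sum((u - u.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return PhaseParams(
        element=element,
        N_um=float(popt[0]),
        K_y=float(popt[1]),
        slope=float("nan"),
        intercept=float("nan"),
        r2_linear=r2,
        n_points=len(y),
    )


def predict_uptake(Y, p: PhaseParams):
    """Predicted cumulative uptake N_um*Y/(K_y + Y), kg/ha; accepts arrays."""
    y = np.asarray(Y, dtype=float)
    if np.any(y < 0):
        raise ValueError("biomass must be >= 0")
    out = p.N_um * y / (p.K_y + y)
    return float(out) if out.ndim == 0 else out


def predict_concentration(Y, p: PhaseParams):
    """Predicted concentration N_um/(K_y + Y), g/kg; strictly decreasing in Y."""
    y = np.asarray(Y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("biomass must be > 0 for a concentration")
    out = p.N_um / (p.K_y + y)
    return float(out) if out.ndim == 0 else out


def efficiency_ratio(p: PhaseParams, applied: float) -> float:
    """Potential uptake over applied fertilizer, rounded to 2 d.p. for reporting.

    A ratio near 1 means the crop could take up essentially all of the
    applied element.
    """
    if applied <= 0:
        raise ValueError(f"applied amount must be > 0, got {applied}")
    return round(p.N_um / applied, 2)
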