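"""Couple biomass observations to the growth quantifier.

The model predicts yield proportional to the growth quantifier, Y = A*Q,
with A the yield factor (Mg/ha per unit Q) absorbing plant population,
fertility and water effects.  Calibration is a linear regression of
observed Y on computed Q — by default with an intercept (the observed
series has Y > 0 at Q = 0), optionally through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import initiation_time, quantifier_asymptote, quantifier_table
from .params import GrowthParams
from .series import FieldSeries

__all__ = ["YieldFit", "InitiationReport", "fit_yield_factor", "initiation_scan", "calibrate"]


@dataclass(frozen=True)
class YieldFit:
    """Calibrated yield factor.

    A: slope (Mg/ha per unit Q); b: intercept (Mg/ha, 0 when fit through the
    origin); r2: coefficient of determination; n_points: rows used.
    """

    A: float
    b: float
    r2: float
    n_points: int
    with_intercept: bool

    def predict(self, Q):
        """Estimated biomass yield b + A*Q, Mg/ha."""
        return self.b + self.A * np.asarray(Q, dtype=float)


@dataclass(frozen=True)
class InitiationReport:
    """Grid evaluation of total seasonal growth potential vs initiation time."""

    grid: pd.DataFrame  # columns x_i, Q_total, t_i
    argmax_x_i: float


def fit_yield_factor(points, with_intercept: bool = True) -> YieldFit:
    """OLS of yield on growth quantifier over (Q, Y) pairs.

    With ``with_intercept=False`` the line is forced through the origin
    (A = sum(Q*Y)/sum(Q^2)), honouring the strict proportional form Y = A*Q.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (Q, Y) points")
    q, y = pts[:, 0], pts[:, 1]
    if np.ptp(q) == 0:
        raise ValueError("zero variance in Q: yield factor not identifiable")
    if with_intercept:
        res = stats.linregress(q, y)
        a, b, r2 = res.slope, res.intercept, res.rvalue**2
    else:
        a = float(q @ y) / float(q @ q)
        b = 0.0
        resid = y - a * q
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    if a <= 0:
        raise ValueError(f"fitted yield factor not positive (A={a:.4g})")
    return YieldFit(A=float(a), b=float(b), r2=float(r2), n_points=len(q), with_intercept=with_intercept)


def initiation_scan(p: GrowthParams, x_i_grid) -> InitiationReport:
    """Evaluate total growth potential Q(inf) over candidate initiation times.

    Restricted to x_i >= 0: the asymptote grows without bound as
    x_i -> -inf, so "latest initiation that loses nothing" is only
    well-posed on the non-negative domain, where Q_total is maximal at
    x_i = 0.
    """
    grid = np.asarray(list(x_i_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("x_i grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("x_i grid entries must be >= 0")
    rows = []
    for xi in grid:
        q = GrowthParams(mu=p.mu, sigma_sqrt2=p.sigma_sqrt2, c=p.c, k=p.k, x_i=float(xi))
        rows.append((float(xi), quantifier_asymptote(q), initiation_time(q)))
    df = pd.DataFrame(rows, columns=["x_i", "Q_total", "t_i"])
    best = float(df.loc[df["Q_total"].idxmax(), "x_i"])
    return InitiationReport(grid=df, argmax_x_i=best)


def calibrate(
    series: FieldSeries, p: GrowthParams, with_intercept: bool = True
) -> tuple[YieldFit, pd.DataFrame]:
    """Fit the yield factor to a field series; return the fit and the
    quantifier table it was computed from, so the reconstruction is
    inspectable row by row."""
    t = series.data["t"].to_numpy(dtype=float)
    y = series.data["Y"].to_numpy(dtype=float)
    table = quantifier_table(t, p)
    post = t >= initiation_time(p) - 1e-12
    if post.sum() < 3:
        raise ValueError(
            f"need >= 3 samplings at or after initiation (t_i={initiation_time(p):.2f}), "
            f"got {int(post.sum())}"
        )
    fit = fit_yield_factor(np.column_stack([table["Q"].to_numpy(), y]), with_intercept)
    return fit, table
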