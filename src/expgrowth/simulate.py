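"""Season-long trajectories of biomass, nutrient uptake and concentration.

Because the growth model is an analytical solution, a trajectory is a
pointwise closed-form evaluation on a time grid — there is no integration
step and no accumulation of numerical error: Q(t) (clamped to 0 before
initiation), then Y_hat = b + A*Q, then per-element uptake and
concentration through the hyperbolic phase relation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .calibration import YieldFit
from .core import quantifier_table
from .params import GrowthParams
from .phase import PhaseParams, predict_uptake

__all__ = ["simulate_trajectory", "concentration_decline_check"]

log = logging.getLogger(__name__)


def simulate_trajectory(
    p: GrowthParams,
    yf: YieldFit,
    phases: list[PhaseParams],
    t_start: float = 15.0,
    t_stop: float = 32.0,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Dense table of (t, x, Q, Y_hat, <el>_u_hat, <el>_c_hat).

    Where Y_hat <= 0 (possible pre-initiation when b <= 0) the uptake is 0
    and the concentration is reported as its Y -> 0+ limit N_um/K_y, with a
    logged flag: concentration is a ratio and has a finite limit even as
    both numerator and denominator vanish.
    """
    if not t_start < t_stop:
        raise ValueError(f"need t_start < t_stop, got {t_start} >= {t_stop}")
    if not dt > 0:
        raise ValueError(f"need dt > 0, got {dt}")
    times = np.arange(t_start, t_stop + dt / 2, dt)
    out = quantifier_table(times, p)
    yhat = yf.predict(out["Q"].to_numpy())
    out["Y_hat"] = yhat
    nonpos = yhat <= 0
    if np.any(nonpos):
        log.info(
            "Y_hat <= 0 at %d grid points; concentration reported as its Y->0+ limit",
            int(nonpos.sum()),
        )
    for ph in phases:
        up = np.where(nonpos, 0.0, predict_uptake(np.maximum(yhat, 0.0), ph))
        conc = np.where(nonpos, ph.N_um / ph.K_y, ph.N_um / (ph.K_y + yhat))
        out[f"{ph.element}_u_hat"] = up
        out[f"{ph.element}_c_hat"] = conc
    return out


def concentration_decline_check(traj: pd.DataFrame, element: str) -> tuple[bool, int | None]:
    """Check that predicted concentration never increases after initiation.

    The decline reflects the shift from nutrient-rich light-gathering tissue
    in young plants to structural tissue later.  Returns (ok, index of the
    first violating row or None).
    """
    col = f"{element}_c_hat"
    if col not in traj.columns:
        raise KeyError(f"trajectory has no concentration column for element {element!r}")
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    conc = traj[col].to_numpy(dtype=float)
    post = traj["Q"].to_numpy() > 0
    idx = np.flatnonzero(post)
    for a, b in zip(idx[:-1], idx[1:]):
        if conc[b] > conc[a] + 1e-12:
            return False, int(b)
    return True, None
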