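"""Synthetic field datasets with known truth, and the recovery harness.

The generator emulates the structure of a season of destructive samplings:
5-10 dates, a yield that follows Y = b + A*Q(t) and per-element uptakes
that follow the hyperbolic phase relation, perturbed by observational
noise.  Because the truth is retained, every stage of the estimation
pipeline can be tested end to end (generate -> recover is the identity at
zero noise, and recovery error should shrink with the noise level).

Noise is observational only: multiplicative lognormal by default (field
biomass errors scale with magnitude), mean-preserving, applied
independently to Y and to each element's uptake.  Concentration is never
noised on its own — it is always recomputed as uptake/Y, as in the real
bookkeeping.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .calibration import YieldFit, calibrate
from .core import quantifier_table
from .params import GrowthParams
from .phase import PhaseParams, fit_phase, predict_uptake
from .series import FieldSeries

__all__ = ["SynthConfig", "generate", "recover", "fixture_florence", "FLORENCE_PLANTING"]

#: Planting metadata of the Florence season (April 2).
FLORENCE_PLANTING = {"t": 15.0, "note": "planting (April 2)"}

_NOISE_MODELS = ("multiplicative-lognormal", "additive-gaussian", "none")


@dataclass(frozen=True)
class SynthConfig:
    """Ground truth and observation model for one synthetic dataset."""

    growth: GrowthParams
    A: float
    b: float
    phases: tuple[PhaseParams, ...]
    sampling_times: tuple[float, ...]
    noise_cv: float = 0.0
    noise_model: str = "multiplicative-lognormal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.noise_model not in _NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}; expected {_NOISE_MODELS}")
        times = np.asarray(self.sampling_times, dtype=float)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("sampling_times must be strictly increasing")


def _stream(seed: int, label: str) -> np.random.Generator:
    # Substream keyed by (seed, label) so adding an element never perturbs
    # the draws of the others.
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(label.encode())]))


def _noised(truth: np.ndarray, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.noise_model == "none" or cfg.noise_cv == 0:
        return truth.copy()
    if cfg.noise_model == "multiplicative-lognormal":
        s = np.sqrt(np.log1p(cfg.noise_cv**2))
        mult = np.exp(rng.normal(-0.5 * s * s, s, size=truth.shape))
        return truth * mult
    # additive-gaussian: sd scales with the true magnitude so cv keeps meaning
    return truth + rng.normal(0.0, cfg.noise_cv * np.abs(truth), size=truth.shape)


def generate(cfg: SynthConfig) -> FieldSeries:
    """Draw one synthetic field series under the configured truth and noise.

    Rows whose true yield is <= 0 (pre-initiation with b <= 0) are emitted
    with uptake 0 and flagged in a ``pre_initiation`` column rather than
    dropped, mirroring how a real planting row appears in the record.
    """
    times = np.asarray(cfg.sampling_times, dtype=float)
    table = quantifier_table(times, cfg.growth)
    y_true = cfg.b + cfg.A * table["Q"].to_numpy()
    degenerate = y_true <= 0

    y_obs = np.where(degenerate, 0.0, _noised(np.maximum(y_true, 0.0), cfg, _stream(cfg.seed, "Y")))
    data = pd.DataFrame({"t": times, "Y": y_obs})
    truth = {"A": cfg.A, "b": cfg.b, "growth": cfg.growth, "Y_true": y_true, "phases": {}}
    for ph in cfg.phases:
        u_true = np.where(degenerate, 0.0, predict_uptake(np.maximum(y_true, 0.0), ph))
        u_obs = np.where(degenerate, 0.0, _noised(u_true, cfg, _stream(cfg.seed, f"uptake:{ph.element}")))
        data[f"{ph.element}_u"] = u_obs
        with np.errstate(divide="ignore", invalid="ignore"):
            data[f"{ph.element}_c"] = np.where(y_obs > 0, u_obs / y_obs, np.nan)
        truth["phases"][ph.element] = ph
    if degenerate.any():
        data["pre_initiation"] = degenerate
    return FieldSeries(data=data, provenance=f"synthetic(seed={cfg.seed})", truth=truth)


def recover(series: FieldSeries, p: GrowthParams) -> tuple[YieldFit, list[PhaseParams]]:
    """Run the full estimation pipeline on a series.

    Calibrates the yield factor against the growth quantifier, then fits the
    hyperbolic phase relation for every element present.  Rows with
    non-positive Y or uptake are excluded from the phase fits (linearization
    needs ratios).
    """
    usable = series.data[series.data["Y"] > 0]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable rows, got {len(usable)}")
    work = FieldSeries(data=usable.reset_index(drop=True), provenance=series.provenance)
    yf, _ = calibrate(work, p)
    fits = [fit_phase(work.observations(el), el) for el in work.elements]
    return yf, fits


def fixture_florence() -> tuple[FieldSeries, pd.DataFrame]:
    """The Florence, SC corn dataset as shipped fixtures.

    Returns the sampling series (6 rows; t, Y and N/P/K uptake and
    concentration) and the published correlation table (7 finite rows of
    t, x, erf x, exp(-x^2), Q, Y — including the t=28.8 row that has no
    counterpart in the sampling series).  Values are verbatim from the
    printed tables; the correlation table is the source's own rendering,
    not a recomputation.
    """
    base = resources.files("expgrowth.data")
    with resources.as_file(base / "florence1982_table1.csv") as fp:
        t1 = pd.read_csv(fp)
    with resources.as_file(base / "florence1982_table2.csv") as fp:
        t2 = pd.read_csv(fp)
    series = FieldSeries(data=t1, provenance="fixture", truth={"planting": dict(FLORENCE_PLANTING)})
    return series, t2
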