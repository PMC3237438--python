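"""Container for field-sampling time series (the shape of the published data).

A FieldSeries holds one row per sampling date: calendar time ``t`` (wk),
biomass yield ``Y`` (Mg/ha), and, per element, cumulative uptake ``<el>_u``
(kg/ha) and concentration ``<el>_c`` (g/kg).  Concentration is bookkeeping,
not an independent measurement: it is always uptake/Y.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FieldSeries", "NutrientObservation"]


@dataclass(frozen=True)
class NutrientObservation:
    """One sampling row for one element."""

    t: float
    Y: float
    uptake: float

    @property
    def concentration(self) -> float:
        """Uptake per unit biomass, g/kg (uptake kg/ha over Y Mg/ha)."""
        return self.uptake / self.Y


@dataclass
class FieldSeries:
    """Observed (or synthetic) sampling series.

    ``data`` columns: ``t``, ``Y``, plus ``<el>_u`` (and optionally
    ``<el>_c``) per element.  ``provenance`` records where the rows came
    from: ``"fixture"``, ``"synthetic(seed=...)"`` or ``"user"``.
    """

    data: pd.DataFrame
    provenance: str = "user"
    truth: dict = field(default_factory=dict)  # ground-truth params for synthetic series

    def __post_init__(self) -> None:
        for col in ("t", "Y"):
            if col not in self.data.columns:
                raise ValueError(f"FieldSeries requires a {col!r} column")

    @property
    def elements(self) -> list[str]:
        return [c[:-2] for c in self.data.columns if c.endswith("_u")]

    def __len__(self) -> int:
        return len(self.data)

    def observations(self, element: str) -> list[NutrientObservation]:
        """Rows for one element as NutrientObservation records."""
        col = f"{element}_u"
        if col not in self.data.columns:
            raise KeyError(f"no uptake column for element {element!r}")
        return [
            NutrientObservation(t=float(r["t"]), Y=float(r["Y"]), uptake=float(r[col]))
            for _, r in self.data.iterrows()
        ]

    def with_concentrations(self) -> pd.DataFrame:
        """Copy of the data with ``<el>_c`` recomputed as uptake/Y."""
        out = self.data.copy()
        y = out["Y"].to_numpy(dtype=float)
        for el in self.elements:
            with np.errstate(divide="ignore", invalid="ignore"):
                out[f"{el}_c"] = np.where(y > 0, out[f"{el}_u"] / y, np.nan)
        return out
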