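"""Growth-model parameter sets and their on-disk format.

The expanded growth model is driven by five parameters: the mean ``mu`` and
spread ``sigma_sqrt2`` (= sqrt(2)*sigma) of the seasonal solar-energy
distribution, an aging coefficient ``c``, a biomass partition coefficient
``k`` (light-gathering vs structural tissue), and the dimensionless
initiation time ``x_i`` at which significant growth begins.  Parameter sets
are named and versioned; the corn calibration for Florence, SC (1982) ships
as the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

__all__ = ["GrowthParams", "FLORENCE_1982", "load_params", "save_params", "get_params"]

_FIELD_NAMES = ("mu", "sigma_sqrt2", "c", "k", "x_i")


@dataclass(frozen=True)
class GrowthParams:
    """Parameter set of the expanded growth model.

    Parameters
    ----------
    mu : float
        Time of the mean of the solar-energy distribution, weeks since Jan. 1.
    sigma_sqrt2 : float
        Time spread sqrt(2)*sigma of the energy distribution, weeks. Must be > 0.
    c : float
        Aging coefficient, 1/wk. Must be >= 0.
    k : float
        Dimensionless partition coefficient between light-gathering and
        structural plant components. Must be >= 0.
    x_i : float
        Dimensionless time of growth initiation.
    """

    mu: float
    sigma_sqrt2: float
    c: float = 0.0
    k: float = 0.0
    x_i: float = 0.0

    def __post_init__(self) -> None:
        for name in _FIELD_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma_sqrt2 <= 0:
            raise ValueError(f"sigma_sqrt2 must be > 0, got {self.sigma_sqrt2}")
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if self.k < 0:
            raise ValueError(f"k must be >= 0, got {self.k}")


#: Corn calibration for Florence, SC, 1982 season (planting April 2, t = 15.0 wk).
FLORENCE_1982 = GrowthParams(mu=26.0, sigma_sqrt2=8.0, c=0.2, k=5.0, x_i=0.0)

_NAMED_SETS = {"florence-1982": "florence-1982.params"}


def load_params(path: str | Path) -> GrowthParams:
    """Read a ``key = value`` parameter file into a :class:`GrowthParams`.

    Lines starting with ``#`` and blank lines are ignored.  Unknown keys are
    rejected so a typo cannot silently fall back to a default.
    """
    values: dict[str, float] = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in _FIELD_NAMES:
            raise ValueError(
                f"{path}:{lineno}: unknown parameter {key!r}; expected one of {_FIELD_NAMES}"
            )
        try:
            values[key] = float(val.strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value {val.strip()!r}") from exc
    missing = {"mu", "sigma_sqrt2"} - values.keys()
    if missing:
        raise ValueError(f"{path}: missing required parameter(s) {sorted(missing)}")
    return GrowthParams(**values)


def save_params(p: GrowthParams, path: str | Path) -> None:
    """Write a parameter set in the flat ``key = value`` format."""
    lines = [f"{f.name} = {getattr(p, f.name)!r}" for f in fields(p)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def get_params(name_or_path: str | Path) -> GrowthParams:
    """Resolve a named parameter set (e.g. ``florence-1982``) or a file path."""
    name = str(name_or_path)
    if name in _NAMED_SETS:
        ref = resources.files("expgrowth.data") / _NAMED_SETS[name]
        with resources.as_file(ref) as fp:
            return load_params(fp)
    path = Path(name_or_path)
    if path.exists():
        return load_params(path)
    raise ValueError(
        f"unknown parameter set {name!r}: not a named set "
        f"({sorted(_NAMED_SETS)}) and no such file"
    )
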