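"""Direct age standardization of mortality rates.

Directly standardized rates weight each age band's death rate by a fixed
standard population so that areas with different age pyramids become
comparable:

    ASR = sum_b  w_b * (deaths_b / person_years_b) * 100,000

with the ``w_b`` summing to one. The default standard is the WHO world
standard population (18 five-year bands, 0-4 through 85+).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "StandardPopulation",
    "direct_standardize",
    "add_adjusted_rate",
    "aggregate_period",
    "band_columns",
]


def band_columns(bands: Sequence[str], prefix: str) -> list[str]:
    """Column names for per-band quantities, e.g. ``py_0-4`` or ``deaths_85+``."""
    return [f"{prefix}_{b}" for b in bands]


@dataclass(frozen=True)
class StandardPopulation:
    """A standard population: ordered age-band labels and normalized weights.

    Weights are renormalized to sum to one on construction; a renormalization
    beyond floating-point noise is logged as a warning.
    """

    bands: tuple[str, ...]
    weights: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.bands) != w.size:
            raise SchemaError(
                f"{len(self.bands)} bands but {w.size} weights"
            )
        if (w < 0).any():
            raise DataError("standard-population weights must be non-negative")
        total = w.sum()
        if total <= 0:
            raise DataError("standard-population weights sum to zero")
        if abs(total - 1.0) > 1e-9:
            logger.warning(
                "standard-population weights sum to %.6g; renormalizing", total
            )
        object.__setattr__(self, "weights", w / total)
        object.__setattr__(self, "bands", tuple(self.bands))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StandardPopulation":
        """Read a two-column (band, weight) CSV."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise SchemaError("standard-population CSV needs (band, weight) columns")
        return cls(tuple(df.iloc[:, 0].astype(str)), df.iloc[:, 1].to_numpy(float))

    @classmethod
    def who_world(cls) -> "StandardPopulation":
        """The bundled WHO world standard population (2000-2025)."""
        return _who_world_cached()


from functools import lru_cache


@lru_cache(maxsize=1)
def _who_world_cached() -> "StandardPopulation":
    from .datasets import load_who_standard_weights

    df = load_who_standard_weights()
    return StandardPopulation(tuple(df["band"]), df["weight"].to_numpy(float))


def direct_standardize(
    deaths: np.ndarray | Sequence[float],
    person_years: np.ndarray | Sequence[float],
    std: StandardPopulation,
) -> float | np.ndarray:
    """Directly age-standardized rate per 100,000.

    Parameters
    ----------
    deaths, person_years
        Per-band arrays, either 1-D (one unit) or 2-D ``(n_units, n_bands)``.
    std
        Standard population whose band count must match.

    Bands with zero person-years and zero deaths contribute zero to the sum;
    deaths in a band with no person-years are a data error.
    """
    d = np.atleast_2d(np.asarray(deaths, dtype=float))
    py = np.atleast_2d(np.asarray(person_years, dtype=float))
    if d.shape != py.shape:
        raise SchemaError(f"deaths shape {d.shape} != person-years shape {py.shape}")
    if d.shape[1] != len(std.bands):
        raise SchemaError(
            f"{d.shape[1]} band columns but standard population has {len(std.bands)}"
        )
    if (d < 0).any():
        raise DataError("negative death counts")
    if (py < 0).any():
        raise DataError("negative person-years")
    bad = (py == 0) & (d > 0)
    if bad.any():
        raise DataError("deaths observed in a band with zero person-years")
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(py > 0, d / np.where(py > 0, py, 1.0), 0.0)
    asr = rates @ std.weights * 1e5
    return float(asr[0]) if np.asarray(deaths).ndim == 1 else asr


def add_adjusted_rate(
    units: pd.DataFrame, std: StandardPopulation, out_col: str = "adjusted_rate"
) -> pd.DataFrame:
    """Attach a directly standardized rate column computed from the table's
    ``deaths_<band>`` / ``py_<band>`` columns."""
    dcols = band_columns(std.bands, "deaths")
    pcols = band_columns(std.bands, "py")
    missing = [c for c in dcols + pcols if c not in units.columns]
    if missing:
        raise SchemaError(f"unit table lacks band columns: {missing[:4]}...")
    out = units.copy()
    out[out_col] = direct_standardize(
        units[dcols].to_numpy(float), units[pcols].to_numpy(float), std
    )
    return out


def aggregate_period(
    yearly: Sequence[pd.DataFrame],
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Sum per-band deaths and person-years over a period of yearly tables.

    All tables must share the same unit set (``unit_id``). With
    ``strict=False`` a unit absent from some years contributes zero for
    those years instead of raising.
    """
    if not yearly:
        raise DataError("no yearly tables supplied")
    base = yearly[0]
    if "unit_id" not in base.columns:
        raise SchemaError("yearly tables need a unit_id column")
    ids = set(base["unit_id"])
    sum_cols = [
        c for c in base.columns if c.startswith("deaths_") or c.startswith("py_")
    ]
    acc = base.set_index("unit_id")[sum_cols].astype(float)
    for t in yearly[1:]:
        other = set(t["unit_id"])
        if other != ids:
            if strict:
                raise DataError(
                    f"unit sets differ across years ({len(ids ^ other)} mismatched)"
                )
            logger.warning("unit sets differ across years; zero-filling")
        cur = t.set_index("unit_id")[sum_cols].astype(float)
        acc = acc.add(cur, fill_value=0.0)
    static = [c for c in base.columns if c not in sum_cols and c != "unit_id"]
    out = base.set_index("unit_id")[static].join(acc).reset_index()
    if "population" in out.columns:
        pcols = [c for c in sum_cols if c.startswith("py_")]
        out["population"] = out[pcols].sum(axis=1)
    return out
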