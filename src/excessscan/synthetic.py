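"""Seeded synthetic municipality-level mortality data.

Emulates the statistical structure of a national ecological cancer-mortality
study: a few thousand municipalities with centroid coordinates, log-normal
populations split into five-year age bands, a block-correlated covariate
matrix of census-style proportions, covariate-driven baseline
age-standardized rates near 98.5 per 100,000, Poisson death counts, planted
multiplicative excess-risk disks, and missing-completely-at-random covariate
cells. Everything is reproducible from a single integer seed.

The generator produces points, not polygons, and makes no attempt to match
real census marginals; it exists so that every downstream stage (imputation,
out-of-fold prediction, scan, reporting) can be exercised and validated
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, ndtr

from ._geo import haversine_km
from .errors import ConfigurationError, DataError

__all__ = [
    "DEFAULT_AGE_BANDS",
    "PlantedCluster",
    "SimConfig",
    "generate_units",
    "simulate_deaths",
    "inject_missingness",
    "regression_outcome",
    "write_units",
    "read_units",
    "covariate_columns",
]

#: 18 five-year bands matching the WHO world-standard convention.
DEFAULT_AGE_BANDS: tuple[str, ...] = tuple(
    [f"{5 * i}-{5 * i + 4}" for i in range(17)] + ["85+"]
)

_BAND_MIDPOINTS = np.array([5.0 * i + 2.5 for i in range(17)] + [90.0])

# Cancer mortality rises roughly exponentially with age; the national age
# pyramid declines with age. Both shapes are fixed conventions of the
# generator, normalized at use.
_PYRAMID_SHAPE = np.exp(-0.030 * _BAND_MIDPOINTS)
_AGE_RATE_SHAPE = np.exp(0.085 * _BAND_MIDPOINTS)


@dataclass(frozen=True)
class PlantedCluster:
    """A disk of elevated risk: ground truth for scan recovery tests."""

    center: tuple[float, float]  # (lat, lon) decimal degrees
    radius_km: float
    relative_risk: float

    def __post_init__(self) -> None:
        if self.radius_km <= 0:
            raise ConfigurationError("planted cluster radius must be positive")
        if self.relative_risk <= 0:
            raise ConfigurationError("planted relative risk must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic dataset.

    Defaults mirror the study design the generator emulates: 5,565 units,
    40 covariates, a Brazil-sized bounding box, log-normal populations
    (median ~18k persons), and a baseline-rate link calibrated to a national
    mean age-standardized rate near 98.5 per 100,000.
    """

    n_units: int = 5565
    n_covariates: int = 40
    bbox: tuple[float, float, float, float] = (-34.0, 5.0, -74.0, -34.0)
    population_distribution: tuple[float, float] = (9.8, 1.2)  # log-mean, log-sd
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    baseline_rate_fn: str = "saturating"  # "linear" | "saturating"
    clusters: tuple[PlantedCluster, ...] = ()
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 2:
            raise ConfigurationError("n_units must be at least 2")
        if self.n_covariates < 1:
            raise ConfigurationError("n_covariates must be positive")
        lat_min, lat_max, lon_min, lon_max = self.bbox
        if not (lat_min < lat_max and lon_min < lon_max):
            raise ConfigurationError(f"bbox not well-ordered: {self.bbox}")
        if not 0.0 <= self.missing_fraction <= 1.0:
            raise ConfigurationError("missing_fraction must lie in [0, 1]")
        if self.baseline_rate_fn not in ("linear", "saturating"):
            raise ConfigurationError(
                f"unknown baseline_rate_fn {self.baseline_rate_fn!r}"
            )
        object.__setattr__(self, "age_bands", tuple(self.age_bands))
        object.__setattr__(
            self, "clusters", tuple(
                c if isinstance(c, PlantedCluster) else PlantedCluster(**c)
                for c in self.clusters
            )
        )

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["clusters"] = [asdict(c) for c in self.clusters]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["clusters"] = tuple(PlantedCluster(
            center=tuple(c["center"]), radius_km=c["radius_km"],
            relative_risk=c["relative_risk"]) for c in d.get("clusters", []))
        for key in ("bbox", "population_distribution", "age_bands"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def covariate_columns(frame_or_n) -> list[str]:
    """Covariate column names (``x_00``, ``x_01``, ...)."""
    if isinstance(frame_or_n, pd.DataFrame):
        return [c for c in frame_or_n.columns if c.startswith("x_")]
    return [f"x_{j:02d}" for j in range(int(frame_or_n))]


def _integer_split(population: np.ndarray, shares: np.ndarray) -> np.ndarray:
    """Largest-remainder rounding of ``population * shares`` so each row sums
    exactly to its population."""
    raw = population[:, None] * shares
    base = np.floor(raw)
    short = (population - base.sum(axis=1)).astype(int)
    order = np.argsort(-(raw - base), axis=1, kind="stable")
    out = base.astype(np.int64)
    for i in range(out.shape[0]):
        out[i, order[i, : short[i]]] += 1
    return out


def _block_correlated_uniforms(rng, n, p, block=5, rho=0.5) -> np.ndarray:
    """Census-style covariates: exchangeable correlation ``rho`` within blocks
    of ``block`` Gaussians, pushed through the normal CDF onto [0, 1]."""
    z = np.empty((n, p))
    for start in range(0, p, block):
        width = min(block, p - start)
        shared = rng.standard_normal(n)[:, None]
        own = rng.standard_normal((n, width))
        z[:, start : start + width] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
    return ndtr(z)


def _baseline_asr(x: np.ndarray, link: str) -> np.ndarray:
    """Map [0,1] covariates to a baseline age-standardized rate per 100,000.

    Coefficients decay over the first covariates so that a handful carry
    most of the signal, as in real census blocks. Both links are centered to
    a national mean near 98.5.
    """
    p = x.shape[1]
    k = min(10, p)
    if link == "linear":
        beta = 40.0 / (1.0 + np.arange(k))
        asr = 98.5 + (x[:, :k] - 0.5) @ beta * 2.0
    else:  # saturating
        beta = 6.0 / (1.0 + np.arange(k))
        g = (x[:, :k] - 0.5) @ beta * 2.0
        asr = 58.5 + 80.0 * expit(g)
    return np.maximum(asr, 5.0)


def band_rate_shape(std_weights: np.ndarray | None = None) -> np.ndarray:
    """Age-specific multipliers s_b with sum_b w_b * s_b = 1, so a unit's
    true directly standardized rate equals its baseline rate exactly."""
    if std_weights is None:
        from .standardize import StandardPopulation

        std_weights = StandardPopulation.who_world().weights
    return _AGE_RATE_SHAPE / float(_AGE_RATE_SHAPE @ std_weights)


def generate_units(config: SimConfig) -> pd.DataFrame:
    """Draw the unit table: coordinates, populations, age split, covariates,
    and the true baseline rate (column ``true_rate``, sidecar-only on disk).

    Deterministic: the same config (including seed) yields an identical table.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_units
    lat_min, lat_max, lon_min, lon_max = config.bbox
    lat = rng.uniform(lat_min, lat_max, n)
    lon = rng.uniform(lon_min, lon_max, n)
    mu, sigma = config.population_distribution
    population = np.maximum(1, rng.lognormal(mu, sigma, n).astype(np.int64))

    shares = _PYRAMID_SHAPE / _PYRAMID_SHAPE.sum()
    pyramid = rng.dirichlet(shares * 300.0, size=n)
    py = _integer_split(population, pyramid)

    x = _block_correlated_uniforms(rng, n, config.n_covariates)
    true_rate = _baseline_asr(x, config.baseline_rate_fn)

    df = pd.DataFrame(
        {
            "unit_id": [f"U{i:05d}" for i in range(n)],
            "name": [f"Unit {i}" for i in range(n)],
            "lat": lat,
            "lon": lon,
            "population": population,
        }
    )
    for b, col in zip(config.age_bands, py.T):
        df[f"py_{b}"] = col
    for j in range(config.n_covariates):
        df[f"x_{j:02d}"] = x[:, j]
    df["true_rate"] = true_rate
    if config.missing_fraction > 0:
        df = inject_missingness(df, config.missing_fraction, seed=config.seed + 1)
    return df


def planted_relative_risk(units: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """Per-unit multiplicative risk from the planted disks (great-circle
    containment; overlapping disks multiply)."""
    rr = np.ones(len(units))
    for cl in config.clusters:
        d = haversine_km(units["lat"].to_numpy(), units["lon"].to_numpy(), *cl.center)
        rr[d <= cl.radius_km] *= cl.relative_risk
    return rr


def simulate_deaths(units: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Draw Poisson age-band death counts.

    Band means are ``person_years * true_rate * s_b / 100,000`` scaled by the
    planted relative risk for units inside any planted disk, where the age
    shape ``s_b`` is normalized against the WHO standard so each unit's true
    ASR equals ``true_rate * rr_true``. Adds ``deaths_<band>``, ``rr_true``
    and ``in_cluster`` columns. Uses a stream derived from the config seed,
    independent of the one used by :func:`generate_units`.
    """
    py_cols = [f"py_{b}" for b in config.age_bands]
    py = units[py_cols].to_numpy(float)
    if (py < 0).any():
        raise DataError("negative person-years")
    rng = np.random.default_rng([1, config.seed])
    shape = band_rate_shape()
    rr = planted_relative_risk(units, config)
    lam = py * (units["true_rate"].to_numpy()[:, None] * shape[None, :] / 1e5)
    lam *= rr[:, None]
    deaths = rng.poisson(lam)
    out = units.copy()
    for b, col in zip(config.age_bands, deaths.T):
        out[f"deaths_{b}"] = col
    out["rr_true"] = rr
    out["in_cluster"] = rr > 1.0
    return out


def inject_missingness(units: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Mask exactly ``round(fraction * n_cells)`` covariate cells MCAR.

    Coordinates, populations, outcomes and age columns are never masked.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigurationError("missing fraction must lie in [0, 1]")
    cols = covariate_columns(units)
    n_cells = len(units) * len(cols)
    n_mask = int(round(fraction * n_cells))
    if n_mask == 0:
        return units.copy()
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_cells, size=n_mask, replace=False)
    out = units.copy()
    block = out[cols].to_numpy(float)
    block[np.unravel_index(flat, block.shape)] = np.nan
    out[cols] = block
    return out


def regression_outcome(
    covariates: np.ndarray | pd.DataFrame,
    signal_fraction: float,
    seed: int,
    *,
    mean: float = 98.5,
    scale: float = 17.0,
) -> np.ndarray:
    """An outcome with a known, exactly calibrated signal fraction.

    Builds a smooth nonlinear function f of the covariates and adds Gaussian
    noise rescaled so that empirically var(f) / var(y) equals
    ``signal_fraction``; the best attainable out-of-fold R-squared on the
    returned outcome is therefore the signal fraction itself. Used as the
    generative oracle for model-performance tests.
    """
    if not 0.0 <= signal_fraction <= 1.0:
        raise ConfigurationError("signal_fraction must lie in [0, 1]")
    x = covariates[covariate_columns(covariates)].to_numpy(float) \
        if isinstance(covariates, pd.DataFrame) else np.asarray(covariates, float)
    rng = np.random.default_rng(seed)
    k = min(6, x.shape[1])
    beta = 1.0 / (1.0 + np.arange(k))
    f = (x[:, :k] - 0.5) @ beta + 0.6 * np.sin(2.5 * x[:, 0]) * x[:, min(1, k - 1)]
    f = f - f.mean()
    if signal_fraction == 0.0:
        f = np.zeros_like(f)
        noise = rng.standard_normal(len(f))
        return mean + scale * noise / noise.std()
    f = f / f.std()
    noise = rng.standard_normal(len(f))
    noise = noise - noise.mean() - f * (noise @ f) / (f @ f)  # orthogonalize
    noise = noise / noise.std() * np.sqrt((1.0 - signal_fraction) / signal_fraction)
    y = f + noise
    return mean + scale * y / y.std()


_TRUTH_COLS = ("true_rate", "rr_true", "in_cluster")


def write_units(units: pd.DataFrame, path: str | Path) -> None:
    """Write the unit table as CSV; ground-truth columns (planted rates and
    membership) go to a ``*_truth.csv`` sidecar for test harnesses."""
    path = Path(path)
    truth = [c for c in _TRUTH_COLS if c in units.columns]
    units.drop(columns=truth).to_csv(path, index=False)
    if truth:
        sidecar = path.with_name(path.stem + "_truth.csv")
        units[["unit_id", *truth]].to_csv(sidecar, index=False)


def read_units(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    sidecar = Path(path).with_name(Path(path).stem + "_truth.csv")
    if sidecar.exists():
        df = df.merge(pd.read_csv(sidecar), on="unit_id", how="left")
    return df
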