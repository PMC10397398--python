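"""Kulldorff circular spatial scan statistic, Poisson model, high-rate scan.

The scan slides variable-size circular windows over unit centroids. A
window with observed cases c and expected cases mu, out of C total cases,
scores the log-likelihood ratio

    LLR = c ln(c / mu) + (C - c) ln((C - c) / (C - mu))   if c > mu, else 0

and the window maximizing the LLR is the most likely cluster. Significance
comes from Monte Carlo replication: the C cases are redistributed under the
null in proportion to the expected counts and the replicate maxima form
the reference distribution, so the smallest attainable p-value is
1 / (n_replicates + 1).

Unlike the classical population-proportional scan, the expected counts here
come from a covariate-based model surface, so detected clusters represent
mortality in excess of what local sociodemographic characteristics predict.
Because observed "counts" are derived from age-adjusted rates they are
real-valued; the LLR is evaluated on them directly (the Poisson likelihood
formula is well-defined for non-integer values) and the multinomial null
rounds the total to an integer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._geo import DISTANCE_METRICS
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "ScanConfig",
    "Window",
    "Cluster",
    "pseudo_counts",
    "build_windows",
    "poisson_llr",
    "scan",
    "monte_carlo_pvalues",
]


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    ``max_pop_fraction`` bounds the window population (default 0.3% of the
    total, the setting suited to a country with sparse rural population;
    the classical rule of thumb caps it at 50%). ``n_replicates`` defaults
    to 999, giving a p-value floor of 0.001. The scan is one-sided
    (high-rate) only.
    """

    max_pop_fraction: float = 0.003
    n_replicates: int = 999
    direction: str = "high"
    null_model: str = "multinomial"  # "multinomial" | "poisson"
    alpha: float = 0.05
    seed: int = 0
    distance_metric: str = "haversine"  # "haversine" | "euclidean"

    def __post_init__(self) -> None:
        if not 0.0 < self.max_pop_fraction <= 0.5:
            raise ConfigurationError("max_pop_fraction must lie in (0, 0.5]")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if self.direction != "high":
            raise ConfigurationError("only the high-rate scan is implemented")
        if self.null_model not in ("multinomial", "poisson"):
            raise ConfigurationError("null_model must be multinomial or poisson")
        if self.distance_metric not in DISTANCE_METRICS:
            raise ConfigurationError(f"unknown metric {self.distance_metric!r}")


@dataclass(frozen=True)
class Window:
    """A circular window: a center unit and its members ordered by distance."""

    center: int  # positional index of the center unit
    members: tuple[int, ...]  # positional indices, nearest first (center first)
    population: float

    def __post_init__(self) -> None:
        if self.center not in self.members:
            raise ConfigurationError("window center must be a member")


@dataclass
class Cluster:
    """A reported cluster: window, score, Monte Carlo p-value and rank."""

    window: Window
    llr: float
    p_value: float
    rank: int
    observed: float
    expected: float
    observed_rate: float  # per 100,000
    expected_rate: float  # per 100,000
    significant: bool

    @property
    def members(self) -> tuple[int, ...]:
        return self.window.members


def pseudo_counts(
    units: pd.DataFrame, surface
) -> tuple[np.ndarray, np.ndarray]:
    """Observed and expected case counts from rates and populations.

    observed_i = adjusted_rate_i x pop_i / 100,000 and likewise expected
    from the model-predicted rate; expected is then rescaled so its total
    matches the observed total (the Poisson scan conditions on the total).
    ``surface`` may be an ExpectedSurface or a frame with unit_id and
    predicted_rate; alignment is by unit_id.
    """
    frame = surface.frame if hasattr(surface, "frame") else surface
    merged = units.merge(
        frame[["unit_id", "predicted_rate"]], on="unit_id", how="left",
        suffixes=("", "_surf"),
    )
    pred_col = "predicted_rate_surf" if "predicted_rate_surf" in merged else "predicted_rate"
    if merged[pred_col].isna().any():
        raise DataError("expected surface is missing units")
    pop = merged["population"].to_numpy(float)
    observed = merged["adjusted_rate"].to_numpy(float) * pop / 1e5
    expected = merged[pred_col].to_numpy(float) * pop / 1e5
    total_exp = expected.sum()
    if total_exp <= 0:
        raise DataError("total expected count is zero")
    expected = expected * (observed.sum() / total_exp)
    return observed, expected


def build_windows(units: pd.DataFrame, config: ScanConfig) -> list[Window]:
    """All circular windows within the population bound.

    For each center, units are added in increasing distance (ties broken by
    unit_id ascending) while the cumulative population stays within
    ``max_pop_fraction`` of the total; every prefix is a window. Windows
    identical as member sets across centers are deduplicated. A center
    whose own population already exceeds the bound yields no window there.
    """
    n = len(units)
    if n < 2:
        raise DataError("need at least 2 units with coordinates")
    lat = units["lat"].to_numpy(float)
    lon = units["lon"].to_numpy(float)
    pop = units["population"].to_numpy(float)
    if np.isnan(lat).any() or np.isnan(lon).any():
        raise DataError("units with missing coordinates")
    dist_fn = DISTANCE_METRICS[config.distance_metric]
    bound = config.max_pop_fraction * pop.sum()
    # tie-break: ascending unit_id
    id_rank = np.argsort(np.argsort(units["unit_id"].astype(str).to_numpy(), kind="stable"))
    windows: list[Window] = []
    seen: set[frozenset] = set()
    for center in range(n):
        d = dist_fn(lat[center], lon[center], lat, lon)
        rank = id_rank.copy()
        rank[center] = -1  # the center leads its own window even under ties
        order = np.lexsort((rank, d))
        csum = np.cumsum(pop[order])
        n_prefix = int(np.searchsorted(csum, bound, side="right"))
        if n_prefix == 0:
            logger.debug("unit %d alone exceeds the population bound", center)
            continue
        for L in range(1, n_prefix + 1):
            members = tuple(int(i) for i in order[:L])
            key = frozenset(members)
            if key in seen:
                continue
            seen.add(key)
            windows.append(Window(center=center, members=members,
                                  population=float(csum[L - 1])))
    if not windows:
        logger.warning("no window satisfies the population bound")
    return windows


def poisson_llr(c, mu, C):
    """High-rate Poisson log-likelihood ratio; 0 unless c > mu.

    Vectorized over c and mu. Uses the convention 0 ln 0 = 0 (covers c = C).
    """
    c = np.asarray(c, float)
    mu = np.asarray(mu, float)
    if np.any((mu <= 0) & (c > 0)):
        raise DataError("expected count must be positive where cases occur")
    with np.errstate(divide="ignore", invalid="ignore"):
        inside = np.where(c > 0, c * np.log(np.where(c > 0, c, 1.0) / mu), 0.0)
        rem = C - c
        rem_mu = C - mu
        outside = np.where(
            rem > 0, rem * np.log(np.where(rem > 0, rem, 1.0) / rem_mu), 0.0
        )
    llr = np.where(c > mu, inside + outside, 0.0)
    return float(llr) if llr.ndim == 0 else llr


def _window_sums(values: np.ndarray, windows: Sequence[Window]) -> np.ndarray:
    """Sum ``values`` over each window's members.

    ``values`` may be 1-D (n_units,) or 2-D (n_units, R); returns
    (n_windows,) or (n_windows, R).
    """
    out = np.empty((len(windows),) + values.shape[1:])
    for i, w in enumerate(windows):
        out[i] = values[list(w.members)].sum(axis=0)
    return out


def _max_llr(obs_mat: np.ndarray, mu_w: np.ndarray, windows, C: float) -> np.ndarray:
    """Per-column maximum LLR over all windows for an (n_units, R) matrix."""
    c_w = _window_sums(obs_mat, windows)
    llr = poisson_llr(c_w, mu_w[:, None], C)
    return llr.max(axis=0)


def monte_carlo_pvalues(
    llrs: Sequence[float],
    windows: Sequence[Window],
    expected: np.ndarray,
    C: float,
    config: ScanConfig,
) -> np.ndarray:
    """Monte Carlo p-values for cluster LLRs against the null maximum.

    Each replicate redistributes the C cases under the null — multinomial
    over units with probabilities expected/C (C rounded to an integer), or
    independent Poissons with means ``expected`` — and records the maximum
    LLR over all windows. Every cluster is compared against this same
    max-LLR distribution: p = (1 + #{max >= LLR}) / (R + 1).
    """
    expected = np.asarray(expected, float)
    rng = np.random.default_rng(config.seed)
    R = config.n_replicates
    if config.null_model == "multinomial":
        total = int(round(C))
        obs_mat = rng.multinomial(total, expected / expected.sum(), size=R).T.astype(float)
    else:
        obs_mat = rng.poisson(expected[:, None].repeat(R, axis=1)).astype(float)
    mu_w = _window_sums(expected, windows)
    null_max = _max_llr(obs_mat, mu_w, windows, C)
    llrs = np.asarray(llrs, float)
    exceed = (null_max[None, :] >= llrs[:, None]).sum(axis=1)
    return (1.0 + exceed) / (R + 1.0)


def scan(
    observed: np.ndarray,
    expected: np.ndarray,
    windows: Sequence[Window],
    config: ScanConfig,
    population: np.ndarray | None = None,
) -> list[Cluster]:
    """Score all windows, rank clusters, and attach Monte Carlo p-values.

    Clusters are ranked by LLR descending; secondary clusters are reported
    greedily with zero membership overlap with any higher-ranked reported
    cluster. Only positive-LLR windows are reported. Each reported cluster
    is flagged significant when p <= alpha.
    """
    if not windows:
        logger.warning("empty window list: nothing to scan")
        return []
    observed = np.asarray(observed, float)
    expected = np.asarray(expected, float)
    C = float(observed.sum())
    if abs(expected.sum() - C) > 1e-6 * max(C, 1.0):
        logger.warning(
            "expected total %.6g differs from observed total %.6g; "
            "p-values assume conditioning on the observed total",
            expected.sum(), C,
        )
    mu_w = _window_sums(expected, windows)
    c_w = _window_sums(observed, windows)
    llr = poisson_llr(c_w, mu_w, C)
    order = np.lexsort((np.arange(len(windows)), -llr))
    reported: list[tuple[Window, float, float, float]] = []
    used: set[int] = set()
    for i in order:
        if llr[i] <= 0:
            break
        members = set(windows[i].members)
        if members & used:
            continue
        used |= members
        reported.append((windows[i], float(llr[i]), float(c_w[i]), float(mu_w[i])))
    if not reported:
        return []
    pvals = monte_carlo_pvalues(
        [r[1] for r in reported], windows, expected, C, config
    )
    clusters = []
    for rank, ((w, score, c, mu), p) in enumerate(zip(reported, pvals), start=1):
        pop_w = w.population if population is None else float(
            np.asarray(population, float)[list(w.members)].sum()
        )
        clusters.append(
            Cluster(
                window=w,
                llr=score,
                p_value=float(p),
                rank=rank,
                observed=c,
                expected=mu,
                observed_rate=c / pop_w * 1e5 if pop_w > 0 else np.nan,
                expected_rate=mu / pop_w * 1e5 if pop_w > 0 else np.nan,
                significant=bool(p <= config.alpha),
            )
        )
    return clusters


def clusters_to_frame(clusters: Sequence[Cluster], units: pd.DataFrame) -> pd.DataFrame:
    """Flatten clusters to the CSV reporting schema (members pipe-delimited)."""
    ids = units["unit_id"].to_numpy()
    rows = []
    for cl in clusters:
        rows.append(
            {
                "rank": cl.rank,
                "center_unit": ids[cl.window.center],
                "n_units": len(cl.members),
                "population": cl.window.population,
                "observed": cl.observed,
                "expected": cl.expected,
                "llr": cl.llr,
                "p_value": cl.p_value,
                "significant": cl.significant,
                "member_ids": "|".join(ids[list(cl.members)]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["rank", "center_unit", "n_units", "population", "observed",
                 "expected", "llr", "p_value", "significant", "member_ids"],
    )
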