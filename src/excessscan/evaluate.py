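"""Validation harnesses: calibration, recovery and oracle-agreement studies.

These routines measure the statistical behavior of the pipeline on data
with known ground truth — type-I error of the Monte Carlo scan under the
null, recovery of planted excess-risk disks, agreement of the windowed
scan with exhaustive enumeration, and out-of-fold R-squared against the
generative signal fraction. They are what the package's own quality checks
run; they are not part of the analysis pipeline itself.
"""

from __future__ import annotations

import numpy as np

from ._geo import DISTANCE_METRICS, haversine_km
from .expected import ModelSpec, oof_predict
from .scan import ScanConfig, build_windows, poisson_llr, pseudo_counts, scan
from .standardize import StandardPopulation, add_adjusted_rate
from .synthetic import (
    SimConfig,
    covariate_columns,
    generate_units,
    regression_outcome,
    simulate_deaths,
)

__all__ = [
    "exhaustive_max_llr",
    "scan_oracle_agreement",
    "null_calibration_rate",
    "planted_recovery_rate",
    "oof_noise_r2",
    "oof_signal_r2",
]


def exhaustive_max_llr(observed, expected, units, config) -> tuple[float, frozenset]:
    """Brute-force reference: enumerate every circular prefix from every
    center independently of the production window/scan code path and return
    the maximum LLR with its member set."""
    lat = units["lat"].to_numpy(float)
    lon = units["lon"].to_numpy(float)
    pop = units["population"].to_numpy(float)
    ids = units["unit_id"].astype(str).to_numpy()
    dist = DISTANCE_METRICS[config.distance_metric]
    bound = config.max_pop_fraction * pop.sum()
    C = float(np.sum(observed))
    best_llr, best_members = 0.0, frozenset()
    for center in range(len(units)):
        d = dist(lat[center], lon[center], lat, lon)
        order = sorted(
            range(len(units)),
            key=lambda j: (d[j], j != center, ids[j]),
        )
        cum = c = mu = 0.0
        members: list[int] = []
        for j in order:
            cum += pop[j]
            if cum > bound:
                break
            members.append(j)
            c += observed[j]
            mu += expected[j]
            if mu <= 0 or mu >= C:
                continue
            llr = float(poisson_llr(c, mu, C))
            if llr > best_llr:
                best_llr, best_members = llr, frozenset(members)
    return best_llr, best_members


def scan_oracle_agreement(n_instances: int, seed: int) -> float:
    """Fraction of random small instances (5-15 units) where the scan's
    maximum LLR and argmax member set equal exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    hits = 0
    for i in range(n_instances):
        n = int(rng.integers(5, 16))
        units = _toy(n, rng)
        config = ScanConfig(
            max_pop_fraction=float(rng.uniform(0.2, 0.5)),
            n_replicates=1,
            seed=int(rng.integers(2**31 - 1)),
            distance_metric="euclidean",
        )
        expected = units["population"].to_numpy(float) * 1e-3
        obs = rng.poisson(expected * rng.uniform(0.5, 2.0, n)).astype(float)
        if obs.sum() == 0:
            obs[int(rng.integers(n))] = 1.0
        expected = expected * obs.sum() / expected.sum()
        oracle_llr, oracle_members = exhaustive_max_llr(obs, expected, units, config)
        clusters = scan(obs, expected, build_windows(units, config), config)
        if oracle_llr == 0.0:
            hits += not clusters
        elif clusters and abs(clusters[0].llr - oracle_llr) <= 1e-9 * max(oracle_llr, 1) \
                and frozenset(clusters[0].members) == oracle_members:
            hits += 1
    return hits / n_instances


def _toy(n, rng):
    import pandas as pd

    return pd.DataFrame(
        {
            "unit_id": [f"T{i:03d}" for i in range(n)],
            "lat": rng.uniform(-2, 2, n),
            "lon": rng.uniform(-2, 2, n),
            "population": rng.integers(500, 5000, n).astype(float),
        }
    )


def null_calibration_rate(
    n_runs: int = 500,
    n_units: int = 30,
    replicates: int = 99,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Empirical P(primary-cluster p <= alpha) with observed data drawn from
    the scan's own null (multinomial over the expected surface). Should sit
    near alpha for a calibrated Monte Carlo test."""
    rng = np.random.default_rng(seed)
    cfg = SimConfig(n_units=n_units, n_covariates=5, seed=seed)
    units = generate_units(cfg)
    expected = units["true_rate"].to_numpy() * units["population"].to_numpy() / 1e5
    C = int(round(expected.sum()))
    windows = build_windows(units, ScanConfig(max_pop_fraction=0.2))
    hits = 0
    for r in range(n_runs):
        obs = rng.multinomial(C, expected / expected.sum()).astype(float)
        run_cfg = ScanConfig(
            max_pop_fraction=0.2, n_replicates=replicates,
            seed=int(rng.integers(2**31 - 1)),
        )
        clusters = scan(obs, expected * (obs.sum() / expected.sum()), windows, run_cfg)
        p = clusters[0].p_value if clusters else 1.0
        hits += p <= alpha
    return hits / n_runs


def planted_recovery_rate(
    n_runs: int = 100,
    n_units: int = 400,
    cluster_size: int = 8,
    relative_risk: float = 2.0,
    replicates: int = 99,
    seed: int = 0,
    max_pop_fraction: float = 0.05,
    jaccard_threshold: float = 0.8,
    alpha: float = 0.05,
) -> float:
    """Fraction of seeded runs where the primary cluster recovers a planted
    excess-risk disk (membership Jaccard >= threshold and p <= alpha).

    Each run generates a fresh national-style dataset, plants one disk of
    ``cluster_size`` units around a random center at the given relative
    risk, simulates Poisson deaths, standardizes, and scans the observed
    rates against the true baseline surface.
    """
    rng = np.random.default_rng(seed)
    std = StandardPopulation.who_world()
    hits = 0
    for r in range(n_runs):
        base_seed = int(rng.integers(2**31 - 1))
        base = generate_units(SimConfig(n_units=n_units, n_covariates=10, seed=base_seed))
        ci = int(rng.integers(n_units))
        d = haversine_km(
            base["lat"].iat[ci], base["lon"].iat[ci],
            base["lat"].to_numpy(), base["lon"].to_numpy(),
        )
        radius = float(np.sort(d)[cluster_size - 1]) + 1e-6
        cfg = SimConfig(
            n_units=n_units, n_covariates=10, seed=base_seed,
            clusters=(
                {
                    "center": (float(base["lat"].iat[ci]), float(base["lon"].iat[ci])),
                    "radius_km": radius,
                    "relative_risk": relative_risk,
                },
            ),
        )
        units = add_adjusted_rate(simulate_deaths(generate_units(cfg), cfg), std)
        truth = frozenset(np.flatnonzero(units["in_cluster"].to_numpy()))
        surface = units[["unit_id"]].assign(predicted_rate=units["true_rate"])
        observed, expected = pseudo_counts(units, surface)
        scan_cfg = ScanConfig(
            max_pop_fraction=max_pop_fraction, n_replicates=replicates,
            seed=int(rng.integers(2**31 - 1)),
        )
        clusters = scan(
            observed, expected, build_windows(units, scan_cfg), scan_cfg,
            population=units["population"].to_numpy(float),
        )
        if not clusters:
            continue
        found = frozenset(clusters[0].members)
        jaccard = len(found & truth) / len(found | truth)
        hits += jaccard >= jaccard_threshold and clusters[0].p_value <= alpha
    return hits / n_runs


def oof_noise_r2(
    n_seeds: int = 50, n_units: int = 250, seed: int = 0,
    family: str = "gradient-boosted-trees",
) -> np.ndarray:
    """Pooled out-of-fold R-squared on pure-noise outcomes, one per seed.

    An honest OOF scheme has no optimistic bias: these should scatter at or
    below zero.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in range(n_seeds):
        gen_seed = int(rng.integers(2**31 - 1))
        u = generate_units(SimConfig(n_units=n_units, n_covariates=20, seed=gen_seed))
        y = regression_outcome(u[covariate_columns(u)].to_numpy(), 0.0, gen_seed + 1)
        surface = oof_predict(
            u.assign(adjusted_rate=y), ModelSpec(family), k=10,
            seed=int(rng.integers(2**31 - 1)),
        )
        out.append(surface.r2_full)
    return np.array(out)


def oof_signal_r2(
    signal_fraction: float = 0.6, n_units: int = 3000, seed: int = 0,
    family: str = "gradient-boosted-trees",
) -> float:
    """Pooled out-of-fold R-squared on an outcome with a known generative
    signal fraction; should approach that fraction from below."""
    u = generate_units(SimConfig(n_units=n_units, n_covariates=40, seed=seed))
    y = regression_outcome(
        u[covariate_columns(u)].to_numpy(), signal_fraction, seed + 1
    )
    surface = oof_predict(u.assign(adjusted_rate=y), ModelSpec(family), k=10, seed=seed + 2)
    return surface.r2_full
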