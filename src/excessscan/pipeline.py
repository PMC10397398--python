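"""End-to-end orchestration: simulate/load -> standardize -> expected
surface per model family -> scan per family -> report with cross-family
overlap, under one seeded run configuration with a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, DataError
from .expected import CVSpec, ModelSpec, oof_predict, tune
from .report import (
    cluster_overlap,
    cluster_table,
    overlap_table,
    round_report,
    weighted_excess_summary,
    write_clusters_geojson,
)
from .scan import ScanConfig, build_windows, clusters_to_frame, pseudo_counts, scan
from .standardize import StandardPopulation, add_adjusted_rate
from .synthetic import SimConfig, generate_units, simulate_deaths, write_units

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]

_DEFAULT_FAMILIES = ("gradient-boosted-trees", "random-forest", "lasso")


@dataclass
class RunConfig:
    """One analysis run over one or more outcome columns.

    Either ``units_path`` (a unit-table CSV) or ``sim`` (a synthetic-data
    configuration for demo runs) must be given. One scan is performed per
    model family and the per-family clusters feed the overlap analysis.
    """

    units_path: str | None = None
    sim: SimConfig | None = None
    outcomes: tuple[str, ...] = ("adjusted_rate",)
    families: tuple[str, ...] = _DEFAULT_FAMILIES
    cv: CVSpec = field(default_factory=CVSpec)
    scan: ScanConfig = field(default_factory=ScanConfig)
    std_path: str | None = None  # standard-population CSV; WHO default
    tune_models: bool = False
    out_dir: str = "excessscan_out"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ConfigurationError("need at least one outcome column")
        if not self.families:
            raise ConfigurationError("need at least one model family")
        self.outcomes = tuple(self.outcomes)
        self.families = tuple(self.families)
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        if isinstance(self.cv, dict):
            self.cv = CVSpec(**self.cv)
        if isinstance(self.scan, dict):
            self.scan = ScanConfig(**self.scan)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        payload = _serializable(self)
        payload.pop("out_dir", None)  # environmental, not scientific
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _serializable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _serializable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    return obj


def _load_units(config: RunConfig) -> pd.DataFrame:
    if config.units_path:
        units = pd.read_csv(config.units_path)
        logger.info("loaded %d units from %s", len(units), config.units_path)
        return units
    if config.sim is None:
        raise ConfigurationError("RunConfig needs units_path or a sim block")
    sim = config.sim
    units = simulate_deaths(generate_units(sim), sim)
    logger.info("simulated %d units (seed %d)", len(units), sim.seed)
    return units


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to
    ``manifest.json``). Deterministic given the config, including its seeds."""
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    units = _load_units(config)

    std = (
        StandardPopulation.from_csv(config.std_path)
        if config.std_path
        else StandardPopulation.who_world()
    )
    has_bands = any(c.startswith("deaths_") for c in units.columns)
    manifest = {
        "package_version": __version__,
        "config": _serializable(config),
        "config_digest": config.digest(),
        "n_units": len(units),
        "outcomes": {},
    }
    if has_bands and "adjusted_rate" not in units.columns:
        units = add_adjusted_rate(units, std)
        logger.info("standardization: attached adjusted_rate")
    write_units(units, out / "units.csv")

    windows = build_windows(units, config.scan)
    logger.info("scan: %d candidate windows", len(windows))

    for outcome in config.outcomes:
        if outcome not in units.columns:
            raise DataError(f"outcome column {outcome!r} missing")
        o_dir = out / outcome if len(config.outcomes) > 1 else out
        o_dir.mkdir(exist_ok=True)
        per_family = {}
        cluster_sets = {}
        work = units
        if outcome != "adjusted_rate":
            work = units.drop(columns=["adjusted_rate"], errors="ignore").rename(
                columns={outcome: "adjusted_rate"}
            )
        for j, family in enumerate(config.families):
            seed = config.seed + 1000 * j
            if config.tune_models:
                spec = tune(family, work,
                            CVSpec(k_folds=config.cv.k_folds,
                                   repeats=config.cv.repeats,
                                   search_iterations=config.cv.search_iterations,
                                   seed=seed))
            else:
                spec = ModelSpec(family)
            surface = oof_predict(work, spec, k=config.cv.k_folds, seed=seed)
            surface.to_csv(o_dir / f"expected_surface_{family}.csv")
            logger.info("expected_rates[%s/%s]: OOF R2=%.3f RMSE=%.2f",
                        outcome, family, surface.r2_full, surface.rmse_full)
            observed, expected = pseudo_counts(work, surface)
            fam_scan = ScanConfig(**{**asdict(config.scan), "seed": seed})
            clusters = scan(observed, expected, windows, fam_scan,
                            population=work["population"].to_numpy(float))
            sig = [cl for cl in clusters if cl.significant]
            clusters_to_frame(clusters, work).to_csv(
                o_dir / f"clusters_{family}.csv", index=False
            )
            logger.info("scan[%s/%s]: %d reported clusters, %d significant",
                        outcome, family, len(clusters), len(sig))
            table = cluster_table(work, surface.frame, sig)
            round_report(table).to_csv(
                o_dir / f"clusters_report_{family}.csv", index=False
            )
            table.to_csv(o_dir / f"clusters_report_{family}_full.csv", index=False)
            if sig:
                write_clusters_geojson(work, sig, o_dir / f"clusters_{family}.geojson")
            per_family[family] = {
                "model": {"family": spec.family, "params": _serializable(dict(spec.params))},
                "oof_r2": surface.r2_full,
                "oof_rmse": surface.rmse_full,
                "n_significant_clusters": len(sig),
                "primary_p_value": sig[0].p_value if sig else None,
            }
            cluster_sets[family] = sig
        groups = cluster_overlap(cluster_sets) if any(cluster_sets.values()) else []
        otab = overlap_table(groups, outcome)
        round_report(otab).to_csv(o_dir / "overlap_report.csv", index=False)
        summary = {}
        valid = otab.dropna(subset=["excess_percent"])
        if len(valid) and valid["mean_expected"].sum() > 0:
            mean, sd = weighted_excess_summary(
                valid["excess_percent"], valid["mean_expected"]
            )
            summary = {"weighted_excess_mean_pct": mean,
                       "weighted_excess_sd_pct": sd}
        (o_dir / "summary.json").write_text(json.dumps(summary, indent=1))
        manifest["outcomes"][outcome] = {
            "families": per_family,
            "n_overlap_groups": len(groups),
            **summary,
        }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
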