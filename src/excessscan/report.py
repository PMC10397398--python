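"""Excess-mortality arithmetic and cluster reporting.

Turns scan output into the tables an epidemiologist reads: per-cluster
residual rates (observed age-adjusted minus model-predicted, per 100,000),
additional cases above expectation, excess percentages, expected-case-
weighted summaries across clusters, and cross-model overlap groups.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "residual_rate",
    "additional_cases",
    "excess_percent",
    "weighted_excess_summary",
    "cluster_overlap",
    "OverlapGroup",
    "cluster_table",
    "overlap_table",
    "round_report",
    "write_clusters_geojson",
]


def residual_rate(adjusted, predicted):
    """Observed minus predicted rate, per 100,000 (negative where the model
    over-predicts)."""
    return np.asarray(adjusted, float) - np.asarray(predicted, float)


def additional_cases(residual, population):
    """Excess deaths implied by a residual rate: residual x population / 100,000."""
    population = np.asarray(population, float)
    if (population < 0).any():
        raise DataError("negative population")
    return np.asarray(residual, float) * population / 1e5


def excess_percent(observed_cases, expected_cases):
    """(observed - expected) / expected x 100; NaN with a warning when
    expected is zero."""
    obs = np.asarray(observed_cases, float)
    exp = np.asarray(expected_cases, float)
    if (exp == 0).any():
        logger.warning("excess percent undefined for zero expected cases")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(exp > 0, (obs - exp) / np.where(exp > 0, exp, 1.0) * 100.0,
                       np.nan)
    return float(out) if out.ndim == 0 else out


def weighted_excess_summary(percents, weights) -> tuple[float, float]:
    """Weighted mean and (population-formula) weighted SD of excess percents,
    conventionally weighted by expected cases."""
    x = np.asarray(percents, float)
    w = np.asarray(weights, float)
    if (w < 0).any():
        raise DataError("negative weights")
    if w.sum() <= 0:
        raise DataError("weights sum to zero")
    mean = float((w * x).sum() / w.sum())
    sd = float(np.sqrt((w * (x - mean) ** 2).sum() / w.sum()))
    return mean, sd


@dataclass
class OverlapGroup:
    """Clusters from different model families linked by shared member units
    (transitive closure)."""

    models: tuple[str, ...]
    clusters: list  # (model, Cluster) pairs
    union: frozenset
    intersection: frozenset
    p_min: float
    p_max: float

    @property
    def n_models(self) -> int:
        return len(set(self.models))


def _member_set(cluster) -> frozenset:
    if hasattr(cluster, "members"):
        return frozenset(cluster.members)
    return frozenset(cluster)


def cluster_overlap(cluster_sets: Mapping[str, Sequence]) -> list[OverlapGroup]:
    """Group clusters across models when they share at least one member unit.

    Grouping is the transitive closure of pairwise overlap (a chain A-B,
    B-C joins A and C even if disjoint) and is independent of model input
    order. Each group reports the distinct-model count, union and
    intersection of members, and the p-value range.
    """
    if not cluster_sets:
        raise DataError("no cluster sets supplied")
    nodes = [
        (model, i)
        for model in sorted(cluster_sets)
        for i in range(len(cluster_sets[model]))
    ]
    members = {node: _member_set(cluster_sets[node[0]][node[1]]) for node in nodes}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if members[nodes[a]] & members[nodes[b]]:
                g.add_edge(nodes[a], nodes[b])
    groups = []
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        sets = [members[node] for node in comp]
        cl = [(model, cluster_sets[model][i]) for model, i in comp]
        pvals = [c.p_value for _, c in cl if hasattr(c, "p_value")]
        groups.append(
            OverlapGroup(
                models=tuple(model for model, _ in comp),
                clusters=cl,
                union=frozenset().union(*sets),
                intersection=frozenset.intersection(*sets),
                p_min=min(pvals) if pvals else np.nan,
                p_max=max(pvals) if pvals else np.nan,
            )
        )
    groups.sort(key=lambda grp: (-grp.n_models, -len(grp.union), sorted(grp.union)))
    return groups


def cluster_table(
    units: pd.DataFrame,
    surface_frame: pd.DataFrame,
    clusters: Sequence,
    *,
    include_others: bool = True,
) -> pd.DataFrame:
    """Per-cluster excess-mortality table with one row per cluster and one
    per member municipality.

    Cluster-level adjusted and predicted rates are population-weighted
    means of member rates, so a cluster's residual equals its total excess
    cases over its total population. An optional trailing row summarizes
    all non-cluster units.
    """
    merged = units.merge(
        surface_frame[["unit_id", "predicted_rate"]], on="unit_id", how="left",
        suffixes=("_unit", ""),
    )
    pop = merged["population"].to_numpy(float)
    adj = merged["adjusted_rate"].to_numpy(float)
    pred = merged["predicted_rate"].to_numpy(float)
    rows = []

    def _row(label, name, idx, p_value=np.nan):
        w = pop[idx]
        if w.sum() <= 0:
            wa = wp = np.nan
        else:
            wa = float((adj[idx] * w).sum() / w.sum())
            wp = float((pred[idx] * w).sum() / w.sum())
        res = wa - wp
        rows.append(
            {
                "cluster": label,
                "municipality": name,
                "adjusted_rate": wa,
                "predicted_rate": wp,
                "residual_rate": res,
                "population_thousands": w.sum() / 1e3,
                "additional_cases": res * w.sum() / 1e5,
                "p_value": p_value,
            }
        )

    in_any: set[int] = set()
    for cl in clusters:
        idx = np.array(sorted(cl.members, key=lambda i: -pop[i]))
        in_any |= set(cl.members)
        _row(f"Cluster {cl.rank}", "(all members)", idx, cl.p_value)
        for i in idx:
            _row(f"Cluster {cl.rank}", merged["name"].iat[i]
                 if "name" in merged else merged["unit_id"].iat[i],
                 np.array([i]), cl.p_value)
    if include_others:
        rest = np.array([i for i in range(len(merged)) if i not in in_any])
        if rest.size:
            _row("Others", "(all non-cluster units)", rest)
    return pd.DataFrame(rows)


def overlap_table(groups: Sequence[OverlapGroup], outcome: str = "") -> pd.DataFrame:
    """Cross-model overlap summary: one row per group with the distinct-model
    count, mean expected and observed cases across member clusters, the
    p-value range, and the excess percentage from the mean counts."""
    rows = []
    for grp in groups:
        exp = np.mean([c.expected for _, c in grp.clusters])
        obs = np.mean([c.observed for _, c in grp.clusters])
        rows.append(
            {
                "outcome": outcome,
                "n_models": grp.n_models,
                "models": "|".join(sorted(set(grp.models))),
                "n_units": len(grp.union),
                "mean_expected": exp,
                "mean_observed": obs,
                "p_min": grp.p_min,
                "p_max": grp.p_max,
                "excess_percent": excess_percent(obs, exp),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["outcome", "n_models", "models", "n_units", "mean_expected",
                 "mean_observed", "p_min", "p_max", "excess_percent"],
    )


def round_report(table: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: rates and cases to 1 decimal, populations to 0.1
    thousand, excess percents to the nearest integer. Full-precision values
    stay in the machine-readable outputs."""
    out = table.copy()
    if out.empty:
        return out
    one_dp = ["adjusted_rate", "predicted_rate", "residual_rate",
              "additional_cases", "population_thousands",
              "mean_expected", "mean_observed"]
    for col in one_dp:
        if col in out.columns:
            out[col] = out[col].round(1)
    if "excess_percent" in out.columns:
        out["excess_percent"] = out["excess_percent"].round(0).astype("Int64")
    return out


def write_clusters_geojson(
    units: pd.DataFrame, clusters: Sequence, path: str | Path
) -> None:
    """Member centroids as GeoJSON points with cluster attributes."""
    features = []
    for cl in clusters:
        for i in cl.members:
            row = units.iloc[i]
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Point",
                        "coordinates": [float(row["lon"]), float(row["lat"])],
                    },
                    "properties": {
                        "unit_id": str(row["unit_id"]),
                        "cluster_rank": cl.rank,
                        "llr": cl.llr,
                        "p_value": cl.p_value,
                        "significant": cl.significant,
                    },
                }
            )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features}, indent=1)
    )
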