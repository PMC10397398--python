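"""Bundled example data.

Two small published summary tables of excess cancer mortality clusters in
Brazilian municipalities (2007-2016, all-cancer and type-specific analyses)
and the WHO world standard population age weights. The cluster tables are
the worked examples used throughout the documentation and the acceptance
checks: they carry exactly the columns the reporting stage produces
(adjusted, predicted and residual rates per 100,000, populations in
thousands, observed and model-expected case counts, excess percentages and
Monte Carlo p-value ranges).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_who_standard_weights",
    "load_brazil_cluster_municipalities",
    "load_brazil_cluster_overlaps",
]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("excessscan.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_who_standard_weights() -> pd.DataFrame:
    """WHO world standard population weights, 18 five-year bands 0-4 ... 85+.

    Returns a DataFrame with columns ``band`` and ``weight`` (percent of the
    standard population; the canonical table sums to 100.03 and is
    renormalized by :class:`excessscan.standardize.StandardPopulation`).
    """
    return _read("who_standard_population.csv")


def load_brazil_cluster_municipalities() -> pd.DataFrame:
    """Municipality-level rows of three Brazilian excess-cancer-mortality clusters.

    One row per municipality with its cluster id, age-adjusted and
    model-predicted all-cancer mortality rates (deaths per 100,000) and
    population in thousands. Cluster 1 is the Bagé-Rio Grande region of
    Rio Grande do Sul, cluster 2 the Porto Velho region, cluster 3 Barueri.
    """
    return _read("brazil_cluster_municipalities.csv")


def load_brazil_cluster_overlaps() -> pd.DataFrame:
    """Cross-model cluster overlap summary for Brazilian cancer mortality.

    One row per overlap group: cancer type, number and names of model
    families whose clusters intersect (pipe-delimited), number of member
    cities, population (thousands), model-expected and observed case
    counts, the p-value range across members, and the printed excess
    percentage ``(observed - expected) / expected * 100``.
    """
    return _read("brazil_cluster_overlaps.csv")
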