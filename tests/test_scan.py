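"""Scan statistic: LLR formula, window construction, brute-force oracle
equivalence, Monte Carlo inference, and secondary-cluster rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from excessscan._geo import DISTANCE_METRICS, haversine_km
from excessscan.errors import ConfigurationError, DataError
from excessscan.scan import (
    ScanConfig,
    Window,
    build_windows,
    monte_carlo_pvalues,
    poisson_llr,
    pseudo_counts,
    scan,
)

from conftest import toy_grid


def brute_force_max(observed, expected, units, config):
    """Independent oracle: enumerate every circular prefix from every center
    directly and maximize the LLR by exhaustive search."""
    n = len(units)
    lat, lon = units["lat"].to_numpy(), units["lon"].to_numpy()
    pop = units["population"].to_numpy(float)
    dist = DISTANCE_METRICS[config.distance_metric]
    bound = config.max_pop_fraction * pop.sum()
    C = observed.sum()
    ids = units["unit_id"].astype(str).to_numpy()
    best = (0.0, None)
    for center in range(n):
        d = dist(lat[center], lon[center], lat, lon)
        order = sorted(range(n), key=lambda j: (d[j], ids[j]))
        cum_pop = c = mu = 0.0
        members = []
        for j in order:
            cum_pop += pop[j]
            if cum_pop > bound:
                break
            members.append(j)
            c += observed[j]
            mu += expected[j]
            if c > mu and 0 < mu < C:
                llr = c * np.log(c / mu) + (C - c) * np.log((C - c) / (C - mu)) \
                    if c < C else c * np.log(c / mu)
                if llr > best[0]:
                    best = (llr, frozenset(members))
    return best


class TestPoissonLlr:
    def test_equal_observed_and_expected_scores_zero(self):
        assert poisson_llr(10.0, 10.0, 100.0) == 0.0

    def test_deficit_scores_zero_in_high_rate_scan(self):
        assert poisson_llr(5.0, 10.0, 100.0) == 0.0

    def test_worked_value(self):
        assert poisson_llr(20.0, 10.0, 100.0) == pytest.approx(4.440, abs=5e-4)

    def test_all_cases_in_window_uses_zero_log_zero_convention(self):
        val = poisson_llr(100.0, 10.0, 100.0)
        assert np.isfinite(val) and val == pytest.approx(100 * np.log(10.0))

    def test_zero_expected_with_cases_rejected(self):
        with pytest.raises(DataError):
            poisson_llr(5.0, 0.0, 100.0)

    @given(st.floats(10.001, 99.9))
    def test_monotone_in_observed_above_expected(self, c):
        lo = poisson_llr(c, 10.0, 100.0)
        hi = poisson_llr(min(c + 0.5, 100.0), 10.0, 100.0)
        assert hi >= lo

    def test_vectorized_matches_scalar(self):
        c = np.array([5.0, 15.0, 20.0])
        mu = np.array([10.0, 10.0, 10.0])
        out = poisson_llr(c, mu, 100.0)
        assert out[0] == 0.0
        assert out[2] == pytest.approx(poisson_llr(20.0, 10.0, 100.0))


class TestPseudoCounts:
    def test_rate_times_population(self):
        units = pd.DataFrame(
            {
                "unit_id": ["a", "b"],
                "population": [205_200.0, 100_000.0],
                "adjusted_rate": [160.0, 100.0],
            }
        )
        surface = pd.DataFrame({"unit_id": ["a", "b"], "predicted_rate": [124.5, 100.0]})
        obs, exp = pseudo_counts(units, surface)
        assert obs[0] == pytest.approx(328.32)
        assert exp.sum() == pytest.approx(obs.sum(), rel=1e-12)

    def test_perfect_prediction_rescales_to_identity(self):
        units = toy_grid(8, seed=1)
        surface = units[["unit_id"]].assign(predicted_rate=units["adjusted_rate"])
        obs, exp = pseudo_counts(units, surface)
        np.testing.assert_allclose(obs, exp, rtol=1e-12)

    def test_zero_population_unit_contributes_nothing(self):
        units = toy_grid(4, seed=2)
        units.loc[0, "population"] = 0.0
        surface = units[["unit_id", "predicted_rate"]]
        obs, exp = pseudo_counts(units, surface)
        assert obs[0] == 0.0 and exp[0] == 0.0

    def test_zero_total_expected_rejected(self):
        units = toy_grid(4, seed=3)
        surface = units[["unit_id"]].assign(predicted_rate=0.0)
        with pytest.raises(DataError):
            pseudo_counts(units, surface)

    def test_conservation_after_rescaling(self):
        units = toy_grid(50, seed=4)
        surface = units[["unit_id", "predicted_rate"]]
        obs, exp = pseudo_counts(units, surface)
        assert abs(exp.sum() - obs.sum()) < 1e-9 * obs.sum()


class TestBuildWindows:
    def test_three_units_hand_enumeration(self):
        units = pd.DataFrame(
            {
                "unit_id": ["a", "b", "c"],
                "lat": [0.0, 0.0, 0.0],
                "lon": [0.0, 1.0, 3.0],
                "population": [10.0, 10.0, 10.0],
            }
        )
        cfg = ScanConfig(max_pop_fraction=0.5, distance_metric="euclidean")
        # bound = 15 -> only singletons fit
        ws = build_windows(units, cfg)
        assert sorted(frozenset(w.members) for w in ws) == [
            frozenset({0}), frozenset({1}), frozenset({2})
        ]

    def test_prefixes_deduplicated_across_centers(self):
        units = pd.DataFrame(
            {
                "unit_id": ["a", "b", "c"],
                "lat": [0.0, 0.0, 0.0],
                "lon": [0.0, 1.0, 3.0],
                "population": [1.0, 1.0, 1.0],
            }
        )
        cfg = ScanConfig(max_pop_fraction=0.5, distance_metric="euclidean")
        # bound covers any single unit; with fraction 0.5 the bound is 1.5
        ws = build_windows(units, cfg)
        member_sets = [frozenset(w.members) for w in ws]
        assert len(member_sets) == len(set(member_sets))

    def test_population_bound_respected_and_ordered_by_distance(self):
        units = toy_grid(30, seed=5)
        cfg = ScanConfig(max_pop_fraction=0.2, distance_metric="euclidean")
        ws = build_windows(units, cfg)
        bound = 0.2 * units["population"].sum()
        lat, lon = units["lat"].to_numpy(), units["lon"].to_numpy()
        for w in ws:
            assert units["population"].to_numpy()[list(w.members)].sum() <= bound
            d = np.hypot(lat[list(w.members)] - lat[w.center],
                         lon[list(w.members)] - lon[w.center])
            assert (np.diff(d) >= -1e-12).all()

    def test_bound_below_smallest_population_yields_empty_list(self, caplog):
        units = toy_grid(5, seed=6, pop_low=4000, pop_high=5000)
        cfg = ScanConfig(max_pop_fraction=0.05, distance_metric="euclidean")
        assert build_windows(units, cfg) == []
        assert any("no window" in r.message for r in caplog.records)

    def test_identical_coordinates_tie_broken_by_unit_id(self):
        units = pd.DataFrame(
            {
                "unit_id": ["z9", "a1", "m5"],
                "lat": [0.0, 0.0, 0.0],
                "lon": [0.0, 0.0, 0.0],
                "population": [1.0, 1.0, 1.0],
            }
        )
        cfg = ScanConfig(max_pop_fraction=0.5, distance_metric="euclidean")
        ws = build_windows(units, cfg)
        # every center leads its own window; remaining ties order by unit_id
        for w in ws:
            assert w.members[0] == w.center
        assert [w.members for w in build_windows(units, cfg)] == [w.members for w in ws]

    def test_center_must_be_member(self):
        with pytest.raises(ConfigurationError):
            Window(center=3, members=(0, 1), population=2.0)


class TestScan:
    def test_flat_surface_has_no_clusters(self):
        units = toy_grid(15, seed=7)
        cfg = ScanConfig(max_pop_fraction=0.3, n_replicates=19,
                         distance_metric="euclidean")
        ws = build_windows(units, cfg)
        exp = units["population"].to_numpy(float) / 10.0
        clusters = scan(exp.copy(), exp, ws, cfg)
        assert clusters == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        units = toy_grid(int(rng.integers(5, 13)), seed=100 + seed)
        cfg = ScanConfig(max_pop_fraction=0.4, n_replicates=9, seed=seed,
                         distance_metric="euclidean")
        exp = units["population"].to_numpy(float) * 1e-3
        obs = rng.poisson(exp * rng.uniform(0.5, 2.0, len(units))).astype(float)
        if obs.sum() == 0:
            obs[0] = 1.0
        exp = exp * obs.sum() / exp.sum()
        ws = build_windows(units, cfg)
        clusters = scan(obs, exp, ws, cfg)
        oracle_llr, oracle_members = brute_force_max(obs, exp, units, cfg)
        if oracle_llr == 0.0:
            assert clusters == []
        else:
            assert clusters[0].llr == pytest.approx(oracle_llr, rel=1e-9)
            assert frozenset(clusters[0].members) == oracle_members

    def test_overwhelming_planted_signal_found_at_p_floor(self):
        units = toy_grid(50, seed=8, pop_low=900, pop_high=1100)
        cfg = ScanConfig(max_pop_fraction=0.15, n_replicates=99, seed=9,
                         distance_metric="euclidean")
        # plant RR=3 on the 5 units nearest unit 0
        lat, lon = units["lat"].to_numpy(), units["lon"].to_numpy()
        d = np.hypot(lat - lat[0], lon - lon[0])
        planted = set(np.argsort(d)[:5])
        exp = units["population"].to_numpy(float) * 2.0  # ~100k total cases
        obs = exp.copy()
        for i in planted:
            obs[i] *= 3.0
        exp = exp * obs.sum() / exp.sum()
        ws = build_windows(units, cfg)
        clusters = scan(obs, exp, ws, cfg)
        assert frozenset(clusters[0].members) == frozenset(planted)
        assert clusters[0].p_value == pytest.approx(1.0 / 100.0)
        assert clusters[0].significant

    def test_secondary_clusters_disjoint_and_rank_ordered(self):
        units = toy_grid(40, seed=10)
        cfg = ScanConfig(max_pop_fraction=0.2, n_replicates=19, seed=11,
                         distance_metric="euclidean")
        surface = units[["unit_id", "predicted_rate"]]
        obs, exp = pseudo_counts(units, surface)
        clusters = scan(obs, exp, build_windows(units, cfg), cfg)
        seen = set()
        llrs = [cl.llr for cl in clusters]
        assert llrs == sorted(llrs, reverse=True)
        assert [cl.rank for cl in clusters] == list(range(1, len(clusters) + 1))
        for cl in clusters:
            assert not (set(cl.members) & seen)
            seen |= set(cl.members)

    def test_empty_window_list_returns_empty(self, caplog):
        assert scan(np.array([1.0]), np.array([1.0]), [], ScanConfig()) == []


class TestMonteCarlo:
    def test_zero_llr_cluster_has_p_one(self):
        units = toy_grid(10, seed=12)
        cfg = ScanConfig(max_pop_fraction=0.4, n_replicates=39, seed=13,
                         distance_metric="euclidean")
        ws = build_windows(units, cfg)
        exp = units["population"].to_numpy(float)
        p = monte_carlo_pvalues([0.0], ws, exp, exp.sum(), cfg)
        assert p[0] == 1.0

    def test_p_floor_is_one_over_replicates_plus_one(self):
        units = toy_grid(10, seed=14)
        cfg = ScanConfig(max_pop_fraction=0.4, n_replicates=999, seed=15,
                         distance_metric="euclidean")
        ws = build_windows(units, cfg)
        exp = units["population"].to_numpy(float)
        p = monte_carlo_pvalues([1e9], ws, exp, exp.sum(), cfg)
        assert p[0] == pytest.approx(0.001)

    def test_pvalues_live_on_the_replicate_grid(self):
        units = toy_grid(12, seed=16)
        R = 49
        cfg = ScanConfig(max_pop_fraction=0.4, n_replicates=R, seed=17,
                         distance_metric="euclidean")
        ws = build_windows(units, cfg)
        surface = units[["unit_id", "predicted_rate"]]
        obs, exp = pseudo_counts(units, surface)
        clusters = scan(obs, exp, ws, cfg)
        grid = {k / (R + 1.0) for k in range(1, R + 2)}
        for cl in clusters:
            assert min(abs(cl.p_value - g) for g in grid) < 1e-12

    def test_poisson_null_model_also_calibrates_at_floor(self):
        units = toy_grid(10, seed=18)
        cfg = ScanConfig(max_pop_fraction=0.4, n_replicates=99, seed=19,
                         null_model="poisson", distance_metric="euclidean")
        ws = build_windows(units, cfg)
        exp = units["population"].to_numpy(float) / 100.0
        p = monte_carlo_pvalues([1e9], ws, exp, exp.sum(), cfg)
        assert p[0] == pytest.approx(0.01)


def test_haversine_known_distance():
    # one degree of latitude is ~111.2 km
    assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.2, rel=0.01)


def test_invalid_scan_configs_rejected():
    with pytest.raises(ConfigurationError):
        ScanConfig(max_pop_fraction=0.0)
    with pytest.raises(ConfigurationError):
        ScanConfig(n_replicates=0)
    with pytest.raises(ConfigurationError):
        ScanConfig(direction="low")
    with pytest.raises(ConfigurationError):
        ScanConfig(null_model="gumbel")
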