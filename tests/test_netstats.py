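"""Comparison statistics: t-tests, bootstrap density test, bivariate OLS."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from supplynet.io_model import (
    CentralityTable,
    DataError,
    OneModeNetwork,
    UsageError,
)
from supplynet.classify import build_networks
from supplynet.netmetrics import degree_centrality, project_one_mode
from supplynet.netstats import (
    AnalysisConfig,
    bivariate_ols,
    bootstrap_density_compare,
    compare_centrality,
    run_full_analysis,
)
from supplynet.synthetic import SyntheticConfig, generate

from conftest import make_store


def table(mode, values):
    frame = pd.DataFrame(
        {
            "store_id": [f"s{i:02d}" for i in range(len(values))],
            "raw_degree": values,
            "normalized_pct": [10.0 * v for v in values],
        }
    )
    return CentralityTable(mode=mode, table=frame, n_suppliers=10)


def er_one_mode(n, p, rng):
    nodes = [f"s{i}" for i in range(n)]
    weights = {
        tuple(sorted((a, b))): 1
        for a, b in itertools.combinations(nodes, 2)
        if rng.random() < p
    }
    return OneModeNetwork(frozenset(nodes), weights)


class TestCompareCentrality:
    def test_identical_tables_null(self):
        t1 = table("UHSN", [1, 2, 3, 4])
        t2 = table("HSN", [1, 2, 3, 4])
        res = compare_centrality(t1, t2, method="paired")
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_pooled_textbook_example(self):
        res = compare_centrality(
            table("UHSN", [1, 2, 3]), table("HSN", [4, 5, 6]),
            method="independent_pooled", scale="raw_degree",
        )
        # closed-form pooled-variance t for (1,2,3) vs (4,5,6)
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.df == 4
        assert res.group_means == (2.0, 5.0)

    def test_constant_nonzero_difference_is_degenerate(self):
        res = compare_centrality(
            table("UHSN", [3, 4, 5]), table("HSN", [1, 2, 3]), method="paired",
            scale="raw_degree",
        )
        assert res.degenerate
        assert np.isnan(res.statistic)

    def test_paired_reduces_to_one_sample_t_of_differences(self):
        rng = np.random.default_rng(4)
        x = rng.normal(5, 2, 12)
        y = x + 1.0 + rng.normal(0, 1, 12)
        res = compare_centrality(
            table("UHSN", x), table("HSN", y), method="paired", scale="raw_degree"
        )
        oracle = sps.ttest_1samp(x - y, 0.0)
        assert res.statistic == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 3, 14)
        res = compare_centrality(
            table("UHSN", x), table("HSN", y), method="welch", scale="raw_degree"
        )
        oracle = sps.ttest_ind(x, y, equal_var=False)
        assert res.statistic == pytest.approx(oracle.statistic)
        assert res.p == pytest.approx(oracle.pvalue)

    def test_too_few_observations(self):
        with pytest.raises(DataError):
            compare_centrality(table("UHSN", [1]), table("HSN", [2]), method="welch")


class TestBootstrapDensity:
    def test_same_graph_gives_t_zero(self):
        rng = np.random.default_rng(0)
        g = er_one_mode(10, 0.4, rng)
        res = bootstrap_density_compare(g, g, n_boot=200, seed=1)
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        a, b = er_one_mode(12, 0.3, rng), er_one_mode(12, 0.6, rng)
        r1 = bootstrap_density_compare(a, b, n_boot=300, seed=77)
        r2 = bootstrap_density_compare(a, b, n_boot=300, seed=77)
        assert r1.statistic == r2.statistic
        assert r1.ci_95 == r2.ci_95

    def test_small_n_boot_and_missing_seed_are_usage_errors(self):
        rng = np.random.default_rng(0)
        g = er_one_mode(5, 0.5, rng)
        with pytest.raises(UsageError):
            bootstrap_density_compare(g, g, n_boot=50, seed=1)
        with pytest.raises(UsageError):
            bootstrap_density_compare(g, g, n_boot=200)

    def test_power_increases_with_density_gap(self):
        rng = np.random.default_rng(42)
        gaps = (0.05, 0.15, 0.30)
        power = []
        for gap in gaps:
            rej = 0
            for _ in range(60):
                a = er_one_mode(24, 0.35, rng)
                b = er_one_mode(24, 0.35 + gap, rng)
                res = bootstrap_density_compare(
                    a, b, n_boot=400, seed=int(rng.integers(2**31))
                )
                rej += res.p < 0.05
            power.append(rej / 60)
        assert power[0] < power[1] <= power[2]

    def test_node_resampling_is_more_conservative(self):
        rng = np.random.default_rng(3)
        a, b = er_one_mode(20, 0.3, rng), er_one_mode(20, 0.6, rng)
        dyad = bootstrap_density_compare(a, b, n_boot=500, seed=5, resample="dyad")
        node = bootstrap_density_compare(a, b, n_boot=500, seed=5, resample="node")
        assert abs(node.statistic) < abs(dyad.statistic)


class TestBivariateOls:
    def _centrality(self, stores, values):
        frame = pd.DataFrame(
            {
                "store_id": [s.store_id for s in stores],
                "raw_degree": values,
                "normalized_pct": values,
            }
        )
        return CentralityTable("HSN", frame, n_suppliers=10)

    def test_perfect_fit_is_degenerate(self):
        stores = [make_store(i) for i in range(1, 7)]
        x = [s.years_current_store for s in stores]
        res = bivariate_ols(
            stores, self._centrality(stores, [2 * v for v in x]), "years_current_store"
        )
        assert res.b == pytest.approx(2.0)
        assert res.degenerate
        assert res.ci_95 == (res.b, res.b)

    def test_balanced_binary_null_slope(self):
        stores = [
            make_store(1, accepts_wic=True),
            make_store(2, accepts_wic=True),
            make_store(3, accepts_wic=False),
            make_store(4, accepts_wic=False),
        ]
        res = bivariate_ols(stores, self._centrality(stores, [1, 3, 3, 1]), "accepts_wic")
        assert res.b == pytest.approx(0.0, abs=1e-12)

    def test_binary_slope_equals_group_mean_difference(self):
        stores = [
            make_store(i, owner_ethnicity="asian_hispanic" if i < 4 else "african_american")
            for i in range(1, 9)
        ]
        y = [4.0, 2.0, 3.0, 1.0, 6.0, 8.0, 7.0, 9.0]
        res = bivariate_ols(
            stores, self._centrality(stores, y), "ethnicity_asian_hispanic"
        )
        # exact oracle: difference of group means (coded 1 = asian_hispanic)
        grp1 = [yi for s, yi in zip(stores, y) if s.owner_ethnicity == "asian_hispanic"]
        grp0 = [yi for s, yi in zip(stores, y) if s.owner_ethnicity == "african_american"]
        assert res.b == pytest.approx(np.mean(grp1) - np.mean(grp0), abs=1e-12)

    def test_slope_matches_closed_form(self):
        stores = [make_store(i) for i in range(1, 7)]
        x = np.array([s.customers_per_day for s in stores])
        y = np.array([3.0, 5.0, 4.0, 8.0, 7.0, 9.0])
        res = bivariate_ols(stores, self._centrality(stores, y), "customers_per_day")
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert res.b == pytest.approx(slope)

    def test_zero_variance_covariate_is_degenerate_design(self):
        stores = [make_store(i, accepts_snap=True) for i in range(1, 6)]
        with pytest.raises(DataError, match="zero variance"):
            bivariate_ols(stores, self._centrality(stores, [1, 2, 3, 4, 5]), "accepts_snap")

    def test_too_few_cases(self):
        stores = [make_store(1), make_store(2)]
        with pytest.raises(DataError, match="complete cases"):
            bivariate_ols(stores, self._centrality(stores, [1, 2]), "accepts_wic")


@pytest.fixture(scope="module")
def bundle():
    cfg = SyntheticConfig(seed=11, snap_effect=0.0, wic_effect=0.0,
                          ethnicity_effect=-1.5, delivery_rate=0.0)
    ds = generate(cfg)
    return run_full_analysis(ds, AnalysisConfig(seed=21, n_boot=500)), ds


class TestFullAnalysis:
    def test_recovers_configured_ethnicity_effect_within_ci(self, bundle):
        report, _ = bundle
        row = report.regressions.query(
            "mode == 'HSN' and covariate == 'ethnicity_asian_hispanic'"
        ).iloc[0]
        assert row["ci_low"] <= -1.5 <= row["ci_high"]

    def test_no_delivering_suppliers_makes_sensitivity_identical(self, bundle):
        report, _ = bundle
        pd.testing.assert_frame_equal(report.regressions, report.sensitivity_regressions)

    def test_report_tables_cover_nine_covariates_both_modes(self, bundle):
        report, _ = bundle
        assert len(report.regressions) == 18
        assert set(report.regressions["mode"]) == {"HSN", "UHSN"}

    def test_identical_networks_give_null_comparison(self, small_catalog):
        from supplynet.io_model import PurchaseRecord
        from conftest import make_supplier

        stores = [make_store(i) for i in range(1, 5)]
        suppliers = [make_supplier(1), make_supplier(2)]
        purchases = []
        for j, s in enumerate(stores):
            uid = "u01" if j < 3 else "u02"
            purchases.append(PurchaseRecord(s.store_id, uid, "chips"))
            purchases.append(PurchaseRecord(s.store_id, uid, "bananas"))
        hsn, uhsn, _ = build_networks(purchases, small_catalog, stores, suppliers)
        assert hsn.edges == uhsn.edges
        res = compare_centrality(degree_centrality(uhsn), degree_centrality(hsn))
        assert res.statistic == 0.0 and res.p == 1.0
        boot = bootstrap_density_compare(
            project_one_mode(uhsn), project_one_mode(hsn), n_boot=200, seed=9
        )
        assert boot.statistic == 0.0
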