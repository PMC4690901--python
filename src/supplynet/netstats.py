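"""Comparison statistics and bivariate regressions.

Three inferential pieces sit on top of the network metrics:

* a t-test comparing store degree centrality between the unhealthy and
  healthy supplier networks (paired across the same stores by default);
* a bootstrap test for the difference of one-mode densities, with the
  standard error taken from resampling each network;
* bivariate ordinary least squares of degree centrality on one store
  characteristic at a time (the sample is deliberately too small for
  multivariate adjustment), re-run after removing delivering suppliers as
  a sensitivity analysis.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .classify import (
    build_networks,
    filter_delivering,
    roster_summary,
    unknown_items_frame,
)
from .geo import DistanceTable, store_supplier_distances
from .io_model import (
    BipartiteNetwork,
    CentralityTable,
    ConfigurationError,
    DataError,
    Dataset,
    OneModeNetwork,
    RegressionResult,
    Store,
    TTestResult,
    UsageError,
    export_graph,
)
from .netmetrics import (
    degree_centrality,
    density,
    diversity_table,
    extract_core,
    project_one_mode,
    shared_stats,
)

logger = logging.getLogger("supplynet")

__all__ = [
    "COVARIATES",
    "compare_centrality",
    "bootstrap_density_compare",
    "bivariate_ols",
    "AnalysisConfig",
    "ReportBundle",
    "run_full_analysis",
]

# The nine store characteristics regressed one at a time against degree
# centrality; ethnicity is coded 1 = Asian/Hispanic with African American
# as the reference level.
COVARIATES = (
    "mean_distance_km",
    "accepts_wic",
    "accepts_snap",
    "ethnicity_asian_hispanic",
    "years_current_store",
    "years_any_store",
    "customers_per_day",
    "n_nonfamily_employees",
    "n_family_employees",
)


# ---------------------------------------------------------------------------
# Centrality comparison t-tests


def compare_centrality(
    table_a: CentralityTable,
    table_b: CentralityTable,
    method: str = "paired",
    scale: str = "normalized_pct",
) -> TTestResult:
    """t-test of degree centrality between two networks.

    ``method`` is 'paired' (default: the same stores appear in both
    networks), 'independent_pooled' or 'welch'.  ``scale`` selects the raw
    or normalized centrality column.
    """
    if method not in ("paired", "independent_pooled", "welch"):
        raise UsageError(f"unknown t-test method {method!r}")
    x = table_a.values(scale).to_numpy(dtype=float)
    y = table_b.values(scale).to_numpy(dtype=float)
    if method == "paired":
        if set(table_a.table["store_id"]) != set(table_b.table["store_id"]):
            raise UsageError("paired comparison requires identical store sets")
        # both tables are store-sorted, so rows align
    if len(x) < 2 or len(y) < 2:
        raise DataError("need at least 2 observations per group")
    mx, my = float(np.mean(x)), float(np.mean(y))

    if method == "paired":
        d = x - y
        n = len(d)
        sd = float(np.std(d, ddof=1))
        if sd == 0.0:
            if float(np.mean(d)) == 0.0:
                return TTestResult(0.0, n - 1, 1.0, (mx, my), (0.0, 0.0), method)
            return TTestResult(
                float("nan"), n - 1, float("nan"), (mx, my),
                (float(np.mean(d)), float(np.mean(d))), method,
                degenerate=True,
                note="zero variance of paired differences with nonzero mean",
            )
        se = sd / math.sqrt(n)
        t = float(np.mean(d)) / se
        df = n - 1
        p = 2.0 * sps.t.sf(abs(t), df)
        tcrit = sps.t.ppf(0.975, df)
        ci = (float(np.mean(d)) - tcrit * se, float(np.mean(d)) + tcrit * se)
        return TTestResult(t, df, float(p), (mx, my), ci, method)

    n1, n2 = len(x), len(y)
    v1, v2 = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    diff = mx - my
    if method == "independent_pooled":
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:  # welch
        se2_1, se2_2 = v1 / n1, v2 / n2
        se = math.sqrt(se2_1 + se2_2)
        df = (
            (se2_1 + se2_2) ** 2 / (se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1))
            if se2_1 + se2_2 > 0
            else n1 + n2 - 2
        )
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, (mx, my), (0.0, 0.0), method)
        return TTestResult(
            float("nan"), df, float("nan"), (mx, my), (diff, diff), method,
            degenerate=True, note="zero variance in both groups with nonzero difference",
        )
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    ci = (diff - tcrit * se, diff + tcrit * se)
    return TTestResult(float(t), float(df), float(p), (mx, my), ci, method)


# ---------------------------------------------------------------------------
# Bootstrap density-difference test


def _adjacency(one_mode: OneModeNetwork) -> np.ndarray:
    nodes = sorted(one_mode.store_nodes)
    index = {s: i for i, s in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)), dtype=float)
    for (u, v) in one_mode.weights:
        a[index[u], index[v]] = 1.0
        a[index[v], index[u]] = 1.0
    return a


def _boot_densities(
    a: np.ndarray, n_boot: int, rng: np.random.Generator, resample: str
) -> np.ndarray:
    n = a.shape[0]
    if resample == "dyad":
        vals = a[np.triu_indices(n, 1)]
        m = vals.size
        idx = rng.integers(0, m, size=(n_boot, m))
        return vals[idx].mean(axis=1)
    if resample == "node":
        # node resampling in the UCINET tradition: duplicate-node dyads are
        # filled with the node's mean tie propensity
        rowmean = a.sum(axis=1) / (n - 1)
        idx = rng.integers(0, n, size=(n_boot, n))
        sub = a[idx[:, :, None], idx[:, None, :]]
        same = idx[:, :, None] == idx[:, None, :]
        fill = np.broadcast_to(rowmean[idx][:, :, None], sub.shape)
        sub = np.where(same, fill, sub)
        tot = sub.sum(axis=(1, 2)) - np.einsum("bii->b", sub)
        return tot / (n * (n - 1))
    raise UsageError(f"unknown resample scheme {resample!r}; use 'dyad' or 'node'")


def bootstrap_density_compare(
    one_mode_a: OneModeNetwork,
    one_mode_b: OneModeNetwork,
    n_boot: int = 5000,
    seed: int | None = None,
    resample: str = "dyad",
) -> TTestResult:
    """Bootstrap test for the difference of two one-mode densities.

    Each network's density standard error is estimated by resampling
    (dyads by default; ``resample='node'`` for node resampling, which is
    markedly conservative when ties are close to independent).  The
    statistic is t = (d_A − d_B) / sqrt(SE_A² + SE_B²) with a t reference
    distribution on n_A + n_B − 2 degrees of freedom.  Group means and the
    confidence interval are on the percentage scale.
    """
    if n_boot < 100:
        raise UsageError(f"n_boot must be >= 100, got {n_boot}")
    if seed is None:
        raise UsageError("a seed is required for a reproducible bootstrap")
    for net, label in ((one_mode_a, "A"), (one_mode_b, "B")):
        if len(net.store_nodes) < 2:
            raise UsageError(f"network {label} needs >= 2 nodes")
    rng = np.random.default_rng(seed)
    a, b = _adjacency(one_mode_a), _adjacency(one_mode_b)
    na, nb = a.shape[0], b.shape[0]
    d_a = a.sum() / (na * (na - 1))
    d_b = b.sum() / (nb * (nb - 1))
    boot_a = _boot_densities(a, n_boot, rng, resample)
    boot_b = _boot_densities(b, n_boot, rng, resample)
    se = math.sqrt(float(boot_a.var(ddof=1)) + float(boot_b.var(ddof=1)))
    diff = float(d_a - d_b)
    df = na + nb - 2
    means = (100.0 * float(d_a), 100.0 * float(d_b))
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0, means, (0.0, 0.0), "bootstrap_density")
        return TTestResult(
            math.copysign(math.inf, diff), df, 0.0, means,
            (100 * diff, 100 * diff), "bootstrap_density",
            degenerate=True, note="zero bootstrap variance in both networks",
        )
    t = diff / se
    p = 2.0 * sps.t.sf(abs(t), df)
    tcrit = sps.t.ppf(0.975, df)
    ci = (100.0 * (diff - tcrit * se), 100.0 * (diff + tcrit * se))
    return TTestResult(float(t), float(df), float(p), means, ci, "bootstrap_density")


# ---------------------------------------------------------------------------
# Bivariate OLS


def covariate_values(
    stores: Sequence[Store],
    covariate: str,
    distance_means: Mapping[str, float] | None = None,
) -> pd.Series:
    """Extract one covariate as a store-indexed series (binary coded 0/1)."""
    if covariate == "mean_distance_km":
        if distance_means is None:
            raise UsageError(
                "mean_distance_km requires per-store distance means "
                "(see geo.store_supplier_distances)"
            )
        return pd.Series(
            {s.store_id: float(distance_means.get(s.store_id, float("nan"))) for s in stores}
        )
    extractors = {
        "accepts_wic": lambda s: float(s.accepts_wic),
        "accepts_snap": lambda s: float(s.accepts_snap),
        "ethnicity_asian_hispanic": lambda s: float(s.owner_ethnicity == "asian_hispanic"),
        "years_current_store": lambda s: s.years_current_store,
        "years_any_store": lambda s: s.years_any_store,
        "customers_per_day": lambda s: s.customers_per_day,
        "n_nonfamily_employees": lambda s: s.n_nonfamily_employees,
        "n_family_employees": lambda s: s.n_family_employees,
    }
    if covariate not in extractors:
        raise UsageError(f"unknown covariate {covariate!r}; choose from {COVARIATES}")
    return pd.Series({s.store_id: extractors[covariate](s) for s in stores})


def bivariate_ols(
    stores: Sequence[Store],
    centrality: CentralityTable,
    covariate: str,
    outcome_scale: str = "raw_degree",
    distance_means: Mapping[str, float] | None = None,
) -> RegressionResult:
    """OLS of degree centrality on one store characteristic.

    Returns the slope b (outcome units per covariate unit), its
    normal-theory 95% CI and two-sided p.  With a binary covariate the slope
    equals the difference of group means.
    """
    x = covariate_values(stores, covariate, distance_means)
    y = centrality.values(outcome_scale).astype(float)
    frame = pd.DataFrame({"x": x, "y": y}).dropna()
    n = len(frame)
    if n < 3:
        raise DataError(f"covariate {covariate!r}: need >= 3 complete cases, have {n}")
    if float(frame["x"].var(ddof=1)) == 0.0:
        raise DataError(f"covariate {covariate!r}: zero variance (degenerate design)")
    design = sm.add_constant(frame["x"].to_numpy())
    fit = sm.OLS(frame["y"].to_numpy(), design).fit()
    b = float(fit.params[1])
    if fit.ssr <= 1e-12 * max(1.0, float(np.sum(frame["y"] ** 2))):
        return RegressionResult(
            covariate, b, (b, b), 0.0, n, outcome_scale,
            degenerate=True, note="perfect fit: zero residual variance",
        )
    lo, hi = fit.conf_int()[1]
    return RegressionResult(
        covariate, b, (float(lo), float(hi)), float(fit.pvalues[1]), n, outcome_scale
    )


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the end-to-end analysis."""

    seed: int
    core_threshold: float = 0.80
    ttest_method: str = "paired"
    outcome_scale: str = "raw_degree"
    n_boot: int = 5000
    bootstrap_resample: str = "dyad"
    bh_correction: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.core_threshold <= 1.0):
            raise ConfigurationError("core_threshold must be in (0, 1]")
        if self.ttest_method not in ("paired", "independent_pooled", "welch"):
            raise ConfigurationError(f"unknown ttest_method {self.ttest_method!r}")
        if self.outcome_scale not in ("raw_degree", "normalized_pct"):
            raise ConfigurationError(f"unknown outcome_scale {self.outcome_scale!r}")


@dataclass
class ReportBundle:
    """Everything the end-to-end analysis produces."""

    hsn: BipartiteNetwork
    uhsn: BipartiteNetwork
    unknown_items: pd.DataFrame
    centrality: dict[str, CentralityTable]
    cores: dict[str, object]
    one_mode: dict[str, OneModeNetwork]
    densities: dict[str, float]
    shared: dict[str, object]
    diversity: dict[str, pd.DataFrame]
    distances: dict[str, DistanceTable]
    centrality_test: TTestResult
    density_test: TTestResult
    table1: pd.DataFrame
    network_summary: pd.DataFrame
    regressions: pd.DataFrame
    sensitivity_regressions: pd.DataFrame
    config: AnalysisConfig
    dataset: Dataset = field(repr=False)

    def write(self, out_dir: str | os.PathLike) -> None:
        """Write the tidy CSV tables, the statistics log and graph exports."""
        os.makedirs(out_dir, exist_ok=True)
        self.table1.to_csv(os.path.join(out_dir, "table1_summary.csv"), index=False)
        self.network_summary.to_csv(
            os.path.join(out_dir, "network_summary.csv"), index=False
        )
        self.regressions.to_csv(
            os.path.join(out_dir, "table3_regressions.csv"), index=False
        )
        self.sensitivity_regressions.to_csv(
            os.path.join(out_dir, "sensitivity_regressions.csv"), index=False
        )
        self.unknown_items.to_csv(
            os.path.join(out_dir, "unknown_items.csv"), index=False
        )
        for mode, ct in self.centrality.items():
            ct.table.to_csv(
                os.path.join(out_dir, f"centrality_{mode.lower()}.csv"), index=False
            )
        for mode, dt in self.distances.items():
            dt.per_edge.to_csv(
                os.path.join(out_dir, f"distances_{mode.lower()}.csv"), index=False
            )
            dt.per_store.to_csv(
                os.path.join(out_dir, f"store_mean_distance_{mode.lower()}.csv"),
                index=False,
            )
        sup_by_id = self.dataset.supplier_by_id()
        for mode, net in (("HSN", self.hsn), ("UHSN", self.uhsn)):
            export_graph(
                net,
                os.path.join(out_dir, f"two_mode_{mode.lower()}.graphml"),
                "graphml",
                suppliers=sup_by_id,
                core=self.cores[mode].core_suppliers,
            )
            export_graph(
                self.one_mode[mode],
                os.path.join(out_dir, f"one_mode_{mode.lower()}.graphml"),
                "graphml",
            )
        with open(os.path.join(out_dir, "stats_log.txt"), "w") as fh:
            fh.write(self.format_log())

    def format_log(self) -> str:
        lines = ["# supplier-network analysis statistics", ""]
        ct = self.centrality_test
        lines.append(
            f"degree centrality ({ct.method}, normalized %): UHSN mean "
            f"{ct.group_means[0]:.4f}, HSN mean {ct.group_means[1]:.4f}, "
            f"t = {ct.statistic:.4f}, df = {ct.df:.1f}, p = {ct.p:.3g}, "
            f"95% CI of difference ({ct.ci_95[0]:.4f}, {ct.ci_95[1]:.4f})"
        )
        dt = self.density_test
        lines.append(
            f"one-mode density (bootstrap, {self.config.bootstrap_resample} "
            f"resampling, n_boot = {self.config.n_boot}): UHSN "
            f"{dt.group_means[0]:.4f}%, HSN {dt.group_means[1]:.4f}%, "
            f"t = {dt.statistic:.4f}, p = {dt.p:.3g}"
        )
        for mode in ("UHSN", "HSN"):
            core = self.cores[mode]
            sh = self.shared[mode]
            rng_txt = (
                f"range {sh.min_shared}-{sh.max_shared}"
                if sh.min_shared is not None
                else "no shared suppliers"
            )
            lines.append(
                f"{mode}: {self.centrality[mode].n_suppliers} suppliers, "
                f"{len(self.hsn.edges) if mode == 'HSN' else len(self.uhsn.edges)} edges, "
                f"core size {core.size} (coverage {core.covered_edge_fraction:.3f}), "
                f"density {self.densities[mode]:.2f}%, mean shared "
                f"{sh.mean_shared:.2f} ({rng_txt}), isolates {sh.n_isolates}"
            )
        return "\n".join(lines) + "\n"


def _regression_table(
    stores: Sequence[Store],
    centrality: Mapping[str, CentralityTable],
    distance_means: Mapping[str, Mapping[str, float]],
    outcome_scale: str,
    bh_correction: bool,
) -> pd.DataFrame:
    rows = []
    for mode in ("UHSN", "HSN"):
        for cov in COVARIATES:
            try:
                res = bivariate_ols(
                    stores,
                    centrality[mode],
                    cov,
                    outcome_scale=outcome_scale,
                    distance_means=distance_means.get(mode),
                )
                rows.append(
                    {
                        "mode": mode,
                        "covariate": cov,
                        "b": res.b,
                        "ci_low": res.ci_95[0],
                        "ci_high": res.ci_95[1],
                        "p": res.p,
                        "n": res.n,
                        "outcome_scale": res.outcome_scale,
                        "note": res.note,
                    }
                )
            except DataError as exc:
                rows.append(
                    {
                        "mode": mode,
                        "covariate": cov,
                        "b": float("nan"),
                        "ci_low": float("nan"),
                        "ci_high": float("nan"),
                        "p": float("nan"),
                        "n": 0,
                        "outcome_scale": outcome_scale,
                        "note": str(exc),
                    }
                )
    frame = pd.DataFrame(rows)
    if bh_correction:
        from statsmodels.stats.multitest import multipletests

        frame["p_bh"] = float("nan")
        for mode in ("UHSN", "HSN"):
            mask = (frame["mode"] == mode) & frame["p"].notna()
            if mask.sum():
                frame.loc[mask, "p_bh"] = multipletests(
                    frame.loc[mask, "p"], method="fdr_bh"
                )[1]
    return frame


def _table1_summary(stores: Sequence[Store], distance_means: Mapping[str, float]) -> pd.DataFrame:
    def mean_sd(vals: Sequence[float]) -> str:
        arr = np.asarray([v for v in vals if not math.isnan(v)], dtype=float)
        if arr.size == 0:
            return "n/a"
        return f"{arr.mean():.2f} +/- {arr.std(ddof=1):.2f}" if arr.size > 1 else f"{arr.mean():.2f}"

    n = len(stores)
    rows = [
        ("Average distance to suppliers, km", mean_sd([distance_means.get(s.store_id, float('nan')) for s in stores])),
        ("Accept WIC, yes", f"{100.0 * sum(s.accepts_wic for s in stores) / n:.1f}%"),
        ("Accept SNAP, yes", f"{100.0 * sum(s.accepts_snap for s in stores) / n:.1f}%"),
        ("Storeowner ethnicity: African American", f"{100.0 * sum(s.owner_ethnicity == 'african_american' for s in stores) / n:.1f}%"),
        ("Storeowner ethnicity: Asian or Hispanic", f"{100.0 * sum(s.owner_ethnicity == 'asian_hispanic' for s in stores) / n:.1f}%"),
        ("Years operating current store", mean_sd([s.years_current_store for s in stores])),
        ("Years operating any food store", mean_sd([s.years_any_store for s in stores])),
        ("Customers on an average day", mean_sd([s.customers_per_day for s in stores])),
        ("Non-family paid employees", mean_sd([s.n_nonfamily_employees for s in stores])),
        ("Family member employees", mean_sd([s.n_family_employees for s in stores])),
    ]
    return pd.DataFrame(rows, columns=["characteristic", "value"])


def run_full_analysis(dataset: Dataset, config: AnalysisConfig) -> ReportBundle:
    """Run the complete pipeline: networks, metrics, comparisons, regressions,
    and the delivery-exclusion sensitivity re-run."""
    stage = "build_networks"
    try:
        hsn, uhsn, unknown = build_networks(
            dataset.purchases, dataset.catalog, dataset.stores, dataset.suppliers
        )
        nets = {"HSN": hsn, "UHSN": uhsn}
        logger.info(
            "built networks: HSN %d edges / %d suppliers, UHSN %d edges / %d "
            "suppliers, %d unclassifiable purchases",
            hsn.n_edges, len(hsn.supplier_nodes), uhsn.n_edges,
            len(uhsn.supplier_nodes), len(unknown),
        )

        stage = "netmetrics"
        centrality = {m: degree_centrality(n) for m, n in nets.items()}
        cores = {m: extract_core(n, config.core_threshold) for m, n in nets.items()}
        one_mode = {m: project_one_mode(n) for m, n in nets.items()}
        densities = {m: density(g) for m, g in one_mode.items()}
        shared = {m: shared_stats(g) for m, g in one_mode.items()}
        sup_by_id = dataset.supplier_by_id()
        divers = {m: diversity_table(n, sup_by_id) for m, n in nets.items()}

        stage = "geo"
        distances = {
            m: store_supplier_distances(dataset.stores, sup_by_id, n)
            for m, n in nets.items()
        }
        dist_means = {m: d.mean_km() for m, d in distances.items()}
        # Table-1-style overall distance: per-store mean over the union of
        # connected suppliers in either network
        union = BipartiteNetwork.from_edges(
            "UHSN", [s.store_id for s in dataset.stores], hsn.edges | uhsn.edges
        )
        overall_means = (
            store_supplier_distances(dataset.stores, sup_by_id, union).mean_km()
            if union.n_edges
            else {}
        )

        stage = "netstats"
        centrality_test = compare_centrality(
            centrality["UHSN"], centrality["HSN"], method=config.ttest_method
        )
        density_test = bootstrap_density_compare(
            one_mode["UHSN"],
            one_mode["HSN"],
            n_boot=config.n_boot,
            seed=config.seed,
            resample=config.bootstrap_resample,
        )
        regressions = _regression_table(
            dataset.stores, centrality, dist_means, config.outcome_scale,
            config.bh_correction,
        )

        stage = "sensitivity"
        kept = filter_delivering(dataset.purchases, sup_by_id)
        s_hsn, s_uhsn, _ = build_networks(
            kept, dataset.catalog, dataset.stores, dataset.suppliers
        )
        s_nets = {"HSN": s_hsn, "UHSN": s_uhsn}
        s_centrality = {m: degree_centrality(n) for m, n in s_nets.items()}
        s_dist_means = {
            m: (
                store_supplier_distances(dataset.stores, sup_by_id, n).mean_km()
                if n.n_edges
                else {}
            )
            for m, n in s_nets.items()
        }
        sensitivity = _regression_table(
            dataset.stores, s_centrality, s_dist_means, config.outcome_scale,
            config.bh_correction,
        )

        stage = "summaries"
        table1 = _table1_summary(dataset.stores, overall_means)
        summary_rows = []
        for m in ("UHSN", "HSN"):
            rs = roster_summary(nets[m], nets["HSN" if m == "UHSN" else "UHSN"], sup_by_id)
            sh = shared[m]
            summary_rows.append(
                {
                    "mode": m,
                    "n_edges": nets[m].n_edges,
                    "n_suppliers_entries": rs.n_suppliers_entries,
                    "n_suppliers_distinct": rs.n_suppliers_distinct,
                    "overlap_with_other_mode": rs.overlap_with_other_mode,
                    "mean_raw_degree": float(centrality[m].raw().mean()),
                    "mean_normalized_pct": float(centrality[m].normalized().mean())
                    if centrality[m].normalized_defined
                    else float("nan"),
                    "core_size": cores[m].size,
                    "core_coverage": cores[m].covered_edge_fraction,
                    "density_pct": densities[m],
                    "mean_shared": sh.mean_shared,
                    "min_shared": sh.min_shared,
                    "max_shared": sh.max_shared,
                    "n_isolates": sh.n_isolates,
                    "mean_diversity": float(divers[m]["n_categories"].mean()),
                }
            )
        network_summary = pd.DataFrame(summary_rows)
    except Exception as exc:
        from .io_model import SupplyNetError

        if isinstance(exc, SupplyNetError):
            raise type(exc)(f"[stage: {stage}] {exc}") from exc
        raise SupplyNetError(f"[stage: {stage}] {exc}") from exc

    return ReportBundle(
        hsn=hsn,
        uhsn=uhsn,
        unknown_items=unknown_items_frame(unknown),
        centrality=centrality,
        cores=cores,
        one_mode=one_mode,
        densities=densities,
        shared=shared,
        diversity=divers,
        distances=distances,
        centrality_test=centrality_test,
        density_test=density_test,
        table1=table1,
        network_summary=network_summary,
        regressions=regressions,
        sensitivity_regressions=sensitivity,
        config=config,
        dataset=dataset,
    )
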