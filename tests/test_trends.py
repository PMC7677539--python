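"""Yearly aggregation, Huber trend fitting, the Wald test, selection, and TDL."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targettrends import (
    TrendFit,
    compute_trends,
    fit_trend,
    huber_fit,
    percent_of_total,
    robust_wald_p,
    select_trends,
    tdl_evolution,
    yearly_counts,
)
from targettrends.trends import YearlyCountSeries

from conftest import clean_record, make_store


def _targets(*rows):
    return pd.DataFrame(rows, columns=["target_id", "accession", "class_path", "tdl"])


class TestYearlyCounts:
    def test_dedup_semantics(self):
        store = make_store(
            pd.DataFrame(
                [
                    clean_record(compound_id="C1", year=2010),
                    clean_record(compound_id="C1", year=2010, document_id="D2"),
                ]
            ),
            _targets(("T1", "P1", "enzyme:kinase", "Tclin")),
        )
        assert yearly_counts(store, ("all", None), "bioactivities").counts[2010] == 2
        assert yearly_counts(store, ("all", None), "unique_compounds").counts[2010] == 1
        assert yearly_counts(store, ("all", None), "unique_documents").counts[2010] == 2

    def test_go_scope_is_additive_over_targets(self):
        recs = [clean_record(target_id="T1", compound_id=f"C{i}", year=2010) for i in range(3)]
        recs += [clean_record(target_id="T2", compound_id=f"C{i+3}", year=2010) for i in range(2)]
        recs += [clean_record(target_id="T3", year=2010)]
        store = make_store(
            pd.DataFrame(recs),
            _targets(
                ("T1", "P1", "enzyme:kinase", "Tclin"),
                ("T2", "P2", "enzyme:kinase", "Tchem"),
                ("T3", "P3", "enzyme:kinase", "Tbio"),
            ),
            go_terms=pd.DataFrame(
                {"target_id": ["T1", "T2"], "go_term": ["proc", "proc"]}
            ),
        )
        series = yearly_counts(store, ("go", "proc"), "bioactivities")
        assert series.counts[2010] == 5
        assert series.totals[2010] == 6

    def test_unknown_measure_is_fatal(self, filtered_store):
        with pytest.raises(ValueError, match="measure"):
            yearly_counts(filtered_store, ("all", None), "citations")

    def test_universe_counts_match_manifest(self, universe_dir, filtered_store):
        _, _, manifest = universe_dir
        for trend in manifest.trends:
            scope = (trend["kind"].replace("family-measure", "family"),
                     trend["family"] if trend["kind"] == "family-measure"
                     else trend["annotation"])
            series = yearly_counts(filtered_store, scope, "bioactivities")
            for year, count in trend["counts"].items():
                assert series.counts[int(year)] == count


class TestPercent:
    def test_partition_percents(self):
        s = YearlyCountSeries("x", "bioactivities",
                              counts={2000: 2, 2001: 3, 2002: 5},
                              totals={2000: 10, 2001: 10, 2002: 10})
        assert percent_of_total(s).percent == {2000: 20.0, 2001: 30.0, 2002: 50.0}

    def test_zero_count_is_kept_as_zero_percent(self):
        s = YearlyCountSeries("x", "bioactivities",
                              counts={2000: 0}, totals={2000: 10})
        assert s.percent == {2000: 0.0}

    def test_zero_total_year_dropped_from_percent(self):
        s = YearlyCountSeries("x", "bioactivities",
                              counts={2000: 1, 2001: 1},
                              totals={2000: 0, 2001: 10})
        assert list(s.percent) == [2001]

    def test_family_partition_conserves_100_percent(self, filtered_store):
        # six families + other partition the records; per-year percents sum to 100
        fams = ["kinase", "GPCR", "nuclear_receptor", "protease",
                "ion_channel", "transporter", "other"]
        per_year = {}
        for fam in fams[:-1]:
            s = yearly_counts(filtered_store, ("family", fam), "bioactivities")
            for y, p in s.percent.items():
                per_year[y] = per_year.get(y, 0.0) + p
        rec = filtered_store.records
        other = rec.loc[rec["family"] == "other"].groupby("year").size()
        totals = rec.groupby("year").size()
        for y in per_year:
            per_year[y] += 100.0 * other.get(y, 0) / totals[y]
            assert per_year[y] == pytest.approx(100.0, abs=1e-9)


class TestHuberFit:
    def test_exact_line_recovered(self):
        years = np.arange(1998, 2018)
        fit = huber_fit(years, 0.5 * (years - 1998) + 1.0)
        assert fit.slope == pytest.approx(0.5, abs=1e-12)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)

    def test_constant_series_has_zero_slope(self):
        fit = huber_fit(np.arange(2000, 2010), np.full(10, 7.0))
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_fewer_than_three_years_refused(self):
        with pytest.raises(ValueError):
            huber_fit([2000, 2001], [1.0, 2.0])

    def test_outlier_resistance_vs_ols_and_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        from statsmodels.robust.norms import HuberT

        rng = np.random.default_rng(4)
        t = np.arange(20, dtype=float)
        y = 1.0 + 0.5 * t + rng.normal(0, 0.2, 20)
        y[7] += 30.0  # gross outlier
        fit = huber_fit(t, y, tol=1e-12, maxiter=200)
        X = np.column_stack([np.ones(20), t])
        oracle = sm.RLM(y, X, M=HuberT(1.345)).fit(
            conv="coefs", tol=1e-12, maxiter=200, scale_est="mad"
        )
        assert fit.intercept == pytest.approx(oracle.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(oracle.params[1], abs=1e-6)
        ols = np.linalg.lstsq(X, y, rcond=None)[0][1]
        assert abs(fit.slope - 0.5) < abs(ols - 0.5)

    def test_equals_ols_when_no_large_residuals(self):
        # standardized residuals all below 1.345 => every Huber weight is 1
        rng = np.random.default_rng(8)
        t = np.arange(10, dtype=float)
        y = 2.0 + 0.3 * t + rng.uniform(-0.05, 0.05, 10)
        fit = huber_fit(t, y, tol=1e-12, maxiter=200)
        X = np.column_stack([np.ones(10), t])
        bols = np.linalg.lstsq(X, y, rcond=None)[0]
        r = y - X @ bols
        s = 1.482602218505602 * np.median(np.abs(r))
        assert (np.abs(r / s) <= 1.345).all()  # construction check
        assert fit.slope == pytest.approx(bols[1], abs=1e-9)

    @given(st.integers(min_value=-5000, max_value=5000))
    @settings(max_examples=30, deadline=None)
    def test_shift_equivariance_of_slope(self, k):
        rng = np.random.default_rng(17)
        t = np.arange(1998, 2018, dtype=float)
        y = 3.0 + 0.4 * (t - 1998) + rng.normal(0, 1.0, 20)
        a = huber_fit(t, y, tol=1e-12, maxiter=500)
        b = huber_fit(t + k, y, tol=1e-12, maxiter=500)
        assert b.slope == pytest.approx(a.slope, abs=1e-10)


class TestWaldTest:
    def test_exact_line_is_overwhelmingly_significant(self):
        years = np.arange(1998, 2018)
        y = 0.3 * (years - 1998) + 2.0
        fit = huber_fit(years, y)
        assert robust_wald_p(fit, years, y) < 1e-10

    def test_flat_exact_series_is_insignificant(self):
        years = np.arange(1998, 2018)
        y = np.full(20, 5.0)
        fit = huber_fit(years, y)
        assert robust_wald_p(fit, years, y) == 1.0

    def test_two_points_refused(self):
        fit = TrendFit(slope=1.0, intercept=0.0, n_years=2)
        with pytest.raises(ValueError):
            robust_wald_p(fit, [2000, 2001], [1.0, 2.0])

    def test_agrees_with_reference_robust_f(self):
        """p-values match an independent robust Wald route built on
        statsmodels RLM standard errors, on 20 random noisy datasets."""
        sm = pytest.importorskip("statsmodels.api")
        from scipy import stats as sps
        from statsmodels.robust.norms import HuberT

        rng = np.random.default_rng(21)
        t = np.arange(20, dtype=float)
        X = np.column_stack([np.ones(20), t])
        for _ in range(20):
            y = rng.normal(0, 1, 20) + rng.uniform(-0.3, 0.3) * t
            if rng.random() < 0.5:
                y[rng.integers(0, 20)] += rng.uniform(5, 15)
            fit = huber_fit(t, y, tol=1e-12, maxiter=500)
            p_mine = robust_wald_p(fit, t, y)
            m = sm.RLM(y, X, M=HuberT(1.345)).fit(
                conv="coefs", tol=1e-12, maxiter=500, scale_est="mad"
            )
            p_ref = float(sps.f.sf((m.params[1] / m.bse[1]) ** 2, 1, 18))
            assert p_mine == pytest.approx(p_ref, abs=1e-3)


class TestSelection:
    def _fit(self, slope, p):
        f = TrendFit(slope=slope, intercept=0.0, n_years=20)
        f.p_value = p
        return f

    def test_gate_rules(self):
        fits = {
            "steep": self._fit(2.62, 0.001),
            "below-gate": self._fit(0.24, 0.001),
            "insignificant": self._fit(0.90, 0.06),
            "boundary": self._fit(0.25, 0.05),
            "down": self._fit(-0.90, 0.001),
        }
        names = [n for n, _ in select_trends(fits)]
        assert names == ["steep", "boundary", "down"]

    def test_presentation_order_descending_slope_then_name(self):
        fits = [
            ("b", self._fit(0.5, 0.01)),
            ("a", self._fit(0.5, 0.01)),
            ("c", self._fit(1.5, 0.01)),
            ("d", self._fit(-0.5, 0.01)),
        ]
        assert [n for n, _ in select_trends(fits)] == ["c", "a", "b", "d"]

    def test_compute_trends_recovers_universe_slopes(self, universe_dir, filtered_store):
        _, _, manifest = universe_dir
        df = compute_trends(filtered_store, "go").set_index("annotation")
        for trend in manifest.trends:
            if trend["kind"] != "go":
                continue
            got = df.loc[trend["annotation"], "slope"]
            assert got == pytest.approx(trend["slope_pp_per_year"], abs=0.2)


class TestTdlEvolution:
    def test_share_arithmetic(self):
        store = make_store(
            pd.DataFrame(
                [
                    clean_record(target_id="T1", year=2010),
                    clean_record(target_id="T1", year=2010, compound_id="C2"),
                    clean_record(target_id="T2", year=2010),
                    clean_record(target_id="T3", year=2010),
                ]
            ),
            _targets(
                ("T1", "P1", "enzyme:kinase", "Tclin"),
                ("T2", "P2", "enzyme:kinase", "Tclin"),
                ("T3", "P3", "enzyme:kinase", "Tchem"),
            ),
        )
        row = tdl_evolution(store, "kinase").set_index("year").loc[2010]
        assert row["Tclin"] == pytest.approx(2 / 3)
        assert row["Tchem"] == pytest.approx(1 / 3)

    def test_empty_year_is_flagged(self):
        store = make_store(
            pd.DataFrame(
                [
                    clean_record(target_id="T1", year=2010),
                    clean_record(target_id="T2", year=2011),
                ]
            ),
            _targets(
                ("T1", "P1", "enzyme:kinase", "Tclin"),
                ("T2", "P2", "membrane receptor:7tm1", "Tchem"),
            ),
        )
        df = tdl_evolution(store, "kinase").set_index("year")
        assert not df.loc[2010, "empty"]
        assert df.loc[2011, "empty"]
        assert df.loc[2011, ["Tclin", "Tchem", "Tbio", "Tdark", "unknown"]].sum() == 0

    def test_universe_tdl_matches_manifest(self, universe_dir, filtered_store):
        _, _, manifest = universe_dir
        df = tdl_evolution(filtered_store, "kinase").set_index("year")
        rec = filtered_store.records
        year = 2005
        tids = rec.loc[(rec["family"] == "kinase") & (rec["year"] == year), "target_id"]
        expected = pd.Series(
            [manifest.targets[t]["tdl"] for t in tids.unique()]
        ).value_counts(normalize=True)
        for lev in ("Tclin", "Tchem", "Tbio", "Tdark"):
            assert df.loc[year, lev] == pytest.approx(expected.get(lev, 0.0))
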