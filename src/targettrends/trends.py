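"""Yearly aggregation, robust trend fitting, and the trend selection gate.

Research attention to a target family, GO biological process, or disease is
measured per year by one of five measures (raw bioactivity count, distinct
compounds, distinct documents, distinct targets, or drug-efficacy target
annotations), expressed as a percentage of the year's total so that the
secular growth of the literature does not masquerade as a trend.  Each percent
series is then fitted by robust linear regression — an M-estimator with the
Huber influence function (tuning constant 1.345) solved by iteratively
reweighted least squares, the residual scale re-estimated at each iteration by
the median absolute deviation — and the slope is tested with a robust Wald
test referred to F(1, n-2).  A trend is *selected* for reporting when its
p-value is at most ``alpha`` (default 0.05) and its absolute slope is at least
``slope_min`` (default 0.25 percentage points per year).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .store import SIX_FAMILIES, Family, Store

__all__ = [
    "MEASURES",
    "YearlyCountSeries",
    "TrendFit",
    "yearly_counts",
    "percent_of_total",
    "huber_fit",
    "robust_wald_p",
    "fit_trend",
    "select_trends",
    "compute_trends",
    "tdl_evolution",
]

MEASURES = (
    "bioactivities",
    "unique_compounds",
    "unique_documents",
    "unique_targets",
    "drug_efficacy_annotations",
)

HUBER_C = 1.345
#: MAD consistency factor for Gaussian residuals, 1 / Phi^{-1}(3/4).
MAD_FACTOR = 1.482602218505602


@dataclass
class YearlyCountSeries:
    """A (year -> count) series with the companion (year -> total) series.

    ``percent`` maps each counted year with a positive total to
    ``100 * count / total``; years whose total is zero are dropped from the
    percent view (there is nothing to be a share of), while a zero count in a
    populated year yields an honest 0%.
    """

    scope: str
    measure: str
    counts: dict[int, int]
    totals: dict[int, int]

    @property
    def percent(self) -> dict[int, float]:
        return {
            y: 100.0 * c / self.totals[y]
            for y, c in sorted(self.counts.items())
            if self.totals.get(y, 0) > 0
        }

    def percent_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        pct = self.percent
        return np.array(list(pct), dtype=float), np.array(list(pct.values()))


def _measure_count(sub: pd.DataFrame, measure: str, efficacy: pd.DataFrame) -> pd.Series:
    """Per-year count of one measure over a record subset."""
    if measure == "bioactivities":
        return sub.groupby("year").size()
    if measure == "unique_compounds":
        return sub.groupby("year")["compound_id"].nunique()
    if measure == "unique_documents":
        return sub.groupby("year")["document_id"].nunique()
    if measure == "unique_targets":
        return sub.groupby("year")["target_id"].nunique()
    if measure == "drug_efficacy_annotations":
        eff = efficacy.loc[efficacy["disease_efficacy"] == 1]
        pairs = sub[["year", "target_id"]].drop_duplicates().merge(eff, on="target_id")
        return pairs.groupby("year")[["target_id", "drug_id"]].apply(
            lambda g: len(g.drop_duplicates())
        )
    raise ValueError(f"unknown measure: {measure!r}")


def _scope_targets(store: Store, kind: str, value: str | None) -> pd.Series | None:
    """Target ids selected by a scope, or None for record-level scopes."""
    if kind == "family":
        fam = Family(value).value
        return store.targets.loc[store.targets["family"] == fam, "target_id"]
    if kind == "go":
        return store.go_terms.loc[store.go_terms["go_term"] == value, "target_id"]
    if kind == "disease":
        return store.diseases.loc[store.diseases["disease"] == value, "target_id"]
    if kind == "all":
        return None
    raise ValueError(f"unknown scope kind: {kind!r}")


def yearly_counts(
    store: Store,
    scope: tuple[str, str | None],
    measure: str = "bioactivities",
    *,
    denominator: str = "all",
) -> YearlyCountSeries:
    """Count one measure per year for a scope, with totals for normalization.

    ``scope`` is ``(kind, value)`` with kind one of ``all``, ``family``,
    ``go``, ``disease``.  Family/GO/disease scopes select the records of the
    annotated targets.  ``denominator`` chooses the reference population for
    the totals: ``"all"`` uses every filtered record, ``"six-families"``
    restricts to records of targets assigned to one of the six families.
    Years present in the reference population but absent from the scope are
    reported with count 0 (an honest zero share).
    """
    if measure not in MEASURES:
        raise ValueError(f"unknown measure: {measure!r}; expected one of {MEASURES}")
    kind, value = scope
    rec = store.records
    if denominator == "six-families":
        ref = rec.loc[rec["family"].isin([f.value for f in SIX_FAMILIES])]
    elif denominator == "all":
        ref = rec
    else:
        raise ValueError(f"unknown denominator mode: {denominator!r}")

    tids = _scope_targets(store, kind, value)
    sub = ref if tids is None else ref.loc[ref["target_id"].isin(set(tids))]

    counts = _measure_count(sub, measure, store.efficacy)
    totals = _measure_count(ref, measure, store.efficacy)
    years = sorted(totals.index)
    label = "all-targets" if kind == "all" else f"{kind}:{value}"
    return YearlyCountSeries(
        scope=label,
        measure=measure,
        counts={int(y): int(counts.get(y, 0)) for y in years},
        totals={int(y): int(totals.get(y, 0)) for y in years},
    )


def percent_of_total(series: YearlyCountSeries) -> YearlyCountSeries:
    """Validate that totals cover the counted years and return the series.

    The percent view itself is the :class:`YearlyCountSeries` ``percent``
    property; this checks the precondition (a total for every counted year)
    and is the natural seam for external tables — e.g. clinical-trial report
    counts normalized to the total number of reports filed per year.
    """
    missing = [y for y in series.counts if y not in series.totals]
    if missing:
        raise ValueError(f"no totals for counted year(s): {missing}")
    return series


@dataclass
class TrendFit:
    """Robust linear trend of a percent series.

    ``slope`` is in percentage points per year; ``intercept`` is the fitted
    percent at the first year of the series.  ``significant`` means the
    robust Wald p-value is at most alpha; ``selected`` additionally requires
    ``|slope| >= slope_min`` — the reporting gate for trend tables.
    """

    slope: float
    intercept: float
    n_years: int
    p_value: float = math.nan
    significant: bool = False
    selected: bool = False
    direction: str = "flat"
    converged: bool = True
    scale: float = field(default=math.nan, repr=False)

    def __post_init__(self) -> None:
        if self.slope > 0:
            self.direction = "positive"
        elif self.slope < 0:
            self.direction = "negative"


def _irls(
    t: np.ndarray, y: np.ndarray, tol: float, maxiter: int
) -> tuple[np.ndarray, float, bool]:
    """Huber IRLS on a straight-line model; returns (beta, scale, converged).

    Scale is the MAD of residuals about zero times 1/Phi^{-1}(3/4),
    re-estimated every iteration.  A zero residual spread means the data are
    exactly collinear, where the IRLS limit is ordinary least squares itself,
    so the OLS solution is returned with scale 0.
    """
    X = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    converged = False
    scale = 0.0
    # residual spread below this is an exact fit up to rounding
    zero_tol = 1e-12 * max(1.0, float(np.max(np.abs(y))))
    for _ in range(maxiter):
        r = y - X @ beta
        scale = MAD_FACTOR * float(np.median(np.abs(r)))
        if scale <= zero_tol:
            return beta, 0.0, True
        u = r / scale
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, HUBER_C / np.abs(u))
        Xw = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ Xw, Xw.T @ y)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return beta, scale, converged


def huber_fit(
    years: np.ndarray | list[int],
    percents: np.ndarray | list[float],
    *,
    tol: float = 1e-8,
    maxiter: int = 50,
) -> TrendFit:
    """Fit percent ~ year by Huber M-estimation (IRLS, c = 1.345, MAD scale).

    Years are centered at the earliest year, so the intercept is the fitted
    percent there.  Requires at least 3 distinct years.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(percents, dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("trend fitting needs at least 3 distinct years")
    t0 = t.min()
    beta, scale, converged = _irls(t - t0, y, tol, maxiter)
    return TrendFit(
        slope=float(beta[1]),
        intercept=float(beta[0]),
        n_years=len(t),
        converged=converged,
        scale=scale,
    )


def robust_wald_p(
    fit: TrendFit,
    years: np.ndarray | list[int],
    percents: np.ndarray | list[float],
) -> float:
    """Robust Wald p-value for the slope of a converged Huber fit.

    The slope's standard error comes from the M-estimator covariance at the
    final IRLS weights (Huber's correction: psi-based numerator, the mean
    derivative of psi in the denominator, and the finite-sample factor
    ``k = 1 + p * var(psi') / (n * mean(psi')^2)``); the Wald statistic
    ``(slope / se)^2`` is referred to F(1, n-2).  A zero residual scale means
    an exact line: p = 0 for a nonzero slope, 1 for a flat one.
    """
    t = np.asarray(years, dtype=float)
    y = np.asarray(percents, dtype=float)
    n = len(t)
    if n <= 2:
        raise ValueError("the Wald test needs more than 2 years")
    if fit.scale == 0.0 or math.isnan(fit.scale):
        # exact fit: a materially sloped line is unambiguous, a flat one
        # carries no evidence of trend at all
        flat_tol = 1e-12 * max(1.0, abs(fit.intercept))
        return 0.0 if abs(fit.slope) > flat_tol else 1.0
    tc = t - t.min()
    X = np.column_stack([np.ones(n), tc])
    r = y - (fit.intercept + fit.slope * tc)
    u = r / fit.scale
    psi = np.clip(u, -HUBER_C, HUBER_C)
    dpsi = (np.abs(u) <= HUBER_C).astype(float)
    m1 = dpsi.mean()
    if m1 == 0.0:
        return math.nan
    k = 1.0 + 2.0 * dpsi.var() / (n * m1**2)
    s2 = k**2 * np.sum(psi**2) * fit.scale**2 / ((n - 2) * m1**2)
    cov = s2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[1, 1])
    if se == 0.0:
        return 0.0 if fit.slope != 0.0 else 1.0
    F = (fit.slope / se) ** 2
    return float(stats.f.sf(F, 1, n - 2))


def fit_trend(
    years: np.ndarray | list[int],
    percents: np.ndarray | list[float],
    alpha: float = 0.05,
    slope_min: float = 0.25,
) -> TrendFit:
    """Huber fit + robust Wald test + significance/selection flags."""
    fit = huber_fit(years, percents)
    fit.p_value = robust_wald_p(fit, years, percents)
    fit.significant = fit.p_value <= alpha
    fit.selected = fit.significant and abs(fit.slope) >= slope_min
    return fit


def select_trends(
    fits: dict[str, TrendFit] | list[tuple[str, TrendFit]],
    alpha: float = 0.05,
    slope_min: float = 0.25,
) -> list[tuple[str, TrendFit]]:
    """Apply the reporting gate (p <= alpha and |slope| >= slope_min).

    Output is in presentation order: descending slope, ties broken
    alphabetically by annotation name — positive trends first, the steepest
    decline last.
    """
    items = list(fits.items()) if isinstance(fits, dict) else list(fits)
    kept = [
        (name, f)
        for name, f in items
        if not math.isnan(f.p_value) and f.p_value <= alpha and abs(f.slope) >= slope_min
    ]
    return sorted(kept, key=lambda nf: (-nf[1].slope, nf[0]))


def compute_trends(
    store: Store,
    scope_kind: str,
    measure: str = "bioactivities",
    *,
    alpha: float = 0.05,
    slope_min: float = 0.25,
    denominator: str = "all",
    min_years: int = 3,
) -> pd.DataFrame:
    """Fit one trend per annotation of a scope kind; the machine twin of a
    trend table.

    ``scope_kind`` is ``family`` (six families), ``go`` (every GO
    biological-process term in the store), ``disease`` (every retained
    disease association), or ``all`` (the single all-target series).  Returns
    a frame with scope, annotation, measure, slope, intercept, p_value,
    n_years, significant, selected — sorted in presentation order.
    """
    if scope_kind == "family":
        values: list[str | None] = [f.value for f in SIX_FAMILIES]
    elif scope_kind == "go":
        values = sorted(store.go_terms["go_term"].unique())
    elif scope_kind == "disease":
        values = sorted(store.diseases["disease"].unique())
    elif scope_kind == "all":
        values = [None]
    else:
        raise ValueError(f"unknown scope kind: {scope_kind!r}")

    rows = []
    for value in values:
        series = yearly_counts(
            store, (scope_kind, value), measure, denominator=denominator
        )
        t, pct = series.percent_arrays()
        if len(t) < min_years:
            continue
        fit = fit_trend(t, pct, alpha=alpha, slope_min=slope_min)
        rows.append(
            {
                "scope": scope_kind,
                "annotation": value if value is not None else "all-targets",
                "measure": measure,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "p_value": fit.p_value,
                "n_years": fit.n_years,
                "significant": fit.significant,
                "selected": fit.selected,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "scope",
            "annotation",
            "measure",
            "slope",
            "intercept",
            "p_value",
            "n_years",
            "significant",
            "selected",
        ],
    )
    return df.sort_values(
        ["slope", "annotation"], ascending=[False, True]
    ).reset_index(drop=True)


def tdl_evolution(store: Store, family: str | Family) -> pd.DataFrame:
    """Yearly Target-Development-Level composition of a family's published targets.

    For each year of the filtered record window, the distinct targets of the
    family with at least one record that year are partitioned by TDL category
    (Tclin / Tchem / Tbio / Tdark / unknown); shares sum to 1.  Years in which
    no family target was published are emitted with all shares 0 and
    ``empty=True``.
    """
    fam = Family(family).value
    tdl_map = store.targets.set_index("target_id")["tdl"]
    rec = store.records.loc[store.records["family"] == fam]
    all_years = sorted(store.records["year"].unique())
    levels = ["Tclin", "Tchem", "Tbio", "Tdark", "unknown"]
    rows = []
    for year in all_years:
        tids = rec.loc[rec["year"] == year, "target_id"].unique()
        n = len(tids)
        counts = pd.Series([tdl_map.get(t, "unknown") for t in tids]).value_counts()
        row = {"year": int(year), "family": fam, "n_targets": n, "empty": n == 0}
        for lev in levels:
            row[lev] = float(counts.get(lev, 0)) / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
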