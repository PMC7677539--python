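"""Cross-source comparison of disease trends: correlation, Granger causality,
and permutation nulls.

A disease's research attention can be measured two independent ways: ``Dt``,
the yearly sum of target-linked document counts from the bioactivity store,
and ``Dp``, yearly literature counts from a direct abstract search.  For each
disease with enough external data the two series are compared by squared
Pearson correlation and by a bidirectional Granger causality test (does one
series' past improve prediction of the other beyond its own past?), yielding
two p-values per disease: ``gt1`` for Dp driving Dt and ``gt2`` for Dt
driving Dp.

Two permutation nulls calibrate the observed correlations: shuffling a
disease's own Dp counts across years (destroys temporal ordering, preserves
the marginal distribution), and replacing Dp with other diseases' Dp series
(preserves the shared secular literature growth, so its null mean can sit far
above the within-series one).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .store import Store

__all__ = [
    "DiseaseTrendPair",
    "CausalityResult",
    "ShuffleSummary",
    "build_pairs",
    "pearson_r2",
    "granger_bidirectional",
    "granger_f",
    "shuffle_within",
    "shuffle_across",
]


@dataclass
class DiseaseTrendPair:
    """Aligned (Dt, Dp) yearly count series for one disease.

    Both series are year-indexed over the common window; ``n_years`` counts
    the years with external (Dp) data present.  ``mode`` records whether the
    series are absolute counts or counts normalized to each source's yearly
    grand total.
    """

    disease: str
    dt: pd.Series
    dp: pd.Series
    mode: str = "absolute"
    rare_flag: int = 0

    @property
    def n_years(self) -> int:
        return int((self.dp > 0).sum())

    def common(self) -> tuple[np.ndarray, np.ndarray]:
        years = self.dt.index.intersection(self.dp.index)
        return self.dt.loc[years].to_numpy(float), self.dp.loc[years].to_numpy(float)


@dataclass
class CausalityResult:
    disease: str
    n_years: int
    r_squared: float
    gt1: float  # Dp -> Dt
    gt2: float  # Dt -> Dp
    rare_flag: int = 0
    lag: int = 1
    n_contiguous: int = 0


@dataclass
class ShuffleSummary:
    disease: str
    scheme: str  # "within_series" | "across_diseases"
    n_reps: int
    mean_r_squared: float


def build_pairs(
    store: Store,
    external_counts: pd.DataFrame,
    external_totals: pd.DataFrame | None = None,
    *,
    min_years: int = 10,
    mode: str = "absolute",
    dedupe_documents: bool = False,
) -> list[DiseaseTrendPair]:
    """Build one Dt/Dp pair per disease with enough external coverage.

    ``Dt`` for a disease is, per year, the sum over its associated targets of
    that target's distinct-document count (the literal reading: a document
    cited by two targets of the disease counts twice; ``dedupe_documents``
    switches to counting distinct documents across the union of targets).
    ``Dp`` comes from ``external_counts`` (columns disease/year/count).
    Diseases with external data in fewer than ``min_years`` years (boundary
    inclusive), or absent from the store, are skipped.  ``mode="normalized"``
    divides each series by its own source's yearly grand total — the store's
    distinct-document total for Dt and ``external_totals`` for Dp.
    """
    if mode not in ("absolute", "normalized"):
        raise ValueError(f"mode must be 'absolute' or 'normalized', got {mode!r}")
    if mode == "normalized" and external_totals is None:
        raise ValueError("normalized mode needs the external yearly totals")

    rec = store.records
    years = np.sort(rec["year"].unique())
    store_totals = rec.groupby("year")["document_id"].nunique()

    pairs: list[DiseaseTrendPair] = []
    for disease, ext in external_counts.groupby("disease"):
        dp = ext.set_index("year")["count"].reindex(years, fill_value=0).astype(float)
        if int((dp > 0).sum()) < min_years:
            continue
        tids = set(store.diseases.loc[store.diseases["disease"] == disease, "target_id"])
        sub = rec.loc[rec["target_id"].isin(tids)]
        if sub.empty:
            continue
        if dedupe_documents:
            dt = sub.groupby("year")["document_id"].nunique()
        else:
            dt = (
                sub.groupby(["year", "target_id"])["document_id"]
                .nunique()
                .groupby("year")
                .sum()
            )
        dt = dt.reindex(years, fill_value=0).astype(float)
        if mode == "normalized":
            dt = dt / store_totals.reindex(years).replace(0, np.nan)
            ext_tot = external_totals.set_index("year")["total"].reindex(years)
            dp = dp / ext_tot.replace(0, np.nan)
            dt, dp = dt.dropna(), dp.dropna()
        pairs.append(DiseaseTrendPair(disease=str(disease), dt=dt, dp=dp, mode=mode))
    return pairs


def pearson_r2(pair: DiseaseTrendPair) -> float:
    """Squared Pearson correlation of Dt and Dp over their common years.

    Returns NaN (a flagged missing value) when either series is constant —
    the correlation is undefined — or when fewer than 3 paired years exist.
    """
    x, y = pair.common()
    if len(x) < 3:
        raise ValueError("Pearson r^2 needs at least 3 paired years")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def granger_f(x: np.ndarray, y: np.ndarray, lag: int = 1) -> tuple[float, float]:
    """F statistic and p-value for "x Granger-causes y" at the given lag.

    Fits, over the usable observations t = lag..T0-1, the restricted model
    y_t ~ 1 + y_{t-1..lag} and the unrestricted model with x_{t-1..lag} added,
    both by least squares, and refers
    ``F = ((RSS_r - RSS_u) / lag) / (RSS_u / (T - 2*lag - 1))``
    to F(lag, T - 2*lag - 1) with T usable observations.  Returns (nan, nan)
    when the lag matrix is rank-deficient (collinear or constant series).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    T0 = len(y)
    T = T0 - lag
    dof = T - 2 * lag - 1
    if dof <= 0:
        raise ValueError(f"need at least {3 * lag + 2} observations for lag {lag}")
    yt = y[lag:]
    ylags = np.column_stack([y[lag - j : T0 - j] for j in range(1, lag + 1)])
    xlags = np.column_stack([x[lag - j : T0 - j] for j in range(1, lag + 1)])
    Xr = np.column_stack([np.ones(T), ylags])
    Xu = np.column_stack([Xr, xlags])
    if np.linalg.matrix_rank(Xu) < Xu.shape[1]:
        return math.nan, math.nan
    rss_r = float(np.sum((yt - Xr @ np.linalg.lstsq(Xr, yt, rcond=None)[0]) ** 2))
    rss_u = float(np.sum((yt - Xu @ np.linalg.lstsq(Xu, yt, rcond=None)[0]) ** 2))
    if rss_u <= 0:
        return math.inf, 0.0
    F = ((rss_r - rss_u) / lag) / (rss_u / dof)
    return float(F), float(stats.f.sf(F, lag, dof))


def _longest_contiguous(years: np.ndarray) -> np.ndarray:
    """Indices of the longest run of consecutive years (earliest run on ties)."""
    breaks = np.nonzero(np.diff(years) != 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(years) - 1]])
    lengths = ends - starts + 1
    i = int(np.argmax(lengths))
    return np.arange(starts[i], ends[i] + 1)


def granger_bidirectional(
    pair: DiseaseTrendPair, lag: int = 1, alpha: float = 0.05
) -> CausalityResult:
    """Bidirectional Granger test on the longest contiguous common year run.

    Lagged regression is ill-defined across gaps, so the test uses the longest
    run of consecutive years present in both series (length reported as
    ``n_contiguous``).  ``gt1`` tests Dp -> Dt, ``gt2`` tests Dt -> Dp;
    degenerate inputs yield NaN p-values.
    """
    years = pair.dt.index.intersection(pair.dp.index).to_numpy()
    idx = _longest_contiguous(np.sort(years))
    run = np.sort(years)[idx]
    dt = pair.dt.loc[run].to_numpy(float)
    dp = pair.dp.loc[run].to_numpy(float)
    if len(run) < 2 * lag + 3:
        raise ValueError(
            f"need a contiguous run of at least {2 * lag + 3} years, got {len(run)}"
        )
    _, gt1 = granger_f(dp, dt, lag)
    _, gt2 = granger_f(dt, dp, lag)
    return CausalityResult(
        disease=pair.disease,
        n_years=pair.n_years,
        r_squared=pearson_r2(pair),
        gt1=gt1,
        gt2=gt2,
        rare_flag=pair.rare_flag,
        lag=lag,
        n_contiguous=len(run),
    )


def _r2_against_columns(dt: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Squared correlation of ``dt`` with each column of ``cols`` (NaN where
    a column is constant)."""
    dtc = dt - dt.mean()
    denom_t = np.sqrt((dtc**2).sum())
    colc = cols - cols.mean(axis=0)
    denom_c = np.sqrt((colc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dtc @ colc) / (denom_t * denom_c)
    return r**2


def shuffle_within(
    pair: DiseaseTrendPair, n_reps: int = 1000, seed: int = 0
) -> ShuffleSummary:
    """Permutation null from shuffling the disease's own Dp counts across years.

    Each of ``n_reps`` permutations destroys the temporal ordering of Dp while
    keeping its values; the mean squared correlation to the fixed Dt is the
    null level of agreement (for exchangeable independent series it converges
    to 1/(n-1)).  Returns NaN when either series is constant.
    """
    dt, dp = pair.common()
    if np.ptp(dt) == 0 or np.ptp(dp) == 0:
        return ShuffleSummary(pair.disease, "within_series", n_reps, math.nan)
    rng = np.random.default_rng(seed)
    perms = np.empty((len(dp), n_reps))
    for j in range(n_reps):
        perms[:, j] = rng.permutation(dp)
    r2 = _r2_against_columns(dt, perms)
    return ShuffleSummary(
        pair.disease, "within_series", n_reps, float(np.nanmean(r2))
    )


def shuffle_across(
    all_pairs: list[DiseaseTrendPair],
    disease: str,
    n_draws: int = 500,
    seed: int = 0,
) -> ShuffleSummary:
    """Permutation null from correlating Dt with other diseases' Dp series.

    Draws ``n_draws`` diseases at random from the other pairs (with
    replacement when fewer are available) and averages the squared correlation
    of the target disease's Dt against each drawn Dp over their common years.
    Because all Dp series share the secular growth of the literature, this
    null can sit well above the within-series one.
    """
    target = next(p for p in all_pairs if p.disease == disease)
    others = [p for p in all_pairs if p.disease != disease]
    if not others:
        raise ValueError("need at least one other disease to shuffle across")
    rng = np.random.default_rng(seed)
    replace = len(others) < n_draws
    idx = rng.choice(len(others), size=n_draws, replace=replace)
    r2s = []
    for i in idx:
        dp = others[i].dp
        years = target.dt.index.intersection(dp.index)
        a = target.dt.loc[years].to_numpy(float)
        b = dp.loc[years].to_numpy(float)
        if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            r2s.append(math.nan)
            continue
        r = stats.pearsonr(a, b).statistic
        r2s.append(r * r)
    return ShuffleSummary(
        disease, "across_diseases", n_draws, float(np.nanmean(r2s))
    )


def causality_table(
    pairs: list[DiseaseTrendPair], lag: int = 1, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-disease causality results with a Benjamini-Hochberg column added.

    Raw p-values are what the per-disease report shows; the ``gt1_bh`` /
    ``gt2_bh`` columns carry FDR-adjusted values for users who want a
    family-wise view.
    """
    rows = []
    for p in pairs:
        try:
            res = granger_bidirectional(p, lag=lag, alpha=alpha)
        except ValueError:
            continue
        rows.append(
            {
                "disease": res.disease,
                "rare_flag": res.rare_flag,
                "n_years": res.n_years,
                "r_squared": res.r_squared,
                "gt1": res.gt1,
                "gt2": res.gt2,
                "lag": res.lag,
                "n_contiguous": res.n_contiguous,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "disease",
            "rare_flag",
            "n_years",
            "r_squared",
            "gt1",
            "gt2",
            "lag",
            "n_contiguous",
        ],
    )
    for col in ("gt1", "gt2"):
        adj = np.full(len(df), np.nan)
        ok = df[col].notna().to_numpy() if len(df) else np.array([], dtype=bool)
        if ok.any():
            adj[ok] = stats.false_discovery_control(df.loc[ok, col].to_numpy())
        df[f"{col}_bh"] = adj
    return df
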