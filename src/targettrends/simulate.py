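"""Synthetic bioactivity universes and coupled count series with known truth.

The generator emulates the statistical structure the trend analysis consumes:
a 1998-2017 yearly panel in which each annotated group of targets receives a
share of the year's total bioactivity measurements, with the share following a
linear trend in percentage points per year and the realized counts drawn
multinomially over annotations.  The multinomial (rather than independent
Poisson) noise matters: the analysis normalizes counts to the yearly total, so
the generator must induce the compositional coupling that normalization
assumes.

Each injected trend owns a disjoint group of targets carrying exactly one
annotation, so downstream aggregation by GO term, disease, or family recovers
the generated counts exactly and every stage has a parameter-recovery test
against the :class:`TruthManifest`.

Separately, :func:`generate_coupled_series` produces pairs of count series
with a lag-1 linear coupling (a driver and a response) for causality testing,
and :func:`generate_external_counts` produces per-disease yearly literature
count tables with a yearly grand total, emulating abstract-search extracts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .store import SIX_FAMILIES, Family

__all__ = [
    "TrendSpec",
    "UniverseConfig",
    "TruthManifest",
    "generate_universe",
    "write_universe",
    "simulate_share_counts",
    "generate_coupled_series",
    "generate_external_counts",
]

#: Example class names below family level, used to build hierarchical class
#: paths so that class-level decomposition has structure to recover.
_FAMILY_PATHS: dict[str, tuple[str, tuple[str, ...]]] = {
    Family.KINASE.value: ("enzyme:kinase:protein kinase", ("JAK", "SRC", "EGFR class")),
    Family.GPCR.value: (
        "membrane receptor:7tm1",
        ("dopamine receptor", "adrenergic receptor", "adenosine receptor"),
    ),
    Family.NUCLEAR_RECEPTOR.value: (
        "transcription factor:nuclear receptor",
        ("NR1", "NR2", "NR3"),
    ),
    Family.PROTEASE.value: (
        "enzyme:protease",
        ("serine protease", "metallo protease", "cysteine protease"),
    ),
    Family.ION_CHANNEL.value: (
        "ion channel:voltage-gated ion channel",
        ("sodium channel", "potassium channel", "calcium channel"),
    ),
    Family.TRANSPORTER.value: (
        "transporter:electrochemical transporter",
        ("SLC6", "SLC7", "ABC"),
    ),
}
_TDL_CYCLE = ("Tclin", "Tchem", "Tbio", "Tdark")


@dataclass(frozen=True)
class TrendSpec:
    """One injected linear share trend.

    ``kind`` selects which annotation table carries the trend: a GO
    biological-process term (``go``), a disease association (``disease``), or
    the family's own bioactivity share (``family-measure``).  ``slope`` is in
    percentage points of the yearly total per year; ``baseline`` is the share
    (fraction of the yearly total) in the first year.
    """

    kind: str  # "go" | "disease" | "family-measure"
    annotation: str
    slope_pp_per_year: float
    baseline_share: float
    family: str = Family.KINASE.value

    def __post_init__(self) -> None:
        if self.kind not in ("go", "disease", "family-measure"):
            raise ValueError(f"unknown trend kind: {self.kind}")
        if not 0.0 <= self.baseline_share <= 1.0:
            raise ValueError("baseline_share must be a fraction in [0, 1]")


def _default_specs() -> list[TrendSpec]:
    fams = [f.value for f in SIX_FAMILIES]
    return [
        TrendSpec("go", "immune system process", 1.33, 0.05, fams[0]),
        TrendSpec("go", "circulatory system process", -0.90, 0.25, fams[1]),
        TrendSpec("disease", "malignant neoplasm of breast", 0.44, 0.05, fams[0]),
        TrendSpec("disease", "schizophrenia", -0.33, 0.12, fams[5]),
        TrendSpec("family-measure", "protease share", 0.0, 0.08, fams[3]),
        TrendSpec("family-measure", "ion channel share", 0.25, 0.04, fams[4]),
    ]


@dataclass
class UniverseConfig:
    """Parameters of one synthetic universe.

    Defaults reflect the study conditions the pipeline targets: a 20-year
    panel (1998-2017), 5000 bioactivity measurements per year, and a handful
    of injected share trends whose magnitudes bracket the selection gate
    (0.25 pp/year).  Association scores for injected disease trends are drawn
    from a Beta law rescaled to [0.3, 1] so the curation-score filter keeps
    them; decoy associations spanning [0, 1] exercise the filter itself.
    """

    seed: int = 0
    year_min: int = 1998
    year_max: int = 2017
    n_targets_per_group: int = 4
    total_bioactivities_per_year: int = 5000
    trend_specs: list[TrendSpec] = field(default_factory=_default_specs)
    score_beta: tuple[float, float] = (2.0, 2.0)
    records_per_document: int = 20
    noise: str = "multinomial"

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_min, self.year_max + 1)

    def validate(self) -> None:
        if self.year_min > self.year_max:
            raise ValueError("year_min must not exceed year_max")
        if self.total_bioactivities_per_year <= 0:
            raise ValueError("total_bioactivities_per_year must be positive")
        if self.noise != "multinomial":
            raise ValueError("only multinomial noise is supported")
        probs = _share_matrix(self)
        sums = probs.sum(axis=1)
        bad = np.nonzero(sums > 1.0 + 1e-12)[0]
        if bad.size:
            year = int(self.years[bad[0]])
            raise ValueError(
                f"trend shares sum to {sums[bad[0]]:.4f} > 1 in year {year}; "
                "reduce baselines or slopes"
            )


@dataclass
class TruthManifest:
    """Ground truth of one realized universe; reproducible from (config, seed)."""

    seed: int
    years: list[int]
    total_per_year: int
    trends: list[dict]  # per spec: kind, annotation, family, slope, baseline, targets, counts
    background_counts: dict[int, int]
    targets: dict[str, dict]  # target_id -> {family, class_path, tdl, annotation}
    n_records: int

    def to_json(self) -> str:
        d = asdict(self)
        d["trends"] = [
            {**t, "counts": {str(y): c for y, c in t["counts"].items()}}
            for t in d["trends"]
        ]
        d["background_counts"] = {
            str(y): c for y, c in d["background_counts"].items()
        }
        return json.dumps(d, indent=1, sort_keys=True)


def _share_matrix(config: UniverseConfig) -> np.ndarray:
    """Per-year annotation probabilities, years x specs, clamped to [0, 1]."""
    years = config.years
    t = years - years[0]
    probs = np.empty((len(years), len(config.trend_specs)))
    for j, spec in enumerate(config.trend_specs):
        probs[:, j] = np.clip(
            spec.baseline_share + spec.slope_pp_per_year * t / 100.0, 0.0, 1.0
        )
    return probs


def simulate_share_counts(config: UniverseConfig) -> pd.DataFrame:
    """Draw the yearly annotation counts only (no record tables).

    Returns a tidy frame with columns ``year``, ``annotation``, ``count`` and
    one ``__background__`` row per year absorbing the remaining share; counts
    sum to ``total_bioactivities_per_year`` in every year.  This is the fast
    path used for parameter-recovery studies at many seeds; the full
    :func:`generate_universe` consumes the same draw.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = _share_matrix(config)
    names = [s.annotation for s in config.trend_specs]
    rows = []
    for i, year in enumerate(config.years):
        p = np.append(probs[i], max(0.0, 1.0 - probs[i].sum()))
        p = p / p.sum()
        counts = rng.multinomial(config.total_bioactivities_per_year, p)
        for name, c in zip(names + ["__background__"], counts):
            rows.append((int(year), name, int(c)))
    return pd.DataFrame(rows, columns=["year", "annotation", "count"])


def generate_universe(
    config: UniverseConfig,
) -> tuple[dict[str, pd.DataFrame], TruthManifest]:
    """Realize one universe as the five analysis tables plus its truth manifest.

    Each trend spec owns ``n_targets_per_group`` dedicated targets in its
    family, each carrying exactly that one annotation; a background group of
    unclassified targets absorbs the residual share.  Within a year, a spec's
    count is spread round-robin over its targets, compounds are drawn from a
    per-spec pool (so distinct-compound counts are sub-linear in record
    counts), and records are grouped into synthetic documents of about
    ``records_per_document`` measurements so document-count series track
    bioactivity-count series.  Identical (config, seed) gives identical
    tables.
    """
    counts_df = simulate_share_counts(config)
    rng = np.random.default_rng(config.seed + 1)  # annotation draws already used seed

    specs = list(config.trend_specs)
    groups: list[dict] = []
    targets: dict[str, dict] = {}
    tcount = 0
    for j, spec in enumerate(specs):
        base_path, classes = _FAMILY_PATHS[spec.family]
        ids = []
        for k in range(config.n_targets_per_group):
            tid = f"T{tcount:04d}"
            tcount += 1
            cls = classes[k % len(classes)]
            targets[tid] = {
                "family": spec.family,
                "class_path": f"{base_path}:{cls}",
                "tdl": _TDL_CYCLE[k % len(_TDL_CYCLE)],
                "annotation": spec.annotation,
            }
            ids.append(tid)
        groups.append({"spec": spec, "targets": ids})
    bg_ids = []
    for k in range(config.n_targets_per_group):
        tid = f"T{tcount:04d}"
        tcount += 1
        targets[tid] = {
            "family": Family.OTHER.value,
            "class_path": "enzyme:oxidoreductase",
            "tdl": _TDL_CYCLE[k % len(_TDL_CYCLE)],
            "annotation": "__background__",
        }
        bg_ids.append(tid)

    group_of = {g["spec"].annotation: g for g in groups}
    group_of["__background__"] = {"spec": None, "targets": bg_ids}

    # Per-spec compound pools: compounds are reused across years within a
    # group, giving non-trivial unique-compound counts.
    pools = {
        name: [f"C{name_i:02d}_{i:05d}" for i in range(2000)]
        for name_i, name in enumerate(list(group_of))
    }

    rec_rows = []
    doc_serial = 0
    for (year, name), sub in counts_df.groupby(["year", "annotation"], sort=True):
        c = int(sub["count"].iloc[0])
        if c == 0:
            continue
        g = group_of[name]
        tids = np.asarray(g["targets"])[np.arange(c) % len(g["targets"])]
        pool = pools[name]
        comps = rng.choice(len(pool), size=c)
        n_docs = max(1, round(c / config.records_per_document))
        docs = [f"D{doc_serial + i:06d}" for i in range(n_docs)]
        doc_serial += n_docs
        doc_idx = np.arange(c) % n_docs
        for i in range(c):
            rec_rows.append(
                (
                    pool[comps[i]],
                    tids[i],
                    docs[doc_idx[i]],
                    int(year),
                    "1",
                    9,
                    "Homo sapiens",
                    "SINGLE PROTEIN",
                )
            )

    records = pd.DataFrame(
        rec_rows,
        columns=[
            "compound_id",
            "target_id",
            "document_id",
            "year",
            "has_standard_units",
            "assay_confidence",
            "organism",
            "target_type",
        ],
    )

    targets_df = pd.DataFrame(
        [
            (tid, f"P{tid[1:]}", meta["class_path"], meta["tdl"])
            for tid, meta in targets.items()
        ],
        columns=["target_id", "accession", "class_path", "tdl"],
    )

    go_rows, dis_rows, eff_rows = [], [], []
    a, b = config.score_beta
    for g in groups:
        spec: TrendSpec = g["spec"]
        for tid in g["targets"]:
            if spec.kind == "go":
                go_rows.append((tid, spec.annotation))
            elif spec.kind == "disease":
                score = 0.3 + 0.7 * rng.beta(a, b)
                dis_rows.append((tid, spec.annotation, round(float(score), 4)))
            if targets[tid]["tdl"] == "Tclin":
                eff_rows.append((tid, f"DRUG_{tid}", 1))
    # decoy disease associations over the full score range, exercising the
    # curation-score filter without touching any injected trend
    for tid in bg_ids:
        dis_rows.append(
            (tid, "decoy disease", round(float(rng.beta(a, b)), 4))
        )

    tables = {
        "records": records,
        "targets": targets_df,
        "go_terms": pd.DataFrame(go_rows, columns=["target_id", "go_term"]),
        "diseases": pd.DataFrame(dis_rows, columns=["target_id", "disease", "score"]),
        "efficacy": pd.DataFrame(
            eff_rows, columns=["target_id", "drug_id", "disease_efficacy"]
        ),
    }

    trend_truth = []
    for g in groups:
        spec = g["spec"]
        sub = counts_df[counts_df["annotation"] == spec.annotation]
        trend_truth.append(
            {
                "kind": spec.kind,
                "annotation": spec.annotation,
                "family": spec.family,
                "slope_pp_per_year": spec.slope_pp_per_year,
                "baseline_share": spec.baseline_share,
                "targets": g["targets"],
                "counts": dict(zip(sub["year"].astype(int), sub["count"].astype(int))),
            }
        )
    bg = counts_df[counts_df["annotation"] == "__background__"]
    manifest = TruthManifest(
        seed=config.seed,
        years=[int(y) for y in config.years],
        total_per_year=config.total_bioactivities_per_year,
        trends=trend_truth,
        background_counts=dict(zip(bg["year"].astype(int), bg["count"].astype(int))),
        targets=targets,
        n_records=len(records),
    )
    return tables, manifest


def write_universe(config: UniverseConfig, out_dir: str | Path) -> TruthManifest:
    """Realize a universe and write the five CSV tables plus manifest.json."""
    tables, manifest = generate_universe(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def generate_coupled_series(
    n_years: int,
    coupling_beta: float,
    lag: int = 1,
    noise_sd: float = 5.0,
    seed: int = 0,
    *,
    ar_mean: float = 100.0,
    ar_phi: float = 0.7,
    ar_sd: float = 20.0,
    response_intercept: float = 10.0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate a driver/response pair of yearly count series with lagged coupling.

    The driver ``x`` is a stationary AR(1) around ``ar_mean`` (innovation sd
    ``ar_sd``), rounded and floored at 1 to look like literature counts.  The
    response is ``y_t = a + coupling_beta * x_{t-lag} + eps_t`` with Gaussian
    noise of sd ``noise_sd``, floored at 0 and rounded.  The driver is
    simulated with ``lag`` pre-sample values so the coupling holds for every
    returned year.  Returns ``(x, y, truth)`` where ``truth`` records the
    generating parameters.
    """
    if n_years < lag + 3:
        raise ValueError("n_years must be at least lag + 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    m = n_years + lag
    x = np.empty(m)
    x[0] = ar_mean
    for t in range(1, m):
        x[t] = ar_mean + ar_phi * (x[t - 1] - ar_mean) + rng.normal(0.0, ar_sd)
    x = np.maximum(1, np.round(x))
    eps = rng.normal(0.0, noise_sd, n_years) if noise_sd > 0 else np.zeros(n_years)
    y = response_intercept + coupling_beta * x[: m - lag][-n_years:] + eps
    y = np.maximum(0, np.round(y))
    truth = {
        "coupling_beta": coupling_beta,
        "lag": lag,
        "noise_sd": noise_sd,
        "response_intercept": response_intercept,
        "ar_mean": ar_mean,
        "ar_phi": ar_phi,
        "ar_sd": ar_sd,
    }
    return x[lag:], y, truth


def generate_external_counts(
    diseases: list[str],
    years: list[int] | np.ndarray,
    seed: int = 0,
    *,
    base_count: float = 200.0,
    common_growth: float = 1.04,
    noise_sd_log: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate per-disease yearly literature counts plus yearly grand totals.

    Every disease shares a common multiplicative yearly growth
    (``common_growth`` per year) on top of a disease-specific base level drawn
    log-normally, with log-normal year-to-year noise — the shared secular
    growth of literature volume that makes unrelated count series correlate.
    The grand total is the sum over the listed diseases plus a background
    term, so totals always dominate any single disease's count.

    Returns ``(counts, totals)``: ``counts`` has columns disease/year/count,
    ``totals`` has year/total.
    """
    if not diseases:
        raise ValueError("need at least one disease")
    rng = np.random.default_rng(seed)
    years = np.asarray(years, dtype=int)
    t = years - years[0]
    rows = []
    for disease in diseases:
        level = base_count * rng.lognormal(0.0, 0.5)
        noise = rng.lognormal(0.0, noise_sd_log, len(years))
        counts = np.maximum(0, np.round(level * common_growth**t * noise))
        for y, c in zip(years, counts):
            rows.append((disease, int(y), int(c)))
    counts_df = pd.DataFrame(rows, columns=["disease", "year", "count"])
    per_year = counts_df.groupby("year")["count"].sum()
    background = np.round(
        10 * base_count * common_growth**t * rng.lognormal(0.0, 0.05, len(years))
    )
    totals = pd.DataFrame(
        {"year": years, "total": (per_year.reindex(years).to_numpy() + background).astype(int)}
    )
    return counts_df, totals
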