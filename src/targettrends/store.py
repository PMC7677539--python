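"""Loading, validation, and filtering of bioactivity records and target annotations.

The analysis consumes two kinds of tables: *records* (one row per measured
bioactivity, linking a compound, a single-protein target, and the document that
reported the measurement, with the publication year) and *annotations* (the
target's hierarchical protein-class path, UniProt-style accession, Target
Development Level, GO biological-process terms, scored disease associations,
and drug-efficacy flags).  This module turns CSV tables into a validated
:class:`Store` and applies the core filters — publication-year window, target
organism, target type, assay confidence, and presence of standard units — that
define the analysis set everything downstream works on.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

__all__ = [
    "Family",
    "FilterConfig",
    "LoadReport",
    "Store",
    "assign_family",
    "filter_disease_associations",
    "load_tables",
    "apply_core_filters",
]


class Family(str, enum.Enum):
    """Coarse protein family, identified by keyword in the class description."""

    KINASE = "kinase"
    GPCR = "GPCR"
    NUCLEAR_RECEPTOR = "nuclear_receptor"
    PROTEASE = "protease"
    ION_CHANNEL = "ion_channel"
    TRANSPORTER = "transporter"
    OTHER = "other"


#: Keyword -> family, in fixed priority order.  Matching is case-insensitive
#: substring search on the "/"-joined class path; the first keyword that
#: matches wins, so the mapping is deterministic even for pathological paths
#: that mention two keywords.
FAMILY_KEYWORDS: tuple[tuple[str, Family], ...] = (
    ("kinase", Family.KINASE),
    ("7tm1", Family.GPCR),
    ("transcription factor", Family.NUCLEAR_RECEPTOR),
    ("protease", Family.PROTEASE),
    ("ion channel", Family.ION_CHANNEL),
    ("transporter", Family.TRANSPORTER),
)

SIX_FAMILIES: tuple[Family, ...] = tuple(f for _, f in FAMILY_KEYWORDS)


@dataclass(frozen=True)
class FilterConfig:
    """Core record filters.

    Defaults reflect the standard analysis set: human single-protein targets,
    assay confidence strictly greater than 8, standard units present, and
    publication years 1998-2017 inclusive.  Disease associations are kept when
    their curation score is at least ``min_association_score`` (0.3 keeps
    associations backed by at least one curated source).
    """

    year_min: int = 1998
    year_max: int = 2017
    organism: str = "Homo sapiens"
    target_type: str = "SINGLE PROTEIN"
    min_confidence_exclusive: int = 8
    require_units: bool = True
    min_association_score: float = 0.3

    def __post_init__(self) -> None:
        if self.year_min > self.year_max:
            raise ValueError(
                f"year_min ({self.year_min}) must not exceed year_max ({self.year_max})"
            )
        if not 0.0 <= self.min_association_score <= 1.0:
            raise ValueError("min_association_score must lie in [0, 1]")


@dataclass
class LoadReport:
    """Row-level accounting from :func:`load_tables`."""

    n_records_read: int = 0
    n_records_kept: int = 0
    drops: dict[str, int] = field(default_factory=dict)

    @property
    def n_dropped(self) -> int:
        return sum(self.drops.values())


RECORD_COLUMNS = [
    "compound_id",
    "target_id",
    "document_id",
    "year",
    "has_standard_units",
    "assay_confidence",
    "organism",
    "target_type",
]
TARGET_COLUMNS = ["target_id", "accession", "class_path", "tdl"]

TDL_LEVELS = ("Tclin", "Tchem", "Tbio", "Tdark", "unknown")


@dataclass
class Store:
    """Joined analysis set: validated records plus per-target annotations.

    ``records`` has the columns of ``RECORD_COLUMNS`` with ``year`` integer and
    ``family`` added from the target table (``other`` for targets without a
    profile row).  ``targets`` carries one row per target with its parsed
    class path (a ":"-separated string in ``class_path``), TDL category and
    assigned family.  The three annotation tables are long-format
    (target_id, term/score) tables.
    """

    records: pd.DataFrame
    targets: pd.DataFrame
    go_terms: pd.DataFrame
    diseases: pd.DataFrame
    efficacy: pd.DataFrame
    load_report: LoadReport = field(default_factory=LoadReport)
    filtered: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def family_of(self, target_id: str) -> Family:
        row = self.targets.loc[self.targets["target_id"] == target_id]
        if row.empty:
            return Family.OTHER
        return Family(row["family"].iloc[0])


def assign_family(class_path: list[str] | tuple[str, ...] | str) -> Family:
    """Map a hierarchical protein-class description to one of six families.

    The class path (coarse to fine, e.g. ``["enzyme", "kinase",
    "protein kinase", "TK"]``) is flattened with "/" and searched
    case-insensitively for the family keywords in fixed order: ``kinase``,
    ``7tm1`` (class-A GPCRs), ``transcription factor`` (nuclear receptors),
    ``protease``, ``ion channel``, ``transporter``.  The first keyword found
    wins; a path matching none maps to :attr:`Family.OTHER`.
    """
    if isinstance(class_path, str):
        flat = class_path
    else:
        flat = "/".join(class_path)
    flat = flat.lower()
    for keyword, family in FAMILY_KEYWORDS:
        if keyword in flat:
            return family
    return Family.OTHER


def filter_disease_associations(
    associations: pd.DataFrame, min_score: float = 0.3
) -> pd.DataFrame:
    """Keep disease associations whose score is >= ``min_score`` (inclusive).

    ``associations`` must have a ``score`` column with values in [0, 1];
    out-of-range scores indicate a malformed table and raise ``ValueError``.
    """
    scores = pd.to_numeric(associations["score"], errors="coerce")
    if scores.isna().any() or (scores < 0).any() or (scores > 1).any():
        bad = associations.loc[scores.isna() | (scores < 0) | (scores > 1)]
        raise ValueError(
            f"disease association scores outside [0, 1] in {len(bad)} row(s)"
        )
    return associations.loc[scores >= min_score].copy()


def _read_csv(path: str | Path, mandatory: list[str], label: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{label} table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{label} table {path} is missing column(s): {missing}")
    return df


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def load_tables(
    records_path: str | Path,
    targets_path: str | Path,
    config: FilterConfig | None = None,
    *,
    go_terms_path: str | Path | None = None,
    diseases_path: str | Path | None = None,
    efficacy_path: str | Path | None = None,
) -> Store:
    """Load and validate the record and annotation CSV tables into a store.

    Rows with an unparseable year or a missing compound/target/document id are
    dropped and counted in the store's :class:`LoadReport`; more than 50%
    dropped rows aborts the load, since that signals a schema mismatch rather
    than scattered dirt.  Disease associations are filtered by
    ``config.min_association_score`` at load time.  The annotation tables are
    optional; absent tables yield empty frames (family/GO/disease aggregations
    then simply produce no rows).
    """
    config = config or FilterConfig()
    report = LoadReport()

    rec = _read_csv(records_path, RECORD_COLUMNS, "records")
    report.n_records_read = len(rec)

    year = pd.to_numeric(rec["year"], errors="coerce")
    bad_year = year.isna() | (year <= 0) | (year != year.round())
    bad_id = (
        (rec["compound_id"].str.strip() == "")
        | (rec["target_id"].str.strip() == "")
        | (rec["document_id"].str.strip() == "")
    )
    conf = pd.to_numeric(rec["assay_confidence"], errors="coerce")
    bad_conf = conf.isna() | (conf < 0) | (conf > 9)
    report.drops = {
        "bad_year": int((bad_year & ~bad_id).sum()),
        "missing_id": int(bad_id.sum()),
        "bad_confidence": int((bad_conf & ~bad_year & ~bad_id).sum()),
    }
    keep = ~(bad_year | bad_id | bad_conf)
    rec = rec.loc[keep].copy()
    rec["year"] = year.loc[keep].astype(int)
    rec["assay_confidence"] = conf.loc[keep].astype(int)
    rec["has_standard_units"] = (
        rec["has_standard_units"].str.strip().str.lower().isin(("1", "true", "yes"))
    )
    report.n_records_kept = len(rec)
    if report.n_records_read > 0 and report.n_dropped > report.n_records_read / 2:
        raise ValueError(
            f"{report.n_dropped}/{report.n_records_read} record rows dropped; "
            "input schema probably does not match the documented dialect"
        )

    tgt = _read_csv(targets_path, TARGET_COLUMNS, "targets")
    tgt = tgt.loc[tgt["target_id"].str.strip() != ""].copy()
    tgt["tdl"] = tgt["tdl"].where(tgt["tdl"].isin(TDL_LEVELS), "unknown")
    tgt["family"] = [
        assign_family(p.split(":")).value for p in tgt["class_path"]
    ]

    go = (
        _read_csv(go_terms_path, ["target_id", "go_term"], "go_terms")
        if go_terms_path is not None
        else _empty(["target_id", "go_term"])
    )
    dis = (
        _read_csv(diseases_path, ["target_id", "disease", "score"], "diseases")
        if diseases_path is not None
        else _empty(["target_id", "disease", "score"])
    )
    if len(dis):
        dis["score"] = pd.to_numeric(dis["score"], errors="raise")
        dis = filter_disease_associations(dis, config.min_association_score)
    eff = (
        _read_csv(efficacy_path, ["target_id", "drug_id", "disease_efficacy"], "efficacy")
        if efficacy_path is not None
        else _empty(["target_id", "drug_id", "disease_efficacy"])
    )
    if len(eff):
        eff["disease_efficacy"] = pd.to_numeric(eff["disease_efficacy"]).astype(int)

    fam_map = tgt.set_index("target_id")["family"]
    rec["family"] = rec["target_id"].map(fam_map).fillna(Family.OTHER.value)

    return Store(
        records=rec.reset_index(drop=True),
        targets=tgt.reset_index(drop=True),
        go_terms=go.reset_index(drop=True),
        diseases=dis.reset_index(drop=True),
        efficacy=eff.reset_index(drop=True),
        load_report=report,
    )


def load_directory(directory: str | Path, config: FilterConfig | None = None) -> Store:
    """Load the five standard tables (records/targets/go_terms/diseases/efficacy)
    from one directory; annotation tables that are absent are treated as empty."""
    d = Path(directory)
    opt = lambda name: (d / name) if (d / name).exists() else None
    return load_tables(
        d / "records.csv",
        d / "targets.csv",
        config,
        go_terms_path=opt("go_terms.csv"),
        diseases_path=opt("diseases.csv"),
        efficacy_path=opt("efficacy.csv"),
    )


def apply_core_filters(store: Store, config: FilterConfig | None = None) -> Store:
    """Apply the core record filters and return a new store.

    Retains exactly the records with year inside ``[year_min, year_max]``,
    the configured organism and target type, assay confidence strictly greater
    than ``min_confidence_exclusive``, and (when ``require_units``) standard
    units present.  The operation is idempotent; an empty result is legal and
    only warns via the returned store's length.
    """
    config = config or FilterConfig()
    r = store.records
    mask = (
        r["year"].between(config.year_min, config.year_max)
        & (r["organism"] == config.organism)
        & (r["target_type"] == config.target_type)
        & (r["assay_confidence"] > config.min_confidence_exclusive)
    )
    if config.require_units:
        mask &= r["has_standard_units"]
    return replace(store, records=r.loc[mask].reset_index(drop=True), filtered=True)
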