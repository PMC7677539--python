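"""Attribution of an annotation trend to the protein classes driving it.

A GO-term or disease trend is a sum over the targets carrying the annotation;
grouping those targets by a protein-class level of the classification
hierarchy shows which classes carry the trend.  For display, a class is kept
as its own block in a year only if its share is at least 30% of the largest
class share in that year; smaller contributors are merged into an
``X_targets`` bucket.  The rule is evaluated per year, so a class may be
displayed in some years and bucketed in others.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .store import Family, Store

__all__ = ["ContributionBreakdown", "class_contributions"]

DISPLAY_FRACTION = 0.30
BUCKET_LABEL = "X_targets"


@dataclass
class ContributionBreakdown:
    """Per-year, per-class percent contributions to one annotation trend.

    ``table`` has one row per (year, class) with the class's percent of that
    year's total bioactivities and whether the display rule keeps it.
    """

    annotation: str
    class_depth: int | str
    table: pd.DataFrame  # columns: annotation, year, class, percent, displayed

    def display_table(self) -> pd.DataFrame:
        """The displayed classes per year, with bucketed classes merged into
        one ``X_targets`` row (percent 0 rows included for empty buckets)."""
        rows = []
        for year, sub in self.table.groupby("year"):
            for _, r in sub.loc[sub["displayed"]].iterrows():
                rows.append((self.annotation, year, r["class"], r["percent"]))
            bucket = sub.loc[~sub["displayed"], "percent"].sum()
            rows.append((self.annotation, year, BUCKET_LABEL, bucket))
        return pd.DataFrame(rows, columns=["annotation", "year", "class", "percent"])


def _class_at_depth(path: str, depth: int | str, warned: set[str]) -> str:
    parts = path.split(":")
    if depth == "auto":
        return parts[-1]
    if not isinstance(depth, int) or depth < 0:
        raise ValueError(f"class_depth must be 'auto' or a non-negative int, got {depth!r}")
    if depth >= len(parts):
        if path not in warned:
            warnings.warn(
                f"class_depth {depth} exceeds path {path!r}; using deepest level",
                stacklevel=3,
            )
            warned.add(path)
        return parts[-1]
    return parts[depth]


def class_contributions(
    store: Store,
    annotation: tuple[str, str],
    class_depth: int | str = "auto",
    *,
    family: str | Family | None = None,
) -> ContributionBreakdown:
    """Decompose an annotation's yearly bioactivity share by protein class.

    ``annotation`` is ``(kind, value)`` with kind ``go`` or ``disease``.
    For each year, the bioactivity counts of the annotated targets (optionally
    restricted to one family) are grouped by the class name at ``class_depth``
    of the class path (``"auto"`` = the most specific named level) and
    expressed as percent of that year's total bioactivities.  A class is
    flagged displayed in a year iff its share is at least 30% of the largest
    class share that year (the boundary itself is displayed); the largest
    class is therefore always displayed.
    """
    kind, value = annotation
    if kind == "go":
        tids = store.go_terms.loc[store.go_terms["go_term"] == value, "target_id"]
    elif kind == "disease":
        tids = store.diseases.loc[store.diseases["disease"] == value, "target_id"]
    else:
        raise ValueError(f"annotation kind must be 'go' or 'disease', got {kind!r}")
    tids = set(tids)
    if family is not None:
        fam = Family(family).value
        tids &= set(store.targets.loc[store.targets["family"] == fam, "target_id"])

    rec = store.records
    sub = rec.loc[rec["target_id"].isin(tids)]
    if sub.empty:
        raise ValueError(f"annotation {value!r} has no records in any year")

    warned: set[str] = set()
    path_of = store.targets.set_index("target_id")["class_path"]
    cls = sub["target_id"].map(
        lambda t: _class_at_depth(path_of.get(t, "unclassified"), class_depth, warned)
    )
    totals = rec.groupby("year").size()
    grouped = sub.groupby([sub["year"], cls]).size()

    rows = []
    for year, year_counts in grouped.groupby(level=0):
        total = totals[year]
        shares = 100.0 * year_counts.droplevel(0) / total
        cutoff = DISPLAY_FRACTION * shares.max()
        for cname, pct in shares.sort_values(ascending=False).items():
            rows.append(
                {
                    "annotation": value,
                    "year": int(year),
                    "class": cname,
                    "percent": float(pct),
                    "displayed": bool(pct >= cutoff),
                }
            )
    return ContributionBreakdown(
        annotation=value,
        class_depth=class_depth,
        table=pd.DataFrame(rows),
    )
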