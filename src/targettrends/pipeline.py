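"""End-to-end orchestration: filter -> aggregate -> fit -> select -> decompose
-> causality -> shuffle, driven by one serializable configuration.

A run is fully reproducible from its persisted configuration and seeds: every
output table is a deterministic function of the input tables and the
configured parameters, and the run manifest records seeds, parameters, and
row counts at each stage.  On any stage failure, partial outputs are removed
so an output directory is either complete or absent.
"""

from __future__ import annotations

import json
import logging
import shutil
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .causality import build_pairs, causality_table, shuffle_across, shuffle_within
from .decompose import class_contributions
from .store import FilterConfig, Store, apply_core_filters, load_directory
from .trends import compute_trends, tdl_evolution
from .store import SIX_FAMILIES

log = logging.getLogger("targettrends")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Serializable description of one full pipeline run."""

    input_dir: str
    output_dir: str
    external_counts: str | None = None  # CSV: disease,year,count
    external_totals: str | None = None  # CSV: year,total
    filters: FilterConfig = field(default_factory=FilterConfig)
    measure: str = "bioactivities"
    alpha: float = 0.05
    slope_min: float = 0.25
    denominator: str = "all"
    class_depth: int | str = "auto"
    lag: int = 1
    min_years: int = 10
    causality_mode: str = "absolute"
    shuffle_reps: int = 1000
    shuffle_draws: int = 500
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        filt = FilterConfig(**raw.pop("filters", {}))
        cfg = cls(filters=filt, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage and write the output tables plus a run manifest.

    Outputs: ``trends.csv`` (family, GO, disease, and all-target trends with
    the selection flags), ``tdl.csv`` (per-family TDL composition by year),
    ``decomposition.csv`` (class contributions for every selected GO/disease
    trend), and — when external counts are configured — ``causality.csv`` and
    ``shuffle.csv``.  ``run_manifest.json`` records versions, seeds,
    parameters, and stage row counts.
    """
    out_final = Path(config.output_dir)
    tmp = Path(tempfile.mkdtemp(prefix="ttrun_"))
    stage = "load"
    manifest: dict = {
        "targettrends_version": __version__,
        "config": config.to_dict(),
        "stages": {},
    }
    try:
        store = load_directory(config.input_dir, config.filters)
        manifest["stages"]["load"] = {
            "records_read": store.load_report.n_records_read,
            "records_kept": store.load_report.n_records_kept,
            "drops": store.load_report.drops,
        }

        stage = "filter"
        store = apply_core_filters(store, config.filters)
        if len(store) == 0:
            log.warning("core filters retained no records")
        manifest["stages"]["filter"] = {"records": len(store)}

        stage = "trends"
        frames = [
            compute_trends(
                store,
                kind,
                config.measure,
                alpha=config.alpha,
                slope_min=config.slope_min,
                denominator=config.denominator,
            )
            for kind in ("family", "go", "disease", "all")
        ]
        trends = pd.concat(frames, ignore_index=True)
        trends.to_csv(tmp / "trends.csv", index=False)
        manifest["stages"]["trends"] = {
            "fits": len(trends),
            "selected": int(trends["selected"].sum()),
        }

        stage = "tdl"
        tdl = pd.concat(
            [tdl_evolution(store, fam) for fam in SIX_FAMILIES], ignore_index=True
        )
        tdl.to_csv(tmp / "tdl.csv", index=False)
        manifest["stages"]["tdl"] = {"rows": len(tdl)}

        stage = "decompose"
        selected = trends.loc[
            trends["selected"] & trends["scope"].isin(["go", "disease"])
        ]
        decomp_frames = []
        for _, row in selected.iterrows():
            bd = class_contributions(
                store, (row["scope"], row["annotation"]), config.class_depth
            )
            decomp_frames.append(bd.table)
        decomp = (
            pd.concat(decomp_frames, ignore_index=True)
            if decomp_frames
            else pd.DataFrame(
                columns=["annotation", "year", "class", "percent", "displayed"]
            )
        )
        decomp.to_csv(tmp / "decomposition.csv", index=False)
        manifest["stages"]["decompose"] = {"rows": len(decomp)}

        if config.external_counts is not None:
            stage = "causality"
            ext = pd.read_csv(config.external_counts)
            ext_tot = (
                pd.read_csv(config.external_totals)
                if config.external_totals
                else None
            )
            pairs = build_pairs(
                store,
                ext,
                ext_tot,
                min_years=config.min_years,
                mode=config.causality_mode,
            )
            caus = causality_table(pairs, lag=config.lag, alpha=config.alpha)
            caus.to_csv(tmp / "causality.csv", index=False)
            manifest["stages"]["causality"] = {"pairs": len(pairs), "rows": len(caus)}

            stage = "shuffle"
            rows = []
            for i, p in enumerate(pairs):
                s1 = shuffle_within(p, config.shuffle_reps, seed=config.seed + i)
                rows.append(
                    (p.disease, s1.scheme, s1.n_reps, s1.mean_r_squared)
                )
                if len(pairs) > 1:
                    s2 = shuffle_across(
                        pairs, p.disease, config.shuffle_draws, seed=config.seed + i
                    )
                    rows.append((p.disease, s2.scheme, s2.n_reps, s2.mean_r_squared))
            pd.DataFrame(
                rows, columns=["disease", "scheme", "n_reps", "rnd_r_squared"]
            ).to_csv(tmp / "shuffle.csv", index=False)
            manifest["stages"]["shuffle"] = {"rows": len(rows)}

        (tmp / "run_manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    out_final.mkdir(parents=True, exist_ok=True)
    for f in tmp.iterdir():
        shutil.move(str(f), out_final / f.name)
    tmp.rmdir()
    return out_final
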