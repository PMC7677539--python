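import numpy as np
import pandas as pd
import pytest

from targettrends import (
    FilterConfig,
    Store,
    UniverseConfig,
    apply_core_filters,
    load_directory,
    write_universe,
)
from targettrends.store import LoadReport


@pytest.fixture(scope="session")
def universe_dir(tmp_path_factory):
    """One small written universe shared across tests (seed 3, 2000/year)."""
    d = tmp_path_factory.mktemp("universe")
    cfg = UniverseConfig(seed=3, total_bioactivities_per_year=2000)
    manifest = write_universe(cfg, d)
    return d, cfg, manifest


@pytest.fixture(scope="session")
def filtered_store(universe_dir):
    d, cfg, manifest = universe_dir
    fc = FilterConfig()
    return apply_core_filters(load_directory(d, fc), fc)


def make_store(records: pd.DataFrame, targets: pd.DataFrame | None = None,
               go_terms=None, diseases=None, efficacy=None) -> Store:
    """Assemble a Store directly from frames for hand-built test cases."""
    def _empty(cols):
        return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})

    if targets is None:
        targets = _empty(["target_id", "accession", "class_path", "tdl", "family"])
    if "family" not in targets.columns:
        from targettrends import assign_family
        targets = targets.copy()
        targets["family"] = [
            assign_family(p.split(":")).value for p in targets["class_path"]
        ]
    records = records.copy()
    fam_map = targets.set_index("target_id")["family"]
    records["family"] = records["target_id"].map(fam_map).fillna("other")
    return Store(
        records=records,
        targets=targets,
        go_terms=go_terms if go_terms is not None else _empty(["target_id", "go_term"]),
        diseases=diseases if diseases is not None else _empty(["target_id", "disease", "score"]),
        efficacy=efficacy if efficacy is not None else _empty(["target_id", "drug_id", "disease_efficacy"]),
        load_report=LoadReport(),
        filtered=True,
    )


def clean_record(**kw) -> dict:
    base = dict(
        compound_id="C1",
        target_id="T1",
        document_id="D1",
        year=2005,
        has_standard_units=True,
        assay_confidence=9,
        organism="Homo sapiens",
        target_type="SINGLE PROTEIN",
    )
    base.update(kw)
    return base
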