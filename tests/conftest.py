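"""Shared fixtures: tiny hand-built datasets and small synthetic bundles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from microdial.io import RECORD_COLUMNS, Dataset

_DEFAULTS = {
    "pmid": "1",
    "n_animals": 5,
    "strain": "wistar",
    "sex": "male",
    "age_class": "adult",
    "consciousness": "freely_moving",
    "anesthetic": "",
    "anesthetic_dose": np.nan,
    "perfusate": "acsf",
    "calcium_mM": 1.2,
    "flow_rate": 1.5,
    "brain_region": "striatum",
    "neurochemical": "dopamine",
    "drug": "drug a",
    "dose": 10.0,
    "route": "ip",
    "peak_time": 40.0,
    "peak_pct_baseline": 150.0,
}


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Build a valid record table from partial row dicts."""
    full = [{**_DEFAULTS, **row} for row in rows]
    return pd.DataFrame(full)[RECORD_COLUMNS]


def make_dataset(rows: list[dict], ontology: dict | None = None,
                 atc: dict | None = None, smiles: dict | None = None) -> Dataset:
    rec = make_records(rows)
    drugs = sorted(rec["drug"].unique())
    atc = atc or {}
    smiles = smiles or {}
    ann = pd.DataFrame(
        {
            "smiles": [smiles.get(d, "") for d in drugs],
            "atc_codes": [frozenset(atc.get(d, ())) for d in drugs],
        },
        index=pd.Index(drugs, name="compound"),
    )
    return Dataset(records=rec, annotations=ann, ontology=ontology or {})


@pytest.fixture
def records_factory():
    return make_records


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture(scope="session")
def small_bundle():
    """A small default-condition synthetic bundle, shared across tests."""
    from microdial.synth import SimConfig, generate_all

    return generate_all(SimConfig(seed=1234), with_smiles=True)


def fingerprint_frame(entries: dict[str, dict[tuple[str, str], float]]) -> pd.DataFrame:
    """Build a sparse ternary fingerprint matrix from nested dicts."""
    cols = sorted({t for m in entries.values() for t in m})
    idx = pd.MultiIndex.from_tuples(cols, names=["brain_region", "neurochemical"])
    return pd.DataFrame(
        [[entries[c].get(t, np.nan) for t in cols] for c in sorted(entries)],
        index=pd.Index(sorted(entries), name="compound"),
        columns=idx,
        dtype=float,
    )


@pytest.fixture
def fingerprint_factory():
    return fingerprint_frame
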