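"""Reading, validation and summarisation of microdialysis study-record tables.

A *study record* is one published in vivo microdialysis measurement: a drug
given systemically to rats at some dose, the brain region and neurochemical
sampled, the number of animals, the covariates of the experiment, and the peak
effect expressed as percent of the pre-drug baseline (100% = no change).

The canonical on-disk layout is a UTF-8 TSV with a fixed 18-column header (see
:data:`RECORD_COLUMNS`), one row per measurement, accompanied by

* an annotation CSV ``compound,smiles,atc_codes`` (ATC codes at the 3rd,
  pharmacological-subgroup level, semicolon separated, possibly empty),
* a region-ontology TSV ``fine_region<TAB>coarse_region`` mapping fine
  anatomical names many-to-one onto broad region classes, and
* a plain-text brain-expressed target list (one gene symbol per line).

Drug, region and transmitter names are normalized (trimmed, whitespace
collapsed, case-folded) on read so that trade-name capitalisation or spacing
quirks do not split groups; the normalized form is the canonical one
throughout the package.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ._util import normalize_name

#: Canonical study-record columns, in on-disk order.
RECORD_COLUMNS = [
    "pmid",
    "n_animals",
    "strain",
    "sex",
    "age_class",
    "consciousness",
    "anesthetic",
    "anesthetic_dose",
    "perfusate",
    "calcium_mM",
    "flow_rate",
    "brain_region",
    "neurochemical",
    "drug",
    "dose",
    "route",
    "peak_time",
    "peak_pct_baseline",
]

#: Columns that must be present and fully parseable.
MANDATORY_COLUMNS = [
    "pmid",
    "n_animals",
    "brain_region",
    "neurochemical",
    "drug",
    "dose",
    "route",
    "peak_time",
    "peak_pct_baseline",
]

#: Optional numeric columns; unparseable cells become missing (NaN).
OPTIONAL_NUMERIC_COLUMNS = ["anesthetic_dose", "calcium_mM", "flow_rate"]

#: Categorical covariates; blank cells become the "unknown" category.
CATEGORICAL_COLUMNS = ["strain", "sex", "age_class", "consciousness", "perfusate"]

#: Names normalized before any matching.
NAME_COLUMNS = ["drug", "brain_region", "neurochemical"]

ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]$")

_SEPS = {"tsv": "\t", "csv": ","}


@dataclass
class Dataset:
    """A validated study-record table plus its companion annotations.

    Attributes
    ----------
    records:
        DataFrame with :data:`RECORD_COLUMNS`, one row per measurement.
    annotations:
        DataFrame indexed by compound id with columns ``smiles`` (str, may be
        empty) and ``atc_codes`` (frozenset of 3rd-level ATC codes).
    ontology:
        Mapping fine region name -> coarse region name (normalized keys).
    """

    records: pd.DataFrame
    annotations: pd.DataFrame
    ontology: dict[str, str]

    @property
    def compounds(self) -> list[str]:
        return sorted(self.records["drug"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.records["brain_region"].unique())

    @property
    def neurochemicals(self) -> list[str]:
        return sorted(self.records["neurochemical"].unique())

    def __len__(self) -> int:
        return len(self.records)


def _sep(dialect: str) -> str:
    try:
        return _SEPS[dialect]
    except KeyError:
        raise ValueError(f"unknown table dialect {dialect!r}; expected 'tsv' or 'csv'")


def read_records(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read and validate a study-record table.

    Raises
    ------
    ValueError
        If a mandatory column is missing (named in the message), if
        ``n_animals``/``peak_pct_baseline`` (or any mandatory numeric) fail to
        parse (row index in the message), or if a record violates the basic
        invariants (n_animals >= 1, peak_pct_baseline > 0, dose >= 0,
        non-empty drug/region/neurochemical).
    """
    raw = pd.read_csv(path, sep=_sep(dialect), dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(
            f"study-record table {path} is missing mandatory column(s): "
            + ", ".join(missing)
        )
    df = raw.copy()
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df = df[RECORD_COLUMNS]

    for col in ("n_animals", "peak_pct_baseline", "dose", "peak_time"):
        parsed = pd.to_numeric(df[col].mask(df[col].str.strip() == ""), errors="coerce")
        bad = parsed.isna() & (df[col].str.strip() != "")
        if bad.any() or parsed.isna().any():
            rows = df.index[parsed.isna()].tolist()
            raise ValueError(f"non-numeric or empty {col!r} at row(s) {rows}")
        df[col] = parsed
    df["n_animals"] = df["n_animals"].astype(int)

    for col in OPTIONAL_NUMERIC_COLUMNS:
        df[col] = pd.to_numeric(df[col].mask(df[col].str.strip() == ""), errors="coerce")

    for col in CATEGORICAL_COLUMNS:
        df[col] = df[col].str.strip().replace("", "unknown")

    originals = df[NAME_COLUMNS].copy()
    for col in NAME_COLUMNS:
        df[col] = df[col].map(normalize_name)

    empties = (df[NAME_COLUMNS] == "").any(axis=1)
    if empties.any():
        raise ValueError(
            f"empty drug/brain_region/neurochemical at row(s) {df.index[empties].tolist()}"
        )
    if (df["n_animals"] < 1).any():
        rows = df.index[df["n_animals"] < 1].tolist()
        raise ValueError(f"n_animals < 1 at row(s) {rows}")
    if (df["peak_pct_baseline"] <= 0).any():
        rows = df.index[df["peak_pct_baseline"] <= 0].tolist()
        raise ValueError(f"peak_pct_baseline must be positive; violated at row(s) {rows}")
    if (df["dose"] < 0).any():
        rows = df.index[df["dose"] < 0].tolist()
        raise ValueError(f"negative dose at row(s) {rows}")

    dup = df.duplicated(keep="first")
    if dup.any():
        warnings.warn(
            f"dropping {int(dup.sum())} exact duplicate study record(s)",
            stacklevel=2,
        )
        df = df[~dup].reset_index(drop=True)
        originals = originals[~dup.values].reset_index(drop=True)
    df = df.reset_index(drop=True)
    df.attrs["original_names"] = originals.reset_index(drop=True)
    return df


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read the compound annotation CSV (compound, smiles, atc_codes)."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in ("compound", "smiles", "atc_codes"):
        if col not in raw.columns:
            raise ValueError(f"annotation table {path} is missing column {col!r}")
    compounds = raw["compound"].map(normalize_name)
    codes = []
    for i, cell in enumerate(raw["atc_codes"]):
        parts = [p.strip().upper() for p in cell.split(";") if p.strip()]
        bad = [p for p in parts if not ATC_PATTERN.match(p)]
        if bad:
            raise ValueError(
                f"malformed 3rd-level ATC code(s) {bad} at annotation row {i}"
            )
        codes.append(frozenset(parts))
    ann = pd.DataFrame(
        {"smiles": raw["smiles"].str.strip().values, "atc_codes": codes},
        index=pd.Index(compounds, name="compound"),
    )
    if ann.index.duplicated().any():
        dups = sorted(ann.index[ann.index.duplicated()].unique())
        raise ValueError(f"duplicate annotation rows for compound(s): {dups}")
    return ann


def read_ontology(path: str | Path) -> dict[str, str]:
    """Read the fine -> coarse brain-region ontology TSV."""
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("fine_region", "coarse_region"):
        if col not in raw.columns:
            raise ValueError(f"ontology table {path} is missing column {col!r}")
    mapping: dict[str, str] = {}
    for fine, coarse in zip(raw["fine_region"], raw["coarse_region"]):
        mapping[normalize_name(fine)] = normalize_name(coarse)
    return mapping


def read_target_list(path: str | Path) -> list[str]:
    """Read a plain-text target list, one gene symbol per line."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def read_dataset(
    records: str | Path,
    annotations: str | Path | None = None,
    ontology: str | Path | None = None,
    dialect: str = "tsv",
) -> Dataset:
    """Assemble a :class:`Dataset` from its component files.

    Every drug appearing in the records must have an annotation row (its ATC
    set may be empty); if no annotation file is given, empty annotations are
    synthesised for all drugs.
    """
    rec = read_records(records, dialect=dialect)
    if annotations is not None:
        ann = read_annotations(annotations)
        missing = sorted(set(rec["drug"]) - set(ann.index))
        if missing:
            raise ValueError(f"drugs without an annotation row: {missing}")
    else:
        drugs = sorted(rec["drug"].unique())
        ann = pd.DataFrame(
            {"smiles": [""] * len(drugs), "atc_codes": [frozenset()] * len(drugs)},
            index=pd.Index(drugs, name="compound"),
        )
    ont = read_ontology(ontology) if ontology is not None else {}
    return Dataset(records=rec, annotations=ann, ontology=ont)


def write_records(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    df[RECORD_COLUMNS].to_csv(path, sep=_sep(dialect), index=False, na_rep="")


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "compound": ann.index,
            "smiles": ann["smiles"].values,
            "atc_codes": [";".join(sorted(c)) for c in ann["atc_codes"]],
        }
    )
    out.to_csv(path, index=False)


def write_ontology(mapping: Mapping[str, str], path: str | Path) -> None:
    out = pd.DataFrame(sorted(mapping.items()), columns=["fine_region", "coarse_region"])
    out.to_csv(path, sep="\t", index=False)


def write_dataset(ds: Dataset, outdir: str | Path, dialect: str = "tsv") -> dict[str, Path]:
    """Write a dataset to ``outdir`` in the canonical file layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = "tsv" if dialect == "tsv" else "csv"
    paths = {
        "records": outdir / f"records.{ext}",
        "annotations": outdir / "annotations.csv",
        "ontology": outdir / "ontology.tsv",
    }
    write_records(ds.records, paths["records"], dialect=dialect)
    write_annotations(ds.annotations, paths["annotations"])
    write_ontology(ds.ontology, paths["ontology"])
    return paths


def map_regions(ds: Dataset, level: str = "coarse") -> Dataset:
    """Map record brain regions onto the requested ontology level.

    ``level="fine"`` returns the dataset unchanged (a copy); ``level="coarse"``
    replaces every record's region by its coarse class from the ontology.
    Fine regions absent from the ontology raise a ValueError listing them.
    """
    if level == "fine":
        return replace(ds, records=ds.records.copy())
    if level != "coarse":
        raise ValueError(f"unknown ontology level {level!r}; expected 'fine' or 'coarse'")
    regions = ds.records["brain_region"]
    unmapped = sorted(set(regions) - set(ds.ontology))
    if unmapped:
        raise ValueError(f"fine region(s) not covered by the ontology: {unmapped}")
    rec = ds.records.copy()
    rec["brain_region"] = regions.map(ds.ontology)
    return replace(ds, records=rec)


def completeness(ds: Dataset) -> float:
    """Fraction of the compound x region x neurochemical grid actually measured.

    The denominator is the full cross product of all compounds, regions and
    neurochemicals observed anywhere in the dataset; the numerator counts
    distinct measured (compound, region, neurochemical) tuples.
    """
    if len(ds.records) == 0:
        raise ValueError("completeness is undefined on an empty dataset")
    rec = ds.records
    measured = rec[["drug", "brain_region", "neurochemical"]].drop_duplicates()
    total = (
        rec["drug"].nunique()
        * rec["brain_region"].nunique()
        * rec["neurochemical"].nunique()
    )
    return len(measured) / total


def summarize_dataset(ds: Dataset) -> dict[str, pd.DataFrame]:
    """Per-covariate proportions and per-region/neurochemical entry counts.

    Returns a dict of DataFrames (columns ``n`` and ``pct``), keyed by the
    summarized field: the categorical covariates (sex, age_class, strain,
    consciousness) plus ``neurochemical`` and ``brain_region``.
    """
    rec = ds.records
    out: dict[str, pd.DataFrame] = {}
    for col in ("sex", "age_class", "strain", "consciousness", "neurochemical", "brain_region"):
        counts = rec[col].value_counts()
        out[col] = pd.DataFrame(
            {"n": counts, "pct": 100.0 * counts / len(rec) if len(rec) else counts}
        )
        out[col].index.name = col
    return out
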