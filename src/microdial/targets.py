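"""Association of predicted drug-target bioactivities with neurochemical response.

The target-prediction matrix is a binary drug x target table produced
upstream by a ligand-based target-prediction tool at probability threshold
0.5; producing it is out of scope here. Targets are first filtered to those
expressed in brain tissue (a plain gene list input). For every neurochemical
(or brain region) the *hit percentage* of a target is the share of
responding drugs — drugs with at least one measured, non-baseline fingerprint
entry for that category — that are predicted active at the target. Links with
perfect (100%) hit rates are the candidate target-transmitter associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import normalize_name


def read_predictions(path) -> pd.DataFrame:
    """Read a binary predictions CSV (first column compound id, rest targets)."""
    raw = pd.read_csv(path)
    raw = raw.set_index(raw.columns[0])
    raw.index = pd.Index([normalize_name(i) for i in raw.index], name="compound")
    vals = raw.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("prediction matrix must be binary (0/1)")
    if raw.index.duplicated().any() or raw.columns.duplicated().any():
        raise ValueError("prediction matrix has duplicate row or column labels")
    return raw.astype(np.uint8)


@dataclass
class BrainFilterResult:
    matrix: pd.DataFrame
    n_retained: int
    n_total: int


def filter_brain_targets(tp: pd.DataFrame, brain_targets) -> BrainFilterResult:
    """Restrict prediction columns to brain-expressed targets."""
    genes = list(brain_targets)
    if not genes:
        raise ValueError("brain target list is empty")
    keep = [c for c in tp.columns if c in set(genes)]
    if not keep:
        raise ValueError("no prediction target overlaps the brain target list")
    return BrainFilterResult(matrix=tp[keep], n_retained=len(keep), n_total=tp.shape[1])


@dataclass
class AssociationResult:
    """Target x category hit-percentage table.

    ``table`` holds hit percentages in [0, 100] (NaN where a category had no
    responding drug); ``support`` the number of responding drugs per category;
    ``low_support`` flags categories with support < 3; ``missing_compounds``
    lists fingerprinted compounds absent from the prediction matrix.
    """

    table: pd.DataFrame
    support: pd.Series
    by: str
    mode: str
    low_support: pd.Series = field(repr=False, default=None)
    missing_compounds: list = field(default_factory=list)


def hit_percentages(
    tp: pd.DataFrame,
    fps: pd.DataFrame,
    by: str = "neurochemical",
    mode: str = "category",
    direction: str = "any",
) -> AssociationResult:
    """Hit percentage of every target within every neurochemical or region.

    Parameters
    ----------
    by:
        ``"neurochemical"`` or ``"region"`` — the category the fingerprint
        tuples are aggregated over.
    mode:
        ``"category"`` (default): a drug responds at category c if any of its
        measured tuples under c has a non-zero sign; hit% is computed once
        over that responding set. ``"tuple_mean"``: hit% is computed per
        (region, neurochemical) tuple first and then averaged over the
        tuples of the category.
    direction:
        ``"any"`` counts both up and down responses; ``"up"``/``"down"``
        restrict to one direction.
    """
    if by == "neurochemical":
        level = "neurochemical"
    elif by in ("region", "brain_region"):
        level = "brain_region"
    else:
        raise ValueError(f"unknown aggregation {by!r}; expected 'neurochemical' or 'region'")
    if mode not in ("category", "tuple_mean"):
        raise ValueError(f"unknown mode {mode!r}")
    shared = sorted(set(fps.index) & set(tp.index))
    missing = sorted(set(fps.index) - set(tp.index))
    if missing:
        warnings.warn(
            f"{len(missing)} fingerprinted compound(s) absent from the "
            "prediction matrix were excluded",
            stacklevel=2,
        )
    if not shared:
        raise ValueError("no compound is shared between fingerprints and predictions")
    F = fps.loc[shared]
    T = tp.loc[shared].astype(float)
    vals = F.to_numpy(dtype=float)
    if direction == "any":
        responding = (~np.isnan(vals)) & (vals != 0)
    elif direction == "up":
        responding = vals == 1
    elif direction == "down":
        responding = vals == -1
    else:
        raise ValueError(f"unknown direction {direction!r}")
    cats = F.columns.get_level_values(level)
    categories = sorted(cats.unique())
    hit_cols, supports = {}, {}
    for c in categories:
        mask = responding[:, cats == c]
        resp_rows = mask.any(axis=1)
        supports[c] = int(resp_rows.sum())
        if mode == "category":
            if supports[c] == 0:
                hit_cols[c] = pd.Series(np.nan, index=T.columns)
            else:
                hit_cols[c] = 100.0 * T.loc[resp_rows].mean(axis=0)
        else:  # tuple_mean
            per_tuple = []
            for j in range(mask.shape[1]):
                rows = mask[:, j]
                if rows.any():
                    per_tuple.append(100.0 * T.loc[rows].mean(axis=0))
            if per_tuple:
                hit_cols[c] = pd.concat(per_tuple, axis=1).mean(axis=1)
            else:
                hit_cols[c] = pd.Series(np.nan, index=T.columns)
    table = pd.DataFrame(hit_cols)
    table.index.name = "target"
    table.columns.name = level
    support = pd.Series(supports, name="support")
    if (support == 0).all():
        raise ValueError("no category has any responding drug")
    return AssociationResult(
        table=table,
        support=support,
        by=by,
        mode=mode,
        low_support=support < 3,
        missing_compounds=missing,
    )


@dataclass
class TopLinks:
    links: pd.DataFrame  # target, category, hit_pct, support (ranked)
    display_targets: list


def top_links(assoc: AssociationResult, hit_min: float = 100.0, min_categories: int = 3) -> TopLinks:
    """Ranked (category, target) links at or above a hit-percentage threshold.

    Links are ranked by hit percentage, then support. The display subset
    contains targets reaching ``hit_min`` in at least ``min_categories``
    categories (the convention used for dense association heat maps).
    """
    long = assoc.table.stack(future_stack=True).dropna().rename("hit_pct").reset_index()
    long.columns = ["target", "category", "hit_pct"]
    long["support"] = long["category"].map(assoc.support)
    eps = 1e-9
    links = long[long["hit_pct"] >= hit_min - eps].copy()
    links = links.sort_values(
        ["hit_pct", "support", "target", "category"],
        ascending=[False, False, True, True],
    ).reset_index(drop=True)
    counts = links.groupby("target")["category"].nunique()
    display = sorted(counts.index[counts >= min_categories])
    return TopLinks(links=links, display_targets=display)


def association_long(assoc: AssociationResult) -> pd.DataFrame:
    """Long-format export: target, category, hit_pct, support, low_support."""
    long = assoc.table.stack(future_stack=True).dropna().rename("hit_pct").reset_index()
    long.columns = ["target", "category", "hit_pct"]
    long["support"] = long["category"].map(assoc.support)
    long["low_support"] = long["category"].map(assoc.low_support)
    return long
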