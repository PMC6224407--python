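"""Region x transmitter response-frequency maps and hierarchical clustering."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .fingerprints import TUPLE_LEVELS


def updown_fractions(fps: pd.DataFrame) -> pd.DataFrame:
    """Per (neurochemical, region) tuple, how often compounds went up vs down.

    Aggregates fingerprint signs across compounds: ``n_up``/``n_down`` count
    +1/-1 entries, ``n_total`` counts all measured entries (including exact
    no-change), and ``fraction_up = n_up / (n_up + n_down)`` (NaN when no
    directional response was ever recorded). Tuples never measured do not
    appear.
    """
    V = fps.to_numpy(dtype=float)
    n_up = (V == 1).sum(axis=0)
    n_down = (V == -1).sum(axis=0)
    n_total = (~np.isnan(V)).sum(axis=0)
    out = pd.DataFrame(
        {"n_up": n_up, "n_down": n_down, "n_total": n_total}, index=fps.columns
    )
    out = out[out["n_total"] > 0]
    denom = out["n_up"] + out["n_down"]
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction_up"] = np.where(denom > 0, out["n_up"] / denom, np.nan)
    out = out.reset_index()
    # (neurochemical, region) row order for the frequency map
    return out[["neurochemical", "brain_region", "n_up", "n_down", "n_total", "fraction_up"]]


def regions_upregulated(freq: pd.DataFrame, neurochemical: str) -> tuple[int, int]:
    """(#regions with fraction_up strictly > 0.5, #measured regions) for one transmitter."""
    sub = freq[(freq["neurochemical"] == neurochemical) & freq["fraction_up"].notna()]
    return int((sub["fraction_up"] > 0.5).sum()), int(len(sub))


@dataclass
class ClusterResult:
    row_order: list
    col_order: list
    row_linkage: np.ndarray = field(repr=False)
    col_linkage: np.ndarray = field(repr=False)
    matrix: pd.DataFrame = field(repr=False)  # filtered, imputed, original order
    dropped_rows: list = field(default_factory=list)
    impute_value: float = 100.0


def hierarchical_cluster(
    activity: pd.DataFrame,
    completeness_min: float = 0.5,
    impute_value: float = 100.0,
) -> ClusterResult:
    """Complete-linkage Euclidean clustering of the activity matrix.

    Compounds observed at fewer than ``completeness_min`` of the columns are
    dropped; missing cells that survive are imputed at ``impute_value``
    (baseline, i.e. "no change") before clustering rows and columns.
    """
    obs = activity.notna().mean(axis=1)
    keep = obs >= completeness_min
    dropped = activity.index[~keep].tolist()
    sub = activity.loc[keep]
    sub = sub.loc[:, sub.notna().any(axis=0)]
    if sub.shape[0] < 2 or sub.shape[1] < 2:
        raise ValueError(
            "fewer than 2 rows or columns remain after the completeness filter "
            f"(shape {sub.shape})"
        )
    X = sub.fillna(impute_value).to_numpy(dtype=float)
    row_link = hierarchy.linkage(X, method="complete", metric="euclidean")
    col_link = hierarchy.linkage(X.T, method="complete", metric="euclidean")
    return ClusterResult(
        row_order=[sub.index[i] for i in hierarchy.leaves_list(row_link)],
        col_order=[sub.columns[i] for i in hierarchy.leaves_list(col_link)],
        row_linkage=row_link,
        col_linkage=col_link,
        matrix=sub.fillna(impute_value),
        dropped_rows=dropped,
        impute_value=impute_value,
    )


def linkage_table(linkage: np.ndarray, labels: list) -> pd.DataFrame:
    """Merge steps of a linkage as a flat table (step, members, height)."""
    n = len(labels)
    clusters: dict[int, list] = {i: [labels[i]] for i in range(n)}
    rows = []
    for step, (a, b, height, _size) in enumerate(linkage):
        members = clusters[int(a)] + clusters[int(b)]
        clusters[n + step] = members
        rows.append({
            "step": step,
            "height": float(height),
            "members": ";".join(str(m) for m in members),
        })
    return pd.DataFrame(rows)
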