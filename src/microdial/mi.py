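"""Normalized mutual information between annotation spaces and responses.

How well do a drug's labels — its 3rd-level ATC codes, or its predicted
protein targets — explain its neurochemical response? For every (label,
response tuple) pair the drugs measured at that tuple are kept, and the
normalized mutual information between the binary label vector and the ternary
sign vector is computed:

    NMI(X, Y) = I(X; Y) / mean(H(X), H(Y))

with natural-log entropies, so NMI lies in [0, 1]. Conventions for degenerate
vectors: both constant -> 1.0 (each is perfectly determined by the other);
exactly one constant -> 0.0. Scores are aggregated to per-label means and
ranked by per-label medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fingerprints import TUPLE_LEVELS


def nmi(x, y) -> float:
    """Normalized mutual information of two categorical vectors.

    Arithmetic-mean normalization, natural logs; see module docstring for the
    constant-vector conventions. Vectors must have equal length >= 2.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("nmi expects two equal-length 1-D vectors")
    n = x.size
    if n < 2:
        raise ValueError("nmi requires at least 2 observations")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx = int(xi.max()) + 1
    ny = int(yi.max()) + 1
    if nx == 1 and ny == 1:
        return 1.0
    if nx == 1 or ny == 1:
        return 0.0
    c = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny).astype(float)
    pxy = c / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    hx = -np.sum(px[px > 0] * np.log(px[px > 0]))
    hy = -np.sum(py[py > 0] * np.log(py[py > 0]))
    nz = pxy > 0
    info = float(np.sum(pxy[nz] * (np.log(pxy[nz]) - np.log(np.outer(px, py)[nz]))))
    return float(np.clip(info / ((hx + hy) / 2.0), 0.0, 1.0))


def atc_annotation_matrix(annotations: pd.DataFrame) -> pd.DataFrame:
    """Binary compound x ATC-code membership matrix (all-zero rows allowed)."""
    codes = sorted(set().union(*annotations["atc_codes"]))
    if not codes:
        raise ValueError("no compound carries an ATC code")
    data = {
        code: [int(code in s) for s in annotations["atc_codes"]] for code in codes
    }
    return pd.DataFrame(data, index=annotations.index, dtype=np.uint8)


def pairwise_nmi_matrix(ann: pd.DataFrame, fps: pd.DataFrame) -> pd.DataFrame:
    """NMI of every (annotation label, response tuple) pair.

    Drugs lacking a measurement at a tuple are dropped for that pair; pairs
    with fewer than 2 remaining drugs are undefined and omitted. Returns a
    long table (label, brain_region, neurochemical, n_drugs, nmi).
    """
    shared = sorted(set(ann.index) & set(fps.index))
    if len(shared) < 2:
        raise ValueError("fewer than 2 compounds shared between annotations and fingerprints")
    A = ann.loc[shared].to_numpy()
    F = fps.loc[shared].to_numpy(dtype=float)
    labels = list(ann.columns)
    rows = []
    for j, (region, chem) in enumerate(fps.columns):
        mask = ~np.isnan(F[:, j])
        m = int(mask.sum())
        if m < 2:
            continue
        y = F[mask, j].astype(int)
        for li, label in enumerate(labels):
            rows.append({
                "label": label,
                "brain_region": region,
                "neurochemical": chem,
                "n_drugs": m,
                "nmi": nmi(A[mask, li], y),
            })
    return pd.DataFrame(rows, columns=["label", *TUPLE_LEVELS, "n_drugs", "nmi"])


@dataclass
class OverallMI:
    per_label_mean: pd.Series
    median: float
    sd: float
    n_labels: int


def aggregate_mi(scores: pd.DataFrame, per: str = "label", pooled: bool = False):
    """Aggregate pairwise NMI scores.

    ``per="label"`` returns the per-label mean over that label's defined
    pairs. ``per="overall"`` summarises the distribution of per-label means
    (median, SD) — or, with ``pooled=True``, of all pairs pooled.
    """
    if scores.empty:
        raise ValueError("no NMI scores to aggregate")
    means = scores.groupby("label")["nmi"].mean()
    if per == "label":
        return means
    if per != "overall":
        raise ValueError(f"unknown aggregation {per!r}")
    vals = scores["nmi"] if pooled else means
    return OverallMI(
        per_label_mean=means,
        median=float(vals.median()),
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
        n_labels=int(len(means)),
    )


@dataclass
class LeaveOneOutMI:
    medians: pd.Series  # excluded label -> overall median of remaining per-label means
    sd: float


def loo_mi_robustness(
    ann: pd.DataFrame, fps: pd.DataFrame, scores: pd.DataFrame | None = None
) -> LeaveOneOutMI:
    """Shift of the overall median when each label is left out in turn."""
    if ann.shape[1] < 2:
        raise ValueError("leave-one-out robustness requires at least 2 labels")
    if scores is None:
        scores = pairwise_nmi_matrix(ann, fps)
    means = scores.groupby("label")["nmi"].mean()
    medians = pd.Series(
        {lab: float(means.drop(lab, errors="ignore").median()) for lab in ann.columns},
        name="median_without",
    )
    return LeaveOneOutMI(medians=medians, sd=float(medians.std(ddof=1)))


def top_k_features(scores: pd.DataFrame, k: int) -> pd.DataFrame:
    """Labels ranked by median per-pair NMI (ties: mean, then name).

    Returns the top ``k`` rows of (label, median, mean, n_pairs); asking for
    more labels than exist returns them all.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if scores.empty:
        raise ValueError("no NMI scores to rank")
    g = scores.groupby("label")["nmi"]
    ranked = pd.DataFrame(
        {"median": g.median(), "mean": g.mean(), "n_pairs": g.size()}
    ).reset_index()
    ranked = ranked.sort_values(
        ["median", "mean", "label"], ascending=[False, False, True], kind="stable"
    )
    return ranked.head(k).reset_index(drop=True)
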