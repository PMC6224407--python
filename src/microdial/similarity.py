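"""Missing-data-aware similarity between response and chemical fingerprints.

Response fingerprints are sparse ternary vectors; two compounds are compared
only over the tuples measured for *both* (the shared set S). Three metrics
are provided:

``jaccard_updown`` (default)
    Each shared tuple expands into an up-bit and a down-bit; the classic
    Tanimoto/Jaccard |A & B| / |A | B| is applied to the expanded bits.
``rogers_tanimoto``
    The Rogers-Tanimoto similarity (matches / (matches + 2 * mismatches),
    counting both-zero positions as matches) on the same expansion.
``signed_agreement``
    Fraction of shared tuples with identical sign.

Pairs with an empty shared set are *undefined* (NaN), never zero: missingness
is not dissimilarity. Chemical fingerprints are compared by plain Tanimoto.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

METRICS = ("jaccard_updown", "rogers_tanimoto", "signed_agreement")


def _pairwise_from_signs(V: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs response similarity from a signs matrix (rows = compounds)."""
    M = (~np.isnan(V)).astype(float)
    U = (V == 1).astype(float)
    D = (V == -1).astype(float)
    S = M @ M.T  # shared-tuple counts
    UU = U @ U.T
    DD = D @ D.T
    with np.errstate(invalid="ignore", divide="ignore"):
        if metric == "signed_agreement":
            Z = (V == 0).astype(float)
            sim = (UU + DD + Z @ Z.T) / S
        elif metric == "jaccard_updown":
            UM = U @ M.T
            DM = D @ M.T
            union = (UM + UM.T - UU) + (DM + DM.T - DD)
            sim = (UU + DD) / union
            # both sides all "no change" on S: identical, similarity 1
            sim = np.where((union == 0) & (S > 0), 1.0, sim)
        elif metric == "rogers_tanimoto":
            UM = U @ M.T
            DM = D @ M.T
            union = (UM + UM.T - UU) + (DM + DM.T - DD)
            matches = UU + DD + (2.0 * S - union)  # one-one plus zero-zero bits
            sim = matches / (4.0 * S - matches)  # m / (m + 2 * (2S - m))
        else:
            raise ValueError(f"unknown response-similarity metric {metric!r}")
    sim = np.where(S == 0, np.nan, sim)
    return sim


def pairwise_response_similarity(fps: pd.DataFrame, metric: str = "jaccard_updown") -> pd.DataFrame:
    """Square all-pairs similarity matrix over a fingerprint matrix's rows."""
    if metric not in METRICS:
        raise ValueError(f"unknown response-similarity metric {metric!r}")
    sim = _pairwise_from_signs(fps.to_numpy(dtype=float), metric)
    return pd.DataFrame(sim, index=fps.index, columns=fps.index)


def response_similarity(a: pd.Series, b: pd.Series, metric: str = "jaccard_updown") -> float:
    """Similarity of two ternary response fingerprints over their shared tuples.

    Returns NaN (undefined) when no tuple is measured in both.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown response-similarity metric {metric!r}")
    idx = a.index.union(b.index)
    V = np.vstack([
        a.reindex(idx).to_numpy(dtype=float),
        b.reindex(idx).to_numpy(dtype=float),
    ])
    return float(_pairwise_from_signs(V, metric)[0, 1])


def chemical_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient |a & b| / |a | b| of two binary fingerprints.

    Defined as 1.0 when both fingerprints are all-zero (identical).
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(
            f"fingerprint length mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def pairwise_chemical_similarity(chem: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Tanimoto matrix over a compound x bit fingerprint frame."""
    B = chem.to_numpy(dtype=float)
    inter = B @ B.T
    counts = B.sum(axis=1)
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = inter / union
    sim = np.where(union == 0, 1.0, sim)
    return pd.DataFrame(sim, index=chem.index, columns=chem.index)


@dataclass
class SimilarityDistribution:
    """A labelled collection of pairwise similarity coefficients."""

    label: str  # "intra" or "inter"
    space: str  # "response" or "chemical"
    values: np.ndarray

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def median(self) -> float:
        return float(np.median(self.values)) if self.n else float("nan")

    @property
    def q1(self) -> float:
        return float(np.quantile(self.values, 0.25)) if self.n else float("nan")

    @property
    def q3(self) -> float:
        return float(np.quantile(self.values, 0.75)) if self.n else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if self.n > 1 else float("nan")

    def summary(self) -> dict:
        return {
            "label": self.label,
            "space": self.space,
            "n": self.n,
            "median": self.median,
            "q1": self.q1,
            "q3": self.q3,
            "sd": self.sd,
        }


@dataclass
class IntraInterResult:
    intra: SimilarityDistribution
    inter: SimilarityDistribution
    per_class: dict[str, SimilarityDistribution] = field(default_factory=dict)
    n_undefined: int = 0
    pairs: pd.DataFrame | None = field(default=None, repr=False)


def _similarity_matrix(fps, chem, space, metric):
    if space == "response":
        if fps is None:
            raise ValueError("response space requires response fingerprints")
        return pairwise_response_similarity(fps, metric=metric)
    if space == "chemical":
        if chem is None:
            raise ValueError("chemical space requires chemical fingerprints")
        return pairwise_chemical_similarity(chem)
    raise ValueError(f"unknown similarity space {space!r}")


def intra_inter_atc(
    fps: pd.DataFrame | None,
    annotations: pd.DataFrame,
    space: str = "response",
    metric: str = "jaccard_updown",
    min_class_size: int = 4,
    chem: pd.DataFrame | None = None,
) -> IntraInterResult:
    """Contrast within-class vs between-class pairwise similarity.

    Compounds without any ATC code are excluded. A pair sharing at least one
    3rd-level ATC code is *intra*, otherwise *inter*. Pairs with undefined
    similarity (no shared measured tuple) are excluded and counted. Per-class
    distributions are additionally emitted for ATC classes with at least
    ``min_class_size`` member compounds.
    """
    matrix = _similarity_matrix(fps, chem, space, metric)
    codes = {
        c: s for c, s in annotations["atc_codes"].items() if s and c in matrix.index
    }
    compounds = sorted(codes)
    if len(compounds) < 2:
        raise ValueError("need at least 2 ATC-annotated compounds with fingerprints")
    sim = matrix.loc[compounds, compounds].to_numpy()
    intra_vals, inter_vals, rows = [], [], []
    n_undef = 0
    for i, j in combinations(range(len(compounds)), 2):
        v = sim[i, j]
        a, b = compounds[i], compounds[j]
        if np.isnan(v):
            n_undef += 1
            continue
        relation = "intra" if codes[a] & codes[b] else "inter"
        (intra_vals if relation == "intra" else inter_vals).append(v)
        rows.append({"compound_a": a, "compound_b": b, "space": space,
                     "similarity": v, "relation": relation})
    if not rows:
        raise ValueError("no compound pair has a defined similarity")
    per_class: dict[str, SimilarityDistribution] = {}
    all_codes = sorted(set().union(*codes.values()))
    for code in all_codes:
        members = [c for c in compounds if code in codes[c]]
        if len(members) < min_class_size:
            continue
        vals = [
            sim[compounds.index(a), compounds.index(b)]
            for a, b in combinations(members, 2)
        ]
        vals = np.array([v for v in vals if not np.isnan(v)])
        per_class[code] = SimilarityDistribution(label=code, space=space, values=vals)
    return IntraInterResult(
        intra=SimilarityDistribution("intra", space, np.asarray(intra_vals, float)),
        inter=SimilarityDistribution("inter", space, np.asarray(inter_vals, float)),
        per_class=per_class,
        n_undefined=n_undef,
        pairs=pd.DataFrame(rows),
    )


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class ExclusionRobustness:
    """Leave-one-ATC-code-out stability of the intra/inter medians."""

    medians: pd.DataFrame  # index: excluded code; columns intra_median, inter_median
    sd_intra: float
    sd_inter: float


def class_exclusion_robustness(
    fps: pd.DataFrame | None,
    annotations: pd.DataFrame,
    space: str = "response",
    metric: str = "jaccard_updown",
    chem: pd.DataFrame | None = None,
) -> ExclusionRobustness:
    """Recompute intra/inter medians leaving each ATC code out in turn.

    A compound losing its last code drops out of the analysis for that
    exclusion. Exclusions leaving no analysable pairs contribute NaN medians
    (ignored by the reported standard deviations).
    """
    annotated = annotations[annotations["atc_codes"].map(bool)]
    all_codes = sorted(set().union(*annotated["atc_codes"])) if len(annotated) else []
    if len(all_codes) < 2:
        raise ValueError("need at least 2 ATC classes for exclusion robustness")
    rows = []
    for code in all_codes:
        reduced = annotations.copy()
        reduced["atc_codes"] = [s - {code} for s in reduced["atc_codes"]]
        try:
            res = intra_inter_atc(
                fps, reduced, space=space, metric=metric, chem=chem,
                min_class_size=np.iinfo(np.int32).max,
            )
            rows.append({"excluded": code, "intra_median": res.intra.median,
                         "inter_median": res.inter.median})
        except ValueError:
            rows.append({"excluded": code, "intra_median": np.nan,
                         "inter_median": np.nan})
    medians = pd.DataFrame(rows).set_index("excluded")
    return ExclusionRobustness(
        medians=medians,
        sd_intra=float(medians["intra_median"].std(ddof=1)),
        sd_inter=float(medians["inter_median"].std(ddof=1)),
    )
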