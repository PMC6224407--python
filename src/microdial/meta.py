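"""Fixed-effect pooling of replicate study effects and robustness checks.

Replicate measurements of the same drug / dose / region / neurochemical /
route condition are pooled into a single effect size by the animal-weighted
mean

    x_bar = (1/N) * sum_i n_i * x_i,      N = sum_i n_i,

where ``x_i`` is the peak percent-of-baseline effect of study ``i`` and
``n_i`` the number of animals it used. Peak times are pooled with the same
weights. Robustness is probed by leave-one-out jackknife (with a chi-squared
or Fisher exact test on the up/down direction classification of the full vs
the recomputed estimates), by one-factor-at-a-time one-way ANOVA over
covariates, and by a replicate-agreement reproducibility statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset

#: Grouping key for effect pooling: covariates are deliberately excluded
#: (they are analysed separately as effect modifiers).
GROUP_KEY = ["drug", "dose", "brain_region", "neurochemical", "route"]

#: Key identifying replicated experimental conditions for reproducibility.
REPLICATE_KEY = ["drug", "neurochemical", "brain_region", "dose", "route", "peak_time"]


@dataclass(frozen=True)
class PooledEffect:
    """Animal-weighted pooled effect for one condition."""

    effect: float
    peak_time: float
    n_animals: int
    k: int


def pool_effects(x, n, peak_time=None) -> PooledEffect:
    """Pool study effects ``x`` with animal counts ``n`` by the weighted mean."""
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if x.size == 0:
        raise ValueError("cannot pool an empty effect group")
    if x.shape != n.shape:
        raise ValueError("effect and animal-count vectors differ in length")
    if np.any(n < 1):
        raise ValueError("every study must use at least one animal")
    total = n.sum()
    effect = float((n * x).sum() / total)
    if peak_time is not None:
        t = np.asarray(peak_time, dtype=float)
        pooled_t = float((n * t).sum() / total)
    else:
        pooled_t = float("nan")
    return PooledEffect(effect=effect, peak_time=pooled_t, n_animals=int(total), k=int(x.size))


def pool_dataset(ds: Dataset | pd.DataFrame) -> pd.DataFrame:
    """Pool every effect group of a dataset.

    Returns a table with one row per (drug, dose, brain_region, neurochemical,
    route) group: ``effect_pct`` (weighted mean percent of baseline),
    ``peak_time`` (same weighting), ``N`` (total animals) and ``k`` (studies).
    """
    rec = ds.records if isinstance(ds, Dataset) else ds
    if len(rec) == 0:
        raise ValueError("cannot pool an empty dataset")
    work = rec.assign(
        _nx=rec["n_animals"] * rec["peak_pct_baseline"],
        _nt=rec["n_animals"] * rec["peak_time"],
    )
    g = work.groupby(GROUP_KEY, sort=True)
    agg = g.agg(
        _nx=("_nx", "sum"),
        _nt=("_nt", "sum"),
        N=("n_animals", "sum"),
        k=("n_animals", "size"),
    )
    agg["effect_pct"] = agg.pop("_nx") / agg["N"]
    agg["peak_time"] = agg.pop("_nt") / agg["N"]
    return agg.reset_index()[GROUP_KEY + ["effect_pct", "peak_time", "N", "k"]]


def _direction(effect: float) -> str:
    if effect > 100.0:
        return "up"
    if effect < 100.0:
        return "down"
    return "no_change"


@dataclass
class JackknifeReport:
    """Leave-one-out sensitivity of a pooled effect."""

    full_effect: float
    loo: pd.DataFrame  # left_out, effect, deviation, direction
    max_abs_deviation: float
    p_value: float
    test: str
    alpha: float
    skewed: bool


def jackknife(x, n, labels=None, test: str = "chi2", alpha: float = 0.05) -> JackknifeReport:
    """Leave-one-out recomputation of the pooled effect with a direction test.

    For each left-out study the pooled effect is recomputed on the remaining
    members. The direction classification (up / down / no-change relative to
    the 100% baseline) of the full estimate is compared with the leave-one-out
    classifications in a 2x2 (estimate source x up-vs-not-up) contingency
    table via a chi-squared or Fisher exact test; the group is flagged
    "skewed" when the test rejects at ``alpha``. A group whose full and
    leave-one-out estimates all share one direction is never skewed (the
    degenerate table short-circuits to p = 1).
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if x.size < 2:
        raise ValueError("jackknife undefined for groups with fewer than 2 studies")
    if test not in ("chi2", "fisher"):
        raise ValueError(f"unknown test {test!r}; expected 'chi2' or 'fisher'")
    full = pool_effects(x, n).effect
    rows = []
    for i in range(x.size):
        keep = np.arange(x.size) != i
        eff = pool_effects(x[keep], n[keep]).effect
        rows.append(
            {
                "left_out": labels[i] if labels is not None else i,
                "effect": eff,
                "deviation": eff - full,
                "direction": _direction(eff),
            }
        )
    loo = pd.DataFrame(rows)
    full_dir = _direction(full)
    dirs = set(loo["direction"]) | {full_dir}
    if len(dirs) == 1:
        p = 1.0
    else:
        full_up = int(full_dir == "up")
        loo_up = int((loo["direction"] == "up").sum())
        table = np.array(
            [[full_up, 1 - full_up], [loo_up, len(loo) - loo_up]], dtype=int
        )
        if test == "fisher":
            p = float(stats.fisher_exact(table)[1])
        else:
            p = float(stats.chi2_contingency(table, correction=True)[1])
    return JackknifeReport(
        full_effect=full,
        loo=loo,
        max_abs_deviation=float(loo["deviation"].abs().max()),
        p_value=p,
        test=test,
        alpha=alpha,
        skewed=bool(p < alpha),
    )


def covariate_anova(
    records: pd.DataFrame,
    covariate: str,
    value_col: str = "peak_pct_baseline",
    min_per_level: int = 2,
) -> tuple[float, float]:
    """One-way ANOVA of the peak effect over the levels of one covariate.

    Levels with fewer than ``min_per_level`` observations are dropped; at
    least two usable levels must remain. When the response is constant across
    all groups the degenerate F-statistic is reported as (0, 1).
    """
    if covariate not in records.columns:
        raise ValueError(f"unknown covariate {covariate!r}")
    groups = [
        g[value_col].to_numpy(float)
        for _, g in records.groupby(covariate, sort=True)
        if len(g) >= min_per_level
    ]
    if len(groups) < 2:
        raise ValueError(
            f"covariate {covariate!r} has fewer than 2 levels with >= "
            f"{min_per_level} observations"
        )
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def ofat_sensitivity(
    ds: Dataset | pd.DataFrame,
    covariates=("sex", "age_class", "strain", "consciousness"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-factor-at-a-time ANOVA screen over effect groups.

    Runs :func:`covariate_anova` within each pooled effect group for each
    covariate in turn (no interactions) and reports F, p and a significance
    flag at ``alpha``; groups without enough replication for a covariate are
    skipped.
    """
    rec = ds.records if isinstance(ds, Dataset) else ds
    rows = []
    for key, grp in rec.groupby(GROUP_KEY, sort=True):
        for cov in covariates:
            try:
                f, p = covariate_anova(grp, cov)
            except ValueError:
                continue
            rows.append(dict(zip(GROUP_KEY, key)) | {
                "covariate": cov, "F": f, "p": p, "significant": p < alpha})
    return pd.DataFrame(
        rows, columns=GROUP_KEY + ["covariate", "F", "p", "significant"]
    )


@dataclass
class ReproducibilityStats:
    """Agreement of replicated experimental conditions.

    ``fraction_identical`` is the share of replicated conditions (same drug,
    neurochemical, region, dose, route and peak time; >= 2 records) whose
    replicates all fall on the same side of the 100% baseline (values exactly
    at baseline form a third "no-change" symbol that must also be unanimous).
    Replicate bits (up = 1, down = 0; exact-baseline replicates excluded from
    the numeric SD) yield a sample SD per replicated condition; a compound's
    SD is the mean over its conditions, and the reported mean and median are
    taken across compounds — so a fully concordant compound scores 0 no
    matter how many different conditions it mixes.
    """

    fraction_identical: float
    mean_sd: float
    median_sd: float
    n_conditions: int
    per_compound_sd: pd.Series = field(repr=False)


def reproducibility_stats(ds: Dataset | pd.DataFrame) -> ReproducibilityStats:
    rec = ds.records if isinstance(ds, Dataset) else ds
    sizes = rec.groupby(REPLICATE_KEY)["peak_pct_baseline"].transform("size")
    repl = rec[sizes >= 2].copy()
    if repl.empty:
        raise ValueError("dataset contains no replicated conditions")
    x = repl["peak_pct_baseline"].to_numpy(float)
    repl["_symbol"] = np.where(x > 100.0, "up", np.where(x < 100.0, "down", "no_change"))
    agree = repl.groupby(REPLICATE_KEY)["_symbol"].nunique() == 1
    repl["_bit"] = np.where(
        repl["_symbol"] == "up", 1.0, np.where(repl["_symbol"] == "down", 0.0, np.nan)
    )
    numeric = repl.dropna(subset=["_bit"])
    cond_sd = (
        numeric.groupby(REPLICATE_KEY)["_bit"]
        .apply(lambda b: float(b.std(ddof=1)) if len(b) >= 2 else np.nan)
        .dropna()
        .rename("sd")
        .reset_index()
    )
    per_compound = cond_sd.groupby("drug")["sd"].mean()
    return ReproducibilityStats(
        fraction_identical=float(agree.mean()),
        mean_sd=float(per_compound.mean()) if len(per_compound) else float("nan"),
        median_sd=float(per_compound.median()) if len(per_compound) else float("nan"),
        n_conditions=int(len(agree)),
        per_compound_sd=per_compound,
    )
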