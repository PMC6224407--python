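"""Missing-data-aware response similarity, ATC contrasts, KS test."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdial import similarity as sim


def series(entries):
    idx = pd.MultiIndex.from_tuples(
        [(t, "da") for t in entries], names=["brain_region", "neurochemical"]
    )
    return pd.Series(list(entries.values()), index=idx, dtype=float)


def brute_metric(a: dict, b: dict, metric: str) -> float:
    """Independent set-counting oracle over the up/down bit expansion."""
    shared = sorted(set(a) & set(b))
    if not shared:
        return float("nan")
    if metric == "signed_agreement":
        return sum(a[t] == b[t] for t in shared) / len(shared)
    bits_a, bits_b = [], []
    for t in shared:
        bits_a += [a[t] == 1, a[t] == -1]
        bits_b += [b[t] == 1, b[t] == -1]
    both = sum(x and y for x, y in zip(bits_a, bits_b))
    either = sum(x or y for x, y in zip(bits_a, bits_b))
    neither = sum((not x) and (not y) for x, y in zip(bits_a, bits_b))
    mism = len(bits_a) - both - neither
    if metric == "jaccard_updown":
        return both / either if either else 1.0
    if metric == "rogers_tanimoto":
        return (both + neither) / (both + neither + 2 * mism)
    raise ValueError(metric)


ternary_fp = st.dictionaries(
    st.sampled_from([f"r{i}" for i in range(8)]),
    st.sampled_from([1.0, -1.0, 0.0]),
    min_size=1, max_size=8,
)


class TestResponseSimilarity:
    @pytest.mark.parametrize("metric", sim.METRICS)
    def test_identical_fingerprints_score_one(self, metric):
        a = series({"r1": 1.0, "r2": -1.0, "r3": 0.0})
        assert sim.response_similarity(a, a, metric=metric) == pytest.approx(1.0)

    def test_shared_subset_signed_agreement(self):
        a = series({"A": 1.0, "B": -1.0, "C": 1.0})
        b = series({"A": 1.0, "B": 1.0, "D": -1.0})
        assert sim.response_similarity(a, b, metric="signed_agreement") == 0.5

    def test_empty_shared_set_is_undefined_not_zero(self):
        a = series({"A": 1.0})
        b = series({"B": 1.0})
        for metric in sim.METRICS:
            assert np.isnan(sim.response_similarity(a, b, metric=metric))

    def test_unknown_metric_rejected(self):
        a = series({"A": 1.0})
        with pytest.raises(ValueError):
            sim.response_similarity(a, a, metric="cosine")

    @pytest.mark.parametrize("metric", sim.METRICS)
    def test_matches_set_counting_oracle_on_random_pairs(self, metric):
        rng = np.random.default_rng(17)
        tuples = [f"r{i}" for i in range(8)]
        for _ in range(100):
            a = {t: float(rng.choice([1, -1, 0])) for t in tuples if rng.random() < 0.7}
            b = {t: float(rng.choice([1, -1, 0])) for t in tuples if rng.random() < 0.7}
            if not a or not b:
                continue
            got = sim.response_similarity(series(a), series(b), metric=metric)
            want = brute_metric(a, b, metric)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want)

    def test_rogers_tanimoto_matches_scipy_on_expanded_bits(self):
        """Dual route: our closed form vs scipy's distance on explicit bits."""
        from scipy.spatial.distance import rogerstanimoto

        rng = np.random.default_rng(5)
        tuples = [f"r{i}" for i in range(6)]
        for _ in range(30):
            a = {t: float(rng.choice([1, -1, 0])) for t in tuples}
            b = {t: float(rng.choice([1, -1, 0])) for t in tuples}
            bits_a = np.array([[a[t] == 1, a[t] == -1] for t in tuples]).ravel()
            bits_b = np.array([[b[t] == 1, b[t] == -1] for t in tuples]).ravel()
            want = 1.0 - rogerstanimoto(bits_a, bits_b)
            got = sim.response_similarity(series(a), series(b), metric="rogers_tanimoto")
            assert got == pytest.approx(want)

    @given(a=ternary_fp, b=ternary_fp)
    @settings(deadline=None, max_examples=80)
    def test_symmetry_and_bounds(self, a, b):
        for metric in sim.METRICS:
            ab = sim.response_similarity(series(a), series(b), metric=metric)
            ba = sim.response_similarity(series(b), series(a), metric=metric)
            if np.isnan(ab):
                assert np.isnan(ba)
            else:
                assert ab == pytest.approx(ba)
                assert -1e-9 <= ab <= 1 + 1e-9

    def test_restriction_to_shared_tuples_is_invariant(self):
        a = series({"A": 1.0, "B": -1.0, "C": 1.0, "E": 0.0})
        b = series({"A": 1.0, "B": 1.0, "D": -1.0, "E": -1.0})
        shared = ["A", "B", "E"]
        for metric in sim.METRICS:
            full = sim.response_similarity(a, b, metric=metric)
            restricted = sim.response_similarity(
                series({t: a[(t, "da")] for t in shared}),
                series({t: b[(t, "da")] for t in shared}),
                metric=metric,
            )
            assert full == pytest.approx(restricted)

    def test_pairwise_matrix_agrees_with_pair_function(self, fingerprint_factory):
        rng = np.random.default_rng(23)
        entries = {
            f"c{i}": {(f"r{j}", "da"): float(rng.choice([1, -1, 0]))
                      for j in range(6) if rng.random() < 0.8}
            for i in range(6)
        }
        fps = fingerprint_factory(entries)
        for metric in sim.METRICS:
            mat = sim.pairwise_response_similarity(fps, metric=metric)
            for x, y in combinations(fps.index, 2):
                want = sim.response_similarity(fps.loc[x].dropna(), fps.loc[y].dropna(),
                                               metric=metric)
                got = mat.loc[x, y]
                if np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want)


class TestChemicalSimilarity:
    def test_identity_disjoint_and_overlap(self):
        a = np.zeros(8); a[[1, 3, 5]] = 1
        b = np.zeros(8); b[[3, 5, 7]] = 1
        c = np.zeros(8); c[[0, 2]] = 1
        assert sim.chemical_similarity(a, a) == 1.0
        assert sim.chemical_similarity(a, c) == 0.0
        assert sim.chemical_similarity(a, b) == pytest.approx(2 / 4)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            sim.chemical_similarity(np.zeros(8), np.zeros(16))

    def test_all_zero_pair_defined_as_one(self):
        assert sim.chemical_similarity(np.zeros(8), np.zeros(8)) == 1.0


class TestIntraInterATC:
    def ann(self, atc: dict):
        return pd.DataFrame(
            {"smiles": [""] * len(atc), "atc_codes": [frozenset(v) for v in atc.values()]},
            index=pd.Index(sorted(atc), name="compound"),
        )

    def test_degenerate_two_compound_class(self, fingerprint_factory):
        fps = fingerprint_factory({
            "c1": {("r1", "da"): 1.0, ("r2", "da"): -1.0},
            "c2": {("r1", "da"): 1.0, ("r2", "da"): -1.0},
        })
        res = sim.intra_inter_atc(fps, self.ann({"c1": ["N06A"], "c2": ["N06A"]}),
                                  min_class_size=2)
        assert res.intra.values.tolist() == [1.0]
        assert res.inter.n == 0

    def test_two_classes_exhaustive_enumeration(self, fingerprint_factory):
        rng = np.random.default_rng(9)
        entries = {
            f"c{i}": {(f"r{j}", "da"): float(rng.choice([1, -1]))
                      for j in range(5)}
            for i in range(4)
        }
        fps = fingerprint_factory(entries)
        atc = {"c0": ["N01A"], "c1": ["N01A"], "c2": ["N02A"], "c3": ["N02A"]}
        res = sim.intra_inter_atc(fps, self.ann(atc), min_class_size=2)
        assert res.intra.n == 2 and res.inter.n == 4
        # brute-force every pair with the reference metric
        def val(x, y):
            return brute_metric(
                {t[0]: v for t, v in entries[x].items()},
                {t[0]: v for t, v in entries[y].items()},
                "jaccard_updown",
            )
        want_intra = sorted([val("c0", "c1"), val("c2", "c3")])
        assert sorted(res.intra.values.tolist()) == pytest.approx(want_intra)
        want_inter = sorted(val(a, b) for a, b in
                            [("c0", "c2"), ("c0", "c3"), ("c1", "c2"), ("c1", "c3")])
        assert sorted(res.inter.values.tolist()) == pytest.approx(want_inter)

    def test_unannotated_compounds_excluded(self, fingerprint_factory):
        fps = fingerprint_factory({
            "c1": {("r1", "da"): 1.0}, "c2": {("r1", "da"): 1.0},
            "c3": {("r1", "da"): -1.0},
        })
        res = sim.intra_inter_atc(
            fps, self.ann({"c1": ["N01A"], "c2": ["N01A"], "c3": []}), min_class_size=2)
        assert res.intra.n + res.inter.n == 1  # c3 has no codes

    def test_planted_coherence_noise_free(self):
        """With zero flip noise, intra median is 1.0 and exceeds inter."""
        import microdial as md
        from microdial.synth import SimConfig, generate_dataset

        ds, _ = generate_dataset(SimConfig(seed=2, flip_prob=0.0, effect_sd_log=0.0))
        fps = md.response_fingerprint(md.build_activity_matrix(md.pool_dataset(ds)))
        res = sim.intra_inter_atc(fps, ds.annotations)
        assert res.intra.median == pytest.approx(1.0)
        assert res.intra.median > res.inter.median


class TestKSTwoSample:
    def test_identical_samples_have_zero_statistic(self):
        d, p = sim.ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_supports_give_one(self):
        d, _ = sim.ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_statistic_matches_explicit_ecdf_tabulation(self):
        x, y = [1, 2, 3], [2, 3, 4]
        grid = sorted(set(x) | set(y))
        sup = max(
            abs(sum(v <= g for v in x) / 3 - sum(v <= g for v in y) / 3) for g in grid
        )
        d, _ = sim.ks_two_sample(x, y)
        assert d == pytest.approx(sup)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            sim.ks_two_sample([], [1.0])


class TestClassExclusion:
    def ann(self, atc: dict):
        return pd.DataFrame(
            {"smiles": [""] * len(atc), "atc_codes": [frozenset(v) for v in atc.values()]},
            index=pd.Index(sorted(atc), name="compound"),
        )

    def test_symmetric_classes_have_zero_sd(self, fingerprint_factory):
        # three identical-composition classes with identical fingerprints
        entries = {}
        atc = {}
        for ci, code in enumerate(["N01A", "N02A", "N03A"]):
            for j in range(2):
                name = f"c{ci}{j}"
                entries[name] = {("r1", "da"): 1.0, ("r2", "da"): -1.0}
                atc[name] = [code]
        res = sim.class_exclusion_robustness(fingerprint_factory(entries), self.ann(atc))
        assert res.sd_intra == pytest.approx(0.0)
        assert res.sd_inter == pytest.approx(0.0)

    def test_medians_match_direct_recomputation(self, fingerprint_factory):
        rng = np.random.default_rng(31)
        entries = {
            f"c{i}": {(f"r{j}", "da"): float(rng.choice([1, -1])) for j in range(6)}
            for i in range(6)
        }
        fps = fingerprint_factory(entries)
        atc = {f"c{i}": [["N01A", "N02A", "N03A"][i // 2]] for i in range(6)}
        res = sim.class_exclusion_robustness(fps, self.ann(atc))
        for code in ["N01A", "N02A", "N03A"]:
            reduced = {c: [x for x in v if x != code] for c, v in atc.items()}
            reduced = {c: v for c, v in reduced.items()}
            direct = sim.intra_inter_atc(fps, self.ann(reduced), min_class_size=10**6)
            assert res.medians.loc[code, "intra_median"] == pytest.approx(direct.intra.median)
            assert res.medians.loc[code, "inter_median"] == pytest.approx(direct.inter.median)

    def test_single_class_rejected(self, fingerprint_factory):
        fps = fingerprint_factory({"c1": {("r1", "da"): 1.0}, "c2": {("r1", "da"): 1.0}})
        with pytest.raises(ValueError):
            sim.class_exclusion_robustness(fps, self.ann({"c1": ["N01A"], "c2": ["N01A"]}))
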