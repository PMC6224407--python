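"""Normalized mutual information: conventions, oracles, aggregation, ranking."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microdial import mi


def contingency_nmi(x, y):
    """Independent oracle: entropies straight from the contingency table."""
    n = len(x)
    xs, ys = sorted(set(x)), sorted(set(y))
    if len(xs) == 1 and len(ys) == 1:
        return 1.0
    if len(xs) == 1 or len(ys) == 1:
        return 0.0
    joint = {}
    for a, b in zip(x, y):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px = {a: sum(v for (i, _), v in joint.items() if i == a) / n for a in xs}
    py = {b: sum(v for (_, j), v in joint.items() if j == b) / n for b in ys}
    hx = -sum(p * math.log(p) for p in px.values() if p > 0)
    hy = -sum(p * math.log(p) for p in py.values() if p > 0)
    info = sum(
        (v / n) * math.log((v / n) / (px[a] * py[b])) for (a, b), v in joint.items()
    )
    return info / ((hx + hy) / 2)


class TestNMI:
    def test_perfect_dependence(self):
        assert mi.nmi([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0
        assert mi.nmi([0, 0, 1, 1], [1, 1, 0, 0]) == 1.0  # relabeled

    def test_independence_is_zero(self):
        assert mi.nmi([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_constant_vector_conventions(self):
        assert mi.nmi([1, 1, 1], [0, 1, 0]) == 0.0
        assert mi.nmi([1, 1, 1], [2, 2, 2]) == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            mi.nmi([1], [1])

    def test_all_2x2_tables_match_contingency_oracle(self):
        for n00 in range(4):
            for n01 in range(4):
                for n10 in range(4):
                    for n11 in range(4):
                        x = [0] * (n00 + n01) + [1] * (n10 + n11)
                        y = [0] * n00 + [1] * n01 + [0] * n10 + [1] * n11
                        if len(x) < 2:
                            continue
                        assert mi.nmi(x, y) == pytest.approx(
                            max(0.0, contingency_nmi(x, y)), abs=1e-12)

    def test_random_three_category_cases_match_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = int(rng.integers(3, 30))
            x = rng.integers(0, 3, size=n).tolist()
            y = rng.integers(0, 3, size=n).tolist()
            assert mi.nmi(x, y) == pytest.approx(
                np.clip(contingency_nmi(x, y), 0, 1), abs=1e-12)

    def test_matches_sklearn_reference(self):
        """Dual route: sklearn's arithmetic-mean NMI on random vectors."""
        from sklearn.metrics import normalized_mutual_info_score

        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(4, 40))
            x = rng.integers(0, 3, size=n)
            y = rng.integers(0, 2, size=n)
            ref = normalized_mutual_info_score(x, y, average_method="arithmetic")
            assert mi.nmi(x, y) == pytest.approx(ref, abs=1e-9)

    @given(
        xy=st.lists(
            st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=2, max_size=30
        ),
        seed=st.integers(0, 10_000),
    )
    @settings(deadline=None, max_examples=60)
    def test_symmetry_and_permutation_invariance(self, xy, seed):
        x = [a for a, _ in xy]
        y = [b for _, b in xy]
        assert mi.nmi(x, y) == pytest.approx(mi.nmi(y, x))
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(x))
        assert mi.nmi(np.array(x)[perm], np.array(y)[perm]) == pytest.approx(mi.nmi(x, y))
        if len(set(x)) > 1:
            assert mi.nmi(x, x) == pytest.approx(1.0)
        assert mi.nmi(x, y) <= 1.0 + 1e-12


class TestPairwiseMatrix:
    def ann(self, data):
        return pd.DataFrame(data).T.astype(np.uint8).rename_axis("compound")

    def test_perfectly_matching_label(self, fingerprint_factory):
        fps = fingerprint_factory({
            "d0": {("r1", "da"): 1.0}, "d1": {("r1", "da"): 1.0},
            "d2": {("r1", "da"): -1.0}, "d3": {("r1", "da"): -1.0},
        })
        ann = self.ann({"d0": {"L": 1}, "d1": {"L": 1}, "d2": {"L": 0}, "d3": {"L": 0}})
        scores = mi.pairwise_nmi_matrix(ann, fps)
        assert scores.iloc[0]["nmi"] == 1.0

    def test_matches_bruteforce_loop_with_missing_removal(self, fingerprint_factory):
        rng = np.random.default_rng(37)
        drugs = [f"d{i}" for i in range(6)]
        entries = {
            d: {(f"r{j}", "da"): float(rng.choice([1, -1, 0]))
                for j in range(3) if rng.random() < 0.8}
            for d in drugs
        }
        entries = {d: (m or {("r0", "da"): 1.0}) for d, m in entries.items()}
        fps = fingerprint_factory(entries)
        ann = self.ann({d: {"L1": int(rng.random() < 0.5), "L2": int(rng.random() < 0.5)}
                        for d in drugs})
        scores = mi.pairwise_nmi_matrix(ann, fps)
        for _, row in scores.iterrows():
            t = (row["brain_region"], row["neurochemical"])
            keep = [d for d in sorted(entries) if t in entries[d]]
            x = [ann.loc[d, row["label"]] for d in keep]
            y = [int(entries[d][t]) for d in keep]
            assert row["n_drugs"] == len(keep)
            assert row["nmi"] == pytest.approx(np.clip(contingency_nmi(x, y), 0, 1))
        # pairs with < 2 measured drugs are absent
        measured = {t for m in entries.values() for t in m}
        for t in measured:
            n = sum(t in m for m in entries.values())
            present = ((scores["brain_region"] == t[0]) & (scores["neurochemical"] == t[1])).any()
            assert present == (n >= 2)

    def test_single_shared_compound_rejected(self, fingerprint_factory):
        fps = fingerprint_factory({"d0": {("r1", "da"): 1.0}})
        ann = self.ann({"d0": {"L": 1}, "zz": {"L": 0}})
        with pytest.raises(ValueError):
            mi.pairwise_nmi_matrix(ann, fps)


class TestAggregation:
    def scores(self, data):
        return pd.DataFrame(
            [{"label": l, "brain_region": "r", "neurochemical": str(i),
              "n_drugs": 5, "nmi": v}
             for l, vals in data.items() for i, v in enumerate(vals)]
        )

    def test_per_label_mean(self):
        out = mi.aggregate_mi(self.scores({"L": [0.2, 0.4]}), per="label")
        assert out["L"] == pytest.approx(0.3)

    def test_constant_distribution(self):
        overall = mi.aggregate_mi(self.scores({"L1": [0.5, 0.5], "L2": [0.5]}),
                                  per="overall")
        assert overall.median == pytest.approx(0.5)
        assert overall.sd == pytest.approx(0.0)

    def test_means_match_direct_recomputation(self):
        rng = np.random.default_rng(41)
        data = {f"L{i}": rng.random(rng.integers(1, 6)).tolist() for i in range(4)}
        out = mi.aggregate_mi(self.scores(data), per="label")
        for l, vals in data.items():
            assert out[l] == pytest.approx(float(np.mean(vals)))

    def test_loo_symmetric_labels_have_zero_sd(self, fingerprint_factory):
        fps = fingerprint_factory({
            "d0": {("r1", "da"): 1.0}, "d1": {("r1", "da"): 1.0},
            "d2": {("r1", "da"): -1.0},
        })
        ann = pd.DataFrame(
            {"L1": [1, 1, 0], "L2": [1, 1, 0], "L3": [1, 1, 0]},
            index=["d0", "d1", "d2"], dtype=np.uint8,
        )
        rob = mi.loo_mi_robustness(ann, fps)
        assert rob.sd == pytest.approx(0.0)

    def test_loo_matches_bruteforce(self, fingerprint_factory):
        rng = np.random.default_rng(43)
        fps = fingerprint_factory({
            f"d{i}": {(f"r{j}", "da"): float(rng.choice([1, -1])) for j in range(3)}
            for i in range(6)
        })
        ann = pd.DataFrame(
            rng.integers(0, 2, size=(6, 3)),
            index=[f"d{i}" for i in range(6)], columns=["L1", "L2", "L3"],
            dtype=np.uint8,
        )
        rob = mi.loo_mi_robustness(ann, fps)
        scores = mi.pairwise_nmi_matrix(ann, fps)
        means = scores.groupby("label")["nmi"].mean()
        for label in ann.columns:
            assert rob.medians[label] == pytest.approx(float(means.drop(label).median()))

    def test_loo_single_label_rejected(self, fingerprint_factory):
        fps = fingerprint_factory({"d0": {("r1", "da"): 1.0}, "d1": {("r1", "da"): -1.0}})
        ann = pd.DataFrame({"L": [1, 0]}, index=["d0", "d1"], dtype=np.uint8)
        with pytest.raises(ValueError):
            mi.loo_mi_robustness(ann, fps)


class TestTopK:
    def scores(self, data):
        return pd.DataFrame(
            [{"label": l, "brain_region": "r", "neurochemical": str(i),
              "n_drugs": 5, "nmi": v}
             for l, vals in data.items() for i, v in enumerate(vals)]
        )

    def test_ordering_by_median(self):
        top = mi.top_k_features(self.scores({"A": [0.4, 0.4], "B": [0.2, 0.2]}), k=1)
        assert top.iloc[0]["label"] == "A"

    def test_k_larger_than_label_count_returns_all(self):
        top = mi.top_k_features(self.scores({"A": [0.4], "B": [0.2]}), k=10)
        assert len(top) == 2

    def test_tie_broken_by_mean_then_name(self):
        data = {"B": [0.3, 0.3], "A": [0.3, 0.3], "C": [0.3, 0.5]}
        top = mi.top_k_features(self.scores(data), k=3)
        # medians: C 0.4 > A = B 0.3 (equal mean -> lexicographic)
        assert top["label"].tolist() == ["C", "A", "B"]
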