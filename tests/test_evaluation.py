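"""Metrics, ROC/AUC vs the Mann-Whitney oracle, DeLong behaviour,
Fleiss' kappa oracles and the benchmark runner."""

import numpy as np
import pytest
from scipy import stats

from ecochg import (
    StimulusSpec,
    benchmark,
    confusion_metrics,
    delong_one_sided,
    fleiss_kappa,
    rater_false_positive_rates,
    roc_auc,
    synth_dataset,
)


def fleiss_direct(table: np.ndarray) -> float:
    """Direct-formula oracle: kappa from category counts per item."""
    items, raters = table.shape
    cats = np.unique(table)
    counts = np.array([[np.sum(row == c) for c in cats] for row in table])
    p_i = ((counts**2).sum(axis=1) - raters) / (raters * (raters - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (items * raters)
    p_e = float((p_j**2).sum())
    return (p_bar - p_e) / (1 - p_e)


class TestConfusionMetrics:
    def test_perfect_and_inverted(self):
        t = np.array([True, True, False, False])
        m = confusion_metrics(t, t)
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)
        m = confusion_metrics(~t, t)
        assert (m.accuracy, m.sensitivity, m.specificity) == (0.0, 0.0, 0.0)

    def test_91_percent_pattern(self):
        """TP=91, FN=9, TN=91, FP=9 -> acc = sens = spec = 0.91."""
        truth = np.array([True] * 100 + [False] * 100)
        dec = np.array([True] * 91 + [False] * 9 + [False] * 91 + [True] * 9)
        m = confusion_metrics(dec, truth)
        assert m.accuracy == pytest.approx(0.91)
        assert m.sensitivity == pytest.approx(0.91)
        assert m.specificity == pytest.approx(0.91)
        assert m.ci_accuracy == pytest.approx(
            1.96 * np.sqrt(0.91 * 0.09 / 200), rel=1e-3
        )

    def test_one_class_truth(self):
        m = confusion_metrics([True, False], [True, True])
        assert m.specificity is None
        assert m.sensitivity == 0.5


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_null_near_half(self, rng):
        scores = rng.random(2000)
        labels = rng.random(2000) < 0.5
        _, auc = roc_auc(scores, labels)
        assert 0.47 <= auc <= 0.53

    def test_equals_mann_whitney(self, rng):
        """AUC == U / (n1 n0) on random instances, to 1e-12."""
        for _ in range(30):
            n1, n0 = rng.integers(5, 40, size=2)
            s1 = rng.normal(0.5, 1, n1)
            s0 = rng.normal(0.0, 1, n0)
            scores = np.concatenate([s1, s0])
            labels = np.array([1] * n1 + [0] * n0)
            u = stats.mannwhitneyu(s1, s0, alternative="two-sided").statistic
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        p = rng.random(200)
        labels = rng.random(200) < 0.4
        _, a1 = roc_auc(1 - p, labels)
        _, a2 = roc_auc(-np.log(p), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_constant_scores_warn_half(self):
        with pytest.warns(UserWarning, match="constant"):
            _, auc = roc_auc([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0])
        assert auc == 0.5

    def test_roc_monotone(self, rng):
        pts, _ = roc_auc(rng.random(100), rng.random(100) < 0.5)
        assert np.all(np.diff(pts[:, 0]) >= 0)
        assert np.all(np.diff(pts[:, 1]) >= 0)


class TestDeLong:
    def test_self_comparison_exactly_half(self, rng):
        s = rng.random(100)
        t = rng.random(100) < 0.5
        assert delong_one_sided(s, s, t) == 0.5

    def test_perfect_vs_random(self, rng):
        t = np.array([True] * 200 + [False] * 200)
        perfect = t.astype(float) + rng.normal(0, 1e-6, 400)
        random_s = rng.random(400)
        assert delong_one_sided(perfect, random_s, t) < 0.001
        assert delong_one_sided(random_s, perfect, t) > 0.999

    def test_antisymmetry(self, rng):
        t = rng.random(300) < 0.5
        a = rng.normal(size=300) + t
        b = rng.normal(size=300) + 0.5 * t
        assert delong_one_sided(a, b, t) + delong_one_sided(b, a, t) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_bootstrap_oracle(self, rng):
        """DeLong one-sided p within ±0.02 of a stratified bootstrap."""
        n_boot = 4000
        for _ in range(5):
            n1 = n0 = 150
            t = np.array([True] * n1 + [False] * n0)
            base = rng.normal(size=n1 + n0)
            a = base + 0.9 * t
            b = 0.8 * base + rng.normal(0, 0.6, n1 + n0) + 0.75 * t
            p_dl = delong_one_sided(a, b, t)
            if not 0.05 < p_dl < 0.95:
                continue
            idx1 = rng.integers(0, n1, size=(n_boot, n1))
            idx0 = n1 + rng.integers(0, n0, size=(n_boot, n0))

            def auc_batch(s):
                pos = s[idx1]
                neg = s[idx0]
                wins = (pos[:, :, None] > neg[:, None, :]).mean(axis=(1, 2))
                ties = (pos[:, :, None] == neg[:, None, :]).mean(axis=(1, 2))
                return wins + 0.5 * ties

            diffs = auc_batch(a) - auc_batch(b)
            p_boot = float(np.mean(diffs <= 0))
            assert p_dl == pytest.approx(p_boot, abs=0.02)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            delong_one_sided([1, 2], [1, 2, 3], [True, False, True])


class TestFleissKappa:
    def test_unanimous_two_categories(self):
        table = np.array([[1, 1, 1]] * 5 + [[0, 0, 0]] * 5)
        assert fleiss_kappa(table) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        table = (rng.random((1000, 3)) < 0.5).astype(int)
        assert abs(fleiss_kappa(table)) < 0.05

    def test_hand_instance_matches_direct_formula(self, rng):
        table = (rng.random((10, 3)) < 0.6).astype(int)
        assert fleiss_kappa(table) == pytest.approx(fleiss_direct(table), abs=1e-12)

    def test_rater_permutation_and_item_order_invariance(self, rng):
        table = (rng.random((50, 4)) < 0.4).astype(int)
        k = fleiss_kappa(table)
        assert fleiss_kappa(table[:, [2, 0, 3, 1]]) == pytest.approx(k, abs=1e-12)
        assert fleiss_kappa(table[rng.permutation(50)]) == pytest.approx(k, abs=1e-12)

    def test_single_overall_category_undefined(self):
        table = np.ones((6, 3), int)
        assert np.isnan(fleiss_kappa(table))


class TestRaterFPR:
    def test_fpr_against_consensus(self):
        import pandas as pd

        rows = []
        # 4 consensus-negative recordings; rater 'a' calls half positive
        for i, a_vote in enumerate([True, True, False, False]):
            rows += [
                (f"r{i}", "a", 1, a_vote),
                (f"r{i}", "b", 1, False),
                (f"r{i}", "c", 1, False),
            ]
        labels = pd.DataFrame(rows, columns=["recording_id", "rater_id", "round",
                                             "response_present"])
        consensus = pd.Series(False, index=[f"r{i}" for i in range(4)])
        fpr = rater_false_positive_rates(labels, consensus)
        assert fpr["a"] == 0.5
        assert fpr["b"] == 0.0


@pytest.fixture(scope="module")
def small_benchmark_data():
    cells = [
        {"frequency": 500, "category": "supra", "n": 15, "snr_db": 4.41},
        {"frequency": 500, "category": "noise", "n": 15},
    ]
    recs, man = synth_dataset({"cells": cells}, seed=5)
    return recs, man["ground_truth"].to_numpy()


class TestBenchmark:
    def test_statistical_detectors_separate_classes(self, small_benchmark_data):
        recs, labels = small_benchmark_data
        rep = benchmark(
            recs, labels, detectors=("hotelling", "correlation"),
            split_seed=1, q_grid=(20, 40, 80),
        )
        assert rep.methods["hotelling"]["auc"] >= 0.9
        assert rep.methods["correlation"]["auc"] >= 0.75
        assert "hotelling>correlation" in rep.delong

    def test_determinism(self, small_benchmark_data):
        recs, labels = small_benchmark_data
        kw = dict(detectors=("hotelling",), split_seed=2, q_grid=(20, 40))
        a = benchmark(recs, labels, **kw)
        b = benchmark(recs, labels, **kw)
        assert a.methods["hotelling"]["auc"] == b.methods["hotelling"]["auc"]
        assert a.train_ids == b.train_ids

    def test_split_is_disjoint_and_stratified(self, small_benchmark_data):
        recs, labels = small_benchmark_data
        rep = benchmark(recs, labels, detectors=("hotelling",),
                        split_seed=3, q_grid=(20,))
        assert not set(rep.train_ids) & set(rep.test_ids)
        assert len(rep.train_ids) + len(rep.test_ids) == len(recs)

    def test_report_serializes(self, small_benchmark_data, tmp_path):
        import json

        recs, labels = small_benchmark_data
        rep = benchmark(recs, labels, detectors=("hotelling",),
                        split_seed=4, q_grid=(20,))
        out = tmp_path / "report.json"
        rep.to_json(out)
        payload = json.loads(out.read_text())
        assert "hotelling" in payload["methods"]
        assert payload["methods"]["hotelling"]["metrics"]["accuracy"] <= 1.0

    def test_truth_fed_as_score_gives_auc_one(self, small_benchmark_data, rng):
        """Leak self-test: a detector scoring the truth column must hit 1."""
        recs, labels = small_benchmark_data
        scores = labels.astype(float) + rng.normal(0, 1e-9, len(labels))
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0
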