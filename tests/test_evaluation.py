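"""Metric oracles (exhaustive pair enumeration, hand step-integration),
bootstrap behavior, profile order invariance, and the ordering check."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from expressivity.evaluation import (ExpressivityProfile, auprc, auroc,
                                     bootstrap_ci, derive_seed,
                                     expressivity_profile, metric_report,
                                     ordering_check)
from expressivity.mine import ExpressivityResult, MineTrainConfig


def auroc_by_enumeration(scores, labels):
    """Oracle: average over all (positive, negative) pairs with half-credit ties."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def auprc_by_step_integration(scores, labels):
    """Oracle: precision accumulated at each positive, scanning by rank."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    labels = np.asarray(labels)[order]
    tp = 0
    total = 0.0
    for k, lab in enumerate(labels, start=1):
        if lab == 1:
            tp += 1
            total += tp / k
    return total / labels.sum()


small_dataset = st.integers(2, 12).flatmap(
    lambda n: st.tuples(
        st.lists(st.integers(0, 20), min_size=n, max_size=n),
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: 0 < sum(ls) < len(ls))))


class TestAuroc:
    def test_perfect_and_inverted_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_worked_three_sample_example(self):
        assert auroc([0.9, 0.8, 0.3], [1, 0, 1]) == 0.5

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(small_dataset)
    def test_equals_exhaustive_pair_enumeration(self, data):
        scores, labels = data
        scores = np.array(scores) / 20.0  # integer grid -> deliberate ties
        assert auroc(scores, labels) == pytest.approx(
            auroc_by_enumeration(scores, labels), abs=1e-12)

    def test_single_class_is_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.9], [1, 1])


class TestAuprc:
    def test_perfect_ranking(self):
        assert auprc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_four_sample_example(self):
        assert auprc([0.9, 0.7, 0.4, 0.2], [1, 0, 1, 0]) == pytest.approx(
            (1.0 + 2.0 / 3.0) / 2.0)

    def test_chance_level_tracks_prevalence(self):
        rng = np.random.default_rng(0)
        labels = (rng.random(4000) < 0.2).astype(int)
        assert auprc(rng.random(4000), labels) == pytest.approx(0.2, abs=0.03)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.integers(2, 8).flatmap(lambda n: st.tuples(
        st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
            lambda ls: sum(ls) > 0),
        st.permutations(range(n)))))
    def test_equals_hand_step_integration(self, data):
        labels, ranks = data
        scores = (np.array(ranks) + 1) / 10.0  # distinct scores
        assert auprc(scores, labels) == pytest.approx(
            auprc_by_step_integration(scores, labels), abs=1e-12)

    def test_no_positives_is_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            auprc([0.1, 0.9], [0, 0])


class TestBootstrap:
    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([0, 1] * (n // 2))
        scores = rng.random(n) + 0.5 * labels
        return scores, labels

    def test_same_seed_same_interval(self):
        s, y = self._data()
        assert bootstrap_ci(auroc, s, y, 200, seed=5) == \
            bootstrap_ci(auroc, s, y, 200, seed=5)

    def test_wider_level_nests_narrower(self):
        s, y = self._data()
        lo95, hi95 = bootstrap_ci(auroc, s, y, 400, level=0.95, seed=1)
        lo50, hi50 = bootstrap_ci(auroc, s, y, 400, level=0.50, seed=1)
        assert lo95 <= lo50 <= hi50 <= hi95

    def test_all_tie_scores_collapse_to_half(self):
        y = np.array([0, 1] * 10)
        lo, hi = bootstrap_ci(auroc, np.ones(20), y, 100, seed=0)
        assert (lo, hi) == (0.5, 0.5)

    def test_interval_covers_known_auroc(self):
        """95% interval covers the binormal truth in ~95% of datasets."""
        mu = 1.0
        true = norm.cdf(mu / np.sqrt(2.0))
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            neg = rng.normal(0, 1, 40)
            pos = rng.normal(mu, 1, 40)
            scores = np.concatenate([neg, pos])
            labels = np.array([0] * 40 + [1] * 40)
            lo, hi = bootstrap_ci(auroc, scores, labels, 250, seed=rep)
            covered += lo <= true <= hi
        assert covered / n_rep >= 0.88

    def test_metric_report_invariants(self):
        s, y = self._data(n=80, seed=3)
        rep = metric_report(s, y, n_boot=200, seed=0)
        assert rep.auroc_ci[0] <= rep.auroc <= rep.auroc_ci[1]
        assert rep.auprc_ci[0] <= rep.auprc <= rep.auprc_ci[1]
        fpr = np.array(rep.roc_curve["fpr"])
        rec = np.array(rep.pr_curve["recall"])
        assert (np.diff(fpr) >= 0).all()
        assert (np.diff(rec) <= 0).all()  # sklearn returns recall descending


class _PassthroughModel:
    """Fake backbone: stage-dependent deterministic features from pixels."""

    family = "conv"

    def available_tags(self):
        return ["early", "final"]

    def features(self, x, tag, batch=256):
        pooled = x.mean(axis=(2, 3))  # (n, 3)
        if tag.stage == "early":
            return pooled
        return np.concatenate([pooled, pooled ** 2], axis=1)


class TestProfile:
    def _profile(self, stages):
        rng = np.random.default_rng(0)
        n = 300
        images = rng.random((n, 8, 8))
        table = pd.DataFrame({"age": rng.normal(60, 10, n),
                              "sex": rng.integers(0, 2, n).astype(float)})
        cfg = MineTrainConfig(n_seeds=1, max_epochs=3, batch_size=30,
                              plateau_patience=2)
        return expressivity_profile(_PassthroughModel(), images, table,
                                    stages=stages, attributes=("age", "sex"),
                                    train_cfg=cfg, base_seed=7)

    def test_grid_is_complete_and_order_invariant(self):
        p1 = self._profile(("early", "final"))
        p2 = self._profile(("final", "early"))
        assert set(p1.cells) == {("early", "age"), ("early", "sex"),
                                 ("final", "age"), ("final", "sex")}
        for key in p1.cells:
            assert p1.cells[key].mean_estimate == p2.cells[key].mean_estimate

    def test_missing_attribute_is_named(self):
        rng = np.random.default_rng(0)
        with pytest.raises(KeyError, match="IVSDd"):
            expressivity_profile(_PassthroughModel(), rng.random((20, 8, 8)),
                                 pd.DataFrame({"age": rng.random(20)}),
                                 attributes=("age", "IVSDd"))

    def test_roundtrips_through_dict(self):
        p = self._profile(("early",))
        q = ExpressivityProfile.from_dict(p.to_dict())
        assert q.mean("early", "age") == p.mean("early", "age")


def _fake_profile(means):
    cells = {("final", a): ExpressivityResult(
        per_seed_estimates=[m], mean_estimate=m, std_estimate=0.0,
        attribute_name=a, layer_tag="final", config_fingerprint="x")
        for a, m in means.items()}
    return ExpressivityProfile(cells=cells, stages=["final"],
                               attributes=list(means))


class TestOrderingCheck:
    EXPECTED = ["age", "sex", "IVSDd", "LVPWDd", "LVIDd"]

    def test_identical_ranking_matches(self):
        p = _fake_profile(dict(zip(self.EXPECTED, [1.0, 0.6, 0.35, 0.2, 0.05])))
        out = ordering_check(p, "final", self.EXPECTED)
        assert out["match"] and out["kendall_tau"] == 1.0

    def test_reversed_ranking_is_antisymmetric(self):
        p = _fake_profile(dict(zip(self.EXPECTED, [0.05, 0.2, 0.35, 0.6, 1.0])))
        out = ordering_check(p, "final", self.EXPECTED)
        assert not out["match"] and out["kendall_tau"] == -1.0

    def test_adjacent_swap_costs_one_pair(self):
        p = _fake_profile(dict(zip(self.EXPECTED, [1.0, 0.6, 0.2, 0.35, 0.05])))
        out = ordering_check(p, "final", self.EXPECTED)
        assert not out["match"]
        assert out["kendall_tau"] == pytest.approx(1.0 - 2.0 / 10.0)

    def test_ties_flagged_and_never_match(self):
        p = _fake_profile(dict(zip(self.EXPECTED, [1.0, 0.6, 0.35, 0.35, 0.05])))
        out = ordering_check(p, "final", self.EXPECTED)
        assert out["ties"] and not out["match"]


def test_derive_seed_is_stable_and_bounded():
    a = derive_seed(1, "stage", "x")
    assert a == derive_seed(1, "stage", "x")
    assert a != derive_seed(2, "stage", "x")
    assert 0 <= a < 2 ** 31
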