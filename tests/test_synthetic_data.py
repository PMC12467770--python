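"""Generator tests: cohort statistics, known-MI channels, renderer
geometry, and the class-balancing rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from expressivity.synthetic_data import (ChannelSpec, CohortConfig,
                                         RenderConfig, SyntheticCohort,
                                         assign_splits,
                                         binary_gaussian_channel_mi,
                                         gain_for_target_mi,
                                         make_balanced_subset,
                                         make_linear_gaussian_features,
                                         render_images, sample_cohort)


class TestCohort:
    def test_same_seed_reproduces_table(self):
        cfg = CohortConfig(n=500, seed=3)
        a = sample_cohort(cfg).table
        b = sample_cohort(cfg).table
        pd.testing.assert_frame_equal(a, b)

    def test_sex_frequency_and_age_moments(self):
        t = sample_cohort(CohortConfig(n=10_000, seed=0)).table
        assert abs(t.sex.mean() - 0.5) < 3 * np.sqrt(0.25 / 10_000)
        # truncation narrows the spread slightly; 3-SE band on the mean
        assert abs(t.age.mean() - 62.0) < 3 * 14.0 / np.sqrt(10_000) + 1.0

    def test_label_rule_applied_exactly(self):
        cfg = CohortConfig(n=2000, seed=1)
        t = sample_cohort(cfg).table
        thr_i = np.where(t.sex == 1, cfg.ivsdd_threshold[1], cfg.ivsdd_threshold[0])
        thr_p = np.where(t.sex == 1, cfg.lvpwdd_threshold[1], cfg.lvpwdd_threshold[0])
        expected = ((t.IVSDd > thr_i) | (t.LVPWDd > thr_p)).astype(int)
        assert (t.slvh == expected).all()
        assert 0.0 < t.slvh.mean() < 1.0

    def test_zero_coefficients_decouple_anatomy(self):
        cfg = CohortConfig(n=10_000, seed=2,
                           ivsdd=(0.85, 0.0, 0.0, 0.22),
                           lvpwdd=(0.82, 0.0, 0.0, 0.20),
                           lvidd=(4.80, 0.0, 0.0, 0.45))
        t = sample_cohort(cfg).table
        for dim in ("IVSDd", "LVPWDd", "LVIDd"):
            assert abs(np.corrcoef(t[dim], t.age)[0, 1]) < 0.05
            assert abs(np.corrcoef(t[dim], t.sex)[0, 1]) < 0.05

    def test_degenerate_labels_are_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            sample_cohort(CohortConfig(n=50, seed=0,
                                       ivsdd_threshold=(9.0, 9.0),
                                       lvpwdd_threshold=(9.0, 9.0)))


class TestLinearGaussianChannel:
    def test_unit_snr_gives_half_log_two(self):
        assert gain_for_target_mi(0.5 * np.log(2.0)) == pytest.approx(1.0)

    def test_gain_roundtrips_continuous_and_binary(self):
        for mi in (0.05, 0.2, 0.6):
            g = gain_for_target_mi(mi)
            assert 0.5 * np.log1p(g * g) == pytest.approx(mi, abs=1e-12)
        g = gain_for_target_mi(0.3, binary=True)
        assert binary_gaussian_channel_mi(g, 1.0) == pytest.approx(0.3, abs=1e-8)
        with pytest.raises(ValueError, match="capped"):
            gain_for_target_mi(0.8, binary=True)

    def test_binary_mi_quadrature_against_monte_carlo(self):
        """The mixture-entropy quadrature agrees with a sampling estimate."""
        gain, sd, p = 1.5, 1.0, 0.5
        mi_quad = binary_gaussian_channel_mi(gain, sd, p)
        rng = np.random.default_rng(0)
        n = 200_000
        x = (rng.random(n) < p).astype(float)
        z = (x - p) / np.sqrt(p * (1 - p))
        y = gain * z + rng.normal(0, sd, n)
        mu0 = gain * (0 - p) / np.sqrt(p * (1 - p))
        mu1 = gain * (1 - p) / np.sqrt(p * (1 - p))
        dens = (1 - p) * stats.norm.pdf(y, mu0, sd) + p * stats.norm.pdf(y, mu1, sd)
        h_y_mc = -np.mean(np.log(dens))
        mi_mc = h_y_mc - 0.5 * np.log(2 * np.pi * np.e * sd * sd)
        assert mi_quad == pytest.approx(mi_mc, abs=0.01)
        assert 0.0 < mi_quad < np.log(2.0)

    def test_injection_structure_and_true_mi(self):
        cohort = sample_cohort(CohortConfig(n=3000, seed=5))
        spec = ChannelSpec(gains={"age": 1.0, "LVIDd": 0.0}, d=4)
        fm, true_mi = make_linear_gaussian_features(cohort, spec, seed=1)
        assert fm.values.shape == (3000, 4)
        assert true_mi["LVIDd"] == 0.0
        assert true_mi["age"] == pytest.approx(0.5 * np.log(2.0))
        z_age = ((cohort.table.age - cohort.table.age.mean())
                 / cohort.table.age.std(ddof=0))
        # injected coordinate correlates with its attribute, pure-noise ones do not
        assert np.corrcoef(fm.values[:, 0], z_age)[0, 1] > 0.5
        assert abs(np.corrcoef(fm.values[:, 2], z_age)[0, 1]) < 0.1

    def test_same_seed_reproduces_features(self):
        cohort = sample_cohort(CohortConfig(n=200, seed=5))
        spec = ChannelSpec(gains={"age": 1.0}, d=3)
        a, _ = make_linear_gaussian_features(cohort, spec, seed=7)
        b, _ = make_linear_gaussian_features(cohort, spec, seed=7)
        assert np.array_equal(a.values, b.values)


def _constant_attr_cohort(ivsdd_values):
    """Cohort table with controlled IVSDd and everything else constant-ish."""
    n = len(ivsdd_values)
    table = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "age": np.linspace(60.0, 60.1, n),
        "sex": [0.0, 1.0] * (n // 2) + [0.0] * (n % 2),
        "IVSDd": ivsdd_values,
        "LVPWDd": np.linspace(0.9, 0.901, n),
        "LVIDd": np.linspace(4.8, 4.801, n),
        "slvh": [0, 1] * (n // 2) + [0] * (n % 2),
    })
    return SyntheticCohort(table=table, config=CohortConfig(n=n))


class TestRenderer:
    QUIET = dict(noise_sd=0.0, exposure_sd=0.0, offset_sd=0.0)

    def test_deterministic_given_seed(self):
        cohort = sample_cohort(CohortConfig(n=60, seed=1))
        a = render_images(cohort, RenderConfig(), seed=3)
        b = render_images(cohort, RenderConfig(), seed=3)
        assert np.array_equal(a, b)

    def test_noiseless_render_is_a_function_of_attributes_only(self):
        cohort = _constant_attr_cohort([1.0, 1.0, 1.3, 1.3])
        imgs = render_images(cohort, RenderConfig(**self.QUIET), seed=0)
        same = _constant_attr_cohort([1.0, 1.0, 1.3, 1.3])
        imgs2 = render_images(same, RenderConfig(**self.QUIET), seed=9)
        assert np.array_equal(imgs, imgs2)  # seed only enters through noise

    def test_ring_grows_with_septal_thickness(self):
        vals = np.linspace(0.8, 1.5, 8)
        cohort = _constant_attr_cohort(vals)
        imgs = render_images(cohort, RenderConfig(**self.QUIET), seed=0)
        counts = [(img > 0.6).sum() for img in imgs]
        assert all(b >= a for a, b in zip(counts, counts[1:])), counts

    def test_oversized_geometry_is_rejected(self):
        cohort = sample_cohort(CohortConfig(n=60, seed=1))
        with pytest.raises(ValueError, match="exceeds"):
            render_images(cohort, RenderConfig(size=32, base_silhouette=40.0),
                          seed=0)


class TestBalancedSubset:
    def test_minority_class_governs(self):
        labels = np.array([1] * 20 + [0] * 80)
        out = make_balanced_subset(labels, np.array(["train"] * 100), seed=0)
        idx = out["train"]
        assert len(idx) == 40
        assert labels[idx].sum() == 20

    def test_three_split_toy_counts(self):
        labels = np.concatenate([[1] * 20 + [0] * 80, [1] * 5 + [0] * 20,
                                 [1] * 5 + [0] * 15])
        split = np.array(["train"] * 100 + ["val"] * 25 + ["test"] * 20)
        out = make_balanced_subset(labels, split, seed=1)
        assert {k: len(v) for k, v in out.items()} == {
            "train": 40, "val": 10, "test": 10}
        for k, v in out.items():
            assert labels[v].mean() == 0.5

    def test_already_balanced_is_identity(self):
        labels = np.array([0, 1, 0, 1])
        out = make_balanced_subset(labels, np.array(["t"] * 4), seed=0)
        assert sorted(out["t"].tolist()) == [0, 1, 2, 3]

    def test_empty_class_errors(self):
        with pytest.raises(ValueError, match="lacks one class"):
            make_balanced_subset(np.array([0, 0]), np.array(["t", "t"]), seed=0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_equal_classes_in_every_split(self, data):
        n_splits = data.draw(st.integers(1, 3))
        labels, split = [], []
        for s in range(n_splits):
            pos = data.draw(st.integers(1, 30))
            neg = data.draw(st.integers(1, 30))
            labels += [1] * pos + [0] * neg
            split += [f"s{s}"] * (pos + neg)
        seed = data.draw(st.integers(0, 2 ** 20))
        out = make_balanced_subset(np.array(labels), np.array(split), seed=seed)
        labels = np.array(labels)
        for s, idx in out.items():
            assert labels[idx].sum() * 2 == len(idx)
            assert len(np.unique(idx)) == len(idx)  # sampled w/o replacement


class TestAssignSplits:
    def test_groups_stay_together(self):
        groups = np.repeat(np.arange(40), 5)
        split = assign_splits(200, (0.6, 0.2, 0.2), seed=1, groups=groups)
        df = pd.DataFrame({"g": groups, "s": split})
        assert (df.groupby("g")["s"].nunique() == 1).all()

    def test_proportions_roughly_respected(self):
        split = assign_splits(1000, (0.7, 0.15, 0.15), seed=0)
        frac = pd.Series(split).value_counts(normalize=True)
        assert abs(frac["train"] - 0.7) < 0.02
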