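"""Detection statistics: AUC oracles, ROC mechanics, GLMM behaviour, DeLong."""

import warnings

import numpy as np
import pytest

from cardimu.detection import (
    auc,
    delong_compare,
    fit_ischemia_probability,
    label_from_intervention,
    roc_points,
    sensitivity_at_specificity,
)


def _auc_bruteforce(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (pos.size * neg.size)


class TestAUC:
    def test_perfect_separation(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert auc(scores, labels) == 1.0
        assert auc(-scores, labels) == 0.0

    def test_all_tied_is_half(self):
        assert auc(np.ones(10), np.repeat([0, 1], 5)) == 0.5

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            # discretised scores to force ties
            scores = np.round(rng.normal(size=n) + labels, 1)
            assert auc(scores, labels) == pytest.approx(
                _auc_bruteforce(scores, labels), abs=1e-12
            )

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auc(np.arange(4.0), np.ones(4, dtype=int))


class TestROCPoints:
    def test_known_small_case(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        roc = roc_points(scores, labels)
        # thresholds: inf, .8, .6, .4, .2
        np.testing.assert_allclose(roc.sensitivity, [0, 0.5, 0.5, 1.0, 1.0])
        np.testing.assert_allclose(roc.specificity, [1, 1.0, 0.5, 0.5, 0.0])
        assert roc.auc == pytest.approx(0.75)

    def test_trapezoid_equals_mann_whitney(self, rng):
        scores = np.round(rng.normal(size=50), 1)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        roc = roc_points(scores, labels)
        fpr = 1 - roc.specificity
        area = float(np.trapezoid(roc.sensitivity, fpr))
        assert area == pytest.approx(roc.auc, abs=1e-12)

    def test_sensitivity_at_specificity(self):
        scores = np.array([0.2, 0.4, 0.6, 0.8])
        labels = np.array([0, 1, 0, 1])
        cutoff, sens = sensitivity_at_specificity(roc_points(scores, labels), 0.8)
        assert cutoff == pytest.approx(0.8)
        assert sens == pytest.approx(0.5)
        # lower target admits the higher-sensitivity point
        cutoff, sens = sensitivity_at_specificity(roc_points(scores, labels), 0.5)
        assert cutoff == pytest.approx(0.4)
        assert sens == pytest.approx(1.0)

    def test_always_has_an_operating_point(self):
        scores = np.array([0.5, 0.5, 0.5, 0.5])
        labels = np.array([0, 1, 0, 1])
        cutoff, sens = sensitivity_at_specificity(roc_points(scores, labels), 0.99)
        assert cutoff == np.inf
        assert sens == 0.0


class TestMixedModel:
    @staticmethod
    def _clustered_data(seed, n_subj=12, n_per=30, b0=-0.5, b1=1.2, sd_u=1.0):
        rng = np.random.default_rng(seed)
        subj = np.repeat(np.arange(n_subj), n_per)
        u = rng.normal(0, sd_u, n_subj)
        x = rng.normal(0, 1, n_subj * n_per)
        eta = b0 + b1 * x + u[subj]
        y = (rng.random(eta.size) < 1 / (1 + np.exp(-eta))).astype(int)
        return x, y, subj

    def test_recovers_clustered_effects(self):
        x, y, subj = self._clustered_data(seed=3)
        probs, fit = fit_ischemia_probability(x, y, subj, return_model=True)
        assert fit is not None
        # slope on the standardised covariate stays positive and near truth
        assert 0.5 < fit.fe_mean[1] < 2.0
        # random-intercept sd recovered within a factor ~2
        sd_u = float(np.exp(fit.vcp_mean[0]))
        assert 0.4 < sd_u < 2.0
        # scores discriminate: AUC well above chance
        assert auc(probs, y) > 0.7

    def test_scores_monotone_in_esm_within_subject(self):
        x, y, subj = self._clustered_data(seed=5)
        probs = fit_ischemia_probability(x, y, subj)
        one = subj == 0
        order = np.argsort(x[one])
        assert np.all(np.diff(probs[one][order]) >= -1e-12)

    def test_null_labels_near_chance(self):
        """With labels independent of ESM (permuted, 1000 rows, fixed seed)
        the fixed-effect part of the model is at chance (AUC in
        [0.45, 0.55]).  The full in-sample scores include the subject
        random intercepts, which absorb per-subject label imbalance and
        inflate the apparent AUC slightly; that inflation stays bounded."""
        rng = np.random.default_rng(3)
        n_subj, n_per = 20, 50
        subj = np.repeat(np.arange(n_subj), n_per)
        x = rng.normal(size=n_subj * n_per)
        y = rng.permutation(np.repeat([0, 1], n_subj * n_per // 2))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            probs, fit = fit_ischemia_probability(x, y, subj, return_model=True)
        xs = (x - x.mean()) / x.std()
        eta_fe = fit.fe_mean[0] + fit.fe_mean[1] * xs
        assert 0.45 <= auc(eta_fe, y) <= 0.55
        assert auc(probs, y) < 0.65  # bounded in-sample inflation

    def test_few_subjects_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = (rng.random(40) < 1 / (1 + np.exp(-x))).astype(int)
        subj = np.repeat(["a", "b"], 20)
        with pytest.warns(UserWarning, match="plain logistic"):
            probs = fit_ischemia_probability(x, y, subj)
        assert probs.shape == (40,)
        assert np.all((probs > 0) & (probs < 1))

    def test_complete_separation_uses_ridge(self):
        x = np.concatenate([np.zeros(10), np.ones(10) * 10.0])
        y = np.repeat([0, 1], 10)
        subj = np.repeat(["a", "b"], 10)
        with pytest.warns(UserWarning):
            probs = fit_ischemia_probability(x, y, subj)
        assert np.all(np.isfinite(probs))
        assert auc(probs, y) == 1.0

    def test_misaligned_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_ischemia_probability(np.zeros(5), np.array([0, 1, 0, 1]),
                                     np.zeros(4))


class TestDeLong:
    @staticmethod
    def _paired_scores():
        rng = np.random.default_rng(1)
        lab = np.repeat([0, 1], 20)
        latent = rng.normal(size=40)
        s_a = latent + lab * 0.9 + rng.normal(0, 0.8, 40)
        s_b = latent + lab * 0.5 + rng.normal(0, 0.8, 40)
        return s_a, s_b, lab

    def test_identical_curves_give_p_one(self):
        s = np.arange(10.0)
        lab = np.repeat([0, 1], 5)
        z, p = delong_compare(s, s, lab)
        assert z == 0.0
        assert p == 1.0

    def test_symmetry(self):
        s_a, s_b, lab = self._paired_scores()
        z1, p1 = delong_compare(s_a, s_b, lab)
        z2, p2 = delong_compare(s_b, s_a, lab)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_matches_paired_bootstrap(self):
        """DeLong p-value agrees with a paired stratified bootstrap of the
        AUC difference (20000 resamples) to within 0.02."""
        from scipy.stats import norm

        s_a, s_b, lab = self._paired_scores()
        z, p = delong_compare(s_a, s_b, lab)

        rng = np.random.default_rng(1)
        pos = np.flatnonzero(lab == 1)
        neg = np.flatnonzero(lab == 0)
        n_boot = 20000
        ip = rng.integers(0, pos.size, size=(n_boot, pos.size))
        ineg = rng.integers(0, neg.size, size=(n_boot, neg.size))

        def _auc_mat(scores):
            p_mat = scores[pos][ip][:, :, None]  # (B, m, 1)
            n_mat = scores[neg][ineg][:, None, :]  # (B, 1, n)
            return ((p_mat > n_mat).mean(axis=(1, 2))
                    + 0.5 * (p_mat == n_mat).mean(axis=(1, 2)))

        diffs = _auc_mat(s_a) - _auc_mat(s_b)
        d0 = auc(s_a, lab) - auc(s_b, lab)
        p_boot = 2.0 * norm.sf(abs(d0) / diffs.std(ddof=1))
        assert abs(p - p_boot) < 0.02

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            delong_compare(np.zeros(4), np.zeros(5), np.array([0, 1, 0, 1]))


class TestLabels:
    def test_label_mapping(self):
        assert label_from_intervention("ischemia") == 1
        assert label_from_intervention("dob_isc") == 1
        assert label_from_intervention("baseline") == 0
        assert label_from_intervention("dobutamine") == 0
        assert label_from_intervention("reperfusion") == 0
        with pytest.raises(ValueError):
            label_from_intervention("mystery")
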