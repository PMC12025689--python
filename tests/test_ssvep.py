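"""SSVEP pipeline: narrowband bank, CSP, variance features, multi-class LDA."""

import numpy as np
import pytest

from bciloop import (
    EpochSet,
    FrequencyBank,
    SSVEPConfig,
    classify_frequency,
    crossvalidate_ssvep,
    csp_fit,
    generate_ssvep_session,
    make_background,
    train_ssvep_models,
    variance_features,
)
from bciloop.ssvep import ClassModel, LDAModel, lda_fit, lda_score, stimulation_epochs


def _epochset(data, fs=256.0, labels=None, channels=None):
    data = np.asarray(data, float)
    n_t, n_c, n_s = data.shape
    return EpochSet(
        data=data, window=(0.0, n_s / fs), fs=fs,
        labels=labels or [""] * n_t,
        channel_labels=channels or [f"c{i}" for i in range(n_c)],
    )


class TestBankFilter:
    bank = FrequencyBank(fs=256)

    @pytest.mark.parametrize("tone,lo,hi", [(12.0, 0.7, 1.05), (15.0, 0.0, 0.2)])
    def test_selectivity_around_12hz(self, tone, lo, hi):
        from bciloop import bank_filter

        t = np.arange(4 * 256) / 256
        x = np.sin(2 * np.pi * tone * t)
        trials = _epochset(np.tile(x, (2, 3, 1)))
        out = bank_filter(trials, self.bank, 12.0)
        ratio = out.data[0, 0].std() / x.std()
        assert lo <= ratio <= hi

    def test_zero_trial(self):
        from bciloop import bank_filter

        trials = _epochset(np.zeros((2, 3, 1024)))
        out = bank_filter(trials, self.bank, 15.0)
        assert np.allclose(out.data, 0)

    def test_unknown_frequency_rejected(self):
        from bciloop import bank_filter

        with pytest.raises(KeyError):
            bank_filter(_epochset(np.zeros((2, 3, 1024))), self.bank, 17.0)


def _two_class_toy(rng, n_trials=20, n_ch=8, n_samp=256):
    """Class A varies on channel 0 only, class B on channel 1 only."""
    base = 0.01 * rng.standard_normal((2 * n_trials, n_ch, n_samp))
    a, b = base[:n_trials].copy(), base[n_trials:].copy()
    a[:, 0, :] += rng.standard_normal((n_trials, n_samp))
    b[:, 1, :] += rng.standard_normal((n_trials, n_samp))
    return a, b


class TestCSP:
    def test_constructed_instance_separates_variance(self, rng):
        a, b = _two_class_toy(rng)
        model = csp_fit(a, b)
        top = model.W[0]
        var_a = np.mean([(top @ x).var() for x in a])
        var_b = np.mean([(top @ x).var() for x in b])
        assert var_a / var_b >= 100

    def test_identical_covariances_give_half_eigenvalues(self, rng):
        x = rng.standard_normal((30, 4, 200))
        model = csp_fit(x, x)
        assert np.allclose(model.eigenvalues, 0.5, atol=1e-6)

    def test_top_filter_beats_random_filters(self, rng):
        # brute-force oracle: Rayleigh quotient of 10000 random unit filters
        a = rng.standard_normal((15, 4, 300)) * np.array([2.0, 1.0, 0.5, 1.5])[:, None]
        b = rng.standard_normal((15, 4, 300))
        model = csp_fit(a, b)

        def rayleigh(w, ca, cb):
            return (w @ ca @ w) / (w @ (ca + cb) @ w)

        from bciloop.ssvep import _mean_normalized_covariance

        ca, cb = _mean_normalized_covariance(a), _mean_normalized_covariance(b)
        top = rayleigh(model.W[0], ca, cb)
        w_rand = rng.standard_normal((10000, 4))
        w_rand /= np.linalg.norm(w_rand, axis=1, keepdims=True)
        rand_best = max(rayleigh(w, ca, cb) for w in w_rand)
        assert top >= rand_best - 1e-12

    def test_eigenvalue_duality_under_class_swap(self, rng):
        a = rng.standard_normal((10, 5, 200)) * np.linspace(0.5, 2, 5)[:, None]
        b = rng.standard_normal((10, 5, 200))
        fwd = csp_fit(a, b).eigenvalues
        rev = csp_fit(b, a).eigenvalues
        assert np.allclose(np.sort(fwd), np.sort(1 - rev), atol=1e-8)

    def test_projected_pooled_covariance_diagonal(self, rng):
        a = rng.standard_normal((10, 5, 200)) * np.linspace(0.5, 2, 5)[:, None]
        b = rng.standard_normal((10, 5, 200))
        model = csp_fit(a, b)
        from bciloop.ssvep import _mean_normalized_covariance

        pooled = _mean_normalized_covariance(a) + _mean_normalized_covariance(b)
        proj = model.W @ pooled @ model.W.T
        off = proj - np.diag(np.diag(proj))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(np.diag(proj)))

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            csp_fit(rng.standard_normal((1, 4, 100)), rng.standard_normal((5, 4, 100)))


class TestVarianceFeatures:
    def test_scaling_law(self, rng):
        a, b = _two_class_toy(rng)
        model = csp_fit(a, b)
        f1 = variance_features(a[:1], model)
        f4 = variance_features(2.0 * a[:1], model)
        assert np.allclose(f4, 4.0 * f1)

    def test_zero_trial_gives_zero_features(self, rng):
        a, b = _two_class_toy(rng)
        model = csp_fit(a, b)
        assert np.allclose(variance_features(np.zeros((1, 8, 100)), model), 0)

    def test_toy_classes_linearly_separable_on_top_feature(self, rng):
        a, b = _two_class_toy(rng)
        model = csp_fit(a, b)
        fa = variance_features(a, model)[:, 0]
        fb = variance_features(b, model)[:, 0]
        assert fa.min() > fb.max()


@pytest.fixture(scope="module")
def trained():
    s = generate_ssvep_session(SSVEPConfig(trials_per_class=10, snr=1.0, seed=0))
    ep = stimulation_epochs(s)
    return train_ssvep_models(ep, FrequencyBank(fs=256))


class TestClassify:
    bank = FrequencyBank(fs=256)

    def test_strong_trial_classified_correctly(self, trained):
        s = generate_ssvep_session(SSVEPConfig(trials_per_class=3, snr=2.0, seed=7))
        ep = stimulation_epochs(s)
        for name in ("12Hz", "15Hz", "20Hz"):
            i = ep.labels.index(name)
            assert classify_frequency(ep.data[i], trained, self.bank) == name

    def test_background_trial_falls_back_to_rest(self, trained):
        n_rest = 0
        for i in range(100):
            trial = make_background(8, 1100, 256, seed=5000 + i)[:, :1024]
            n_rest += classify_frequency(trial, trained, self.bank) == "rest"
        assert n_rest >= 90

    def test_tie_breaks_toward_lowest_frequency(self):
        # constant LDA scores (w=0, positive bias) for every class
        dummy_csp = csp_fit(
            np.random.default_rng(0).standard_normal((4, 8, 64)),
            np.random.default_rng(1).standard_normal((4, 8, 64)),
        )
        lda = LDAModel(w=np.zeros(2), b=1.0, class_means=np.zeros((2, 2)),
                       pooled_covariance=np.eye(2))
        models = {f: ClassModel(f, dummy_csp, lda) for f in (12.0, 15.0, 20.0)}
        trial = np.random.default_rng(2).standard_normal((8, 1024))
        assert classify_frequency(trial, models, self.bank) == "12Hz"

    def test_missing_model_rejected(self, trained):
        partial = {12.0: trained[12.0]}
        with pytest.raises(KeyError):
            classify_frequency(np.zeros((8, 1024)), partial, self.bank)


class TestLDA:
    def test_separates_shifted_gaussians(self, rng):
        # 5-sigma mean separation: Bayes accuracy ~99.4%
        f_pos = rng.standard_normal((50, 2)) + np.array([5.0, 0.0])
        f_neg = rng.standard_normal((50, 2))
        F = np.vstack([f_pos, f_neg])
        y = np.array([1] * 50 + [-1] * 50)
        model = lda_fit(F, y)
        scores = lda_score(model, F)
        assert np.mean((scores > 0) == (y == 1)) >= 0.95
        assert np.allclose(model.pooled_covariance, model.pooled_covariance.T)


class TestCrossValidation:
    def test_deterministic_under_seed(self, small_ssvep_session):
        a = crossvalidate_ssvep(small_ssvep_session, k=3, seed=1)
        b = crossvalidate_ssvep(small_ssvep_session, k=3, seed=1)
        assert a.fold_accuracy == b.fold_accuracy
        assert a.extras["confusion_matrix"] == b.extras["confusion_matrix"]

    def test_confusion_matrix_sums_to_trial_count(self, small_ssvep_session):
        res = crossvalidate_ssvep(small_ssvep_session, k=3, seed=1)
        assert np.sum(res.extras["confusion_matrix"]) == res.n_trials

    def test_too_few_per_class_rejected(self, small_ssvep_session):
        with pytest.raises(ValueError):
            crossvalidate_ssvep(small_ssvep_session, k=10)

    def test_narrowband_selectivity_at_low_snr(self):
        # inflating the bands from +-0.25 Hz to +-3 Hz must not help
        wins = 0
        for seed in range(6):
            s = generate_ssvep_session(SSVEPConfig(trials_per_class=12, snr=0.1, seed=seed))
            narrow = crossvalidate_ssvep(s, k=3, seed=seed).mean_accuracy
            wide = crossvalidate_ssvep(
                s, k=3, seed=seed, bank=FrequencyBank(fs=256, margin=3.0)
            ).mean_accuracy
            wins += narrow >= wide
        assert wins >= 4
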