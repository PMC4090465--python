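import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from shiftmotif.defs import CLASSES
from shiftmotif.features import FeatureVector
from shiftmotif.io_formats import Segment
from shiftmotif.qda import (
    ClassModel,
    QDModel,
    UndefinedMarginError,
    apply_correction,
    classify,
    discriminant,
    fit_class,
    fit_qd,
    mahalanobis_sq,
    margin_coefficient,
)

from conftest import random_gaussian_problem


def fv(values, label=None, names=None):
    values = np.atleast_1d(np.asarray(values, dtype=float))
    names = names or tuple(f"f{i}" for i in range(values.size))
    seg = Segment("p", "A", 1, 2, label=label)
    return FeatureVector(values=values, feature_names=names, segment_ref=seg, label=label)


def fit_model(X, y, prior_mode="count"):
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    return fit_qd([fv(x, label=lab, names=names) for x, lab in zip(X, y)], prior_mode)


def oracle_predict(X_train, y_train, probe, prior="count"):
    """Independent Bayes rule: argmax of log-prior + Gaussian log-density.

    Moments are recomputed here with the population divisor; scoring goes
    through scipy's multivariate-normal density, not the discriminant.
    """
    scores = {}
    n_total = len(y_train)
    for lab in sorted(set(y_train)):
        G = X_train[np.array([l == lab for l in y_train])]
        mean = G.mean(axis=0)
        cov = (G - mean).T @ (G - mean) / len(G)
        p = len(G) if prior == "count" else len(G) / n_total
        scores[lab] = math.log(p) + multivariate_normal.logpdf(
            probe, mean=mean, cov=cov, allow_singular=False
        )
    # fixed-order tie-break, as the implementation documents
    best = max(scores.values())
    return next(lab for lab in CLASSES if lab in scores and scores[lab] == best)


class TestFitClass:
    def test_population_divisor_hand_arithmetic(self):
        m = fit_class([fv([1.0]), fv([3.0])], "HH")
        assert m.mean[0] == 2.0
        assert m.covariance[0, 0] == 1.0  # divisor p_v = 2, not p_v - 1
        assert m.sample_count == 2

    def test_identical_vectors_ridged_and_flagged(self):
        m = fit_class([fv([2.0, 5.0]) for _ in range(4)], "EE")
        assert m.regularized
        assert np.isfinite(m.log_det)

    def test_fewer_than_two_vectors_rejected(self):
        with pytest.raises(ValueError, match=">= 2 vectors"):
            fit_class([fv([1.0])], "HH")

    def test_parameter_recovery_from_generator(self):
        """Moments fitted on many draws land near the generating parameters."""
        rng = np.random.default_rng(42)
        mean = np.array([176.0, 55.0, 38.5, 8.2, 4.4, 119.0])
        sd = np.full(6, 0.5)
        corr = np.full((6, 6), 0.3) + 0.7 * np.eye(6)
        cov = np.outer(sd, sd) * corr
        X = rng.multivariate_normal(mean, cov, size=5000)
        m = fit_class([fv(x) for x in X], "HH")
        assert np.abs(m.mean - mean).max() < 0.05
        scale = np.outer(sd, sd)
        assert (np.abs(m.covariance - cov) / scale).max() < 0.05


class TestMahalanobis:
    def test_zero_at_mean(self):
        m = fit_class([fv([1.0, 2.0]), fv([3.0, 4.0])], "HH")
        assert mahalanobis_sq(m.mean, m) == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_is_squared_euclidean(self):
        m = ClassModel.from_moments("HH", 2, np.zeros(2), np.eye(2))
        assert mahalanobis_sq(np.array([3.0, 4.0]), m) == pytest.approx(25.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(6, 6))
        m = ClassModel.from_moments("HH", 10, rng.normal(size=6), A @ A.T + np.eye(6))
        x = rng.normal(size=6)
        d = x - m.mean
        brute = sum(
            d[i] * m.inverse[i, j] * d[j] for i in range(6) for j in range(6)
        )
        assert mahalanobis_sq(x, m) == pytest.approx(brute, rel=1e-10)

    def test_dimension_mismatch(self):
        m = ClassModel.from_moments("HH", 2, np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="dimension mismatch"):
            mahalanobis_sq(np.zeros(3), m)

    def test_nonnegative_and_zero_only_at_mean(self):
        rng = np.random.default_rng(12)
        A = rng.normal(size=(4, 4))
        m = ClassModel.from_moments("HH", 5, rng.normal(size=4), A @ A.T + np.eye(4))
        for _ in range(50):
            x = rng.normal(size=4, scale=5)
            assert mahalanobis_sq(x, m) >= 0.0


class TestDiscriminant:
    def test_all_terms_vanish(self):
        m = ClassModel.from_moments("HH", 1, np.zeros(1), np.eye(1))
        assert discriminant(np.zeros(1), m) == pytest.approx(0.0, abs=1e-12)

    def test_prior_modes_differ_by_ln_total(self):
        rng = np.random.default_rng(1)
        X, y = random_gaussian_problem(rng, dim=3, n_per_class=20)
        model = fit_model(X, y)
        x = rng.normal(size=3)
        total = model.total_count
        for cm in model.classes:
            count = discriminant(x, cm, "count")
            prop = discriminant(x, cm, "proportion", total_count=total)
            assert count - prop == pytest.approx(math.log(total), rel=1e-12)

    def test_matches_density_oracle(self):
        """eta equals log p + Gaussian log-density + (d/2) ln(2 pi), class-constant aside."""
        rng = np.random.default_rng(2)
        d = 4
        A = rng.normal(size=(d, d))
        m = ClassModel.from_moments("EH", 17, rng.normal(size=d), A @ A.T + np.eye(d))
        x = rng.normal(size=d)
        expected = (
            math.log(17)
            + multivariate_normal.logpdf(x, mean=m.mean, cov=m.covariance)
            + d / 2 * math.log(2 * math.pi)
        )
        assert discriminant(x, m) == pytest.approx(expected, rel=1e-10)

    def test_decreases_along_eigenvector(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(3, 3))
        m = ClassModel.from_moments("HH", 5, rng.normal(size=3), A @ A.T + np.eye(3))
        _, vecs = np.linalg.eigh(m.covariance)
        v = vecs[:, 0]
        etas = [discriminant(m.mean + t * v, m) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(etas, etas[1:]))


class TestClassify:
    def test_matching_mean_wins(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=2)
        classes = []
        for k, lab in enumerate(CLASSES):
            mean = x if lab == "HE" else x + 5.0 + k
            classes.append(ClassModel.from_moments(lab, 10, mean, np.eye(2)))
        model = QDModel(tuple(classes), ("f0", "f1"))
        assert classify(x, model).predicted == "HE"

    def test_exact_tie_breaks_to_fixed_order(self):
        classes = tuple(
            ClassModel.from_moments(lab, 10, np.zeros(2), np.eye(2)) for lab in CLASSES
        )
        model = QDModel(classes, ("f0", "f1"))
        result = classify(np.array([1.0, 1.0]), model)
        assert result.predicted == "HH"  # earliest in (HH, EH, HE, EE)
        assert result.tie

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_bayes_density_oracle(self, seed):
        """argmax eta reproduces the Bayes rule scored through scipy densities."""
        rng = np.random.default_rng(seed)
        X, y = random_gaussian_problem(rng)
        model = fit_model(X, y)
        probes = rng.normal(0, 4, size=(100, X.shape[1]))
        for probe in probes:
            assert classify(probe, model).predicted == oracle_predict(X, y, probe)

    def test_cross_check_against_sklearn_qda(self):
        """High agreement with sklearn's QDA (which uses the n-1 covariance divisor)."""
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(6)
        X, y = random_gaussian_problem(rng, dim=4, n_per_class=200)
        model = fit_model(X, y, prior_mode="proportion")
        sk = QuadraticDiscriminantAnalysis(priors=None, reg_param=0.0).fit(X, y)
        probes = rng.normal(0, 4, size=(300, 4))
        ours = [classify(p, model).predicted for p in probes]
        theirs = sk.predict(probes)
        agreement = np.mean([a == b for a, b in zip(ours, theirs)])
        assert agreement >= 0.98

    def test_equal_cov_equal_prior_reduces_to_nearest_mean(self):
        rng = np.random.default_rng(7)
        A = rng.normal(size=(3, 3))
        cov = A @ A.T + np.eye(3)
        means = {lab: rng.normal(0, 3, size=3) for lab in CLASSES}
        classes = tuple(
            ClassModel.from_moments(lab, 25, means[lab], cov) for lab in CLASSES
        )
        model = QDModel(classes, ("f0", "f1", "f2"))
        for _ in range(50):
            x = rng.normal(0, 3, size=3)
            by_distance = min(
                CLASSES, key=lambda lab: mahalanobis_sq(x, model.class_model(lab))
            )
            assert classify(x, model).predicted == by_distance


class TestAffineInvariance:
    @pytest.mark.parametrize("seed", [10, 11])
    def test_predictions_unchanged_under_affine_map(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_gaussian_problem(rng, dim=3, n_per_class=30)
        probes = rng.normal(0, 4, size=(50, 3))
        M = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        b = rng.normal(size=3)
        base = fit_model(X, y)
        mapped = fit_model(X @ M.T + b, y)
        for p in probes:
            assert (
                classify(p, base).predicted == classify(M @ p + b, mapped).predicted
            )


class TestMarginCoefficient:
    def eta(self, corr, wro):
        return {"HH": corr, "EH": wro, "HE": wro - 1, "EE": wro - 2}

    def test_hand_substitution(self):
        assert margin_coefficient(self.eta(10.0, 6.0), "HH") == pytest.approx(0.4)

    def test_zero_margin(self):
        assert margin_coefficient(self.eta(7.0, 7.0), "HH") == 0.0

    def test_negative_denominator_conventions(self):
        """Both the as-defined formula and the sign-stable margin are exposed."""
        eta = self.eta(-2.0, -4.0)
        assert margin_coefficient(eta, "HH", mode="paper") == pytest.approx(-1.0)
        assert margin_coefficient(eta, "HH", mode="margin") == pytest.approx(1.0)

    def test_zero_reference_undefined(self):
        with pytest.raises(UndefinedMarginError):
            margin_coefficient(self.eta(0.0, -1.0), "HH")

    @settings(derandomize=True, max_examples=80)
    @given(
        vals=st.lists(
            st.floats(-50, 50, allow_nan=False), min_size=4, max_size=4, unique=True
        )
    )
    def test_margin_mode_nonnegative_at_argmax(self, vals):
        """Referenced at the best class, the sign-stable margin is >= 0 and
        zero only on ties."""
        eta = dict(zip(CLASSES, vals))
        ref = max(eta, key=eta.get)
        if eta[ref] == 0.0:
            return
        R = margin_coefficient(eta, ref, mode="margin")
        assert R >= 0.0
        assert (R == 0.0) == (sorted(vals)[-1] == sorted(vals)[-2])


class TestApplyCorrection:
    def make_result(self, margin):
        from shiftmotif.qda import PredictionResult

        return PredictionResult(
            segment_ref=None,
            eta={"HH": 10.0, "EH": 6.0, "HE": 5.0, "EE": 4.0},
            predicted="HH",
            margin_R=margin,
        )

    def test_margin_flagging_threshold(self):
        results = apply_correction(
            [self.make_result(0.5), self.make_result(0.39)], threshold=0.4
        )
        assert [r.low_confidence for r in results] == [False, True]
        assert all(r.predicted == "HH" for r in results)  # labels never change

    def test_label_aware_requires_labels(self):
        with pytest.raises(ValueError, match="true labels"):
            apply_correction([self.make_result(0.5)], mode="label_aware")

    @pytest.mark.parametrize("seed", range(10))
    def test_label_aware_never_hurts_accuracy(self, seed):
        """Re-counting near-misses as correct can only raise accuracy."""
        rng = np.random.default_rng(seed)
        X, y = random_gaussian_problem(rng, dim=2, n_per_class=20)
        model = fit_model(X, y)
        probes, truth = random_gaussian_problem(rng, dim=2, n_per_class=15)
        results = [classify(fv(p, names=model.feature_names), model) for p in probes]
        plain = np.mean([r.predicted == t for r, t in zip(results, truth)])
        fixed = apply_correction(results, mode="label_aware", true_labels=truth)
        aware = np.mean([r.predicted == t for r, t in zip(fixed, truth)])
        assert aware >= plain
        assert all(r.corrected == (r.predicted != o.predicted) for r, o in zip(fixed, results))
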