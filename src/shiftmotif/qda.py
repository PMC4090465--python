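"""Four-class quadratic Bayes discriminant over averaged-shift features.

Each motif class v in (HH, EH, HE, EE) is modelled as a multivariate
Gaussian fitted on its training vectors:

    mu_v      class mean,
    Sigma_v   class covariance with divisor p_v (population form),
    p_v       number of training samples in the class.

A query vector R is scored per class with the discriminant

    eta_v = ln p_v - delta_v / 2 - (1/2) ln |Sigma_v|,
    delta_v = (R - mu_v)^T Sigma_v^{-1} (R - mu_v)   (squared Mahalanobis),

and assigned to the class with maximal eta.  eta differs from the log
posterior only by the class-constant (d/2) ln(2 pi) (and, under count
priors, ln N), so the argmax is the Bayes rule under Gaussian class
densities.

The relative margin between discriminant scores,

    R = (eta_corr - eta_wro) / eta_corr,

with cutoff 0.4 flags predictions whose top scores are nearly tied.  Two
operational modes are provided because the printed rule needs the true
class: ``margin`` (prediction-time; reference = best class, denominator
|eta_top1|, prediction never changed, only a low-confidence flag) and
``label_aware`` (evaluation-only replication that re-counts a near-miss as
correct; explicitly label-leaking).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from shiftmotif.defs import CLASSES
from shiftmotif.features import FeatureVector

logger = logging.getLogger(__name__)

#: Relative ridge applied to a singular class covariance: eps * trace/d on the
#: diagonal.  Small classes with few segments are expected in motif data.
RIDGE_EPS = 1e-6


class UndefinedMarginError(ZeroDivisionError):
    """The margin coefficient's denominator is zero."""


@dataclass(frozen=True)
class ClassModel:
    """Gaussian model of one motif class: prior weight, mean, covariance.

    The log-determinant and inverse are cached at construction.
    ``regularized`` records whether a ridge was needed to invert the
    covariance.
    """

    label: str
    sample_count: int
    mean: np.ndarray
    covariance: np.ndarray
    log_det: float
    inverse: np.ndarray
    regularized: bool = False

    @classmethod
    def from_moments(
        cls,
        label: str,
        sample_count: int,
        mean: np.ndarray,
        covariance: np.ndarray,
        regularized: bool = False,
    ) -> "ClassModel":
        """Build a model from mean and covariance, ridging if singular."""
        mean = np.asarray(mean, dtype=float)
        cov = np.asarray(covariance, dtype=float)
        d = mean.size
        if cov.shape != (d, d):
            raise ValueError(f"covariance shape {cov.shape} != ({d}, {d})")
        cov = (cov + cov.T) / 2.0
        sign, log_det = np.linalg.slogdet(cov)
        if sign <= 0 or not np.isfinite(log_det):
            ridge = RIDGE_EPS * np.trace(cov) / d
            if ridge <= 0:
                ridge = RIDGE_EPS
            cov = cov + ridge * np.eye(d)
            regularized = True
            sign, log_det = np.linalg.slogdet(cov)
            if sign <= 0 or not np.isfinite(log_det):
                raise np.linalg.LinAlgError(
                    f"class {label}: covariance singular even after ridge"
                )
            logger.info("class %s: singular covariance, ridge %.3g applied", label, ridge)
        inverse = np.linalg.inv(cov)
        if not (np.all(np.isfinite(inverse)) and np.isfinite(log_det)):
            raise np.linalg.LinAlgError(f"class {label}: non-finite model")
        return cls(
            label=label,
            sample_count=int(sample_count),
            mean=mean,
            covariance=cov,
            log_det=float(log_det),
            inverse=inverse,
            regularized=regularized,
        )

    @property
    def dimension(self) -> int:
        return self.mean.size


@dataclass(frozen=True)
class QDModel:
    """One fitted ClassModel per motif class, in fixed order (HH, EH, HE, EE).

    ``prior_mode`` selects p in the ln p term: ``count`` uses the raw class
    sample count (the discriminant as written above); ``proportion`` uses
    count/N.  The two differ by the class-constant ln N, so predictions are
    identical.
    """

    classes: tuple[ClassModel, ...]
    feature_names: tuple[str, ...]
    prior_mode: str = "count"
    regularization: float = RIDGE_EPS

    def __post_init__(self) -> None:
        if self.prior_mode not in ("count", "proportion"):
            raise ValueError(f"unknown prior_mode {self.prior_mode!r}")
        labels = [cm.label for cm in self.classes]
        if sorted(labels) != sorted(set(labels)):
            raise ValueError(f"duplicate class labels {labels}")
        dims = {cm.dimension for cm in self.classes}
        if dims != {len(self.feature_names)}:
            raise ValueError("class models and feature_names disagree on dimension")
        order = {lab: k for k, lab in enumerate(CLASSES)}
        object.__setattr__(
            self,
            "classes",
            tuple(sorted(self.classes, key=lambda cm: order.get(cm.label, 99))),
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(cm.label for cm in self.classes)

    @property
    def total_count(self) -> int:
        return sum(cm.sample_count for cm in self.classes)

    def class_model(self, label: str) -> ClassModel:
        for cm in self.classes:
            if cm.label == label:
                return cm
        raise KeyError(label)


@dataclass(frozen=True)
class PredictionResult:
    """Discriminant scores and the resulting class call for one segment."""

    segment_ref: object
    eta: Mapping[str, float]
    predicted: str
    margin_R: float
    corrected: bool = False
    low_confidence: bool = False
    tie: bool = False


def fit_class(
    vectors: Sequence[FeatureVector] | np.ndarray,
    label: str,
) -> ClassModel:
    """Fit one class's Gaussian: mean and population covariance (divisor p_v).

    Requires at least two vectors.  A singular covariance (e.g. identical
    vectors) is ridged and flagged rather than rejected.
    """
    X = _as_matrix(vectors)
    p_v, d = X.shape
    if p_v < 2:
        raise ValueError(f"class {label}: need >= 2 vectors, got {p_v}")
    mean = X.mean(axis=0)
    centered = X - mean
    cov = centered.T @ centered / p_v  # population divisor, not p_v - 1
    model = ClassModel.from_moments(label, p_v, mean, cov)
    if p_v < d + 1 and not model.regularized:
        logger.info("class %s: %d samples for dimension %d", label, p_v, d)
    return model


def fit_qd(
    vectors: Iterable[FeatureVector],
    prior_mode: str = "count",
) -> QDModel:
    """Fit the full four-class model by grouping labeled vectors by class."""
    groups: dict[str, list[FeatureVector]] = {}
    feature_names: tuple[str, ...] | None = None
    for v in vectors:
        if v.label is None:
            raise ValueError(f"unlabeled vector for {v.segment_ref.describe()}")
        if feature_names is None:
            feature_names = v.feature_names
        elif v.feature_names != feature_names:
            raise ValueError("inconsistent feature names across training vectors")
        groups.setdefault(v.label, []).append(v)
    if feature_names is None:
        raise ValueError("no training vectors")
    class_models = tuple(
        fit_class(vecs, label) for label, vecs in groups.items()
    )
    return QDModel(
        classes=class_models, feature_names=feature_names, prior_mode=prior_mode
    )


def mahalanobis_sq(x: FeatureVector | np.ndarray, model: ClassModel) -> float:
    """Squared Mahalanobis distance from x to the class mean under the class covariance."""
    v = _as_vector(x)
    if v.size != model.dimension:
        raise ValueError(
            f"dimension mismatch: vector {v.size} vs model {model.dimension}"
        )
    diff = v - model.mean
    return float(diff @ model.inverse @ diff)


def discriminant(
    x: FeatureVector | np.ndarray,
    model: ClassModel,
    prior_mode: str = "count",
    total_count: int | None = None,
) -> float:
    """eta = ln p - delta/2 - (1/2) ln |Sigma| for one class.

    ``prior_mode="count"`` takes p as the class sample count;
    ``"proportion"`` takes p = count/total_count, shifting every class's eta
    by the same ln(total) and leaving the argmax unchanged.
    """
    p = float(model.sample_count)
    if prior_mode == "proportion":
        if total_count is None:
            raise ValueError("prior_mode='proportion' needs total_count")
        p /= total_count
    elif prior_mode != "count":
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    delta = mahalanobis_sq(x, model)
    return math.log(p) - delta / 2.0 - model.log_det / 2.0


def classify(x: FeatureVector | np.ndarray, model: QDModel) -> PredictionResult:
    """Assign x to the class with maximal discriminant score.

    Exact ties go to the class earliest in the fixed order (HH, EH, HE, EE)
    and are flagged.  The top-two margin coefficient is recorded.
    """
    total = model.total_count
    eta = {
        cm.label: discriminant(x, cm, model.prior_mode, total) for cm in model.classes
    }
    best = max(eta, key=lambda lab: (eta[lab], -model.labels.index(lab)))
    tie = sum(1 for v in eta.values() if v == eta[best]) > 1
    margin = margin_coefficient(eta, reference=best, mode="margin")
    segment = x.segment_ref if isinstance(x, FeatureVector) else None
    return PredictionResult(
        segment_ref=segment,
        eta=eta,
        predicted=best,
        margin_R=margin,
        tie=tie,
    )


def margin_coefficient(
    eta: Mapping[str, float],
    reference: str,
    mode: str = "paper",
) -> float:
    """Relative margin R between the reference class and its best rival.

    ``mode="paper"`` evaluates R = (eta_ref - eta_wro) / eta_ref exactly as
    defined, where eta_wro is the maximum over the other classes; because
    eta is a log-scale quantity the denominator can be negative, flipping
    the sign of R.  ``mode="margin"`` divides by |eta_ref| instead, giving a
    sign-stable confidence margin.  A zero reference score is an error.
    """
    if reference not in eta:
        raise KeyError(f"reference class {reference!r} not in eta")
    eta_ref = eta[reference]
    rivals = [v for lab, v in eta.items() if lab != reference]
    if not rivals:
        raise ValueError("margin needs at least two classes")
    eta_wro = max(rivals)
    if mode == "paper":
        denom = eta_ref
    elif mode == "margin":
        denom = abs(eta_ref)
    else:
        raise ValueError(f"unknown margin mode {mode!r}")
    if denom == 0.0:
        raise UndefinedMarginError("margin coefficient undefined: eta_ref = 0")
    return (eta_ref - eta_wro) / denom


def apply_correction(
    results: Sequence[PredictionResult],
    threshold: float = 0.4,
    mode: str = "margin",
    true_labels: Sequence[str] | None = None,
) -> list[PredictionResult]:
    """Apply the R < threshold rule to a batch of predictions.

    ``margin`` mode flags predictions whose top-two margin is below the
    threshold as low-confidence without changing any label.  ``label_aware``
    mode replicates the evaluation-time correction: a misclassified item
    whose R relative to its *true* class is below the threshold is re-counted
    as correct (predicted set to the true label, ``corrected=True``).  This
    uses the true labels and therefore leaks them into the score; it exists
    only so evaluations can report the corrected figure alongside the
    honest one.
    """
    if mode == "margin":
        return [
            replace(r, low_confidence=(r.margin_R < threshold)) for r in results
        ]
    if mode != "label_aware":
        raise ValueError(f"unknown correction mode {mode!r}")
    if true_labels is None:
        raise ValueError("label_aware correction requires true labels")
    if len(true_labels) != len(results):
        raise ValueError("true_labels length mismatch")
    out: list[PredictionResult] = []
    n_corrected = 0
    for r, truth in zip(results, true_labels):
        if r.predicted != truth and truth in r.eta:
            R = margin_coefficient(r.eta, reference=truth, mode="paper")
            if R < threshold:
                r = replace(r, predicted=truth, corrected=True)
                n_corrected += 1
        out.append(r)
    if n_corrected:
        logger.warning(
            "label-aware correction re-counted %d/%d misclassifications as"
            " correct; this score uses the true labels",
            n_corrected,
            len(results),
        )
    return out


def _as_vector(x: FeatureVector | np.ndarray) -> np.ndarray:
    if isinstance(x, FeatureVector):
        return x.values
    return np.asarray(x, dtype=float)


def _as_matrix(vectors: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return np.atleast_2d(np.asarray(vectors, dtype=float))
    return np.array([_as_vector(v) for v in vectors], dtype=float)
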