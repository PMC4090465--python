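"""Cross-validated evaluation: confusion matrices, SN/SP/Q_total, experiment grid.

Per-class metrics over a confusion matrix with rows = true class and
columns = predicted class:

    SN_i = TP_i / (TP_i + FN_i) * 100      (sensitivity / recall)
    SP_i = TP_i / (TP_i + FP_i) * 100      (precision form, as conventional
                                            in this literature; the
                                            true-negative rate is reported
                                            separately as TNR)
    Q_total = sum_i TP_i / N * 100         (overall accuracy)

Evaluation uses stratified threefold cross-validation: segments are
shuffled within each class under an explicit seed and dealt into three
parts; each part is scored once against a model fitted on the other two.
Per-fold metrics are reported alongside metrics pooled over the three test
folds.  The nuclei-combination experiment re-uses one fold assignment
across feature subsets so their scores are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from shiftmotif.defs import CLASSES
from shiftmotif.features import Design, FeatureVector, build_design
from shiftmotif.io_formats import Segment, ShiftTable
from shiftmotif.qda import PredictionResult, apply_correction, classify, fit_qd

DEFAULT_SEED = 20140618


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count matrix, rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError(f"counts shape {counts.shape} != ({k}, {k})")
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def from_pairs(
        cls,
        true_labels: Sequence[str],
        predicted: Sequence[str],
        labels: tuple[str, ...] = CLASSES,
    ) -> "ConfusionMatrix":
        idx = {lab: k for k, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(true_labels, predicted, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(counts, labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise ValueError("label order mismatch")
        return ConfusionMatrix(self.counts + other.counts, self.labels)


@dataclass(frozen=True)
class Metrics:
    """Per-class SN/SP (percent; NaN where the denominator is empty) and Q_total."""

    sn: Mapping[str, float]
    sp: Mapping[str, float]
    tnr: Mapping[str, float]
    q_total: float

    @property
    def average_sn(self) -> float:
        return _nanmean(list(self.sn.values()))

    @property
    def average_sp(self) -> float:
        return _nanmean(list(self.sp.values()))


def _nanmean(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    return float(finite.mean()) if finite.size else float("nan")


def metrics(cm: ConfusionMatrix) -> Metrics:
    """SN, SP (precision form), TNR and Q_total from a confusion matrix.

    A class with an empty denominator gets NaN and is excluded from the
    averages.
    """
    counts = cm.counts
    n = cm.total
    if n < 1:
        raise ValueError("empty confusion matrix")
    sn, sp, tnr = {}, {}, {}
    for k, lab in enumerate(cm.labels):
        tp = counts[k, k]
        fn = counts[k, :].sum() - tp
        fp = counts[:, k].sum() - tp
        tn = n - tp - fn - fp
        sn[lab] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        sp[lab] = 100.0 * tp / (tp + fp) if tp + fp else float("nan")
        tnr[lab] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    q_total = 100.0 * np.trace(counts) / n
    return Metrics(sn=sn, sp=sp, tnr=tnr, q_total=float(q_total))


@dataclass(frozen=True)
class FoldResult:
    fold: int
    cm: ConfusionMatrix
    metrics: Metrics
    n_test: int


@dataclass(frozen=True)
class EvaluationReport:
    """Per-fold and pooled cross-validation metrics plus the run settings.

    Pooled metrics are computed on the sum of the per-fold test confusion
    matrices, so ``pooled.q_total`` is correct predictions over all
    evaluated segments.
    """

    per_fold: tuple[FoldResult, ...]
    pooled_cm: ConfusionMatrix
    pooled: Metrics
    settings: Mapping[str, object]
    n_corrected: int = 0

    @property
    def q_total(self) -> float:
        return self.pooled.q_total


def stratified_folds(
    labels: Sequence[str], n_folds: int, seed: int
) -> np.ndarray:
    """Deal items into folds round-robin within each class after a seeded shuffle.

    Guarantees every class appears in every fold when each class has at
    least ``n_folds`` members; errors otherwise, naming the class.
    """
    labels = list(labels)
    rng = np.random.default_rng(seed)
    assignment = np.full(len(labels), -1, dtype=int)
    for lab in sorted(set(labels)):
        idx = np.array([i for i, l in enumerate(labels) if l == lab])
        if idx.size < n_folds:
            raise ValueError(
                f"class {lab} has {idx.size} segments; need >= {n_folds} to"
                f" populate every fold"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % n_folds
    return assignment


def threefold_cv(
    vectors: Sequence[FeatureVector],
    seed: int = DEFAULT_SEED,
    threshold: float = 0.4,
    correction_mode: str = "margin",
    prior_mode: str = "count",
    n_folds: int = 3,
    folds: np.ndarray | None = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation (threefold by default) of the discriminant.

    ``correction_mode="margin"`` only flags low-confidence predictions;
    ``"label_aware"`` additionally re-counts near-miss errors as correct
    using the true labels (evaluation-only, label-leaking; reported as
    ``n_corrected``).  Deterministic given the seed.
    """
    labels = [v.label for v in vectors]
    if any(lab is None for lab in labels):
        raise ValueError("cross-validation requires labeled vectors")
    if folds is None:
        folds = stratified_folds(labels, n_folds, seed)
    folds = np.asarray(folds)
    if folds.shape != (len(vectors),):
        raise ValueError("fold assignment length mismatch")

    fold_results: list[FoldResult] = []
    n_corrected = 0
    present = tuple(lab for lab in CLASSES if lab in set(labels))
    for fold in range(n_folds):
        train = [v for v, f in zip(vectors, folds) if f != fold]
        test = [v for v, f in zip(vectors, folds) if f == fold]
        model = fit_qd(train, prior_mode=prior_mode)
        results = [classify(v, model) for v in test]
        truth = [v.label for v in test]
        results = apply_correction(
            results, threshold=threshold, mode=correction_mode, true_labels=truth
        )
        n_corrected += sum(r.corrected for r in results)
        cm = ConfusionMatrix.from_pairs(truth, [r.predicted for r in results], present)
        fold_results.append(
            FoldResult(fold=fold, cm=cm, metrics=metrics(cm), n_test=len(test))
        )

    pooled_cm = fold_results[0].cm
    for fr in fold_results[1:]:
        pooled_cm = pooled_cm + fr.cm
    settings = {
        "features": tuple(vectors[0].feature_names),
        "seed": int(seed),
        "threshold": float(threshold),
        "correction_mode": correction_mode,
        "prior_mode": prior_mode,
        "n_folds": int(n_folds),
    }
    return EvaluationReport(
        per_fold=tuple(fold_results),
        pooled_cm=pooled_cm,
        pooled=metrics(pooled_cm),
        settings=settings,
        n_corrected=n_corrected,
    )


def combination_experiment(
    segments: Sequence[Segment],
    shifts: ShiftTable,
    subsets: Sequence[Sequence[str]],
    include_aac: bool = False,
    seed: int = DEFAULT_SEED,
    threshold: float = 0.4,
    correction_mode: str = "margin",
    prior_mode: str = "count",
) -> list[tuple[str, EvaluationReport, Design]]:
    """Run the cross-validation once per nuclei subset (plus optional AAC baseline).

    One stratified fold assignment is drawn on the full segment list and
    re-used for every subset; a subset that excludes segments (missing
    assignments) keeps the surviving segments' fold indices, so scores stay
    comparable up to those exclusions.
    """
    if not subsets and not include_aac:
        raise ValueError("no feature subsets requested")
    for sub in subsets:
        if not list(sub):
            raise ValueError("empty nuclei subset")
    base_folds = stratified_folds([s.label for s in segments], 3, seed)
    seg_fold = {id(s): f for s, f in zip(segments, base_folds)}

    runs: list[tuple[str, str | None, Sequence[str]]] = [
        (",".join(sub), "cs", sub) for sub in subsets
    ]
    if include_aac:
        runs.append(("AAC", "aac", ()))

    out = []
    for name, mode, sub in runs:
        if mode == "cs":
            design = build_design(segments, shifts=shifts, nuclei=sub, mode="cs")
        else:
            design = build_design(segments, mode="aac")
        folds = np.array([seg_fold[id(v.segment_ref)] for v in design.vectors])
        report = threefold_cv(
            design.vectors,
            seed=seed,
            threshold=threshold,
            correction_mode=correction_mode,
            prior_mode=prior_mode,
            folds=folds,
        )
        out.append((name, report, design))
    return out


# ---------------------------------------------------------------------------
# report rendering


def _fmt(x: float) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.1f}"


def format_report(report: EvaluationReport) -> str:
    """Render one report as a per-class table (single-run layout).

    Columns: class, SN (%), SP (%), then the averaged SN/SP and Q_total.
    """
    m = report.pooled
    lines = ["Class structure\tSN (%)\tSP (%)\tAverage SN (%)\tAverage SP (%)\tQ_total (%)"]
    labs = report.pooled_cm.labels
    for k, lab in enumerate(labs):
        tail = (
            f"\t{_fmt(m.average_sn)}\t{_fmt(m.average_sp)}\t{_fmt(m.q_total)}"
            if k == 0
            else "\t\t\t"
        )
        lines.append(f"{lab}\t{_fmt(m.sn[lab])}\t{_fmt(m.sp[lab])}{tail}")
    lines.append("")
    lines.append("Per-fold Q_total (%): " + ", ".join(_fmt(fr.metrics.q_total) for fr in report.per_fold))
    s = report.settings
    lines.append(
        f"settings: features={','.join(s['features'])} seed={s['seed']}"
        f" threshold={s['threshold']} correction={s['correction_mode']}"
        f" prior={s['prior_mode']} folds={s['n_folds']}"
        + (f" corrected={report.n_corrected}" if report.n_corrected else "")
    )
    return "\n".join(lines) + "\n"


def format_combination_table(
    results: Sequence[tuple[str, EvaluationReport]]
) -> str:
    """Render the experiment grid: one row per feature combination.

    Columns: per-class SN/SP pairs, then Average SN, Average SP, Q_total.
    """
    labs = results[0][1].pooled_cm.labels
    header = ["Feature combinations"]
    for lab in labs:
        header += [f"{lab} SN (%)", f"{lab} SP (%)"]
    header += ["Average SN (%)", "Average SP (%)", "Q_total (%)"]
    lines = ["\t".join(header)]
    for name, report in results:
        m = report.pooled
        row = [name]
        for lab in labs:
            row += [_fmt(m.sn[lab]), _fmt(m.sp[lab])]
        row += [_fmt(m.average_sn), _fmt(m.average_sp), _fmt(m.q_total)]
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
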