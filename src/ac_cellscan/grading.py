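"""Log-curve calibration of spot counts to continuous SUN grades.

The clinician's SUN score g and the per-eye cellular-spot count x are
related by a logarithmic approximation curve

    y = a * ln(x) + b

fit by ordinary least squares of g on ln(x). The reference coefficients
reported for the original uveitis cohort are a = 0.4347, b = 0.2276;
:func:`published_model` returns them. Evaluation utilities cover Spearman
rank correlation, the Kruskal-Wallis test across grade groups, a seeded
stratified train/test split, and leave-one-out cross-validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError

logger = logging.getLogger(__name__)

#: Reference calibration reported for the original 26-eye training set.
PUBLISHED_SLOPE = 0.4347
PUBLISHED_INTERCEPT = 0.2276


@dataclass
class CalibrationModel:
    """Coefficients of the count-to-grade curve y = slope*ln(x) + intercept."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.slope) and math.isfinite(self.intercept)):
            raise FitError("calibration coefficients must be finite")


def published_model() -> CalibrationModel:
    """The calibration curve reported for the original clinical cohort."""
    return CalibrationModel(slope=PUBLISHED_SLOPE, intercept=PUBLISHED_INTERCEPT)


def fit_log_curve(points: list[tuple[float, float]]) -> CalibrationModel:
    """OLS fit of grade on ln(count).

    ``points`` are (count x, grade g) pairs. Counts below 1 fall outside
    the domain of ln and are dropped with a warning. Raises
    :class:`FitError` with fewer than 2 usable points or when all usable
    counts coincide (degenerate design).
    """
    usable = [(x, g) for x, g in points if x >= 1]
    dropped = len(points) - len(usable)
    if dropped:
        logger.warning("fit_log_curve: dropped %d zero-count point(s) outside the ln domain", dropped)
    if len(usable) < 2:
        raise FitError(f"need >= 2 points with count >= 1, have {len(usable)}")
    x = np.log([p[0] for p in usable])
    g = np.array([p[1] for p in usable], dtype=float)
    if np.ptp(x) == 0:
        raise FitError("degenerate design: all counts identical")
    slope, intercept = np.polyfit(x, g, 1)
    return CalibrationModel(slope=float(slope), intercept=float(intercept))


def predict_grade(model: CalibrationModel, count: float, clip: bool = False) -> float:
    """Continuous grade for a spot count; count 0 maps to grade 0.0.

    With ``clip=True`` the prediction is constrained to the SUN range
    [0, 4].
    """
    if count < 0:
        raise ValueError("count must be non-negative")
    y = 0.0 if count == 0 else model.slope * math.log(count) + model.intercept
    if clip:
        y = min(max(y, 0.0), 4.0)
    return y


def spearman_rho(xs, ys) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t approximation with n - 2 degrees of freedom.
    Raises ``ValueError`` when either argument has zero rank variance.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.shape != ys.shape or xs.size < 3:
        raise ValueError("need equal-length sequences of at least 3 values")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise ValueError("undefined correlation: zero rank variance")
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k - 1 df).

    All observations identical across groups yields H = 0, p = 1 rather
    than an error.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def split_train_test(eyes: list, n_train: int, seed: int, grade_of=None) -> tuple[list, list]:
    """Seeded pseudo-random train/test split, stratified by SUN grade.

    ``grade_of`` extracts the grade from an element (default: index 1 of
    a (count, grade) pair, or an ``sun_grade`` attribute). Stratum
    allocations follow largest-remainder rounding so the train set has
    exactly ``n_train`` elements; the same seed always yields the same
    partition.
    """
    n = len(eyes)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    if grade_of is None:
        def grade_of(e):  # noqa: E731 - tiny default accessor
            return e.sun_grade if hasattr(e, "sun_grade") else e[1]

    rng = np.random.default_rng(seed)
    strata: dict[float, list[int]] = {}
    for idx, eye in enumerate(eyes):
        strata.setdefault(float(grade_of(eye)), []).append(idx)

    frac = n_train / n
    keys = sorted(strata)
    quotas = {k: len(strata[k]) * frac for k in keys}
    take = {k: int(math.floor(quotas[k])) for k in keys}
    remainder = n_train - sum(take.values())
    by_frac = sorted(keys, key=lambda k: (-(quotas[k] - take[k]), k))
    for k in by_frac[:remainder]:
        take[k] += 1

    train_idx: list[int] = []
    for k in keys:
        members = np.array(strata[k])
        picked = rng.permutation(members)[: take[k]]
        train_idx.extend(int(i) for i in picked)
    train_set = set(train_idx)
    train = [eyes[i] for i in sorted(train_set)]
    test = [eyes[i] for i in range(n) if i not in train_set]
    return train, test


@dataclass
class EvaluationReport:
    """Correlation summary plus per-eye predictions."""

    spearman_rho: float
    p_value: float
    kruskal_H: float
    kruskal_p: float
    n: int
    per_eye: list[tuple[str, float, float, float]] = field(default_factory=list)
    # per_eye rows: (eye_id, observed grade, spot count, predicted grade)


def evaluate_predictions(
    eye_ids: list[str], grades, counts, predictions
) -> EvaluationReport:
    """Spearman of grade vs prediction plus Kruskal-Wallis of counts by grade."""
    grades = np.asarray(grades, dtype=float)
    counts = np.asarray(counts, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    rho, p = spearman_rho(grades, predictions)
    groups = [counts[grades == g] for g in np.unique(grades)]
    if len(groups) >= 2:
        h, kp = kruskal_wallis([g.tolist() for g in groups])
    else:
        h, kp = float("nan"), float("nan")
    per_eye = [
        (eid, float(g), float(c), float(pred))
        for eid, g, c, pred in zip(eye_ids, grades, counts, predictions)
    ]
    return EvaluationReport(
        spearman_rho=rho, p_value=p, kruskal_H=h, kruskal_p=kp, n=len(per_eye), per_eye=per_eye
    )


def loocv(eyes: list[tuple[float, float]], eye_ids: list[str] | None = None, clip: bool = False) -> EvaluationReport:
    """Leave-one-out cross-validation of the log-curve calibration.

    For each of the n eyes a curve is fit on the other n - 1 and the
    held-out eye's grade is predicted from its count. The report's rho
    correlates observed grades with the LOOCV predictions. Predictions
    are independent of input ordering.
    """
    n = len(eyes)
    if n < 3:
        raise ValueError(f"LOOCV needs at least 3 eyes, got {n}")
    if eye_ids is None:
        eye_ids = [f"eye_{i}" for i in range(n)]
    counts = [float(x) for x, _ in eyes]
    grades = [float(g) for _, g in eyes]
    predictions = []
    for i in range(n):
        rest = [(counts[j], grades[j]) for j in range(n) if j != i]
        model = fit_log_curve(rest)
        predictions.append(predict_grade(model, counts[i], clip=clip))
    return evaluate_predictions(eye_ids, grades, counts, predictions)
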