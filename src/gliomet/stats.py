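"""Group comparison, ROC analysis and classifier combination.

Statistical stage of the GB-vs-BM workflow: two-sample t tests per feature
(Welch by default — the group SDs are clearly unequal), empirical ROC curves
with the Mann-Whitney (tie-aware) AUC, Youden-optimal cutoffs, a
maximum-likelihood logistic combination of several biomarkers, the
three-threshold decision rule (perilesional rCBV max > 1.37, PSR > 75%,
mean lesional ADC < 1e-3 mm^2/s, conjunctive by default) and confusion
metrics with GB as the positive class throughout. ``binormal_auc`` provides
the closed-form ROC area of two Gaussian score distributions,
Phi(|mu_pos - mu_neg| / sqrt(sd_pos^2 + sd_neg^2)), used as the analytic
oracle for the empirical estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "RocResult",
    "DecisionRule",
    "TTestResult",
    "default_decision_rule",
    "two_sample_t_test",
    "roc_analysis",
    "optimal_cutoff_youden",
    "combine_classifiers",
    "binormal_auc",
    "apply_decision_rule",
    "confusion_metrics",
    "bootstrap_auc_ci",
]

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "GB"


@dataclass
class RocResult:
    """Empirical ROC curve with AUC and the Youden-optimal cutoff.

    ``thresholds``/``sensitivity``/``specificity`` are aligned per candidate
    cutoff, on the original score scale; ``direction`` states whether larger
    or smaller scores indicate the positive (GB) class. A case is called
    positive when its score is strictly beyond the cutoff in that direction.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    direction: str = "greater_is_positive"
    pooled_median: float = field(default=float("nan"), repr=False)


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class DecisionRule:
    """Multi-threshold GB/BM rule: list of (feature, direction, cutoff).

    ``direction`` is ">" or "<" (strict; boundary values do not satisfy a
    criterion). ``combination``: "all" (conjunction), "any", or "majority".
    """

    criteria: list[tuple[str, str, float]]
    combination: str = "all"

    def __post_init__(self) -> None:
        if self.combination not in ("all", "any", "majority"):
            raise ValueError("combination must be one of all/any/majority")
        for feat, direction, cutoff in self.criteria:
            if direction not in (">", "<"):
                raise ValueError(f"criterion for {feat!r}: direction must be '>' or '<'")
            if not np.isfinite(cutoff):
                raise ValueError(f"criterion for {feat!r}: cutoff must be finite")


def default_decision_rule(combination: str = "all") -> DecisionRule:
    """The published three-threshold rule for calling GB."""
    return DecisionRule(
        criteria=[
            ("perilesional_rcbv_max", ">", 1.37),
            ("psr_percent", ">", 75.0),
            ("lesion_adc_mean", "<", 1.0e-3),
        ],
        combination=combination,
    )


def two_sample_t_test(
    group_a: np.ndarray, group_b: np.ndarray, variant: str = "welch"
) -> TTestResult:
    """Two-sided two-sample t test (Welch default, pooled available)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2 or not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("each group needs >= 2 finite values")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return TTestResult(t=0.0, df=float(df), p=1.0)
        raise ValueError("zero variance in both groups with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def _as_positive_indicator(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        return labels.astype(int)
    return (labels == POSITIVE_CLASS).astype(int)


def roc_analysis(
    scores: np.ndarray, labels: np.ndarray, direction: str = "greater_is_positive"
) -> RocResult:
    """Empirical ROC over all distinct score cutoffs.

    The AUC equals the normalized Mann-Whitney statistic (ties get half
    credit) and is invariant under strictly monotone score transforms. The
    optimal cutoff maximizes the Youden index J = sensitivity +
    specificity - 1, ties broken toward the cutoff nearest the pooled
    median score.
    """
    if direction not in ("greater_is_positive", "less_is_positive"):
        raise ValueError("invalid direction")
    scores = np.asarray(scores, dtype=float)
    y = _as_positive_indicator(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    oriented = scores if direction == "greater_is_positive" else -scores
    fpr, tpr, thr = roc_curve(y, oriented, drop_intermediate=False)
    finite = np.isfinite(thr)
    thresholds = thr[finite] if direction == "greater_is_positive" else -thr[finite]
    sens = tpr[finite]
    spec = 1.0 - fpr[finite]
    auc = float(roc_auc_score(y, oriented))
    pooled_median = float(np.median(scores))
    result = RocResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float("nan"),
        direction=direction,
        pooled_median=pooled_median,
    )
    result.optimal_cutoff = optimal_cutoff_youden(result)
    return result


def optimal_cutoff_youden(roc: RocResult) -> float:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Near-ties (within 1e-12) are resolved toward the cutoff closest to the
    pooled median score, which stabilizes the choice on plateaus of J.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    best = j.max()
    tied = np.flatnonzero(j >= best - 1e-12)
    if np.isfinite(roc.pooled_median) and tied.size > 1:
        pick = tied[np.argmin(np.abs(roc.thresholds[tied] - roc.pooled_median))]
    else:
        pick = tied[0]
    return float(roc.thresholds[pick])


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form ROC area of two Gaussian score distributions."""
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be > 0")
    delta = abs(mean_pos - mean_neg)
    return float(sps.norm.cdf(delta / np.hypot(sd_pos, sd_neg)))


def combine_classifiers(
    features: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    method: str = "logistic",
) -> tuple[np.ndarray, RocResult]:
    """Maximum-likelihood linear combination of several biomarkers.

    Features are standardized, then a logistic regression is fit by maximum
    likelihood (deterministic convex fit); the combined score is the linear
    predictor and its ROC is returned. Under perfect separation the ML fit
    diverges, so the Fisher-discriminant (LDA) direction is used instead and
    a warning logged. With a single feature the combined ROC coincides with
    that feature's ROC (monotone mapping).
    """
    if method != "logistic":
        raise ValueError("only the logistic maximum-likelihood combiner is implemented")
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be 2D (cases x features)")
    y = _as_positive_indicator(labels)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - mu) / sd
    coef = None
    try:
        with np.errstate(all="ignore"):
            model = sm.Logit(y, sm.add_constant(z))
            fit = model.fit(disp=0, maxiter=200)
        coef = np.asarray(fit.params[1:], dtype=float)
        if not np.all(np.isfinite(coef)) or not fit.mle_retvals.get("converged", True):
            coef = None
    except Exception:  # perfect separation and numeric failures
        coef = None
    if coef is None:
        logger.warning("logistic fit did not converge (perfect separation?); using LDA direction")
        z_pos, z_neg = z[y == 1], z[y == 0]
        pooled = (
            np.cov(z_pos, rowvar=False) * (len(z_pos) - 1)
            + np.cov(z_neg, rowvar=False) * (len(z_neg) - 1)
        ) / max(len(z) - 2, 1)
        pooled = np.atleast_2d(pooled) + 1e-9 * np.eye(z.shape[1])
        coef = np.linalg.solve(pooled, z_pos.mean(axis=0) - z_neg.mean(axis=0))
    scores = z @ coef
    return scores, roc_analysis(scores, y.astype(bool), "greater_is_positive")


def apply_decision_rule(features: pd.DataFrame, rule: DecisionRule) -> np.ndarray:
    """Label each case GB/BM by the multi-threshold rule.

    Inequalities are strict (a value exactly at a cutoff does not satisfy
    its criterion). Cases with a missing rule feature are labeled
    "undetermined".
    """
    missing = [f for f, _, _ in rule.criteria if f not in features.columns]
    if missing:
        raise ValueError(f"rule features absent from table: {missing}")
    n = len(features)
    votes = np.zeros((n, len(rule.criteria)), dtype=bool)
    undetermined = np.zeros(n, dtype=bool)
    for j, (feat, direction, cutoff) in enumerate(rule.criteria):
        vals = features[feat].to_numpy(dtype=float)
        undetermined |= ~np.isfinite(vals)
        votes[:, j] = vals > cutoff if direction == ">" else vals < cutoff
    if rule.combination == "all":
        is_gb = votes.all(axis=1)
    elif rule.combination == "any":
        is_gb = votes.any(axis=1)
    else:  # majority
        is_gb = votes.sum(axis=1) * 2 > len(rule.criteria)
    labels = np.where(is_gb, "GB", "BM").astype(object)
    labels[undetermined] = "undetermined"
    return np.asarray(labels, dtype=object)


def confusion_metrics(predicted: np.ndarray, truth: np.ndarray) -> dict:
    """Sensitivity, specificity and accuracy with GB as the positive class.

    Cases predicted "undetermined" are excluded from the metrics and counted
    separately. A metric whose denominator is empty is NaN.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth must align")
    keep = predicted != "undetermined"
    n_undetermined = int((~keep).sum())
    p, t = predicted[keep], truth[keep]
    tp = int(((p == "GB") & (t == "GB")).sum())
    fn = int(((p == "BM") & (t == "GB")).sum())
    tn = int(((p == "BM") & (t == "BM")).sum())
    fp = int(((p == "GB") & (t == "BM")).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / p.size if p.size else float("nan")
    if np.isnan(sens) or np.isnan(spec):
        logger.warning("confusion_metrics: a class is absent from truth; metric undefined")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "n_undetermined": n_undetermined,
    }


def bootstrap_auc_ci(
    scores: np.ndarray,
    labels: np.ndarray,
    direction: str = "greater_is_positive",
    n_resamples: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the empirical AUC (seeded, case resampling)."""
    scores = np.asarray(scores, dtype=float)
    y = _as_positive_indicator(labels)
    oriented = scores if direction == "greater_is_positive" else -scores
    rng = np.random.default_rng(seed)
    n = scores.size
    aucs = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.integers(0, n, n)
        yi = y[idx]
        if yi.min() == yi.max():
            aucs[i] = np.nan
            continue
        aucs[i] = roc_auc_score(yi, oriented[idx])
    lo, hi = np.nanpercentile(aucs, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)
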