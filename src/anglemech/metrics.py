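"""Performance statistics for the mechanism classifiers.

Binary metrics (accuracy, sensitivity, specificity, PPV, NPV, F1, MCC) with
Wilson-score confidence intervals, rank-based ROC/AUC with half-credit for
ties, Pearson chi-square comparison of two accuracies, Cohen's kappa, and
multi-class accuracy for the integrated four-way assessment.

Undefined metrics (zero denominators) are flagged as NaN rather than coerced
to 0, so they cannot silently distort model selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import AngleMechError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "MetricInputError",
    "confusion",
    "binary_metrics",
    "proportion_ci",
    "roc_auc",
    "chi_square_accuracy_diff",
    "cohens_kappa",
    "multiclass_accuracy",
]

CI_METHOD = "wilson"


class MetricInputError(AngleMechError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise MetricInputError("confusion counts must be nonnegative")
        if self.total < 1:
            raise MetricInputError("confusion counts must sum to >= 1")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """Point estimates (NaN = undefined), Wilson 95% CIs for the rate metrics."""

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float
    mcc: float
    auc: float = float("nan")
    ci: dict = field(default_factory=dict)  # metric name -> (low, high)
    ci_method: str = CI_METHOD

    def as_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "f1", "mcc", "auc")
        }
        out["ci"] = self.ci
        out["ci_method"] = self.ci_method
        return out


def _as_bool(x) -> np.ndarray:
    return np.asarray(x, dtype=bool)


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard 2x2 counts, positive = mechanism present."""
    t, p = _as_bool(y_true), _as_bool(y_pred)
    if t.shape != p.shape or t.ndim != 1 or len(t) < 1:
        raise MetricInputError("y_true and y_pred must be equal-length 1-D, n >= 1")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if not (0 <= k <= n) or n < 1:
        raise MetricInputError(f"invalid proportion counts k={k}, n={n}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1.0 + z**2 / n
    centre = (phat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, centre - half), min(1.0, centre + half))


def binary_metrics(c: ConfusionCounts, level: float = 0.95) -> MetricReport:
    """All binary rates plus F1 and MCC from a confusion table.

    Rate metrics carry Wilson CIs; a zero denominator flags the metric (and
    its CI) as undefined instead of zeroing it.
    """
    nan = float("nan")

    def rate(num: int, den: int) -> float:
        return num / den if den > 0 else nan

    n = c.total
    acc = rate(c.tp + c.tn, n)
    sens = rate(c.tp, c.tp + c.fn)
    spec = rate(c.tn, c.tn + c.fp)
    ppv = rate(c.tp, c.tp + c.fp)
    npv = rate(c.tn, c.tn + c.fn)
    f1 = rate(2 * c.tp, 2 * c.tp + c.fp + c.fn)
    denom = (
        float(c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / np.sqrt(denom) if denom > 0 else nan

    ci: dict[str, tuple[float, float]] = {}
    for name, num, den in (
        ("accuracy", c.tp + c.tn, n),
        ("sensitivity", c.tp, c.tp + c.fn),
        ("specificity", c.tn, c.tn + c.fp),
        ("ppv", c.tp, c.tp + c.fp),
        ("npv", c.tn, c.tn + c.fn),
    ):
        ci[name] = proportion_ci(num, den, level) if den > 0 else (nan, nan)
    return MetricReport(
        accuracy=acc, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        f1=f1, mcc=float(mcc), ci=ci,
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """AUC by the rank (Mann-Whitney) formulation with half-credit for ties.

    Returns (auc, curve) where curve is an (m, 2) array of (fpr, tpr) step
    points swept over decreasing score thresholds.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_bool(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise MetricInputError("scores and labels must be equal-length 1-D")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricInputError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(s)  # average ranks give tie half-credit
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # keep only the last point of each tied-score block
    last = np.r_[ss[1:] != ss[:-1], True]
    curve = np.column_stack([fps[last] / n_neg, tps[last] / n_pos])
    curve = np.vstack([[0.0, 0.0], curve])
    return float(auc), curve


def chi_square_accuracy_diff(
    correct_a: int, n_a: int, correct_b: int, n_b: int, continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the 2x2 correct/incorrect table.

    No continuity correction by default; Yates' correction behind the flag.
    """
    if n_a < 1 or n_b < 1 or not (0 <= correct_a <= n_a) or not (0 <= correct_b <= n_b):
        raise MetricInputError("invalid accuracy counts")
    obs = np.array(
        [[correct_a, n_a - correct_a], [correct_b, n_b - correct_b]], dtype=float
    )
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if (exp == 0).any():
        return 0.0, 1.0
    diff = np.abs(obs - exp)
    if continuity:
        diff = np.clip(diff - 0.5, 0.0, None)
    statistic = float((diff**2 / exp).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, p


def cohens_kappa(rater_a, rater_b) -> float:
    """Cohen's kappa with marginal-product expected agreement.

    Returns NaN (flagged undefined) when expected agreement is 1."""
    a = np.asarray(rater_a)
    b = np.asarray(rater_b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise MetricInputError("rater vectors must be equal-length 1-D")
    labels = np.unique(np.concatenate([a, b]))
    n = len(a)
    p_o = float(np.mean(a == b))
    p_e = float(
        sum((np.sum(a == lab) / n) * (np.sum(b == lab) / n) for lab in labels)
    )
    if p_e >= 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def multiclass_accuracy(y_true, y_pred, classes=None) -> tuple[float, np.ndarray]:
    """Exact-match accuracy plus confusion table (rows = truth, cols = prediction)."""
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape or t.ndim != 1 or len(t) < 1:
        raise MetricInputError("label vectors must be equal-length 1-D")
    if classes is None:
        classes = np.unique(np.concatenate([t, p]))
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    table = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        table[idx[ti], idx[pi]] += 1
    return float(np.mean(t == p)), table
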