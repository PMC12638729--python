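"""Method-comparison and diagnostic-performance statistics.

The battery used to validate simulated vFFR against invasive FFR:
contingency metrics with Clopper-Pearson exact binomial confidence
intervals, Pearson chi-square comparison of per-model failure rates,
Bland-Altman bias and limits of agreement fitted by quantile regression
(for data violating the parametric assumptions of the classical
method), Passing-Bablok regression, ROC/AUC with the orientation
"lower score predicts disease", and the a-priori paired-t sample-size
calculation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.regression.quantile_regression import QuantReg
from statsmodels.stats.proportion import proportion_confint

from .errors import DegenerateInput, DomainError


@dataclass(frozen=True)
class DiagnosticCounts:
    """2x2 contingency counts of a binary diagnostic test."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise DomainError(f"{name} must be a non-negative integer, got {v!r}")
        if self.total == 0:
            raise DomainError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_scores(cls, reference, test, ref_threshold: float = 0.80,
                    test_threshold: float | None = None) -> "DiagnosticCounts":
        """Tabulate counts with 'value <= threshold' meaning disease-positive."""
        if test_threshold is None:
            test_threshold = ref_threshold
        ref_pos = np.asarray(reference, dtype=float) <= ref_threshold
        test_pos = np.asarray(test, dtype=float) <= test_threshold
        return cls(
            tp=int(np.sum(ref_pos & test_pos)),
            tn=int(np.sum(~ref_pos & ~test_pos)),
            fp=int(np.sum(~ref_pos & test_pos)),
            fn=int(np.sum(ref_pos & ~test_pos)),
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """A percentage with its exact (Clopper-Pearson) confidence interval."""

    value_pct: float
    ci_low_pct: float
    ci_high_pct: float
    numerator: int
    denominator: int


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval (fractions) via beta quantiles."""
    if not (0 < level < 1):
        raise DomainError("confidence level must lie in (0, 1)")
    if n <= 0 or k < 0 or k > n:
        raise DomainError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    low, high = proportion_confint(k, n, alpha=1.0 - level, method="beta")
    # statsmodels returns NaN at the k=0 / k=n boundaries; the exact
    # interval endpoints there are 0 and 1.
    low = 0.0 if np.isnan(low) else float(low)
    high = 1.0 if np.isnan(high) else float(high)
    return low, high


def _proportion(k: int, n: int, level: float) -> ProportionEstimate | None:
    if n == 0:
        return None  # undefined, never reported as 0
    low, high = clopper_pearson(k, n, level)
    return ProportionEstimate(
        value_pct=100.0 * k / n,
        ci_low_pct=100.0 * low,
        ci_high_pct=100.0 * high,
        numerator=k,
        denominator=n,
    )


def diagnostic_metrics(counts: DiagnosticCounts,
                       level: float = 0.95) -> dict[str, ProportionEstimate | None]:
    """Accuracy, sensitivity, specificity, PPV and NPV with exact CIs.

    Point estimates in percent; a metric with zero denominator is
    reported as None (undefined).
    """
    c = counts
    return {
        "accuracy": _proportion(c.tp + c.tn, c.total, level),
        "sensitivity": _proportion(c.tp, c.tp + c.fn, level),
        "specificity": _proportion(c.tn, c.tn + c.fp, level),
        "ppv": _proportion(c.tp, c.tp + c.fp, level),
        "npv": _proportion(c.tn, c.tn + c.fn, level),
    }


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a counts matrix.

    Returns (statistic, degrees of freedom, p-value); expected counts
    from the row/column margins, no continuity correction.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise DomainError("need an r x c table with r, c >= 2")
    if np.any(table < 0):
        raise DomainError("counts must be non-negative")
    if np.any(table.sum(axis=0) <= 0) or np.any(table.sum(axis=1) <= 0):
        raise DomainError("all row and column margins must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass(frozen=True)
class AgreementResult:
    """Quantile-regression Bland-Altman summary.

    Each line is an (intercept, slope) pair of the regression of the
    difference (test - reference) on the pair mean, at the 50th
    (bias), 2.5th and 97.5th centiles; ``bias_at_ref`` and
    ``loa_at_ref`` evaluate the lines at ``ref_mean``.
    """

    bias_line: tuple[float, float]
    lo_line: tuple[float, float]
    hi_line: tuple[float, float]
    bias_at_ref: float
    loa_at_ref: tuple[float, float]
    ref_mean: float
    n: int
    fallback_unconditional: bool = False


def _quantile_line(mean: np.ndarray, diff: np.ndarray, q: float) -> tuple[float, float]:
    x = np.column_stack([np.ones_like(mean), mean])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # QuantReg emits benign IterationLimit warnings
        fit = QuantReg(diff, x).fit(q=q)
    return float(fit.params[0]), float(fit.params[1])


def bland_altman_quantile(reference, test, ref_mean: float = 0.80,
                          quantiles: tuple[float, float, float] = (0.025, 0.5, 0.975),
                          ) -> AgreementResult:
    """Median bias and 95% limits of agreement by quantile regression.

    Regresses the difference (test - reference) on the pair mean at the
    2.5th, 50th and 97.5th centiles and evaluates the three lines at
    ``ref_mean`` (the diagnostic threshold, 0.80 by default).  With
    degenerate spread of the pair means (or constant differences) the
    unconditional quantiles are used and the result is flagged.
    """
    reference = np.asarray(reference, dtype=float)
    test = np.asarray(test, dtype=float)
    if reference.shape != test.shape or reference.ndim != 1:
        raise DomainError("reference and test must be 1-D arrays of equal length")
    n = reference.size
    if n < 20:
        warnings.warn(f"only {n} pairs; agreement limits are unstable below 20",
                      UserWarning, stacklevel=2)
    diff = test - reference
    mean = 0.5 * (test + reference)
    q_lo, q_mid, q_hi = quantiles
    degenerate = float(np.ptp(mean)) < 1e-12 or float(np.ptp(diff)) < 1e-12
    if degenerate:
        lines = {q: (float(np.quantile(diff, q)), 0.0) for q in quantiles}
    else:
        lines = {q: _quantile_line(mean, diff, q) for q in quantiles}

    def at_ref(line: tuple[float, float]) -> float:
        return line[0] + line[1] * ref_mean

    return AgreementResult(
        bias_line=lines[q_mid],
        lo_line=lines[q_lo],
        hi_line=lines[q_hi],
        bias_at_ref=at_ref(lines[q_mid]),
        loa_at_ref=(at_ref(lines[q_lo]), at_ref(lines[q_hi])),
        ref_mean=ref_mean,
        n=n,
        fallback_unconditional=degenerate,
    )


def passing_bablok(x, y) -> tuple[float, float]:
    """Passing-Bablok regression slope and intercept.

    The slope is the shifted median of all pairwise slopes
    (y_j - y_i)/(x_j - x_i): slopes of exactly -1 and 0/0 pairs are
    excluded, and the median index is offset by the number of slopes
    below -1, per the standard estimator; the intercept is
    median(y - slope * x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 10:
        warnings.warn(f"only {n} pairs; Passing-Bablok is unstable below 10",
                      UserWarning, stacklevel=2)
    i, j = np.triu_indices(n, k=1)
    dx = x[j] - x[i]
    dy = y[j] - y[i]
    both_zero = (dx == 0) & (dy == 0)
    with np.errstate(divide="ignore"):
        slopes = np.where(dx != 0, dy / np.where(dx == 0, 1.0, dx),
                          np.where(dy > 0, np.inf, -np.inf))
    slopes = slopes[~both_zero]
    slopes = slopes[slopes != -1.0]
    if slopes.size == 0:
        raise DegenerateInput("no defined pairwise slopes")
    slopes = np.sort(slopes)
    n_s = slopes.size
    k = int(np.sum(slopes < -1.0))
    if n_s % 2 == 1:
        slope = slopes[(n_s - 1) // 2 + k]
    else:
        slope = 0.5 * (slopes[n_s // 2 - 1 + k] + slopes[n_s // 2 + k])
    if not np.isfinite(slope):
        raise DegenerateInput("median pairwise slope is not finite")
    intercept = float(np.median(y - slope * x))
    return float(slope), intercept


@dataclass(frozen=True)
class RocResult:
    """ROC curve with trapezoidal AUC, oriented 'lower score = positive'."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for a marker where *low* values predict disease.

    ``labels`` are disease indicators; a case is called positive when
    its score is at or below a threshold (vFFR orientation: lower
    means more diseased).  The AUC is the trapezoidal area, equivalent
    to the tie-averaged rank (Mann-Whitney) statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be 1-D arrays of equal length")
    if labels.all() or not labels.any():
        raise DomainError("both classes must be present")
    fpr, tpr, thr = roc_curve(labels.astype(int), -scores)
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(auc=auc, fpr=fpr, tpr=tpr, thresholds=-thr)


def paired_t_sample_size(effect_size: float, alpha: float = 0.05,
                         power: float = 0.80, method: str = "exact",
                         n_max: int = 1_000_000) -> int:
    """Minimum n for a two-tailed one-sample t-test on paired differences.

    ``method="exact"``: smallest n whose exact noncentral-t power (df =
    n - 1, noncentrality d_z * sqrt(n)) reaches ``power``.
    ``method="normal"``: the classical z-approximation
    ceil(((z_{1-alpha/2} + z_{power}) / d_z)^2).
    """
    if not effect_size > 0:
        raise DomainError("effect size must be positive")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise DomainError("alpha and power must lie in (0, 1)")
    if method == "normal":
        z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
        return int(np.ceil((z / effect_size) ** 2))
    if method != "exact":
        raise DomainError(f"unknown method {method!r}")
    for n in range(2, n_max + 1):
        df = n - 1
        t_crit = stats.t.ppf(1 - alpha / 2, df)
        nc = effect_size * np.sqrt(n)
        achieved = stats.nct.sf(t_crit, df, nc) + stats.nct.cdf(-t_crit, df, nc)
        if achieved >= power:
            return n
    raise DomainError("sample size search exceeded n_max")
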