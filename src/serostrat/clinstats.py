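"""Clinical statistics layer.

Implements the study's statistical toolbox: a rank-based 95% CI for the
median, the normality/variance-homogeneity decision tree for group
comparisons, Fisher's exact test for categorical 2x2 tables, ROC analysis
with DeLong AUC confidence intervals and Youden-threshold operating point,
responder classification on the MG-ADL scale (>= 3-point improvement), and
the time-weighted average steroid dose over a 183-day pre-baseline window
with an 80% day-coverage requirement.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


class StatisticsError(ValueError):
    pass


# ----------------------------------------------------------------------
def median_ci(x) -> tuple[float, float, float]:
    """Median with rank-based binomial 95% CI.

    Bounding ranks are n/2 - 1.96*sqrt(n/4) and n/2 + 1.96*sqrt(n/4),
    rounded to the nearest integer (0.5 rounds up) and clamped to [1, n];
    the bounds are the order statistics at those ranks.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 6:
        raise StatisticsError(f"median_ci needs n >= 6 (got {n})")
    half = 1.96 * math.sqrt(n / 4.0)
    r_lo = int(min(max(math.floor(n / 2.0 - half + 0.5), 1), n))
    r_hi = int(min(max(math.floor(n / 2.0 + half + 0.5), 1), n))
    return float(np.median(x)), float(x[r_lo - 1]), float(x[r_hi - 1])


def responder_label(mgadl_baseline, mgadl_followup) -> bool | None:
    """Treatment responder iff MG-ADL improved by >= 3 points.

    Returns None (explicit missing) when the follow-up score is absent —
    never silently "non-responder".
    """
    if mgadl_baseline is None or mgadl_followup is None:
        return None
    if (isinstance(mgadl_followup, float) and math.isnan(mgadl_followup)) or (
        isinstance(mgadl_baseline, float) and math.isnan(mgadl_baseline)
    ):
        return None
    return (mgadl_baseline - mgadl_followup) >= 3


def twa_steroid_dose(
    series: dict[int, float], window_days: int = 183, min_coverage: float = 0.8
) -> float | None:
    """Time-weighted average daily steroid dose, or None when excluded.

    `series` maps day offsets within the window to mg/day.  Computed only
    when doses are known for at least ``min_coverage`` of the window days;
    the average divides the summed observed doses by the number of
    observed days.  The inclusion decision depends only on coverage.
    """
    observed = {d: v for d, v in series.items() if 0 <= int(d) < window_days}
    if any(v < 0 for v in observed.values()):
        raise ValueError("negative steroid dose")
    if len(observed) / window_days < min_coverage:
        return None
    return float(sum(observed.values()) / len(observed))


# ----------------------------------------------------------------------
def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table of non-negative counts:
    the summed hypergeometric probability of all tables with the observed
    margins whose probability does not exceed the observed table's."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("negative counts")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


# ----------------------------------------------------------------------
@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    threshold: float
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    direction: str          # ">=" : higher scores indicate the positive class

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "direction": self.direction,
        }


def _delong_auc_variance(pos: np.ndarray, neg: np.ndarray) -> tuple[float, float]:
    """DeLong AUC and its variance via placement values (ties count half)."""
    m, n = len(pos), len(neg)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def roc_analysis(scores, labels, positive_direction: str = ">=") -> RocResult:
    """ROC analysis: rank-statistic AUC with DeLong 95% CI, operating
    threshold by Youden's J, sensitivity/specificity with Wilson CIs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise StatisticsError("both label classes must be present")
    s = scores if positive_direction == ">=" else -scores
    pos, neg = s[labels], s[~labels]
    auc, var = _delong_auc_variance(pos, neg)
    half = 1.96 * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    thresholds = np.unique(s)
    best_j, best_t = -np.inf, thresholds[0]
    for t in thresholds:
        sens = np.mean(pos >= t)
        spec = np.mean(neg < t)
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_t = j, t
    tp = int(np.sum(pos >= best_t))
    tn = int(np.sum(neg < best_t))
    sens, spec = tp / len(pos), tn / len(neg)
    sens_ci = proportion_confint(tp, len(pos), alpha=0.05, method="wilson")
    spec_ci = proportion_confint(tn, len(neg), alpha=0.05, method="wilson")
    thr = best_t if positive_direction == ">=" else -best_t
    return RocResult(
        auc=auc, auc_ci=ci, threshold=float(thr),
        sensitivity=float(sens), sensitivity_ci=tuple(map(float, sens_ci)),
        specificity=float(spec), specificity_ci=tuple(map(float, spec_ci)),
        direction=positive_direction,
    )


# ----------------------------------------------------------------------
@dataclass
class GroupCompareResult:
    test: str
    statistic: float
    p: float
    normality_ok: bool
    variance_ok: bool

    def to_dict(self) -> dict:
        return {"test": self.test, "statistic": self.statistic, "p": self.p,
                "normality_ok": self.normality_ok, "variance_ok": self.variance_ok}


def _f_test_two_variances(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test of equal variances for two samples."""
    f = a.var(ddof=1) / b.var(ddof=1)
    dfa, dfb = len(a) - 1, len(b) - 1
    p = 2.0 * min(stats.f.cdf(f, dfa, dfb), stats.f.sf(f, dfa, dfb))
    return min(p, 1.0)


def group_compare(values, groups, alpha: float = 0.05) -> GroupCompareResult:
    """Decision-tree group comparison.

    Per-group Shapiro–Wilk normality screen (alpha = 0.05) and variance
    homogeneity by F test (two groups) or Bartlett's test (more).  When
    both pass: Student's t test / one-way ANOVA; otherwise Mann–Whitney U /
    Kruskal–Wallis.  Groups identical up to zero variance everywhere return
    p = 1 with a warning.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in np.unique(groups)]
    if len(samples) < 2:
        raise StatisticsError("need at least 2 groups")
    if any(len(s) < 3 for s in samples):
        raise StatisticsError("every group needs n >= 3")
    if all(s.var(ddof=1) == 0 for s in samples) and len({s[0] for s in samples}) == 1:
        warnings.warn("all groups constant and identical; returning p = 1")
        return GroupCompareResult("degenerate", 0.0, 1.0, False, False)
    normality_ok = True
    for s in samples:
        if s.var(ddof=1) == 0:
            normality_ok = False
            break
        if stats.shapiro(s)[1] < alpha:
            normality_ok = False
            break
    variance_ok = False
    if normality_ok:
        if len(samples) == 2:
            variance_ok = _f_test_two_variances(samples[0], samples[1]) >= alpha
        else:
            variance_ok = stats.bartlett(*samples)[1] >= alpha
    if normality_ok and variance_ok:
        if len(samples) == 2:
            stat, p = stats.ttest_ind(samples[0], samples[1])
            name = "t-test"
        else:
            stat, p = stats.f_oneway(*samples)
            name = "anova"
    else:
        if len(samples) == 2:
            stat, p = stats.mannwhitneyu(samples[0], samples[1],
                                         alternative="two-sided")
            name = "mann-whitney"
        else:
            stat, p = stats.kruskal(*samples)
            name = "kruskal-wallis"
    return GroupCompareResult(name, float(stat), float(p), normality_ok, variance_ok)
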