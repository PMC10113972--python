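"""Two-sample tests, 2x2 contingency tests, ROC/Youden analysis and the
age-residual adjustment used for the cohort comparisons.

All formulas are implemented directly (scipy supplies only distribution
CDFs/PMFs) so the test suite can check each one against an independent
oracle — enumeration, quadrature, or brute-force pairwise counting.

Conventions worth stating once:

* the Welch (unequal-variance) form is the default t-test; the pooled
  (Student) form is available via ``pooled=True``;
* Fisher's exact test is two-sided by the minimum-likelihood convention;
* the Mann-Whitney test is exact (null enumeration) for tie-free samples
  with n1+n2 <= 30, otherwise a normal approximation with tie and
  continuity correction;
* ROC orientation is higher-score => positive class; AUC uses the
  Mann-Whitney identity with ties credited 1/2; the Youden-optimal
  threshold ties break toward the smallest threshold (highest sensitivity);
* no multiple-testing correction is applied — p-values are raw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "SummaryStat",
    "TestResult",
    "ROCResult",
    "welch_t_summary",
    "welch_t_data",
    "mann_whitney",
    "chi_square_2x2",
    "fisher_exact_2x2",
    "roc_empirical",
    "binormal_auc",
    "age_adjust_residuals",
    "proportion_percent",
    "analyze_cohort",
]


@dataclass(frozen=True)
class SummaryStat:
    """Sample mean, SD (ddof=1) and size."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise DomainError(f"summary requires n >= 2, got {self.n}")
        if not self.sd > 0:
            raise DomainError(f"summary requires sd > 0, got {self.sd}")

    @classmethod
    def from_data(cls, x) -> "SummaryStat":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise DomainError(f"need at least 2 observations, got {x.size}")
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_two_sided: float
    method: str

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_two_sided": self.p_two_sided,
            "method": self.method,
        }


@dataclass(frozen=True)
class ROCResult:
    """ROC curve (thresholds with sens/spec), AUC, and the Youden optimum."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    sens_at_youden: float
    spec_at_youden: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "youden_threshold": self.youden_threshold,
            "sensitivity_at_youden": self.sens_at_youden,
            "specificity_at_youden": self.spec_at_youden,
        }


def welch_t_summary(a: SummaryStat, b: SummaryStat, pooled: bool = False) -> TestResult:
    """Two-sample t-test from summary statistics.

    Welch form by default: t = (ma - mb) / sqrt(sa^2/na + sb^2/nb) with
    Welch-Satterthwaite degrees of freedom; ``pooled=True`` gives the
    classical equal-variance form.
    """
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    if pooled:
        sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
        t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
        df = float(a.n + b.n - 2)
        method = "student_t_summary"
    else:
        t = (a.mean - b.mean) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
        method = "welch_t_summary"
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_two_sided=float(min(p, 1.0)), method=method)


def welch_t_data(x, y, pooled: bool = False) -> TestResult:
    """Two-sample t-test from raw data; identical to the summary form applied
    to the samples' own summaries (consistency contract)."""
    return welch_t_summary(SummaryStat.from_data(x), SummaryStat.from_data(y), pooled=pooled)


def _mw_null_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of U for tie-free samples.

    Uses the counting recursion N(u; m, n) = N(u - n; m - 1, n) + N(u; m, n - 1):
    the largest pooled value is either an x (beating all n y's) or a y
    (beaten by no x).
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def table(m: int, n: int) -> tuple:
        if m == 0 or n == 0:
            return (1.0,)
        with_x = table(m - 1, n)
        with_y = table(m, n - 1)
        out = [0.0] * (m * n + 1)
        for u, v in enumerate(with_y):
            out[u] += v
        for u, v in enumerate(with_x):
            out[u + n] += v
        return tuple(out)

    pmf = np.array(table(n1, n2))
    return pmf / pmf.sum()


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact when the pooled sample is tie-free and n1+n2 <= 30; otherwise a
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("mann_whitney requires non-empty samples")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and n1 + n2 <= 30:
        pmf = _mw_null_pmf(n1, n2)
        u_obs = int(round(u1))
        mid = n1 * n2 / 2.0
        # symmetric two-sided: mass at least as far from the center
        dist = abs(u_obs - mid)
        us = np.arange(pmf.size)
        p = float(pmf[np.abs(us - mid) >= dist - 1e-12].sum())
        return TestResult(statistic=float(u1), df=None, p_two_sided=min(p, 1.0),
                          method="mann_whitney_exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return TestResult(statistic=float(u1), df=None, p_two_sided=1.0,
                          method="mann_whitney_normal")
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    z = max(z, 0.0)
    p = 2.0 * stats.norm.sf(z)
    return TestResult(statistic=float(u1), df=None, p_two_sided=float(min(p, 1.0)),
                      method="mann_whitney_normal")


def _check_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise DomainError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise DomainError("2x2 table must hold non-negative integer counts")
    return t


def chi_square_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (df = 1), optional Yates correction."""
    t = _check_2x2(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if np.any(rows == 0) or np.any(cols == 0):
        raise DomainError("chi-square undefined: a row or column marginal is zero")
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return TestResult(statistic=statistic, df=1.0, p_two_sided=p,
                      method="chi_square_yates" if yates else "chi_square")


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test, two-sided by the minimum-likelihood convention.

    With margins fixed, sums the hypergeometric probabilities of every table
    whose point probability does not exceed the observed one.
    """
    t = _check_2x2(table).astype(int)
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    if n == 0:
        raise DomainError("empty 2x2 table")
    k_obs = t[0, 0]
    k_min = max(0, r1 + c1 - n)
    k_max = min(r1, c1)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, r1, c1)
    p_obs = stats.hypergeom.pmf(k_obs, n, r1, c1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    odds = np.inf
    if t[0, 1] * t[1, 0] > 0:
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return TestResult(statistic=float(odds), df=None, p_two_sided=min(p, 1.0),
                      method="fisher_exact_minlike")


def roc_empirical(scores, labels) -> ROCResult:
    """Empirical ROC curve, Mann-Whitney AUC, and the Youden-optimal threshold.

    Orientation: higher score predicts the positive class; a voxel is called
    positive when ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise DomainError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise DomainError("roc_empirical requires both classes present")

    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(scores)  # ascending
    pos_scores = np.sort(scores[labels])
    neg_scores = np.sort(scores[~labels])
    # sens(t) = P(score >= t | pos); spec(t) = P(score < t | neg)
    sens = 1.0 - np.searchsorted(pos_scores, thresholds, side="left") / n_pos
    spec = np.searchsorted(neg_scores, thresholds, side="left") / n_neg

    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # argmax returns the first (smallest) maximizer
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=float(auc),
        youden_threshold=float(thresholds[best]),
        sens_at_youden=float(sens[best]),
        spec_at_youden=float(spec[best]),
    )


def binormal_auc(a: SummaryStat | tuple, b: SummaryStat | tuple) -> float:
    """Closed-form ROC area under two-normal score distributions:
    Phi((m_a - m_b) / sqrt(s_a^2 + s_b^2)), with group a the positive class."""
    ma, sa = (a.mean, a.sd) if isinstance(a, SummaryStat) else (a[0], a[1])
    mb, sb = (b.mean, b.sd) if isinstance(b, SummaryStat) else (b[0], b[1])
    if sa <= 0 or sb <= 0:
        raise DomainError("binormal_auc requires positive SDs")
    return float(stats.norm.cdf((ma - mb) / np.hypot(sa, sb)))


def age_adjust_residuals(score, age, group):
    """Age adjustment by pooled OLS residuals.

    Fits ``score ~ age`` (with intercept) over all patients pooled, then
    reports the residual mean +/- SD per group and a two-sided Welch test on
    the residuals between the two groups.

    Returns
    -------
    dict with keys ``slope``, ``intercept``, ``residuals``, ``groups``
    (group label -> SummaryStat) and ``test`` (TestResult).
    """
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    group = np.asarray(group)
    if score.size != age.size or score.size != group.size:
        raise DomainError("score, age and group must have equal length")
    if score.size < 3:
        raise DomainError("age adjustment needs at least 3 points")
    levels = np.unique(group)
    if levels.size != 2:
        raise DomainError(f"exactly two groups required, got {levels.size}")
    if np.ptp(age) == 0:
        raise DomainError("age is constant; regression fit is singular")

    slope, intercept = np.polyfit(age, score, 1)
    residuals = score - (slope * age + intercept)
    groups = {str(lv): SummaryStat.from_data(residuals[group == lv]) for lv in levels}
    test = welch_t_data(residuals[group == levels[0]], residuals[group == levels[1]])
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "residuals": residuals,
        "groups": groups,
        "test": test,
    }


def proportion_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage of a cohort with an attribute, rounded for reporting."""
    if total <= 0 or count < 0 or count > total:
        raise DomainError(f"invalid proportion {count}/{total}")
    return round(100.0 * count / total, decimals)


def _group_summary(values) -> dict | None:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return None
    s = SummaryStat.from_data(values)
    return {"mean": round(s.mean, 3), "sd": round(s.sd, 3), "n": s.n}


def analyze_cohort(table) -> dict:
    """Full cohort report: severity-group and pneumonia-group comparisons
    plus the ROC block for pneumonia prediction from the contusion ratio.

    ``table`` is a cohort DataFrame with the documented column dictionary.
    Strata with fewer than two patients are reported as absent rather than
    producing NaN statistics.
    """
    report: dict = {"n": int(len(table))}
    report["outcome_percent"] = {
        "pneumonia": proportion_percent(int(table["pneumonia"].sum()), len(table)),
        "ards": proportion_percent(int(table["ards"].sum()), len(table)),
        "mortality": proportion_percent(int(table["mortality"].sum()), len(table)),
    }

    sev = table["severity"].to_numpy()
    by_severity: dict = {
        "n_moderate": int((sev == "moderate").sum()),
        "n_severe": int((sev == "severe").sum()),
    }
    for col in ("age", "iss", "chest_ais", "gcs", "lactate"):
        mod = table.loc[sev == "moderate", col]
        seve = table.loc[sev == "severe", col]
        entry = {
            "moderate": _group_summary(mod),
            "severe": _group_summary(seve),
        }
        if entry["moderate"] and entry["severe"]:
            entry["welch"] = welch_t_data(mod, seve).to_dict()
        by_severity[col] = entry
    for flag in ("pneumonia", "ards", "mortality"):
        a = int(table.loc[sev == "moderate", flag].sum())
        b = int(table.loc[sev == "severe", flag].sum())
        t2x2 = [[a, by_severity["n_moderate"] - a], [b, by_severity["n_severe"] - b]]
        entry = {"moderate": a, "severe": b, "table": t2x2}
        try:
            entry["chi_square"] = chi_square_2x2(t2x2).to_dict()
        except DomainError as exc:
            entry["chi_square"] = {"error": str(exc)}
        entry["fisher_exact"] = fisher_exact_2x2(t2x2).to_dict()
        by_severity[flag] = entry
    report["by_severity"] = by_severity

    pneu = table["pneumonia"].to_numpy(dtype=bool)
    by_pneumonia: dict = {"n_pneumonia": int(pneu.sum()), "n_no_pneumonia": int((~pneu).sum())}
    for col in ("gcs", "iss", "lactate", "contusion_ratio"):
        yes = table.loc[pneu, col]
        no = table.loc[~pneu, col]
        entry = {"pneumonia": _group_summary(yes), "no_pneumonia": _group_summary(no)}
        if entry["pneumonia"] and entry["no_pneumonia"]:
            entry["welch"] = welch_t_data(yes, no).to_dict()
            entry["binormal_auc"] = round(
                binormal_auc(SummaryStat.from_data(yes), SummaryStat.from_data(no)), 4
            )
        by_pneumonia[col] = entry
    report["by_pneumonia"] = by_pneumonia

    if 0 < pneu.sum() < len(table):
        roc = roc_empirical(table["contusion_ratio"].to_numpy(dtype=float), pneu)
        block = roc.to_dict()
        # the threshold restated on the normal-lung-percentage scale
        block["normal_lung_percent_threshold"] = round(100.0 - roc.youden_threshold, 2)
        report["roc_contusion_ratio_vs_pneumonia"] = block

        adj = age_adjust_residuals(
            table["contusion_ratio"].to_numpy(dtype=float),
            table["age"].to_numpy(dtype=float),
            sev,
        )
        report["age_adjusted_contusion_ratio"] = {
            "slope_per_year": round(adj["slope"], 4),
            "groups": {
                k: {"mean": round(v.mean, 3), "sd": round(v.sd, 3), "n": v.n}
                for k, v in adj["groups"].items()
            },
            "welch": adj["test"].to_dict(),
        }
    return report
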