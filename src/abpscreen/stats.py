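"""Diagnostic-accuracy estimation and agreement testing.

2x2 validity measures with binomial CIs, likelihood ratios, AUROC in both
single-cutoff and continuous-score forms, McNemar's test, Bland-Altman
limits of agreement with the Pitman-Morgan trend test, and OLS regression
of paired device differences on covariates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Z95 = 1.96  # conventional limits-of-agreement multiplier


@dataclass(frozen=True)
class ConfusionTable:
    """Screen-vs-reference cross-classification.

    tp = sustained hypertension, fp = white-coat, fn = masked,
    tn = normotensive.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionTable") -> "ConfusionTable":
        return ConfusionTable(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
        )


@dataclass
class MetricEstimate:
    """A point estimate with its 95% CI; NaN bounds flag undefined values."""

    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.estimate)

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "n": self.n,
        }


@dataclass
class AgreementResult:
    """Bland-Altman summary of paired differences."""

    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    pitman_r: float
    pitman_p: float

    def as_dict(self) -> dict:
        return vars(self).copy()


def confusion_table(
    screen: Sequence[bool], reference: Sequence[bool]
) -> ConfusionTable:
    """Cross-classify paired screen and reference flags."""
    s = np.asarray(screen, dtype=bool)
    r = np.asarray(reference, dtype=bool)
    if s.shape != r.shape:
        raise ValueError(
            f"length mismatch: {s.shape[0]} screen vs {r.shape[0]} reference flags"
        )
    return ConfusionTable(
        tp=int(np.sum(s & r)),
        fp=int(np.sum(s & ~r)),
        fn=int(np.sum(~s & r)),
        tn=int(np.sum(~s & ~r)),
    )


def wilson_interval(k, n, alpha: float = 0.05):
    """Wilson score interval; accepts scalars or arrays, returns (lo, hi)."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2.0 * n)) / denom
    half = (z / denom) * np.sqrt(p * (1.0 - p) / n + z * z / (4.0 * n * n))
    return centre - half, centre + half


def exact_interval(k, n, alpha: float = 0.05):
    """Clopper-Pearson interval via beta quantiles; vectorised."""
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    lo = np.where(k > 0, sps.beta.ppf(alpha / 2.0, k, n - k + 1.0), 0.0)
    hi = np.where(k < n, sps.beta.ppf(1.0 - alpha / 2.0, k + 1.0, n - k), 1.0)
    return lo, hi


def wald_interval(k, n, alpha: float = 0.05):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    p = k / n
    half = z * np.sqrt(p * (1.0 - p) / n)
    return np.clip(p - half, 0.0, 1.0), np.clip(p + half, 0.0, 1.0)


_CI_FUNCS = {"wilson": wilson_interval, "exact": exact_interval, "wald": wald_interval}


def proportion_ci(
    successes: int, n: int, method: str = "wilson", alpha: float = 0.05
) -> MetricEstimate:
    """Binomial proportion with a 95% (or ``alpha``-level) CI."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if method not in _CI_FUNCS:
        raise ValueError(f"unknown CI method {method!r}")
    lo, hi = _CI_FUNCS[method](successes, n, alpha)
    return MetricEstimate(successes / n, float(lo), float(hi), method, n)


def _undefined(method: str) -> MetricEstimate:
    return MetricEstimate(math.nan, math.nan, math.nan, method, 0)


def validity_metrics(
    table: ConfusionTable, ci_method: str = "wilson"
) -> dict[str, MetricEstimate]:
    """Sensitivity, specificity, PPV and NPV with CIs.

    Metrics with a zero denominator come back flagged undefined (NaN), never
    silently zero.
    """
    pairs = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.tn + table.fn),
    }
    return {
        name: proportion_ci(k, n, ci_method) if n > 0 else _undefined(ci_method)
        for name, (k, n) in pairs.items()
    }


def likelihood_ratios(
    table: ConfusionTable, alpha: float = 0.05
) -> dict[str, MetricEstimate]:
    """LR+ = sens/(1-spec) and LR- = (1-sens)/spec with log-method CIs.

    Division by zero yields an infinite ratio flagged by infinite bounds
    rather than silent truncation.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    n_pos, n_neg = tp + fn, fp + tn
    if n_pos == 0 or n_neg == 0:
        return {"lr_pos": _undefined("log"), "lr_neg": _undefined("log")}
    sens, spec = tp / n_pos, tn / n_neg
    z = sps.norm.ppf(1.0 - alpha / 2.0)

    def _lr(num: float, den: float, cells: tuple[int, int]) -> MetricEstimate:
        if den == 0.0:
            return MetricEstimate(math.inf, math.nan, math.inf, "log", table.total)
        lr = num / den
        a, b = cells
        if lr == 0.0 or a == 0 or b == 0:
            return MetricEstimate(lr, math.nan, math.nan, "log", table.total)
        se = math.sqrt(1.0 / a - 1.0 / n_pos + 1.0 / b - 1.0 / n_neg)
        return MetricEstimate(
            lr, lr * math.exp(-z * se), lr * math.exp(z * se), "log", table.total
        )

    return {
        "lr_pos": _lr(sens, 1.0 - spec, (tp, fp)),
        "lr_neg": _lr(1.0 - sens, spec, (fn, tn)),
    }


def auc_point(table: ConfusionTable) -> float:
    """Trapezoidal AUROC of a single-cutoff binary classifier: (sens+spec)/2."""
    if table.tp + table.fn == 0 or table.fp + table.tn == 0:
        raise ValueError("both reference classes required")
    sens = table.tp / (table.tp + table.fn)
    spec = table.tn / (table.tn + table.fp)
    return (sens + spec) / 2.0


def auc_empirical(
    scores: Sequence[float], labels: Sequence[bool], alpha: float = 0.05
) -> MetricEstimate:
    """Mann-Whitney AUC with ties counted half; Hanley-McNeil CI."""
    x = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if x.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n1 = int(y.sum())
    n0 = int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sps.rankdata(x)
    auc = (ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    var = (
        auc * (1.0 - auc) + (n1 - 1) * (q1 - auc * auc) + (n0 - 1) * (q2 - auc * auc)
    ) / (n1 * n0)
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * math.sqrt(max(var, 0.0))
    return MetricEstimate(
        float(auc),
        float(max(0.0, auc - half)),
        float(min(1.0, auc + half)),
        "hanley-mcneil",
        n0 + n1,
    )


def mcnemar_test(b: int, c: int, mode: str = "auto") -> dict:
    """McNemar's test on the discordant counts of a paired 2x2 table.

    Exact mode is the two-sided binomial(b; b+c, 1/2) test; asymptotic mode
    the chi-square (b-c)^2/(b+c) on 1 df. ``auto`` picks exact when
    b + c < 25. The degenerate b = c = 0 case returns p = 1 flagged.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return {"mode": "degenerate", "statistic": math.nan, "p_value": 1.0, "b": b, "c": c}
    if mode == "auto":
        mode = "exact" if n < 25 else "asymptotic"
    if mode == "exact":
        # symmetric null: doubling the smaller tail equals summing all
        # outcomes at least as extreme
        p = min(1.0, 2.0 * float(sps.binom.cdf(min(b, c), n, 0.5)))
        return {"mode": "exact", "statistic": float(min(b, c)), "p_value": p, "b": b, "c": c}
    if mode == "asymptotic":
        stat = (b - c) ** 2 / n
        return {
            "mode": "asymptotic",
            "statistic": float(stat),
            "p_value": float(sps.chi2.sf(stat, 1)),
            "b": b,
            "c": c,
        }
    raise ValueError(f"unknown mode {mode!r}")


def bland_altman(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Agreement between paired measurements ``x`` (test) and ``y`` (reference).

    Differences are x - y; limits of agreement are mean +/- 1.96 sd (sample
    sd, n-1 denominator). The Pitman test correlates differences with pair
    means and assesses r with a t test on n-2 df; a nonzero r indicates
    unequal variances of the two methods (a proportional trend).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired inputs must have equal length")
    n = x.shape[0]
    if n < 3:
        raise ValueError("at least 3 pairs required")
    diff = x - y
    mean = (x + y) / 2.0
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    if sd == 0.0 or mean.std(ddof=1) == 0.0:
        return AgreementResult(n, md, sd, md, md, math.nan, math.nan)
    r = float(np.corrcoef(diff, mean)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
        p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return AgreementResult(n, md, sd, md - Z95 * sd, md + Z95 * sd, r, p)


def difference_regression(
    data: pd.DataFrame,
    diff_col: str,
    covariates: Sequence[str],
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """OLS of a paired device difference on subject covariates.

    Returns a coefficient table (coef, se, t, p, CI). Raises on a
    rank-deficient design, naming the offending columns.
    """
    import statsmodels.api as sm

    cols = list(covariates)
    df = data[[diff_col] + cols].dropna()
    if cols:
        X = pd.get_dummies(
            df[cols], columns=[c for c in categorical if c in cols], drop_first=True
        ).astype(float)
    else:
        X = pd.DataFrame(index=df.index)
    X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # identify columns not pivotal in a QR factorisation
        _, r = np.linalg.qr(X.values)
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[min(i, r.shape[0] - 1), i]) < 1e-10]
        raise ValueError(f"rank-deficient design matrix; offending columns: {bad}")
    fit = sm.OLS(df[diff_col].astype(float), X).fit()
    ci = fit.conf_int()
    return pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
            "ci_low": ci[0],
            "ci_high": ci[1],
        }
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> dict:
    """Pearson r with its p-value, as used for device cross-correlations."""
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return {"r": float(r), "p_value": float(p), "n": len(x)}
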