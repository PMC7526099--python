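"""Instrument-validation statistics.

Agreement and reliability (Cohen's kappa, Cronbach's alpha, Lin's
concordance correlation coefficient and its sample-size formula),
age/sex-adjusted logistic outcome models, ROC/AUC with the tie-corrected
rank formulation, and stratified prevalence/summary tables with trend
tests.

Terminology note: the exponentiated coefficient of a logistic model is an
odds ratio; clinical validation reports often label it "RR" per unit of
score increase, and the ``EffectEstimate.rr`` field keeps that label
while the value is, strictly, an odds ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from scipy.stats import norm

__all__ = [
    "KappaResult",
    "AlphaResult",
    "SampleSizeResult",
    "EffectEstimate",
    "RocResult",
    "SeparationError",
    "cohens_kappa",
    "cronbach_alpha",
    "lin_ccc",
    "ccc_sample_size",
    "fit_outcome_model",
    "roc_auc",
    "rank_auc",
    "chi_square_trend",
    "format_percent_count",
    "stratum_summary",
]


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


# ---------------------------------------------------------------------------
# Agreement and reliability


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_value: float
    n: int
    observed_agreement: float
    chance_agreement: float
    warning: Optional[str] = None


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> KappaResult:
    """Cohen's kappa for two raters: (p_o − p_e) / (1 − p_e).

    Chance agreement p_e is the product of the two raters' marginal
    distributions.  The p-value tests kappa = 0 with the large-sample
    normal approximation (Fleiss null variance).  If both raters are
    constant and identical, kappa is reported as 1 with a warning —
    agreement is perfect but the marginals are degenerate.
    """
    a = np.asarray(ratings_a)
    b = np.asarray(ratings_b)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("ratings must be equal-length non-empty 1-d sequences")
    n = a.size
    cats = np.union1d(a, b)
    ai = np.searchsorted(cats, a)
    bi = np.searchsorted(cats, b)
    k = cats.size
    table = np.zeros((k, k))
    np.add.at(table, (ai, bi), 1.0)
    table /= n
    po = float(np.trace(table))
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0 - 1e-15:
        return KappaResult(1.0, float("nan"), n, po, pe,
                           warning="degenerate marginals: both raters constant and identical")
    kappa = (po - pe) / (1 - pe)
    var0 = (pe + pe**2 - float(np.sum(row * col * (row + col)))) / (n * (1 - pe) ** 2)
    if var0 <= 0:
        p = float("nan")
    else:
        z = kappa / math.sqrt(var0)
        p = 2 * norm.sf(abs(z))
    return KappaResult(float(kappa), float(p), n, po, pe)


@dataclass(frozen=True)
class AlphaResult:
    alpha: float
    n_items: int
    n_subjects: int
    variance_convention: str = "sample (ddof=1)"


def cronbach_alpha(item_matrix) -> AlphaResult:
    """Cronbach's alpha: (k/(k−1)) · (1 − Σ item variances / total variance).

    Item and total variances use the same sample (ddof=1) denominator,
    declared in the result metadata.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("item_matrix must be (subjects >= 2) x (items >= 2)")
    n, k = x.shape
    total_var = float(np.var(x.sum(axis=1), ddof=1))
    if total_var <= 0:
        raise ValueError("total-score variance is zero: alpha undefined")
    item_var = float(np.var(x, axis=0, ddof=1).sum())
    alpha = (k / (k - 1)) * (1 - item_var / total_var)
    return AlphaResult(float(alpha), k, n)


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient.

    CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²), with biased (1/n) moment
    estimators.  Measures agreement with the identity line, penalising
    location and scale shifts that Pearson correlation ignores.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1 or xa.size < 2:
        raise ValueError("x and y must be equal-length 1-d with n >= 2")
    xm, ym = xa.mean(), ya.mean()
    sx2 = float(np.mean((xa - xm) ** 2))
    sy2 = float(np.mean((ya - ym) ** 2))
    if sx2 == 0 or sy2 == 0:
        raise ValueError("zero variance in a margin: CCC undefined")
    sxy = float(np.mean((xa - xm) * (ya - ym)))
    return 2 * sxy / (sx2 + sy2 + (xm - ym) ** 2)


@dataclass(frozen=True)
class SampleSizeResult:
    n: float  # math.inf when the effect vanishes
    method: str
    message: Optional[str] = None


def ccc_sample_size(
    ccc_null: float, ccc_alt: float, alpha: float = 0.05, power: float = 0.90
) -> SampleSizeResult:
    """Sample size for a one-sided z test that the CCC exceeds ccc_null.

    Uses the Fisher z transform of the CCC with asymptotic variance
    1/(n−3): n = ((z_{1−α} + z_{power}) / (atanh(ccc_alt) − atanh(ccc_null)))² + 3,
    rounded up.  The method (including the +3 finite-sample correction)
    is stated in the result so the assumption is auditable.
    """
    if not (0 < ccc_null < ccc_alt < 1):
        raise ValueError("require 0 < ccc_null < ccc_alt < 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    delta = math.atanh(ccc_alt) - math.atanh(ccc_null)
    method = "one-sided z on Fisher-transformed CCC, var 1/(n-3), n = ((z_a+z_b)/delta)^2 + 3"
    if delta < 1e-12:
        return SampleSizeResult(math.inf, method, "effect size vanishes: unbounded sample size")
    z_sum = norm.ppf(1 - alpha) + norm.ppf(power)
    n = (z_sum / delta) ** 2 + 3
    return SampleSizeResult(float(math.ceil(max(n, 4))), method)


# ---------------------------------------------------------------------------
# Outcome models


@dataclass(frozen=True)
class EffectEstimate:
    """An exponentiated logistic coefficient with Wald 95% CI and p-value."""

    label: str
    rr: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    converged: bool = True

    def __post_init__(self):
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def fit_outcome_model(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    adjust: Sequence[str] = ("age", "sex"),
    label: Optional[str] = None,
) -> EffectEstimate:
    """Logistic model `outcome ~ predictor (+ age + sex)` by maximum likelihood.

    Returns the exponentiated predictor coefficient (per unit of score, or
    per item presence) with Wald 95% CI and two-sided Wald p-value.  Sex
    enters as a female indicator.  Raises :class:`SeparationError` on
    perfect separation and RuntimeError on non-convergence.
    """
    df = data.dropna(subset=[outcome, predictor]).copy()
    y = df[outcome].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError(f"outcome '{outcome}' needs both classes present")
    X = pd.DataFrame({predictor: df[predictor].astype(float)})
    for cov in adjust:
        if cov == "sex":
            X["female"] = (df["sex"] == "female").astype(float)
        else:
            X[cov] = df[cov].astype(float)
    X = sm.add_constant(X, prepend=True)
    from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning) as exc:
        raise SeparationError(f"perfect separation fitting '{predictor}': {exc}") from exc
    converged = bool(res.mle_retvals.get("converged", False))
    if not converged:
        raise RuntimeError(
            f"logistic fit for '{predictor}' did not converge after 200 iterations: "
            f"{res.mle_retvals}"
        )
    beta = float(res.params[predictor])
    lo, hi = (float(v) for v in res.conf_int().loc[predictor])
    return EffectEstimate(
        label=label or predictor,
        rr=math.exp(beta),
        ci_low=math.exp(lo),
        ci_high=math.exp(hi),
        p_value=float(res.pvalues[predictor]),
        n=int(y.size),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    points: Tuple[Tuple[float, float], ...]  # (FPR, TPR), (0,0) → (1,1)
    auc: float

    @property
    def fpr(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def tpr(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])


def roc_auc(scores: Sequence[float], outcome: Sequence[int]) -> RocResult:
    """ROC curve over all distinct score thresholds, AUC by trapezoid.

    With integer screener scores ties are pervasive; the trapezoidal area
    over threshold points is identically the tie-corrected rank (Mann–
    Whitney) AUC: (concordant + ½·tied pairs) / (n₁·n₀).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcome must be equal-length 1-d")
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.nonzero(np.r_[np.diff(s_sorted) != 0, True])[0]
    tp = np.cumsum(y_sorted)[distinct] / n1
    fp = np.cumsum(1 - y_sorted)[distinct] / n0
    fpr = np.r_[0.0, fp]
    tpr = np.r_[0.0, tp]
    auc = float(np.trapezoid(tpr, fpr))
    points = tuple((float(a), float(b)) for a, b in zip(fpr, tpr))
    return RocResult(points, auc)


def rank_auc(scores: Sequence[float], outcome: Sequence[int]) -> float:
    """Tie-corrected Mann–Whitney AUC via midranks (the rank-sum route)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcome, dtype=int)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = sps.rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# Stratified summary tables


def format_percent_count(count: int, total: int) -> str:
    """Render "percent (count)" to one decimal, rounding half away from zero."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    return f"{pct.quantize(Decimal('0.1'), rounding=ROUND_HALF_UP)} ({count})"


def chi_square_trend(counts: Sequence[int], totals: Sequence[int],
                     scores: Optional[Sequence[float]] = None) -> Tuple[float, float]:
    """Cochran–Armitage chi-square test for trend across ordered strata.

    ``counts[i]`` positives of ``totals[i]`` subjects in stratum *i*;
    ``scores`` default to 0, 1, 2, …  Returns (chi2 on 1 df, p-value).
    """
    r = np.asarray(counts, dtype=float)
    n = np.asarray(totals, dtype=float)
    if scores is None:
        scores = np.arange(r.size, dtype=float)
    s = np.asarray(scores, dtype=float)
    N = n.sum()
    R = r.sum()
    if R == 0 or R == N:
        return 0.0, 1.0
    num = N * (N * (s @ r) - R * (s @ n)) ** 2
    den = R * (N - R) * (N * (s**2 @ n) - (s @ n) ** 2)
    if den == 0:
        return 0.0, 1.0
    chi2 = num / den
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def stratum_summary(
    df: pd.DataFrame,
    stratum_col: str = "agile_stratum",
    strata_order: Sequence[str] = ("light", "moderate", "severe"),
    continuous: Sequence[str] = (),
    binary: Sequence[str] = (),
    bonferroni: bool = False,
) -> Dict:
    """Per-stratum summary tables with trend tests.

    Continuous fields: per-stratum "mean ± SD" with a one-way ANOVA p
    across strata (optionally Bonferroni-corrected pairwise t-tests).
    Binary fields: per-stratum "percent (count)" with the chi-square test
    for trend across the ordered strata.  Empty strata are omitted with a
    warning entry.
    """
    present = [s for s in strata_order if (df[stratum_col] == s).any()]
    warnings_list = [f"stratum '{s}' is empty and was omitted"
                     for s in strata_order if s not in present]
    groups = {s: df[df[stratum_col] == s] for s in present}
    out: Dict = {
        "strata": present,
        "n": {s: int(len(groups[s])) for s in present},
        "continuous": {},
        "binary": {},
        "warnings": warnings_list,
    }
    out["n"]["all"] = int(len(df))

    for col in continuous:
        cells = {"all": _mean_sd(df[col])}
        samples = []
        for s in present:
            vals = groups[s][col].dropna().to_numpy(dtype=float)
            cells[s] = _mean_sd(groups[s][col])
            samples.append(vals)
        p = float("nan")
        if len(samples) >= 2 and all(len(v) >= 2 for v in samples):
            p = float(sps.f_oneway(*samples).pvalue)
        row = {"cells": cells, "anova_p": p}
        if bonferroni and len(samples) >= 2:
            m = len(samples) * (len(samples) - 1) // 2
            pw = {}
            for i in range(len(present)):
                for j in range(i + 1, len(present)):
                    t = sps.ttest_ind(samples[i], samples[j], equal_var=False)
                    pw[f"{present[i]}_vs_{present[j]}"] = min(1.0, float(t.pvalue) * m)
            row["bonferroni_pairwise"] = pw
        out["continuous"][col] = row

    for col in binary:
        cells = {}
        counts, totals = [], []
        vals_all = df[col].dropna()
        cells["all"] = format_percent_count(int(vals_all.sum()), int(len(vals_all)))
        for s in present:
            vals = groups[s][col].dropna()
            c, t = int(vals.sum()), int(len(vals))
            cells[s] = format_percent_count(c, t)
            counts.append(c)
            totals.append(t)
        chi2, p = chi_square_trend(counts, totals)
        out["binary"][col] = {"cells": cells, "trend_chi2": chi2, "trend_p": p}

    return out


def _mean_sd(series: pd.Series) -> str:
    vals = series.dropna().to_numpy(dtype=float)
    if vals.size == 0:
        return "–"
    sd = vals.std(ddof=1) if vals.size > 1 else 0.0
    return f"{vals.mean():.1f} ± {sd:.1f}"
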