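"""Inter-rater agreement statistics for PD-L1 scores.

Implements the evaluation battery used to compare raters (human or machine):
the intraclass correlation coefficient from a two-way ANOVA with an F-based
confidence interval and p-value, weighted kappa on ordinal cutoff categories
with equal (linearly spaced) disagreement weights and its mean-pairwise
extension to more than two raters, percent cutoff concordance, and the
Shapiro–Wilk / Wilcoxon signed-rank pair for systematic differences.

Interpretation bands follow the clinical reliability conventions: ICC < 0.5
poor, 0.5–0.75 moderate, 0.75–0.9 good, > 0.9 excellent (boundary values take
the higher band); kappa < 0 poor, 0–0.20 mild, 0.21–0.60 moderate, 0.61–0.80
substantial, >= 0.80 near perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AgreementResult",
    "ratings_matrix",
    "icc",
    "weighted_kappa",
    "mean_pairwise_kappa",
    "cutoff_concordance",
    "paired_difference",
    "icc_interpretation",
    "kappa_interpretation",
]


@dataclass
class AgreementResult:
    estimate: float
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    interpretation: str
    method: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"estimate": self.estimate, "ci95": [self.ci_low, self.ci_high],
                "p_value": self.p_value, "interpretation": self.interpretation,
                "method": self.method}


def icc_interpretation(value: float) -> str:
    """Verbal reliability band of an ICC (boundaries go to the higher band)."""
    if value < 0.5:
        return "poor"
    if value < 0.75:
        return "moderate"
    if value < 0.9:
        return "good"
    return "excellent"


def kappa_interpretation(value: float) -> str:
    if value < 0.0:
        return "poor"
    if value <= 0.20:
        return "mild"
    if value <= 0.60:
        return "moderate"
    if value <= 0.80:
        return "substantial"
    return "near perfect"


def ratings_matrix(data, case_ids=None, rater_ids=None) -> pd.DataFrame:
    """Validate and wrap an n_cases × k_raters score table.

    Cases with any missing rating are dropped (count retained in
    ``df.attrs['n_dropped']``).
    """
    df = pd.DataFrame(data)
    if case_ids is not None:
        df.index = list(case_ids)
    if rater_ids is not None:
        df.columns = list(rater_ids)
    n_before = len(df)
    df = df.dropna()
    df.attrs["n_dropped"] = n_before - len(df)
    if df.shape[0] < 2 or df.shape[1] < 2:
        raise ValueError("need at least 2 cases and 2 raters")
    return df


def _anova_mean_squares(x: np.ndarray) -> tuple[float, float, float, float]:
    """(MSR, MSC, MSE, MSW) of the two-way rater-by-case layout."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    msw = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    return msr, msc, mse, msw


def icc(ratings, model: str = "two_way_random", unit: str = "single",
        definition: str = "agreement", alpha: float = 0.05) -> AgreementResult:
    """Intraclass correlation coefficient of a cases × raters matrix.

    The default — two-way random effects, single rater, absolute agreement,
    i.e. ICC(2,1) — is

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    with MSR/MSC/MSE the case, rater and residual mean squares of the two-way
    ANOVA.  For the default variant the 95% CI and p-value come from the
    standard F approximations; the other five McGraw–Wong variants are
    selectable as point estimates.
    """
    df = ratings if isinstance(ratings, pd.DataFrame) else pd.DataFrame(ratings)
    x = df.to_numpy(dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 cases and 2 raters")
    msr, msc, mse, msw = _anova_mean_squares(x)
    if msr <= 1e-300 and msc <= 1e-300 and mse <= 1e-300:
        raise ValueError("ICC undefined: zero variance across cases and raters")

    variant = (model, unit, definition)
    if model == "one_way":
        est = (msr - msw) / (msr + (k - 1) * msw)
        if unit == "average":
            est = (msr - msw) / msr
    elif model == "two_way_random" and definition == "agreement":
        denom_s = msr + (k - 1) * mse + (k / n) * (msc - mse)
        est = (msr - mse) / denom_s if denom_s > 0 else 1.0
        if unit == "average":
            d = msr + (msc - mse) / n
            est = (msr - mse) / d if d > 0 else 1.0
    else:  # two-way mixed / consistency
        est = (msr - mse) / (msr + (k - 1) * mse) if (msr + (k - 1) * mse) > 0 else 1.0
        if unit == "average":
            est = (msr - mse) / msr if msr > 0 else 1.0

    ci_low = ci_high = p = None
    if model == "two_way_random" and unit == "single" and definition == "agreement":
        if mse <= 1e-300:
            p = 0.0
            ci_low = ci_high = est
        else:
            f_stat = msr / mse
            p = float(sps.f.sf(f_stat, n - 1, (n - 1) * (k - 1)))
            # Satterthwaite df for the absolute-agreement CI (as in irr/psych)
            fj = msc / mse
            vn = (k - 1) * (n - 1) * (k * est * fj + n * (1 + (k - 1) * est)
                                      - k * est) ** 2
            vd = ((n - 1) * k ** 2 * est ** 2 * fj ** 2
                  + (n * (1 + (k - 1) * est) - k * est) ** 2)
            v = vn / vd if vd > 0 else 1.0
            f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
            ci_low = float(n * (msr - f1 * mse) /
                           (f1 * (k * msc + (k * n - k - n) * mse) + n * msr))
            ci_high = float(n * (f2 * msr - mse) /
                            (k * msc + (k * n - k - n) * mse + n * f2 * msr))

    return AgreementResult(estimate=float(est), ci_low=ci_low, ci_high=ci_high,
                           p_value=p, interpretation=icc_interpretation(float(est)),
                           method={"statistic": "ICC", "model": model, "unit": unit,
                                   "definition": definition, "n": n, "k": k})


def weighted_kappa(r1, r2, categories, weighting: str = "equal") -> AgreementResult:
    """Weighted Cohen's kappa on an ordered category list.

    "equal" weighting uses linearly spaced disagreement weights
    ``v_ij = |i - j| / (K - 1)`` (the convention of the cited implementation);
    "quadratic" squares them.  K = 2 reduces to unweighted Cohen's kappa.
    """
    cats = list(categories)
    index = {c: i for i, c in enumerate(cats)}
    a = [index.get(v, -1) for v in r1]
    b = [index.get(v, -1) for v in r2]
    if -1 in a or -1 in b:
        raise ValueError("rater uses a category not in the ordered list")
    if len(a) != len(b):
        raise ValueError("rater vectors differ in length")
    K = len(cats)
    n = len(a)
    p = np.zeros((K, K))
    for i, j in zip(a, b):
        p[i, j] += 1.0 / n
    marg_a = p.sum(axis=1)
    marg_b = p.sum(axis=0)
    e = np.outer(marg_a, marg_b)
    ii, jj = np.meshgrid(np.arange(K), np.arange(K), indexing="ij")
    v = np.abs(ii - jj) / max(K - 1, 1)
    if weighting == "quadratic":
        v = v ** 2
    elif weighting != "equal":
        raise ValueError("weighting must be 'equal' or 'quadratic'")
    obs = (v * p).sum()
    exp = (v * e).sum()
    if exp == 0:
        kap = 1.0 if obs == 0 else 0.0
    else:
        kap = 1.0 - obs / exp
    return AgreementResult(estimate=float(kap), ci_low=None, ci_high=None,
                           p_value=None, interpretation=kappa_interpretation(float(kap)),
                           method={"statistic": "weighted_kappa",
                                   "weighting": weighting, "n": n, "K": K})


def mean_pairwise_kappa(ratings: pd.DataFrame, categories,
                        weighting: str = "equal") -> AgreementResult:
    """Arithmetic mean of weighted kappa over all rater pairs (k >= 2)."""
    df = pd.DataFrame(ratings)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 raters")
    pair_values = {}
    for c1, c2 in combinations(df.columns, 2):
        pair_values[f"{c1}|{c2}"] = weighted_kappa(df[c1], df[c2], categories,
                                                   weighting).estimate
    est = float(np.mean(list(pair_values.values())))
    return AgreementResult(estimate=est, ci_low=None, ci_high=None, p_value=None,
                           interpretation=kappa_interpretation(est),
                           method={"statistic": "mean_pairwise_weighted_kappa",
                                   "weighting": weighting, "pairs": pair_values})


def cutoff_concordance(a, b, cutoffs) -> tuple[float, np.ndarray, np.ndarray]:
    """Percent of cases whose cutoff categories agree between two score lists.

    Scores map to ordinal categories with the ">= cutoff" convention; returns
    (percent concordant, categories of a, categories of b).
    """
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs or len(set(cutoffs)) != len(cutoffs):
        raise ValueError("cutoffs must be strictly increasing")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors differ in length")
    cat_a = np.searchsorted(cutoffs, a, side="right")
    cat_b = np.searchsorted(cutoffs, b, side="right")
    pct = 100.0 * float((cat_a == cat_b).mean())
    return pct, cat_a, cat_b


def paired_difference(a, b) -> dict:
    """Shapiro–Wilk on the paired differences, then two-sided Wilcoxon.

    Zero differences are dropped; mid-ranks for ties; the exact signed-rank
    null is used for n <= 25 without ties, otherwise the normal approximation
    with tie correction.  All-zero differences report "no difference" with
    p = 1.0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    d = a - b
    if len(d) >= 3 and np.ptp(d) > 0:
        sw = sps.shapiro(d)
        shapiro_w, shapiro_p = float(sw.statistic), float(sw.pvalue)
    else:
        shapiro_w = shapiro_p = float("nan")
    nz = d[d != 0]
    if len(nz) == 0:
        return {"shapiro_w": shapiro_w, "shapiro_p": shapiro_p,
                "wilcoxon_statistic": 0.0, "wilcoxon_p": 1.0,
                "note": "no difference"}
    if len(nz) < 4:
        raise ValueError("need at least 4 nonzero differences for the Wilcoxon test")
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    return {"shapiro_w": shapiro_w, "shapiro_p": shapiro_p,
            "wilcoxon_statistic": float(res.statistic),
            "wilcoxon_p": float(res.pvalue), "note": method}
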