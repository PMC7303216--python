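"""Group-level statistics for microstate temporal parameters.

Covers the statistical layer of a case-control/relatives design:
demographics tests (chi-square, summary t-tests), standardized effect
sizes and their conversions, Bonferroni-Holm step-down correction, Pearson
correlations with clinical scores, BIC-approximated Bayes factors, and a
split-plot (mixed-design) ANOVA with between-subject covariates.

The ANOVA is a two-stratum general linear model with Type III sums of
squares under sum-to-zero factor coding: between-subject effects (group,
gender, their interaction, covariates) are tested against the
subject-within-cells error computed on subject means, while the
within-subject factor (microstate class) and its interactions with the
between terms and covariates are tested against the subject x class
residual.  For a design with g between parameters and n subjects over w
within levels this yields the familiar df patterns (1, n - g) for between
effects and (w - 1, (n)(w - 1) - p) for within effects.  No sphericity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq


@dataclass
class GroupSummary:
    """Summary statistics of one group: n, mean, sample SD."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass
class EffectSize:
    """A standardized mean difference with its 95% CI."""

    d: float
    se: float
    ci_low: float
    ci_high: float


def chi_square_2x2(table, correction: bool = False):
    """Pearson chi-square for a 2x2 contingency table.

    Continuity (Yates) correction is off by default: the uncorrected
    statistic is the one conventionally reported for group demographics.
    Returns ``(X2, df, p)`` with df = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    total = t.sum()
    if total <= 0:
        raise ValueError("table total must be positive")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError("degenerate margins: an expected count is 0")
    diff = np.abs(t - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    x2 = float((diff**2 / expected).sum())
    return x2, 1, float(stats.chi2.sf(x2, 1))


def independent_t_from_summary(a: GroupSummary, b: GroupSummary):
    """Pooled-variance two-sample t-test from group summaries.

    Returns ``(t, df, p)`` with df = n_a + n_b - 2 and a two-sided p.
    """
    if a.sd == 0 and b.sd == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return float(res.statistic), a.n + b.n - 2, float(res.pvalue)


def cohens_d_independent(a: GroupSummary, b: GroupSummary) -> EffectSize:
    """Cohen's d for two independent groups: mean difference over pooled SD.

    Positive d means the first group is larger.  The 95% CI uses the
    normal approximation with SE = sqrt((n1+n2)/(n1 n2) + d^2/(2(n1+n2))).
    """
    pooled = np.sqrt(
        ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / (a.n + b.n - 2)
    )
    if pooled == 0:
        raise ValueError("zero pooled SD")
    d = (a.mean - b.mean) / pooled
    se = np.sqrt((a.n + b.n) / (a.n * b.n) + d**2 / (2 * (a.n + b.n)))
    z = stats.norm.ppf(0.975)
    return EffectSize(d=float(d), se=float(se), ci_low=float(d - z * se), ci_high=float(d + z * se))


def cohens_d_one_sample(deltas) -> EffectSize:
    """Cohen's d of difference scores against 0: mean(delta) / SD(delta)."""
    x = np.asarray(deltas, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 difference scores")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero SD of difference scores")
    d = x.mean() / sd
    se = np.sqrt(1.0 / n + d**2 / (2.0 * n))
    z = stats.norm.ppf(0.975)
    return EffectSize(d=float(d), se=float(se), ci_low=float(d - z * se), ci_high=float(d + z * se))


def cohens_d(mode: str, *args) -> EffectSize:
    """Dispatch: ``cohens_d("independent", a, b)`` or ``cohens_d("one_sample", deltas)``."""
    if mode == "independent":
        return cohens_d_independent(*args)
    if mode == "one_sample":
        return cohens_d_one_sample(*args)
    raise ValueError("mode must be 'independent' or 'one_sample'")


def holm_adjust(p, m: int | None = None) -> np.ndarray:
    """Bonferroni-Holm step-down adjusted p-values, in input order.

    The i-th smallest p is multiplied by (m - i + 1); adjusted values are
    made monotone non-decreasing along the sorted order by a running
    maximum and capped at 1.  ``m`` defaults to the number of p-values and
    may be larger (when the family is bigger than the supplied list).
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    if m is None:
        m = n
    if m < n:
        raise ValueError("m must be >= the number of p-values")
    order = np.argsort(p, kind="stable")
    factors = m - np.arange(n)
    adj_sorted = np.maximum.accumulate(p[order] * factors)
    adj_sorted = np.minimum(adj_sorted, 1.0)
    out = np.empty(n)
    out[order] = adj_sorted
    return out


def eta2_to_d(eta2: float) -> float:
    """Convert an eta-squared effect size to Cohen's d: d = 2 sqrt(eta2/(1-eta2))."""
    if not (0 <= eta2 < 1):
        raise ValueError("eta2 must lie in [0, 1)")
    return 2.0 * float(np.sqrt(eta2 / (1.0 - eta2)))


def bayes_factor_bic(bic_null: float, bic_alt: float) -> float:
    """BF_01 (evidence for the null over the alternative) from two BICs.

    Uses the standard unit-information-prior approximation
    BF_01 = exp((BIC_alt - BIC_null) / 2).
    """
    if not (np.isfinite(bic_null) and np.isfinite(bic_alt)):
        raise ValueError("BICs must be finite")
    return float(np.exp((bic_alt - bic_null) / 2.0))


def pearson_correlation(x, y, holm_m: int | None = None):
    """Pearson r with a two-sided p from the t transform (df = n - 2).

    Returns ``(r, df, p)``; when ``holm_m`` is given, returns
    ``(r, df, p, p_holm)`` treating p as the smallest of a family of
    ``holm_m`` comparisons (i.e. p * holm_m, capped at 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    df = x.size - 2
    if holm_m is None:
        return r, df, p
    return r, df, p, min(1.0, p * holm_m)


# --------------------------------------------------------------------------
# Split-plot Type III ANOVA engine


def _sum_coding(values: pd.Series):
    """Sum-to-zero contrast columns for a factor (n x (L-1))."""
    levels = sorted(pd.unique(values))
    L = len(levels)
    if L < 2:
        raise ValueError(f"factor needs >= 2 levels, got {levels}")
    contrast = np.zeros((L, L - 1))
    contrast[: L - 1, :] = np.eye(L - 1)
    contrast[L - 1, :] = -1.0
    idx = pd.Series(range(L), index=levels)
    return contrast[idx[values].to_numpy()]


def _term_block(frame: pd.DataFrame, components, factors) -> np.ndarray:
    """Design block for an interaction term: column-wise Kronecker product."""
    block = np.ones((len(frame), 1))
    for comp in components:
        cols = _sum_coding(frame[comp]) if comp in factors else frame[[comp]].to_numpy(float)
        block = (block[:, :, None] * cols[:, None, :]).reshape(len(frame), -1)
    return block


def _rss(x: np.ndarray, y: np.ndarray):
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return float(r @ r), rank


def _type3_table(frame, y, terms, factors, intercept):
    """Type III SS per term: RSS(model minus term) - RSS(full model)."""
    blocks = {name: _term_block(frame, comps, factors) for name, comps in terms}
    base = [np.ones((len(frame), 1))] if intercept else []
    full = np.hstack(base + [blocks[name] for name, _ in terms])
    rss_full, rank_full = _rss(full, y)
    p_full = full.shape[1]
    if rank_full < p_full:
        raise ValueError("rank-deficient design; aliased terms present")
    rows = []
    for name, _ in terms:
        parts = base + [blocks[n] for n, _ in terms if n != name]
        if parts:
            rss_red, _ = _rss(np.hstack(parts), y)
        else:
            rss_red = float(y @ y)
        rows.append((name, rss_red - rss_full, blocks[name].shape[1]))
    return rows, rss_full, p_full


def eta2_ci(f: float, df1: int, df2: int, conf: float = 0.90):
    """CI for eta-squared by inverting the noncentral F at the observed F."""
    alpha = (1.0 - conf) / 2.0

    def to_eta(ncp):
        return ncp / (ncp + df1 + df2 + 1)

    def solve(prob):
        # find ncp with ncf.cdf(f; df1, df2, ncp) = prob (cdf decreases in ncp)
        if stats.ncf.cdf(f, df1, df2, 0.0) < prob:
            return 0.0
        hi = 10.0
        while stats.ncf.cdf(f, df1, df2, hi) > prob:
            hi *= 2.0
            if hi > 1e7:
                return np.nan
        return brentq(lambda l: stats.ncf.cdf(f, df1, df2, l) - prob, 0.0, hi, xtol=1e-8)

    return to_eta(solve(1.0 - alpha)), to_eta(solve(alpha))


def mixed_design_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: str,
    between=(),
    covariates=(),
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Split-plot ANOVA with Type III sums of squares (sum-to-zero coding).

    ``data`` is a long table with one row per subject x within-level.
    Between factors, their interactions and covariates are tested in the
    between-subject stratum (on subject means, against the subject error);
    the within factor and its interactions with every between term and
    covariate are tested in the within stratum (on subject-centered data,
    against the subject x within residual).  Reports per effect: SS, F,
    dfs, p, classical eta2 (SS / total SS), partial eta2, and a 90% CI for
    the classical eta2 via noncentral-F inversion.

    Requires a complete design: every subject observed once at every
    within level, covariates constant within subject.
    """
    between = list(between)
    covariates = list(covariates)
    cols = [subject, within, dv] + between + covariates
    d = data[cols].copy()
    if d.isna().any().any():
        raise ValueError("missing values in the analysis columns")

    counts = d.groupby([subject, within]).size()
    if (counts != 1).any():
        raise ValueError("each subject needs exactly one observation per within level")
    w = d[within].nunique()
    per_subject = d.groupby(subject)[within].nunique()
    if (per_subject != w).any():
        raise ValueError("unbalanced within-factor coverage")
    for c in between + covariates:
        if (d.groupby(subject)[c].nunique() != 1).any():
            raise ValueError(f"'{c}' must be constant within subject")

    # ---------- between stratum: subject means ----------
    subj = d.groupby(subject).agg({dv: "mean", **{c: "first" for c in between + covariates}})
    n_subj = len(subj)
    y_b = subj[dv].to_numpy(float)
    b_terms = []
    for size in range(1, len(between) + 1):
        for comb in combinations(between, size):
            b_terms.append((":".join(comb), comb))
    b_terms += [(c, (c,)) for c in covariates]
    if b_terms:
        rows_b, rss_b, p_b = _type3_table(subj, y_b, b_terms, set(between), intercept=True)
    else:
        rows_b, p_b = [], 1
        rss_b = float(((y_b - y_b.mean()) ** 2).sum())
    df_err_b = n_subj - p_b
    ss_err_b = rss_b * w

    # ---------- within stratum: subject-centered data ----------
    d = d.sort_values([subject, within])
    centered = d[dv].to_numpy(float) - d.groupby(subject)[dv].transform("mean").to_numpy(float)
    w_terms = [(within, (within,))]
    for name, comps in b_terms:
        w_terms.append((f"{within}:{name}", (within,) + tuple(comps)))
    rows_w, ss_err_w, _ = _type3_table(
        d, centered, w_terms, set(between) | {within}, intercept=False
    )
    df_err_w = n_subj * (w - 1) - sum(nc for _, _, nc in rows_w)

    ss_total = float(((data[dv] - data[dv].mean()) ** 2).sum())

    records = []
    for stratum, rows, ss_err, df_err, scale in (
        ("between", rows_b, ss_err_b, df_err_b, w),
        ("within", rows_w, ss_err_w, df_err_w, 1.0),
    ):
        for name, ss, df1 in rows:
            ss = max(ss * scale, 0.0)
            ms_err = ss_err / df_err
            f = (ss / df1) / ms_err if ms_err > 0 else (0.0 if ss == 0 else np.inf)
            p = float(stats.f.sf(f, df1, df_err))
            eta2 = ss / ss_total if ss_total > 0 else 0.0
            eta2_p = ss / (ss + ss_err) if ss + ss_err > 0 else 0.0
            lo, hi = eta2_ci(f, df1, df_err) if compute_ci else (np.nan, np.nan)
            records.append(
                dict(effect=name, stratum=stratum, ss=ss, df1=df1, df2=df_err,
                     F=f, p=p, eta2=eta2, eta2_partial=eta2_p,
                     eta2_ci_low=lo, eta2_ci_high=hi)
            )
        records.append(
            dict(effect=f"error ({stratum})", stratum=stratum, ss=ss_err, df1=df_err,
                 df2=np.nan, F=np.nan, p=np.nan, eta2=ss_err / ss_total,
                 eta2_partial=np.nan, eta2_ci_low=np.nan, eta2_ci_high=np.nan)
        )
    return pd.DataFrame.from_records(records).set_index("effect")
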