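"""Random-effects meta-analysis of standardized group differences.

Per-study Cohen's d values are converted to Hedges' g with the
small-sample correction J = 1 - 3/(4 df - 1); the between-study variance
tau^2 of the random-effects model g_i ~ N(mu, v_i + tau^2) is estimated by
restricted maximum likelihood (REML); pooling uses inverse-variance
weights w_i = 1/(v_i + tau^2) with normal-quantile confidence intervals
and z-tests (no Knapp-Hartung adjustment).  When several parameter x class
cells are pooled jointly, the pooled p-values are Holm-corrected across
cells.

Sign convention: positive g means the first (patient) group is larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .group_stats import holm_adjust


@dataclass
class StudyEffect:
    """One study's standardized effect: sizes, d, g and var(g)."""

    study_id: str
    n1: int
    n2: int
    d: float
    g: float = None
    var_g: float = None

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if self.g is None or self.var_g is None:
            self.g, self.var_g = hedges_g(self.d, self.n1, self.n2)
        if self.var_g <= 0:
            raise ValueError("var_g must be positive")


@dataclass
class MetaResult:
    """Pooled random-effects estimate for one parameter x class cell."""

    g_star: float
    tau2: float
    se: float
    ci95: tuple
    z: float
    p: float
    k_studies: int
    p_holm: float = np.nan


def hedges_g(d: float, n1: int, n2: int):
    """Hedges' g and its sampling variance from Cohen's d and group sizes.

    g = J d with J = 1 - 3/(4 df - 1), df = n1 + n2 - 2;
    var_g = J^2 ((n1+n2)/(n1 n2) + d^2 / (2 (n1+n2))).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * d
    var_g = j**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
    return float(g), float(var_g)


def _reml_score(tau2, g, v):
    w = 1.0 / (v + tau2)
    mu = np.sum(w * g) / np.sum(w)
    return 0.5 * (np.sum(w**2 * (g - mu) ** 2) - np.sum(w) + np.sum(w**2) / np.sum(w))


def reml_tau2(g, v, tol: float = 1e-10, max_iter: int = 200) -> float:
    """REML estimate of the between-study variance tau^2.

    Fisher scoring on the analytic REML score, with the expected
    information as step scale; if scoring leaves the feasible region or
    fails to converge, falls back to root-finding (Brent bisection) on the
    score function.  The estimate is floored at 0: if the score at 0 is
    non-positive the boundary is the maximizer.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 studies to estimate tau^2")
    if (v <= 0).any():
        raise ValueError("sampling variances must be positive")
    if _reml_score(0.0, g, v) <= 0:
        return 0.0
    tau2 = max(np.var(g, ddof=1) - v.mean(), 1e-8)  # DerSimonian-Laird-ish start
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw, sw2, sw3 = np.sum(w), np.sum(w**2), np.sum(w**3)
        score = _reml_score(tau2, g, v)
        info = 0.5 * sw2 - sw3 / sw + 0.5 * (sw2 / sw) ** 2
        if info <= 0:
            break
        step = score / info
        new = tau2 + step
        if new < 0:
            new = tau2 / 2.0
        if abs(new - tau2) < tol:
            return float(max(new, 0.0))
        tau2 = new
    # fallback: bracket the root of the score and bisect
    hi = max(tau2, 1.0)
    while _reml_score(hi, g, v) > 0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError("REML failed to converge (score positive at huge tau^2)")
    return float(brentq(lambda t: _reml_score(t, g, v), 0.0, hi, xtol=tol))


def pool_random_effects(g, v, tau2: float) -> MetaResult:
    """Inverse-variance pooling at a given tau^2.

    w_i = 1/(v_i + tau^2); g* = sum(w g)/sum(w); se = 1/sqrt(sum w);
    95% CI = g* +/- 1.96 se; z = g*/se with a two-sided normal p.
    """
    g = np.asarray(g, dtype=float)
    v = np.asarray(v, dtype=float)
    if g.size < 1:
        raise ValueError("need at least one study")
    w = 1.0 / (v + tau2)
    g_star = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z975 = stats.norm.ppf(0.975)
    z = g_star / se
    return MetaResult(
        g_star=g_star,
        tau2=float(tau2),
        se=se,
        ci95=(g_star - z975 * se, g_star + z975 * se),
        z=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
        k_studies=int(g.size),
    )


def run_meta(table: pd.DataFrame, holm_m: int = 12):
    """Per-cell random-effects meta-analysis with joint Holm correction.

    ``table`` has one row per study x parameter x class with columns
    ``study_id, parameter, class, n1, n2`` and either ``d`` or ``g`` +
    ``var_g``.  For each (parameter, class) cell, tau^2 is estimated by
    REML (0 for single-study cells) and the studies pooled; the pooled
    p-values are Holm-adjusted jointly with family size ``holm_m``.

    Returns ``(results, forest)``: ``results`` has one row per cell
    (g_star, tau2, ci, z, p, p_holm, k_studies); ``forest`` lists every
    study's g, CI and weight plus a pooled row per cell.  Cells missing
    from the table are simply absent from the output; a study missing a
    parameter contributes nothing to that cell.
    """
    table = table.copy()
    if "g" not in table.columns or "var_g" not in table.columns:
        gv = table.apply(
            lambda r: hedges_g(r["d"], int(r["n1"]), int(r["n2"])), axis=1
        )
        table["g"] = [x[0] for x in gv]
        table["var_g"] = [x[1] for x in gv]

    cells = []
    forest_rows = []
    for (param, cls), grp in table.groupby(["parameter", "class"], sort=True):
        g = grp["g"].to_numpy(float)
        v = grp["var_g"].to_numpy(float)
        tau2 = reml_tau2(g, v) if g.size >= 2 else 0.0
        res = pool_random_effects(g, v, tau2)
        cells.append((param, cls, res))
        w = 1.0 / (v + tau2)
        w = w / w.sum()
        z975 = stats.norm.ppf(0.975)
        for (_, row), wi in zip(grp.iterrows(), w):
            half = z975 * np.sqrt(row["var_g"])
            forest_rows.append(
                dict(parameter=param, **{"class": cls}, study_id=row["study_id"],
                     g=row["g"], ci_low=row["g"] - half, ci_high=row["g"] + half,
                     weight=wi)
            )
        forest_rows.append(
            dict(parameter=param, **{"class": cls}, study_id="pooled",
                 g=res.g_star, ci_low=res.ci95[0], ci_high=res.ci95[1], weight=1.0)
        )

    p_holm = holm_adjust([r.p for _, _, r in cells], m=max(holm_m, len(cells)))
    records = []
    for (param, cls, res), ph in zip(cells, p_holm):
        res.p_holm = float(ph)
        records.append(
            dict(parameter=param, **{"class": cls}, g_star=res.g_star, tau2=res.tau2,
                 se=res.se, ci_low=res.ci95[0], ci_high=res.ci95[1], z=res.z,
                 p=res.p, p_holm=res.p_holm, k_studies=res.k_studies)
        )
    results = pd.DataFrame.from_records(records)
    forest = pd.DataFrame.from_records(forest_rows)
    return results, forest
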