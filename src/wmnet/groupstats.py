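"""Group-level and clinical statistics for network metrics.

Covers the statistics that accompany a two-group connectome comparison:
ANCOVA-style group tests with age regressed out, Benjamini-Hochberg FDR over
metric families, Pearson partial correlation controlling for age, noncentral-t
power for the two-sample design, and demographics-table tests (pooled-variance
unpaired t from summary statistics, Pearson chi-square without continuity
correction for 2x2 counts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult", "PowerSpec", "ancova_group_effect", "fdr_bh",
    "partial_corr", "power_two_sample_t", "chi_square_2x2",
    "unpaired_t_from_summary", "metric_group_comparison",
]


@dataclass
class StatResult:
    statistic: float
    df: float
    p: float
    p_fdr: float | None = None
    kind: str = "t"


@dataclass
class PowerSpec:
    """Two-sample t-test power scenario (difference and SD in metric units)."""

    diff: float = 0.32
    sd: float = 0.37
    n1: int = 21
    n2: int = 25
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("SD must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be at least 2")


def ancova_group_effect(values, group, age) -> StatResult:
    """Group effect on a metric with age as a nuisance covariate.

    Ordinary least squares of value ~ intercept + group(0/1) + age; the group
    coefficient's t and two-sided p are reported (df = n - 3). With one
    covariate this is equivalent to the one-way ANCOVA F test (F = t^2). A
    constant age column is dropped (the model then reduces exactly to the
    unpaired t-test, df = n - 2).
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(group)
    if g.dtype.kind in "UOS":
        g = (g == g[0]).astype(float)  # first-seen label coded 1
    g = g.astype(float)
    a = np.asarray(age, dtype=float)
    if y.size != g.size or y.size != a.size:
        raise ValueError("values, group and age must have equal length")
    if np.ptp(y) == 0:
        raise ValueError("metric values are constant; group effect undefined")
    for lab in np.unique(g):
        if (g == lab).sum() < 3:
            raise ValueError("need at least 3 subjects per group")

    cols = [np.ones_like(y), g]
    if np.ptp(a) > 0:
        cols.append(a)
    X = np.column_stack(cols)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = y.size - X.shape[1]
    s2 = resid @ resid / df
    cov = s2 * np.linalg.inv(X.T @ X)
    t = beta[1] / np.sqrt(cov[1, 1])
    p = 2 * stats.t.sf(abs(t), df)
    return StatResult(float(t), float(df), float(p))


def fdr_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, >= raw p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_corr(x, y, covariate) -> tuple[float, float]:
    """Pearson partial correlation of x and y controlling one covariate.

    Both variables are residualized on (intercept, covariate); r is the
    Pearson correlation of the residuals and p comes from
    t = r sqrt((n-3) / (1-r^2)), df = n - 3, two-sided. A constant covariate
    reduces to the plain Pearson correlation (same df convention as SPSS-style
    partial correlation is kept: df = n - 3 only when the covariate varies).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if y.size != n or c.size != n:
        raise ValueError("x, y and covariate must have equal length")

    if np.ptp(c) > 0:
        X = np.column_stack([np.ones(n), c])
        k_cov = 1
    else:
        X = np.ones((n, 1))
        k_cov = 0
    rx = x - X @ np.linalg.lstsq(X, x, rcond=None)[0]
    ry = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero residual variance; correlation undefined")
    r = float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))
    df = n - 2 - k_cov
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip * r_clip))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p)


def power_two_sample_t(spec: PowerSpec | None = None, **kwargs) -> float:
    """Power of the pooled two-sample t-test via the noncentral t distribution.

    ncp = (diff/SD) * sqrt(n1 n2 / (n1 + n2)), df = n1 + n2 - 2; two-sided
    power is P(|T'| > t_crit) under the noncentral t.
    """
    if spec is None:
        spec = PowerSpec(**kwargs)
    d = spec.diff / spec.sd
    df = spec.n1 + spec.n2 - 2
    ncp = d * np.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    if spec.two_sided:
        tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
        power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    else:
        tcrit = stats.t.ppf(1 - spec.alpha, df)
        power = stats.nct.sf(tcrit, df, ncp)
    if not np.isfinite(power):
        # scipy's noncentral t loses accuracy for large ncp, where the miss
        # probability is below double precision anyway
        if ncp - tcrit > 5:
            return 1.0
        raise FloatingPointError("noncentral-t power evaluation failed")
    return float(power)


def chi_square_2x2(table) -> StatResult:
    """Pearson chi-square on a 2x2 table, no continuity correction, df = 1."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal in the 2x2 table")
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return StatResult(float(chi2), float(df), float(p), kind="chi2")


def unpaired_t_from_summary(mean1, sd1, n1, mean2, sd2, n2) -> StatResult:
    """Pooled-variance unpaired t-test from (mean, SD, n) summaries."""
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=True)
    return StatResult(float(t), float(n1 + n2 - 2), float(p))


def metric_group_comparison(auc: pd.DataFrame, manifest: pd.DataFrame
                            ) -> pd.DataFrame:
    """ANCOVA (age-adjusted) per metric AUC with FDR over the metric family.

    ``auc`` columns: subject_id, metric, auc; ``manifest`` columns include
    subject_id, group, age. The FDR family is all metrics present in ``auc``
    (e.g. the seven global metrics, or the 90 nodal efficiencies).
    """
    merged = auc.merge(manifest[["subject_id", "group", "age"]], on="subject_id")
    rows = []
    for metric, grp in merged.groupby("metric", sort=True):
        res = ancova_group_effect(
            grp["auc"].to_numpy(),
            (grp["group"] == "patient").astype(float).to_numpy(),
            grp["age"].to_numpy())
        rows.append((metric, res.statistic, res.df, res.p))
    out = pd.DataFrame(rows, columns=["metric", "t", "df", "p"])
    out["p_fdr"] = fdr_bh(out["p"].to_numpy())
    return out
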