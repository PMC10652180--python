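"""Cohort-level statistics: covariate-adjusted regressions and paired tests.

The analysis layer mirrors a standard bone-morphometry cohort workflow:

* group comparisons by ordinary least squares of the (possibly log10)
  outcome on a group indicator adjusted for age and sex;
* continuous-exposure models (e.g. lacunar density on HbA1c), adjusted
  the same way;
* paired two-sided Wilcoxon signed-rank tests for central-versus-peripheral
  contrasts within the same sample;
* median (IQR) / mean (SD) summary tables chosen by the normality rule.

Skewed outcomes are log10-transformed; the decision is made by a
Shapiro-Wilk test at p < 0.05 on the raw values (deterministic stand-in
for visual histogram assessment), and only when all values are positive.
Coding: sex female = 1, group 2 (the exposed/complicated group) = 1, so a
positive beta means larger in that group.  Significance is two-sided at
p <= 0.05 with no multiple-testing correction — a faithful-reproduction
choice for this analysis style, not a statistical endorsement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionResult",
    "choose_transform",
    "fit_group_model",
    "fit_exposure_model",
    "paired_region_test",
    "summarize_cohort",
    "SingularDesignError",
]

GROUP_LEVELS = ("T2D", "T2D+MVD")  # reference, exposed


class SingularDesignError(ValueError):
    """The design matrix is rank-deficient; names the collinear column."""


@dataclass
class RegressionResult:
    outcome: str
    transform: str          # "none" | "log10"
    term: str               # the reported coefficient's column
    beta: float
    se: float
    p: float
    r2: float
    n: int
    flagged: bool = False   # constant outcome or otherwise unusable fit

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def choose_transform(values: np.ndarray | pd.Series) -> str:
    """Return "log10" when Shapiro-Wilk rejects normality (p < 0.05) on the
    raw values and all values are positive, else "none".

    Fewer than 3 finite values: "none".  Non-normal but with non-positive
    values: "none" with a warning (log10 undefined).
    """
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < 3 or np.ptp(vals) == 0:
        return "none"
    # Shapiro's implementation caps meaningful n around 5000; subsampling
    # deterministically keeps the decision stable for large simulations.
    test_vals = vals if len(vals) <= 5000 else vals[:: len(vals) // 5000 + 1]
    p = stats.shapiro(test_vals).pvalue
    if p >= 0.05:
        return "none"
    if np.any(vals <= 0):
        warnings.warn(
            "non-normal outcome contains non-positive values; no transform applied",
            stacklevel=2,
        )
        return "none"
    return "log10"


def _encode(cohort: pd.DataFrame, covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex_female"] = (cohort["sex"].astype(str) == "female").astype(float)
        else:
            cols[cov] = pd.to_numeric(cohort[cov])
    return pd.DataFrame(cols, index=cohort.index)


def _check_design(X: pd.DataFrame) -> None:
    for col in X.columns:
        if col != "const" and np.ptp(X[col].to_numpy()) == 0:
            raise SingularDesignError(f"column {col!r} is constant in the modeled rows")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # identify a redundant column by leave-one-out rank
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == np.linalg.matrix_rank(X.to_numpy()):
                raise SingularDesignError(f"column {col!r} is collinear with the rest")
        raise SingularDesignError("design matrix is rank-deficient")


def _fit_ols(
    cohort: pd.DataFrame,
    outcome: str,
    term_col: pd.Series,
    term_name: str,
    covariates: tuple[str, ...],
    transform: str | None,
) -> RegressionResult:
    data = cohort.copy()
    data["_term"] = term_col
    keep = [outcome, "_term"] + [("sex" if c == "sex" else c) for c in covariates]
    data = data.dropna(subset=[c for c in keep if c in data.columns])
    y = pd.to_numeric(data[outcome])
    if transform is None:
        transform = choose_transform(y)
    if transform == "log10":
        y = np.log10(y)
    X = _encode(data, covariates)
    X.insert(0, term_name, pd.to_numeric(data["_term"]))
    X = sm.add_constant(X)
    n = len(data)
    if np.ptp(y.to_numpy()) == 0:
        return RegressionResult(outcome, transform, term_name, 0.0, np.nan,
                                np.nan, 0.0, n, flagged=True)
    _check_design(X)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        outcome=outcome,
        transform=transform,
        term=term_name,
        beta=float(fit.params[term_name]),
        se=float(fit.bse[term_name]),
        p=float(fit.pvalues[term_name]),
        r2=float(fit.rsquared),
        n=n,
    )


def fit_group_model(
    cohort: pd.DataFrame,
    outcome: str,
    group_col: str = "group",
    covariates: tuple[str, ...] = ("age", "sex"),
    transform: str | None = None,
) -> RegressionResult:
    """OLS of (possibly log10) outcome on group indicator + covariates.

    Reports the group coefficient (exposed group = 1), its SE, two-sided
    p, and model R^2.  Rows with missing modeled values are dropped and n
    records what was used.  Requires >= 2 subjects per group.
    """
    groups = cohort[group_col].astype(str)
    levels = sorted(groups.dropna().unique(), key=lambda g: g != GROUP_LEVELS[0])
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels}")
    indicator = (groups == levels[1]).astype(float)
    counts = indicator.value_counts()
    if counts.min() < 2 or len(counts) < 2:
        raise ValueError("need at least 2 subjects per group")
    return _fit_ols(cohort, outcome, indicator, "group", covariates, transform)


def fit_exposure_model(
    cohort: pd.DataFrame,
    outcome: str,
    exposure: str = "hba1c_mmol_mol",
    covariates: tuple[str, ...] = ("age", "sex"),
    transform: str | None = None,
) -> RegressionResult:
    """Adjusted OLS slope of the outcome per unit of a continuous exposure."""
    return _fit_ols(cohort, outcome, pd.to_numeric(cohort[exposure]),
                    exposure, covariates, transform)


def paired_region_test(
    central: np.ndarray | pd.Series,
    peripheral: np.ndarray | pd.Series,
    transform: str | None = None,
) -> tuple[float, float, str]:
    """Two-sided Wilcoxon signed-rank test on per-sample paired values.

    Values are log10-transformed when the transform rule selects it for
    the pooled values (or when forced via ``transform``).  The exact null
    distribution is used for n <= 25 without ties; the normal
    approximation with tie/zero correction above.  Returns
    ``(p, statistic, transform)``.

    Conventions: all differences zero -> p = 1; fewer than 6 pairs is an
    error (the test is uninformative).
    """
    c = np.asarray(pd.Series(central).astype(float))
    p_ = np.asarray(pd.Series(peripheral).astype(float))
    ok = np.isfinite(c) & np.isfinite(p_)
    c, p_ = c[ok], p_[ok]
    if len(c) != len(p_) or len(c) < 6:
        raise ValueError(f"need >= 6 complete pairs, got {len(c)}")
    if transform is None:
        transform = choose_transform(np.concatenate([c, p_]))
    if transform == "log10":
        c, p_ = np.log10(c), np.log10(p_)
    diff = c - p_
    nz = diff[diff != 0]
    if len(nz) == 0:
        return 1.0, 0.0, transform
    has_ties = np.unique(np.abs(nz)).size < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.pvalue), float(res.statistic), transform


def summarize_cohort(
    cohort: pd.DataFrame,
    value_cols: list[str] | None = None,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-group summary table: median (IQR) for skewed columns, mean (SD)
    for approximately normal ones, counts/percent for categoricals."""
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if value_cols is None:
        value_cols = [c for c in cohort.columns
                      if pd.api.types.is_numeric_dtype(cohort[c])]
    groups = []
    for gname, gdf in cohort.groupby(group_col, sort=True):
        if len(gdf) == 0:
            warnings.warn(f"group {gname!r} is empty; omitted", stacklevel=2)
            continue
        row: dict = {group_col: gname, "n": len(gdf),
                     "pct": round(100.0 * len(gdf) / len(cohort))}
        for col in value_cols:
            vals = pd.to_numeric(gdf[col], errors="coerce").dropna()
            if len(vals) == 0:
                row[col] = ""
                continue
            if choose_transform(vals) == "none":
                row[col] = f"{vals.mean():.4g} (SD {vals.std(ddof=1):.3g})"
            else:
                q1, q2, q3 = np.percentile(vals, [25, 50, 75])
                row[col] = f"{q2:.4g} (IQR {q1:.4g}-{q3:.4g})"
        for col in cohort.columns:
            if cohort[col].dtype == object and col not in (group_col, "subject_id"):
                vc = gdf[col].value_counts()
                row[col] = "; ".join(
                    f"{k}: {v} ({100 * v / len(gdf):.0f}%)" for k, v in vc.items()
                )
        groups.append(row)
    return pd.DataFrame(groups)
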