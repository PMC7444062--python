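"""Validation statistics: correlations, partial correlations, test-retest
reliability (ICC), group comparisons, and the full validation report.

The reliability coefficient is the single-measure, absolute-agreement
intraclass correlation from a two-way model, which penalizes both
inconsistency and systematic session offsets:

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

with MS_R, MS_C, MS_E the rows (subjects), columns (sessions) and error
mean squares of the two-way ANOVA over an n x k complete matrix.  The
95% CI follows the McGraw & Wong F-based formulas.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p: float
    n: int
    df: int


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    n: int
    k: int


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


def _paired(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation with pairwise deletion of missing values.

    Two-sided p from the t distribution on n-2 df.  Requires at least 3
    complete pairs and non-constant columns.
    """
    xv, yv = _paired(x, y)
    n = len(xv)
    if n < 3:
        raise ValueError(f"need >=3 complete pairs, have {n}")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("zero-variance column")
    r, p = stats.pearsonr(xv, yv)
    return CorrelationResult(r=float(r), p=float(p), n=n)


def partial_correlation(x, y, covariates: pd.DataFrame) -> PartialCorrelationResult:
    """Correlation of x and y after residualizing both on covariates.

    Complete-case analysis; both variables are regressed (with
    intercept) on the covariate design by least squares and the Pearson
    correlation of the residuals is returned, with p on
    ``n - 2 - n_covariates`` df.  With an empty covariate set this
    reduces to :func:`pearson`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = pd.DataFrame(covariates).astype(float)
    if len(cov.columns) == 0:
        res = pearson(x, y)
        return PartialCorrelationResult(res.r, res.p, res.n, res.n - 2)
    c = cov.to_numpy()
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(c).any(axis=1))
    xv, yv, cv = x[keep], y[keep], c[keep]
    n, k = len(xv), cv.shape[1]
    if n < k + 3:
        raise ValueError(f"need >= {k + 3} complete cases, have {n}")
    design = np.column_stack([np.ones(n), cv])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name columns whose removal restores full rank
        collinear = [
            col
            for j, col in enumerate(cov.columns)
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariate design: {collinear}")
    rx = xv - design @ np.linalg.lstsq(design, xv, rcond=None)[0]
    ry = yv - design @ np.linalg.lstsq(design, yv, rcond=None)[0]
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("zero-variance residuals (variable lies in covariate span)")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p=p, n=n, df=df)


def icc_absolute_agreement(measurements, alpha: float = 0.05) -> IccResult:
    """Single-measure absolute-agreement ICC from a two-way mixed model.

    ``measurements`` is an n-subjects x k-sessions matrix; rows with any
    missing value are dropped (listwise deletion).  Raises on fewer than
    5 complete subjects, fewer than 2 sessions, or zero between-subject
    variance (constant matrix), where the coefficient is undefined.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise ValueError("measurements must be a 2-D matrix")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if n < 5:
        raise ValueError(f"need >=5 complete subjects, have {n}")
    if k < 2:
        raise ValueError("need >=2 sessions")
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = m - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or np.isclose(msr, 0) and np.isclose(msc, 0) and np.isclose(mse, 0):
        raise ValueError("ICC undefined: no between-subject variance")
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1)
    if np.isclose(icc, 1.0):
        lo = hi = 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    return IccResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi), n=n, k=k)


def independent_t(group_a, group_b) -> TTestResult:
    """Two-sided pooled-variance independent-samples t-test."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if np.std(a) == 0 and np.std(b) == 0:
        raise ValueError("degenerate (zero pooled) variance")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(t=float(t), df=len(a) + len(b) - 2, p=float(p))


DEFAULT_MEASURES = (
    "freeplay_sed_pct",
    "daily_sed_min",
    "daily_mvpa_min",
    "vo2peak_ffm",
    "bmi_z",
    "pct_body_fat",
    "fmi",
)


def encode_covariates(
    cohort: pd.DataFrame, race_dummies: bool = False
) -> pd.DataFrame:
    """Numeric age/sex/race design for covariate adjustment.

    Sex is coded girl=1/boy=0; race defaults to a binary white (0) vs
    racial/ethnic minority (1) indicator, or full dummy coding of
    ``race_group`` levels with ``race_dummies=True``.
    """
    out = pd.DataFrame(index=cohort.index)
    out["age"] = cohort["age"].astype(float)
    out["sex"] = (cohort["sex"].astype(str).str.upper().isin(["F", "FEMALE", "GIRL"])).astype(float)
    if race_dummies:
        dummies = pd.get_dummies(cohort["race_group"], prefix="race", drop_first=True)
        out = pd.concat([out, dummies.astype(float)], axis=1)
    else:
        out["minority"] = (cohort["race_group"].astype(str) != "white").astype(float)
    return out


def _cell(fn, *args) -> dict:
    try:
        return asdict(fn(*args))
    except (ValueError, KeyError) as exc:
        return {"error": str(exc)}


def run_validation_report(
    cohort: pd.DataFrame,
    measures: Sequence[str] = DEFAULT_MEASURES,
    race_dummies: bool = False,
) -> dict:
    """Run the full validation analysis grid on a cohort table.

    Returns a JSON-serializable dict with descriptives (mean/SD/n per
    numeric column), the fraction of the cohort with a positive
    (sedentary-leaning) bias score, raw and age/sex/race-adjusted
    correlations of the bias score with every validation measure,
    sex-stratified accelerometry correlations, and the test-retest ICC
    when a second-session score is present.  Column-level failures are
    recorded per cell; the grid never aborts.
    """
    bias = cohort["bias"]
    cov = encode_covariates(cohort, race_dummies=race_dummies)

    numeric = cohort.select_dtypes(include=[np.number])
    descriptives = {
        col: {
            "mean": float(numeric[col].mean()),
            "sd": float(numeric[col].std(ddof=1)),
            "n": int(numeric[col].notna().sum()),
        }
        for col in numeric.columns
    }

    correlations = {}
    for m in measures:
        if m not in cohort.columns:
            correlations[m] = {"error": f"column {m!r} missing"}
            continue
        correlations[m] = {
            "raw": _cell(pearson, bias, cohort[m]),
            "adjusted": _cell(partial_correlation, bias, cohort[m], cov),
        }

    by_sex = {}
    for label, mask in (("girls", cov["sex"] == 1), ("boys", cov["sex"] == 0)):
        sub = cohort[mask]
        by_sex[label] = {
            m: _cell(pearson, sub["bias"], sub[m])
            for m in ("daily_sed_min", "daily_mvpa_min")
            if m in sub.columns
        }

    report = {
        "n": int(len(cohort)),
        "descriptives": descriptives,
        "sedentary_preference_pct": float(100.0 * (bias > 0).mean()),
        "correlations": correlations,
        "accelerometry_by_sex": by_sex,
    }
    if "bias_retest" in cohort.columns:
        report["retest_icc"] = _cell(
            icc_absolute_agreement, cohort[["bias", "bias_retest"]].to_numpy()
        )
    return report


def render_report(report: Mapping) -> str:
    """Plain-text rendering of :func:`run_validation_report` output."""
    lines = [f"Validation report (n = {report['n']})", ""]
    lines.append(
        f"Sedentary-preferring (bias > 0): "
        f"{report['sedentary_preference_pct']:.1f}%"
    )
    if "retest_icc" in report:
        icc = report["retest_icc"]
        if "error" in icc:
            lines.append(f"Test-retest ICC: error: {icc['error']}")
        else:
            lines.append(
                f"Test-retest ICC(A,1): {icc['icc']:.2f} "
                f"[{icc['ci_low']:.2f}, {icc['ci_high']:.2f}]"
            )
    lines += ["", "Bias-score correlations (raw | age/sex/race adjusted):"]
    for m, cell in report["correlations"].items():
        if "error" in cell:
            lines.append(f"  {m:18s} error: {cell['error']}")
            continue
        raw, adj = cell["raw"], cell["adjusted"]
        raw_s = (
            f"r={raw['r']:+.2f} p={raw['p']:.3f} n={raw['n']}"
            if "error" not in raw
            else f"error: {raw['error']}"
        )
        adj_s = (
            f"r={adj['r']:+.2f} p={adj['p']:.3f} n={adj['n']}"
            if "error" not in adj
            else f"error: {adj['error']}"
        )
        lines.append(f"  {m:18s} {raw_s} | {adj_s}")
    lines += ["", "Accelerometry by sex:"]
    for sex, cells in report["accelerometry_by_sex"].items():
        for m, cell in cells.items():
            s = (
                f"r={cell['r']:+.2f} p={cell['p']:.3f} n={cell['n']}"
                if "error" not in cell
                else f"error: {cell['error']}"
            )
            lines.append(f"  {sex:6s} {m:18s} {s}")
    lines += ["", "Descriptives:"]
    for col, d in report["descriptives"].items():
        lines.append(
            f"  {col:18s} mean={d['mean']:8.2f} sd={d['sd']:7.2f} n={d['n']}"
        )
    return "\n".join(lines)
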