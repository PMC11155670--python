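"""Inferential layer: hierarchical OLS, correlations, Bonferroni control.

A hierarchical (nested) regression enters the control variables in step 1
and adds the focal predictor(s) in step 2.  The increment is summarised by

    delta_R2 = R2_full - R2_step1
    F_change = (delta_R2 / df1) / ((1 - R2_full) / df2),  df2 = n - p_full - 1
    f2       = delta_R2 / (1 - R2_full)        (Cohen's effect size)

with ``p_change`` from the F(df1, df2) distribution.  The reported ``b_std``
is the standardized coefficient of the focal predictor (all variables
z-scored with the n-1 denominator before refitting).  Bonferroni control
multiplies the per-test alpha by the family size m (here, typically the
three malleability indices tested per outcome).
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "StatsError",
    "AnalysisPlan",
    "HierarchicalResult",
    "CorrelationResult",
    "hierarchical_regression",
    "run_analysis_plan",
    "correlate_indices",
    "bonferroni_adjust",
    "encode_binary",
]


class StatsError(ValueError):
    """Raised for ill-posed regression or correlation requests."""


@dataclasses.dataclass(frozen=True)
class AnalysisPlan:
    """One hierarchical regression: outcome ~ controls, then + predictor."""

    outcome: str
    controls: tuple[str, ...]
    predictor: str
    family_size: int = 3
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.family_size < 1:
            raise StatsError("family_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise StatsError("alpha must lie in (0, 1)")
        if self.predictor in self.controls:
            raise StatsError("focal predictor must not appear among the controls")


@dataclasses.dataclass(frozen=True)
class HierarchicalResult:
    """Summary of one regression step (see module docstring for formulas)."""

    outcome: str
    predictor: str
    n: int
    r2_step1: float
    r2_full: float
    delta_r2: float
    f_change: float
    df1: int
    df2: int
    p_change: float
    b_std: float
    t_value: float
    t_df: int
    f2: float
    bonferroni_significant: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def encode_binary(values: pd.Series, one: str = "female") -> pd.Series:
    """Code a two-level factor as a 0/1 indicator (``one`` -> 1)."""
    return (values == one).astype(float)


def _design(frame: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(frame))] + [frame[c].to_numpy(float) for c in cols])
    return X


def _collinear_columns(frame: pd.DataFrame, cols: Sequence[str]) -> list[str]:
    """Greedy identification of columns that do not increase design rank."""
    bad = []
    X = np.ones((len(frame), 1))
    rank = 1
    for c in cols:
        Xc = np.column_stack([X, frame[c].to_numpy(float)])
        r = np.linalg.matrix_rank(Xc)
        if r == rank:
            bad.append(c)
        else:
            X, rank = Xc, r
    return bad


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    controls: Sequence[str],
    predictor: str | Sequence[str],
    family_size: int = 1,
    alpha: float = 0.05,
) -> HierarchicalResult:
    """Run one control-then-predictor hierarchical OLS on complete cases.

    ``predictor`` may be a single column name or a list (a block); the
    standardized coefficient ``b_std`` and ``t_value`` are reported only for
    a single-column focal predictor (NaN for blocks).  A focal predictor
    that is exactly collinear with the controls adds no information and
    yields delta_r2 = 0, f_change = 0, p_change = 1; rank deficiency among
    the controls themselves is an error naming the offending columns.
    """
    predictors = [predictor] if isinstance(predictor, str) else list(predictor)
    controls = list(controls)
    if not predictors:
        raise StatsError("at least one focal predictor required")
    for p in predictors:
        if p in controls:
            raise StatsError(f"focal predictor {p!r} must not appear among the controls")
    cols = [outcome] + controls + predictors
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise StatsError(f"columns not in data: {missing}")
    complete = data[cols].dropna().reset_index(drop=True)
    n = len(complete)
    p_full = len(controls) + len(predictors)
    if n <= p_full + 2:
        raise StatsError(f"need n > {p_full + 2} complete cases, got {n}")
    constant = [c for c in controls + predictors if complete[c].nunique() <= 1]
    if constant:
        raise StatsError(f"constant-valued predictor column(s): {constant}")

    y = complete[outcome].to_numpy(float)
    X1 = _design(complete, controls)
    if np.linalg.matrix_rank(X1) < X1.shape[1]:
        raise StatsError(
            f"rank-deficient control design; collinear columns: "
            f"{_collinear_columns(complete, controls)}"
        )
    fit1 = sm.OLS(y, X1).fit()
    r2_step1 = 0.0 if not controls else float(fit1.rsquared)

    Xf = _design(complete, controls + predictors)
    rank_full = np.linalg.matrix_rank(Xf)
    df1 = len(predictors)
    df2 = n - p_full - 1
    if rank_full == X1.shape[1]:
        # focal block is exactly collinear with the controls: no added information
        return HierarchicalResult(
            outcome=outcome,
            predictor="+".join(predictors),
            n=n,
            r2_step1=r2_step1,
            r2_full=r2_step1,
            delta_r2=0.0,
            f_change=0.0,
            df1=df1,
            df2=df2,
            p_change=1.0,
            b_std=float("nan"),
            t_value=float("nan"),
            t_df=df2,
            f2=0.0,
            bonferroni_significant=False,
        )
    fit_full = sm.OLS(y, Xf).fit()
    r2_full = float(fit_full.rsquared)
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0 or fit_full.ssr <= 1e-13 * tss:
        raise StatsError("zero residual variance in the full model")

    delta_r2 = r2_full - r2_step1
    f_change = (delta_r2 / df1) / ((1.0 - r2_full) / df2)
    p_change = float(scipy.stats.f.sf(f_change, df1, df2))

    if len(predictors) == 1:
        z = (complete[cols] - complete[cols].mean()) / complete[cols].std(ddof=1)
        zfit = sm.OLS(
            z[outcome].to_numpy(float), _design(z, controls + predictors)
        ).fit()
        b_std = float(zfit.params[-1])
        t_value = float(fit_full.tvalues[-1])
    else:
        b_std = float("nan")
        t_value = float("nan")

    return HierarchicalResult(
        outcome=outcome,
        predictor="+".join(predictors),
        n=n,
        r2_step1=r2_step1,
        r2_full=r2_full,
        delta_r2=float(delta_r2),
        f_change=float(f_change),
        df1=df1,
        df2=df2,
        p_change=p_change,
        b_std=b_std,
        t_value=t_value,
        t_df=df2,
        f2=float(delta_r2 / (1.0 - r2_full)),
        bonferroni_significant=bool(p_change < alpha / family_size),
    )


def run_analysis_plan(data: pd.DataFrame, plan: AnalysisPlan) -> HierarchicalResult:
    """Convenience wrapper: run a named :class:`AnalysisPlan` on a data table."""
    return hierarchical_regression(
        data,
        plan.outcome,
        list(plan.controls),
        plan.predictor,
        family_size=plan.family_size,
        alpha=plan.alpha,
    )


@dataclasses.dataclass
class CorrelationResult:
    """Pairwise-complete Pearson correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined: list[tuple[str, str]]

    def stars(self) -> pd.DataFrame:
        """Significance markers as in the descriptive tables: * p<.05, ** p<.01."""
        def mark(p):
            if pd.isna(p):
                return ""
            return "**" if p < 0.01 else ("*" if p < 0.05 else "")

        return self.p.map(mark)


def correlate_indices(
    data: pd.DataFrame,
    index_cols: Sequence[str],
    trait_cols: Sequence[str],
) -> CorrelationResult:
    """Correlate attention indices (rows) with trait measures (columns).

    Cells with a zero-variance member are flagged ``undefined`` (NaN, never
    silently 0); fewer than 3 complete pairs in any cell is an error.
    """
    for c in list(index_cols) + list(trait_cols):
        if c not in data.columns:
            raise StatsError(f"column {c!r} not in data")
    r = pd.DataFrame(index=list(index_cols), columns=list(trait_cols), dtype=float)
    p = r.copy()
    n = pd.DataFrame(index=list(index_cols), columns=list(trait_cols), dtype=int)
    undefined: list[tuple[str, str]] = []
    for a in index_cols:
        for b in trait_cols:
            pair = pd.DataFrame({"a": data[a], "b": data[b]}).dropna()
            if len(pair) < 3:
                raise StatsError(f"fewer than 3 complete pairs for ({a}, {b})")
            n.loc[a, b] = len(pair)
            if pair["a"].nunique() <= 1 or pair["b"].nunique() <= 1:
                undefined.append((a, b))
                r.loc[a, b] = np.nan
                p.loc[a, b] = np.nan
                continue
            res = scipy.stats.pearsonr(pair["a"], pair["b"])
            r.loc[a, b] = float(res.statistic)
            p.loc[a, b] = float(res.pvalue)
    return CorrelationResult(r=r, p=p, n=n, undefined=undefined)


def null_calibration(
    n: int = 70,
    replicates: int = 2000,
    alpha: float = 0.05,
    n_controls: int = 2,
    seed: int | None = None,
) -> dict:
    """Empirical type-I rate of the F-change test under a true null.

    Simulates ``replicates`` datasets in which the focal predictor is
    independent of the outcome (controls and predictor iid standard
    normal) and reports the rejection rate of ``p_change < alpha``, with
    the binomial standard error of that rate.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    cols = [f"c{i}" for i in range(n_controls)]
    for _ in range(replicates):
        data = pd.DataFrame(rng.standard_normal((n, n_controls + 2)), columns=["y", *cols, "x"])
        res = hierarchical_regression(data, "y", cols, "x")
        rejections += res.p_change < alpha
    rate = rejections / replicates
    return {
        "n": n,
        "replicates": replicates,
        "alpha": alpha,
        "rejection_rate": rate,
        "binomial_se": float(np.sqrt(alpha * (1 - alpha) / replicates)),
    }


def bonferroni_adjust(
    p_values: Sequence[float], m: int | None = None, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni adjustment: adjusted p = min(1, p * m); decision at alpha."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise StatsError("family size m must be >= the number of p-values")
    adjusted = np.minimum(1.0, p * m)
    return adjusted, adjusted < alpha
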