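"""Reliability and robustness statistics for calibration models.

Two questions are answered here.  Is a fitted calibration curve reliable,
i.e. does it predict data it was not trained on?  This is assessed by
split-sample cross validation: the shrinkage R^2 - R^2* between the
training fit and the squared correlation of holdout predictions with
holdout observations, with shrinkage below 0.10 taken as reliable.

And do two scanners share one calibration curve?  This is the classical
test of coincident regression lines: a pooled fit is compared with one
augmented by a scanner-coding dummy variable (plus dummy-by-predictor
interactions), via a partial F test on the residual sums of squares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from petbtv.calibration import FitResult, ols_fit

#: Shrinkage below this value marks a reliable model.
RELIABILITY_CUTOFF = 0.10


@dataclass(frozen=True)
class ReliabilityResult:
    """Split-sample cross-validation summary."""

    r2_training: float
    r2_holdout: float
    shrinkage: float
    reliable: bool
    split_seed: int
    n_training: int
    n_holdout: int


@dataclass(frozen=True)
class ResidualSummary:
    """Tukey box-and-whisker statistics of holdout residuals (TS points)."""

    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outlier_count: int
    n: int


@dataclass(frozen=True)
class CoincidenceResult:
    """Coincident-regression-lines test between two record sets."""

    reduced: FitResult
    full: FitResult
    f: float
    df: tuple[float, int]
    p_value: float
    dummy_additional_r2: float
    #: F computed with the actual residual-df difference as numerator df,
    #: for when the requested q does not match the fitted parameter count.
    f_delta_df: float


def split_sample(
    data: pd.DataFrame, fraction: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random disjoint, exhaustive partition into training and holdout.

    ``|training| = round(fraction * n)``; reproducible by seed.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    n = len(data)
    if n < 20:
        raise ValueError("split-sample validation needs n >= 20")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(fraction * n))
    train = data.iloc[np.sort(order[:n_train])]
    hold = data.iloc[np.sort(order[n_train:])]
    return train, hold


def cross_validate(
    model_form: Sequence[str],
    data: pd.DataFrame,
    seed: int = 0,
    fraction: float = 0.5,
    response: str = "ts",
) -> ReliabilityResult:
    """Fit on a random half, predict the other, report the shrinkage.

    ``model_form`` lists the predictor columns of ``data``; ``response``
    names the observed-threshold column.  R^2* is the squared Pearson
    correlation between holdout predictions and observations; shrinkage is
    R^2 - R^2* and may legitimately come out negative.
    """
    train, hold = split_sample(data, fraction=fraction, seed=seed)
    fit = ols_fit(train[list(model_form)], train[response])
    predicted = fit.predict(hold[list(model_form)])
    observed = hold[response].to_numpy(dtype=float)
    r_star = np.corrcoef(predicted, observed)[0, 1]
    r2_holdout = float(r_star**2)
    shrinkage = fit.r2 - r2_holdout
    return ReliabilityResult(
        r2_training=fit.r2,
        r2_holdout=r2_holdout,
        shrinkage=float(shrinkage),
        reliable=shrinkage < RELIABILITY_CUTOFF,
        split_seed=seed,
        n_training=len(train),
        n_holdout=len(hold),
    )


def residual_summary(
    predicted: Sequence[float], observed: Sequence[float]
) -> ResidualSummary:
    """Box-plot statistics of the residuals observed - predicted.

    Whiskers follow the 1.5*IQR rule: they reach the most extreme data
    points within the fences; points beyond them are counted as outliers.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if predicted.size < 4:
        raise ValueError("need at least 4 residuals")
    res = observed - predicted
    q1, med, q3 = np.percentile(res, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = res[(res >= lo_fence) & (res <= hi_fence)]
    return ResidualSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outlier_count=int(res.size - inside.size),
        n=int(res.size),
    )


def coincidence_f(
    ss_res_reduced: float, ss_res_full: float, ms_res_full: float, q: int = 3
) -> float:
    """Coincidence F from already-tabulated sums of squares:
    F = (SS_res,reduced - SS_res,full) / q / MS_res,full."""
    return (ss_res_reduced - ss_res_full) / q / ms_res_full


def coincidence_test(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    model_form: Sequence[str],
    q: int = 3,
    response: str = "ts",
) -> CoincidenceResult:
    """Test whether two scanners share one calibration curve.

    The two record sets are pooled; the reduced model regresses TS on
    ``model_form``, the full model adds a scanner dummy and, for q > 1,
    dummy-by-predictor interactions (q extra parameters in total).  The
    statistic follows the conventional layout
    F = (SS_res,reduced - SS_res,full) / q / MS_res,full with numerator df
    q as requested; ``f_delta_df`` uses the realized residual-df difference
    instead, which differs from F only when q exceeds the number of extra
    parameters actually available.
    """
    form = list(model_form)
    if not set(form) <= set(records_a.columns) or not set(form) <= set(
        records_b.columns
    ):
        raise ValueError("both record sets must contain every model_form column")
    if len(records_a) == 0 or len(records_b) == 0:
        raise ValueError("both record sets must be non-empty")
    if q < 1:
        raise ValueError("q must be >= 1")
    pooled = pd.concat(
        [records_a[form + [response]], records_b[form + [response]]],
        ignore_index=True,
    )
    dummy = np.concatenate(
        [np.zeros(len(records_a)), np.ones(len(records_b))]
    )
    X_red = pooled[form]
    y = pooled[response]
    reduced = ols_fit(X_red, y)
    X_full = X_red.copy()
    X_full["scanner"] = dummy
    for name in form[: max(q - 1, 0)]:
        X_full[f"scanner:{name}"] = dummy * pooled[name].to_numpy(dtype=float)
    full = ols_fit(X_full, y)
    f = coincidence_f(reduced.ss_residual, full.ss_residual, full.ms_residual, q)
    delta_df = reduced.df_residual - full.df_residual
    f_delta = coincidence_f(
        reduced.ss_residual, full.ss_residual, full.ms_residual, delta_df
    )
    p = float(stats.f.sf(f, q, full.df_residual))
    return CoincidenceResult(
        reduced=reduced,
        full=full,
        f=float(f),
        df=(q, full.df_residual),
        p_value=p,
        dummy_additional_r2=float(full.r2 - reduced.r2),
        f_delta_df=float(f_delta),
    )
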