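"""Calibration of the adaptive threshold: Eq-style multiple regression.

The optimal threshold of a target is modelled linearly in the target's
maximal cross-sectional area A (mm^2), the contrast term 1 - 1/TBR and the
transaxial post-filter FWHM (mm):

    TS = B0 + B1*A + B2*(1 - 1/TBR) + B3*FWHM + E

Predictors enter by stepwise forward selection with an F-to-enter of 4 and
a required multiple-R^2 increment of 0.01, a deliberately conservative rule
against redundant covariates (scan duration, iteration number, axial
kernels, relaxation, TOF kernel width are offered as candidates and are
expected not to survive it).

Reference calibrations for eight published scanner models are shipped as
package data and can be applied without refitting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from petbtv.phantom import DEFAULT_ESDS, DEFAULT_TBRS
from petbtv.roi import MeasurementRecord

#: Default lower bound (mm^2) on cross-sectional area for model fitting;
#: smaller targets suffer severe partial-volume errors and are excluded.
MIN_FIT_AREA = 133.0

#: Stepwise retention rules.
F_ENTER = 4.0
MIN_DELTA_R2 = 0.01

#: Sphere cross-section areas (mm^2) above the fitting cutoff, used as the
#: default area grid when simulating measurement records.
LARGE_SPHERE_AREAS = tuple(
    round(math.pi * (d / 2.0) ** 2, 2) for d in (17.0, 22.0, 28.0, 37.0, 57.4)
)

_PREDICTOR_COLUMNS = {
    "x1_area": "area",
    "x2": "x2",
    "x3_fwhm": "fwhm",
    "esd": "esd",
    "em_iterations": "iterations",
}


@dataclass(frozen=True)
class FitResult:
    """An ordinary-least-squares fit with its ANOVA decomposition."""

    coefficients: Mapping[str, float]  # includes "intercept"
    std_errors: Mapping[str, float]
    predictors: tuple[str, ...]
    n: int
    ss_regression: float
    ss_residual: float
    ss_total: float
    df_regression: int
    df_residual: int
    r2: float
    adjusted_r2: float

    @property
    def ms_regression(self) -> float:
        return self.ss_regression / self.df_regression if self.df_regression else 0.0

    @property
    def ms_residual(self) -> float:
        return self.ss_residual / self.df_residual

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        out = np.full(len(X), self.coefficients["intercept"], dtype=float)
        for name in self.predictors:
            out += self.coefficients[name] * np.asarray(X[name], dtype=float)
        return out


@dataclass(frozen=True)
class CalibrationModel:
    """A fitted (or shipped) threshold calibration curve.

    ``coefficients`` maps predictor names ("area", "x2", "fwhm", extras)
    to their slopes; ``partial_r2`` holds the variance share explained at
    entry (partial R^2 for the first predictor, additional R^2 for the
    later ones, following the usual reporting of forward selection).
    """

    scanner_model: str
    intercept: float
    coefficients: Mapping[str, float]
    selection_order: tuple[str, ...]
    multiple_r2: float | None = None
    adjusted_r2: float | None = None
    standardized_beta: Mapping[str, float] = field(default_factory=dict)
    partial_r2: Mapping[str, float] = field(default_factory=dict)
    residual_sd: float | None = None
    shrinkage: float | None = None

    def __post_init__(self) -> None:
        if set(self.selection_order) != set(self.coefficients):
            raise ValueError("selection_order must list exactly the retained predictors")
        if self.multiple_r2 is not None:
            if self.multiple_r2 > 1.0 + 1e-12:
                raise ValueError("multiple_r2 cannot exceed 1")
            if (
                self.adjusted_r2 is not None
                and self.adjusted_r2 > self.multiple_r2 + 1e-12
            ):
                raise ValueError("adjusted_r2 cannot exceed multiple_r2")
            if self.partial_r2 and (
                sum(self.partial_r2.values()) > self.multiple_r2 + 0.005
            ):
                raise ValueError("partial R^2 shares exceed the model R^2")

    def linear_predictor(self, values: Mapping[str, float]) -> float:
        ts = self.intercept
        for name, coef in self.coefficients.items():
            ts += coef * values[name]
        return ts


@dataclass(frozen=True)
class PredictedTS:
    """A threshold prediction: clipped value plus nearest-integer percent."""

    ts: float
    percent: int
    unclipped: float


def records_to_frame(records: Iterable[MeasurementRecord]) -> pd.DataFrame:
    """Flatten measurement records (extras included) into a DataFrame."""
    rows = []
    for r in records:
        row = {
            "scanner_id": r.scanner_id,
            "sphere_id": r.sphere_id,
            "x1_area": r.x1_area,
            "tbr_nominal": r.tbr_nominal,
            "tbr_measured": r.tbr_measured,
            "x2": r.x2,
            "x3_fwhm": r.x3_fwhm,
            "esd": r.esd,
            "em_iterations": r.em_iterations,
            "ts": r.ts,
            "converged": r.converged,
        }
        row.update(r.extras)
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_design(
    records: Iterable[MeasurementRecord] | pd.DataFrame,
    min_area: float = MIN_FIT_AREA,
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Build the regression dataset from measurement records.

    Rows with cross-sectional area at or below ``min_area`` are removed.
    Candidate predictors are area, x2 = 1 - 1/TBR, fwhm, esd, iteration
    number, and any numeric extras.  Returns (X, y, n_removed).
    """
    frame = (
        records.copy()
        if isinstance(records, pd.DataFrame)
        else records_to_frame(records)
    )
    if frame.empty:
        raise ValueError("no measurement records supplied")
    keep = frame["x1_area"] > min_area
    removed = int((~keep).sum())
    frame = frame.loc[keep]
    if frame.empty:
        raise ValueError(
            f"all {removed} records fall at or below the {min_area} mm^2 cutoff"
        )
    X = pd.DataFrame(index=frame.index)
    for src, dst in _PREDICTOR_COLUMNS.items():
        if src in frame:
            X[dst] = frame[src].astype(float)
    reserved = set(_PREDICTOR_COLUMNS) | {
        "scanner_id",
        "sphere_id",
        "tbr_nominal",
        "tbr_measured",
        "ts",
        "converged",
    }
    for col in frame.columns:
        if col not in reserved and pd.api.types.is_numeric_dtype(frame[col]):
            X[col] = frame[col].astype(float)
    y = frame["ts"].astype(float)
    return X.reset_index(drop=True), y.reset_index(drop=True), removed


def _check_rank(X: pd.DataFrame) -> None:
    design = np.column_stack([np.ones(len(X))] + [X[c] for c in X.columns])
    if np.linalg.matrix_rank(design) == design.shape[1]:
        return
    # name the columns that do not add rank
    bad = []
    current = np.ones((len(X), 1))
    for c in X.columns:
        trial = np.column_stack([current, X[c]])
        if np.linalg.matrix_rank(trial) == current.shape[1]:
            bad.append(c)
        else:
            current = trial
    raise ValueError(f"design matrix is rank deficient; offending columns: {bad}")


def ols_fit(X: pd.DataFrame, y: Sequence[float]) -> FitResult:
    """Least-squares fit of y on the columns of X (intercept added).

    Raises on rank deficiency (naming the collinear columns) and when the
    sample is too small for the requested predictor count.
    """
    y = np.asarray(y, dtype=float)
    n, p = len(y), X.shape[1]
    if len(X) != n:
        raise ValueError("X and y lengths differ")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    _check_rank(X)
    design = sm.add_constant(X.astype(float), has_constant="add")
    res = sm.OLS(y, design).fit()
    coefs = {"intercept": float(res.params["const"])}
    ses = {"intercept": float(res.bse["const"])}
    for c in X.columns:
        coefs[c] = float(res.params[c])
        ses[c] = float(res.bse[c])
    ss_res = float(res.ssr)
    ss_tot = float(res.centered_tss)
    return FitResult(
        coefficients=coefs,
        std_errors=ses,
        predictors=tuple(X.columns),
        n=n,
        ss_regression=ss_tot - ss_res,
        ss_residual=ss_res,
        ss_total=ss_tot,
        df_regression=p,
        df_residual=n - p - 1,
        r2=float(res.rsquared) if p else 0.0,
        adjusted_r2=float(res.rsquared_adj) if p else 0.0,
    )


def partial_f(current: FitResult, candidate: FitResult) -> float:
    """F-to-enter of the single predictor added by ``candidate``.

    Equals the squared t statistic of the added coefficient.  The candidate
    model must nest the current model with exactly one extra predictor.
    """
    extra = set(candidate.predictors) - set(current.predictors)
    if len(extra) != 1 or not set(current.predictors) <= set(candidate.predictors):
        raise ValueError("candidate must add exactly one predictor to current")
    if candidate.n != current.n:
        raise ValueError("models were fitted on different samples")
    return (current.ss_residual - candidate.ss_residual) / candidate.ms_residual


def standardized_coeffs(
    coefficients: Mapping[str, float], X: pd.DataFrame, y: Sequence[float]
) -> dict[str, float]:
    """Standardized regression coefficients beta_i = B_i * SD(x_i) / SD(y)."""
    y = np.asarray(y, dtype=float)
    sy = y.std(ddof=1)
    if sy == 0:
        raise ValueError("response has zero variance")
    return {
        name: float(coef * X[name].std(ddof=1) / sy)
        for name, coef in coefficients.items()
        if name != "intercept"
    }


def stepwise_forward(
    X: pd.DataFrame,
    y: Sequence[float],
    f_enter: float = F_ENTER,
    min_delta_r2: float = MIN_DELTA_R2,
    scanner_model: str = "custom",
) -> CalibrationModel:
    """Stepwise forward selection with F > ``f_enter`` and dR^2 >= ``min_delta_r2``.

    At each step the remaining candidate with the highest F-to-enter is
    tried; it is retained only if its F exceeds the threshold and it raises
    the multiple R^2 by at least ``min_delta_r2``.  There is no removal
    step.  Ties in F break by candidate column order.  Returns the fitted
    calibration model; with no admissible candidate this is the
    intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    additional_r2: dict[str, float] = {}
    current = ols_fit(X[selected], y)
    remaining = list(X.columns)
    while remaining:
        best_name, best_fit, best_f = None, None, -np.inf
        for name in remaining:
            try:
                fit = ols_fit(X[selected + [name]], y)
            except ValueError:
                continue  # collinear or zero-variance candidate never enters
            f = partial_f(current, fit)
            if f > best_f:
                best_name, best_fit, best_f = name, fit, f
        if best_name is None or best_f <= f_enter:
            break
        if best_fit.r2 - current.r2 < min_delta_r2:
            break
        additional_r2[best_name] = best_fit.r2 - current.r2
        selected.append(best_name)
        remaining.remove(best_name)
        current = best_fit
    betas = standardized_coeffs(current.coefficients, X, y) if selected else {}
    return CalibrationModel(
        scanner_model=scanner_model,
        intercept=current.coefficients["intercept"],
        coefficients={k: current.coefficients[k] for k in selected},
        selection_order=tuple(selected),
        multiple_r2=current.r2,
        adjusted_r2=current.adjusted_r2,
        standardized_beta=betas,
        partial_r2=additional_r2,
        residual_sd=math.sqrt(current.ms_residual),
    )


def predict_ts(
    model: CalibrationModel,
    tbr: float,
    fwhm: float | None = None,
    area: float | None = None,
    extras: Mapping[str, float] | None = None,
) -> PredictedTS:
    """Evaluate a calibration curve at measured TBR / FWHM / area.

    The threshold is clipped to the physical range [1, 100]%; both the
    clipped value and its nearest-integer percent are returned.
    """
    if tbr < 1:
        raise ValueError("TBR must be >= 1")
    known: dict[str, float | None] = {
        "x2": 1.0 - 1.0 / tbr,
        "fwhm": fwhm,
        "area": area,
    }
    if extras:
        known.update(extras)
    values = {}
    for name in model.coefficients:
        if known.get(name) is None:
            raise ValueError(f"model {model.scanner_model!r} requires predictor {name!r}")
        values[name] = float(known[name])
    raw = model.linear_predictor(values)
    clipped = float(min(max(raw, 1.0), 100.0))
    return PredictedTS(ts=clipped, percent=int(round(clipped)), unclipped=raw)


def reference_model_ids() -> tuple[str, ...]:
    return tuple(_load_reference_data())


def reference_model(model_id: str) -> CalibrationModel:
    """Load one of the shipped scanner-model calibration curves."""
    data = _load_reference_data()
    if model_id not in data:
        raise KeyError(
            f"unknown reference model {model_id!r}; available: {sorted(data)}"
        )
    entry = data[model_id]
    return CalibrationModel(
        scanner_model=entry["display_name"],
        intercept=entry["intercept"],
        coefficients=dict(entry["coefficients"]),
        selection_order=tuple(entry["selection_order"]),
        multiple_r2=entry["multiple_r2"],
        standardized_beta=dict(entry["standardized_beta"]),
        partial_r2=dict(entry["partial_r2"]),
        shrinkage=entry["shrinkage"],
    )


def _load_reference_data() -> dict:
    path = resources.files("petbtv").joinpath("data/reference_models.json")
    return json.loads(path.read_text())


def simulate_records(
    model: CalibrationModel,
    n: int,
    *,
    target_r2: float | None = None,
    noise_sd: float | None = None,
    seed: int | np.random.Generator = 0,
    tbrs: Sequence[float] = DEFAULT_TBRS,
    fwhms: Sequence[float] = (4.0, 6.0, 8.0, 11.0),
    areas: Sequence[float] = LARGE_SPHERE_AREAS,
    esds: Sequence[float] = DEFAULT_ESDS,
    iterations: Sequence[int] = (16, 32),
) -> pd.DataFrame:
    """Draw synthetic measurement records from a known calibration curve.

    Predictors are sampled uniformly from the protocol grids (TBR, filter
    FWHM, large-sphere areas) together with the decoy covariates ESD and
    iteration number, which do not influence TS.  TS is the model's linear
    predictor plus zero-mean Gaussian noise.  When ``target_r2`` is given
    the noise SD is set to sd(signal) * sqrt((1 - R2) / R2) so the
    population R^2 of a correct fit equals the target.

    The chosen noise SD is stored in ``frame.attrs['noise_sd']``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    frame = pd.DataFrame(
        {
            "area": rng.choice(np.asarray(areas, dtype=float), size=n),
            "x2": 1.0 - 1.0 / rng.choice(np.asarray(tbrs, dtype=float), size=n),
            "fwhm": rng.choice(np.asarray(fwhms, dtype=float), size=n),
            "esd": rng.choice(np.asarray(esds, dtype=float), size=n),
            "iterations": rng.choice(np.asarray(iterations, dtype=float), size=n),
        }
    )
    signal = np.full(n, model.intercept, dtype=float)
    for name, coef in model.coefficients.items():
        signal += coef * frame[name].to_numpy()
    if noise_sd is None:
        if target_r2 is None:
            raise ValueError("give either noise_sd or target_r2")
        if not (0 < target_r2 < 1):
            raise ValueError("target_r2 must lie in (0, 1)")
        noise_sd = float(signal.std(ddof=0) * math.sqrt((1 - target_r2) / target_r2))
    frame["ts"] = signal + rng.standard_normal(n) * noise_sd
    frame.attrs["noise_sd"] = float(noise_sd)
    return frame
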