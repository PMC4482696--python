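"""Climate-impact decomposition: exposure, sensitivity, vulnerability.

Projected change at a pixel is measured as the Bray-Curtis dissimilarity
between its baseline and future type-probability vectors; for probability
vectors this equals half the L1 distance and lies in [0, 1].  Across a
scenario ensemble:

* sensitivity is the slope, forced through the origin, of per-scenario
  dissimilarity against the local mean-annual-temperature change (degC^-1);
* exposure is the through-origin slope of local warming on the regional
  mean warming (dimensionless; < 1 means warming slower than the region);
* vulnerability is their elementwise product.

Regional change per scenario is the Bray-Curtis distance between regional
frequency vectors.  Per-type trajectories of regional frequency against
warming are fitted with linear, quadratic, or exponential forms (each with
an additive linear precipitation term) selected by BIC; weighted location
indices track the probability-weighted mean position of each type along
reporting axes such as elevation and distance to coast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize

from .landscape import ClimateScenario, EnvironmentalStack, ScenarioSuite
from .projection import FrequencyVector, ProbabilityField

__all__ = [
    "DissimilarityField", "ImpactSummary", "TypeResponse", "ThroughOriginFit",
    "bray_curtis", "pixel_impacts", "regional_change", "sensitivity_slope",
    "exposure_slope", "vulnerability", "decompose_impacts", "local_mat_change",
    "type_response", "weighted_location", "sensitivity_correlates",
]


@dataclass
class DissimilarityField:
    """Per-pixel Bray-Curtis dissimilarity for one scenario."""

    values: np.ndarray
    scenario_label: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("Bray-Curtis values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)


@dataclass
class ImpactSummary:
    """Per-pixel decomposition of projected change.

    sensitivity: dissimilarity per degC of local warming;
    exposure: local/regional warming ratio (> 0 where defined);
    vulnerability = sensitivity * exposure, exactly elementwise;
    fit_diagnostics: residual variance of the through-origin sensitivity
    regression per pixel.
    """

    sensitivity: np.ndarray
    exposure: np.ndarray
    vulnerability: np.ndarray
    fit_diagnostics: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.allclose(self.vulnerability, self.sensitivity * self.exposure,
                           rtol=0, atol=0, equal_nan=True):
            raise ValueError("vulnerability must equal sensitivity * exposure exactly")


@dataclass
class ThroughOriginFit:
    """Through-origin least-squares slope with its residual variance."""

    slope: float
    residual_variance: float

    def __float__(self) -> float:
        return self.slope


@dataclass
class TypeResponse:
    """Fitted response of one type's regional frequency to warming.

    chosen_form is the BIC-best of {linear, quadratic, exponential} in the
    warming covariate, always with an additive linear precipitation term;
    direction summarizes the trend over the scenario warming range.
    """

    class_name: str
    chosen_form: str
    coefficients: dict[str, float]
    direction: str  # decline | increase | hump | flat
    bic: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity between two nonnegative vectors.

    sum |x_i - y_i| / sum (x_i + y_i); equals half the L1 distance for two
    probability vectors.  Two all-zero vectors are degenerate and return 0
    with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("Bray-Curtis requires nonnegative vectors")
    denom = float(np.sum(x + y))
    if denom == 0.0:
        warnings.warn("Bray-Curtis of two all-zero vectors is degenerate; returning 0",
                      RuntimeWarning)
        return 0.0
    return float(np.sum(np.abs(x - y)) / denom)


def _bray_curtis_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = np.abs(a - b).sum(axis=1)
    denom = (a + b).sum(axis=1)
    out = np.zeros(a.shape[0])
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    if not ok.all():
        warnings.warn("degenerate all-zero rows in Bray-Curtis; set to 0", RuntimeWarning)
    return out


def pixel_impacts(baseline: ProbabilityField,
                  futures: Sequence[ProbabilityField]) -> list[DissimilarityField]:
    """Per-pixel baseline-to-future dissimilarity, one field per scenario."""
    out = []
    for fut in futures:
        if fut.values.shape != baseline.values.shape:
            raise ValueError("baseline and future fields must cover the same pixels and classes")
        if fut.class_names != baseline.class_names:
            raise ValueError("class sets differ between baseline and future fields")
        label = getattr(fut, "scenario_label", None) or "scenario"
        out.append(DissimilarityField(
            values=_bray_curtis_rows(baseline.values, fut.values),
            scenario_label=label,
        ))
    return out


def regional_change(baseline: FrequencyVector, future: FrequencyVector) -> float:
    """Bray-Curtis distance between regional frequency vectors."""
    if baseline.class_names != future.class_names:
        raise ValueError("frequency vectors must share one class set")
    return bray_curtis(baseline.f, future.f)


def _through_origin(y: np.ndarray, x: np.ndarray) -> ThroughOriginFit:
    sxx = float(np.sum(x * x))
    if sxx == 0.0:
        raise ValueError("through-origin slope undefined: predictor is identically zero")
    slope = float(np.sum(y * x) / sxx)
    resid = y - slope * x
    dof = max(len(y) - 1, 1)
    return ThroughOriginFit(slope=slope, residual_variance=float(np.sum(resid**2) / dof))


def sensitivity_slope(dissimilarities, delta_t) -> ThroughOriginFit:
    """Through-origin slope of dissimilarity on local warming at one pixel."""
    d = np.asarray(dissimilarities, dtype=float)
    t = np.asarray(delta_t, dtype=float)
    if d.shape != t.shape or d.size < 2:
        raise ValueError("need matching series of at least 2 scenarios")
    return _through_origin(d, t)


def exposure_slope(local_delta_t, regional_delta_t) -> ThroughOriginFit:
    """Through-origin slope of local on regional warming (exposure)."""
    loc = np.asarray(local_delta_t, dtype=float)
    reg = np.asarray(regional_delta_t, dtype=float)
    if loc.shape != reg.shape or loc.size < 2:
        raise ValueError("need matching series of at least 2 scenarios")
    return _through_origin(loc, reg)


def vulnerability(sensitivity: np.ndarray, exposure: np.ndarray) -> np.ndarray:
    """Elementwise product of sensitivity and exposure rasters."""
    s = np.asarray(sensitivity, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if s.shape != e.shape:
        raise ValueError("sensitivity and exposure rasters are misaligned")
    return s * e


def local_mat_change(baseline: EnvironmentalStack, scenario: ClimateScenario) -> np.ndarray:
    """Per-pixel MAT change, operationalized as the mean of JJA and DJF change."""
    djja = scenario.stack.layers["jja"] - baseline.layers["jja"]
    ddjf = scenario.stack.layers["djf"] - baseline.layers["djf"]
    return 0.5 * (djja + ddjf)


def decompose_impacts(
    baseline_field: ProbabilityField,
    future_fields: Sequence[ProbabilityField],
    suite: ScenarioSuite,
) -> ImpactSummary:
    """Vectorized per-pixel sensitivity/exposure/vulnerability over a suite.

    Sensitivity regresses per-pixel dissimilarity through the origin on the
    pixel's own warming series; exposure regresses the local warming series
    on the regional mean series.  Scenarios are the suite's futures (the
    baseline contributes only the origin, which through-origin regression
    makes redundant).
    """
    if len(future_fields) != len(suite):
        raise ValueError("one future field per scenario is required")
    n = baseline_field.n_pixels
    s = len(suite)
    d = np.empty((n, s))
    local_dt = np.empty((n, s))
    for j, (fld, scen) in enumerate(zip(future_fields, suite.scenarios)):
        if fld.values.shape != baseline_field.values.shape:
            raise ValueError("fields must share one pixel set")
        d[:, j] = _bray_curtis_rows(baseline_field.values, fld.values)
        local_dt[:, j] = local_mat_change(suite.baseline, scen).ravel()

    regional_dt = local_dt.mean(axis=0)

    sxx = np.sum(local_dt**2, axis=1)
    if np.any(sxx == 0):
        raise ValueError("through-origin slope undefined: zero local warming series")
    sens = np.sum(d * local_dt, axis=1) / sxx
    resid = d - sens[:, None] * local_dt
    resid_var = np.sum(resid**2, axis=1) / max(s - 1, 1)

    rxx = float(np.sum(regional_dt**2))
    expo = local_dt @ regional_dt / rxx

    shape = baseline_field.grid_shape
    if shape is not None:
        sens = sens.reshape(shape)
        expo = expo.reshape(shape)
        resid_var = resid_var.reshape(shape)
    return ImpactSummary(
        sensitivity=sens,
        exposure=expo,
        vulnerability=sens * expo,
        fit_diagnostics=resid_var,
    )


# ---------------------------------------------------------------------------
# per-type responses and location indices


def _exp_model(x, a, b, c):
    dmat, dppt = x
    # clip the exponent so wild intermediate steps in the optimizer cannot
    # overflow; the data scale keeps converged fits far from the cap
    return a * np.exp(np.clip(b * dmat, -700.0, 700.0)) + c * dppt


def type_response(
    f_trajectory,
    dmat,
    dppt,
    class_name: str = "",
    alpha: float = 0.05,
) -> TypeResponse:
    """Fit and classify one type's frequency response to warming.

    Candidate forms (each with an additive linear precipitation term):
    linear and quadratic in warming via OLS, and a * exp(b * dMAT) via
    nonlinear least squares started from a log-linear fit.  The form with
    the lowest BIC (Gaussian, computed identically for all three) wins.
    Direction is ``hump`` when the winning quadratic has an interior
    maximum within the warming range, ``flat`` when no warming term is
    significant at ``alpha`` (or the trajectory is constant), otherwise
    ``decline``/``increase`` by the sign of the fitted warming trend.
    """
    f = np.asarray(f_trajectory, dtype=float)
    t = np.asarray(dmat, dtype=float)
    p = np.asarray(dppt, dtype=float)
    n = f.size
    if n < 6 or t.size != n or p.size != n:
        raise ValueError("need matching trajectories over at least 6 scenarios")

    if np.allclose(f, f[0]):
        return TypeResponse(class_name=class_name, chosen_form="linear",
                            coefficients={"intercept": float(f[0]), "mat": 0.0, "ppt": 0.0},
                            direction="flat")

    def gauss_bic(rss: float, k: int) -> float:
        rss = max(rss, 1e-300)
        return n * np.log(rss / n) + k * np.log(n)

    results: dict[str, dict] = {}

    lin = sm.OLS(f, sm.add_constant(np.column_stack([t, p]))).fit()
    results["linear"] = {
        "coefficients": {"intercept": lin.params[0], "mat": lin.params[1], "ppt": lin.params[2]},
        "bic": gauss_bic(float(lin.ssr), 3),
        "mat_pvalues": [float(lin.pvalues[1])],
    }

    quad = sm.OLS(f, sm.add_constant(np.column_stack([t, t**2, p]))).fit()
    results["quadratic"] = {
        "coefficients": {"intercept": quad.params[0], "mat": quad.params[1],
                         "mat2": quad.params[2], "ppt": quad.params[3]},
        "bic": gauss_bic(float(quad.ssr), 4),
        "mat_pvalues": [float(quad.pvalues[1]), float(quad.pvalues[2])],
    }

    # exponential: log-linear fit of the positive part seeds nonlinear LS
    try:
        pos = np.clip(f, 1e-8, None)
        loglin = np.polyfit(t, np.log(pos), 1)
        p0 = [float(np.exp(loglin[1])), float(loglin[0]), 0.0]
        with warnings.catch_warnings():
            # exact fits make the parameter covariance singular; harmless here
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, pcov = optimize.curve_fit(_exp_model, (t, p), f, p0=p0, maxfev=20000)
        rss = float(np.sum((f - _exp_model((t, p), *popt)) ** 2))
        se_b = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
        from scipy import stats

        p_b = 2 * stats.t.sf(abs(popt[1] / se_b), df=max(n - 3, 1)) if se_b > 0 else 0.0
        results["exponential"] = {
            "coefficients": {"a": float(popt[0]), "b": float(popt[1]), "ppt": float(popt[2])},
            "bic": gauss_bic(rss, 3),
            "mat_pvalues": [float(p_b)],
        }
    except (RuntimeError, ValueError):
        pass  # exponential fit may fail on ill-posed trajectories

    chosen = min(results, key=lambda k: results[k]["bic"])
    info = results[chosen]
    coefs = {k: float(v) for k, v in info["coefficients"].items()}

    if all(pv > alpha for pv in info["mat_pvalues"]):
        direction = "flat"
    elif chosen == "quadratic":
        b1, b2 = coefs["mat"], coefs["mat2"]
        direction = None
        if b2 < 0:
            vertex = -b1 / (2 * b2)
            if t.min() < vertex < t.max():
                direction = "hump"
        if direction is None:
            lo = b1 * t.min() + b2 * t.min() ** 2
            hi = b1 * t.max() + b2 * t.max() ** 2
            direction = "increase" if hi > lo else "decline"
    elif chosen == "exponential":
        direction = "decline" if coefs["b"] < 0 else "increase"
    else:
        direction = "decline" if coefs["mat"] < 0 else "increase"

    return TypeResponse(
        class_name=class_name,
        chosen_form=chosen,
        coefficients=coefs,
        direction=direction,
        bic={k: float(v["bic"]) for k, v in results.items()},
        p_values={k: float(min(v["mat_pvalues"])) for k, v in results.items()},
    )


def weighted_location(field: ProbabilityField, axis_raster: np.ndarray,
                      class_name: str) -> float:
    """Probability-weighted mean position of one type along a reporting axis."""
    axis = np.asarray(axis_raster, dtype=float).ravel()
    if axis.size != field.n_pixels:
        raise ValueError("axis raster is misaligned with the probability field")
    j = field.class_names.index(class_name)
    w = field.values[:, j]
    total = float(w.sum())
    if total <= 0:
        raise ValueError(f"class {class_name!r} has zero total probability")
    return float(np.dot(w, axis) / total)


def sensitivity_correlates(
    sensitivity: np.ndarray,
    predictor_samples: pd.DataFrame,
    drop: Sequence[str] = (),
) -> dict:
    """OLS of per-pixel sensitivity on baseline predictor values.

    Returns R-squared, coefficients, and the R-squared after refitting with
    the ``drop`` subset removed, plus partial-slope data (coefficient and
    standard error per predictor).

    Raises
    ------
    ValueError
        On a rank-deficient predictor matrix, naming collinear columns.
    """
    y = np.asarray(sensitivity, dtype=float).ravel()
    if len(predictor_samples) != y.size:
        raise ValueError("sensitivity raster and predictor samples are misaligned")
    names = list(predictor_samples.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 predictors")
    x = predictor_samples.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(x)), x]))
    if rank < x.shape[1] + 1:
        # name columns involved in the deficiency via the QR diagonal
        qr_r = np.linalg.qr(x - x.mean(axis=0), mode="r")
        diag = np.abs(np.diag(qr_r))
        bad = [names[i] for i in np.flatnonzero(diag < 1e-10 * diag.max())]
        raise ValueError(f"rank-deficient predictor matrix; collinear columns: {bad or names}")

    full = sm.OLS(y, sm.add_constant(x)).fit()
    report = {
        "r_squared": float(full.rsquared),
        "coefficients": {"intercept": float(full.params[0]),
                         **{n: float(b) for n, b in zip(names, full.params[1:])}},
        "std_errors": {n: float(se) for n, se in zip(names, full.bse[1:])},
        "p_values": {n: float(pv) for n, pv in zip(names, full.pvalues[1:])},
        "n": int(y.size),
    }
    if drop:
        keep = [n for n in names if n not in set(drop)]
        if not keep:
            raise ValueError("cannot drop every predictor")
        xr = predictor_samples[keep].to_numpy(dtype=float)
        reduced = sm.OLS(y, sm.add_constant(xr)).fit()
        report["dropped"] = list(drop)
        report["r_squared_dropped"] = float(reduced.rsquared)
    return report
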