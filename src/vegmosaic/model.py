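"""Multinomial probabilistic vegetation model (PVM).

The model assigns each pixel a vector of relative probabilities over K
vegetation types via a softmax over linear predictors in the expanded
feature basis.  Coefficients are estimated by maximum conditional likelihood
(optionally ridge-penalized); with no penalty and an intercept per class the
score equations force the fitted per-class probability sums to equal the
observed class counts, so modelled regional frequencies reproduce observed
frequencies exactly at the baseline.

Fitting runs a quasi-Newton (L-BFGS) pass on the negative log-likelihood
with analytic gradient, followed by full Newton steps to drive the score
equations to tight tolerance.  Probability computation is overflow-safe for
logits up to +-1e3 (softmax with max subtraction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import logsumexp

from .features import DesignMatrix, FeatureSpec, build_spec, expand

__all__ = [
    "PVMModel", "FitMetrics", "FitOptions", "ModelComparisonRow", "FitError",
    "fit", "predict_probabilities", "evaluate", "drop_one_importance",
    "random_assignment_baseline", "majority_baseline",
]

_FORMAT_VERSION = 1


class FitError(RuntimeError):
    """Raised when the likelihood optimization fails.

    Carries iteration diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class FitOptions:
    """Optimizer settings for :func:`fit`.

    ridge
        Quadratic penalty on non-intercept coefficients.  The default 1e-6
        survives quasi-separation (near-certain classes); use 0 for the
        exact column-sum constraint.
    tolerance
        Relative convergence tolerance on the objective.
    max_iterations
        Cap on quasi-Newton iterations.
    newton_polish
        Run exact Newton steps after L-BFGS to tighten the score equations.
    """

    ridge: float = 1e-6
    tolerance: float = 1e-8
    max_iterations: int = 500
    newton_polish: bool = True
    seed: int | None = None


@dataclass
class PVMModel:
    """Fitted multinomial model.

    coefficients has shape (K-1, M): one row per non-reference class over
    the feature basis; the reference class row is implicitly zero.
    """

    coefficients: np.ndarray
    class_names: list[str]
    reference_class: str
    feature_spec: FeatureSpec
    fit_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficient matrix must be finite")
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("class names must be unique")
        if self.reference_class not in self.class_names:
            raise ValueError("reference_class must be one of class_names")
        k, m = self.coefficients.shape
        if k != len(self.class_names) - 1:
            raise ValueError("coefficients must have K-1 rows")
        if m != self.feature_spec.n_columns:
            raise ValueError("coefficient columns must match the feature basis")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def n_parameters(self) -> int:
        return self.coefficients.size

    def logits(self, design: DesignMatrix | np.ndarray) -> np.ndarray:
        """N x K logit matrix with the reference class fixed at zero."""
        x = design.values if isinstance(design, DesignMatrix) else np.asarray(design)
        eta = np.zeros((x.shape[0], self.n_classes))
        ref = self.class_names.index(self.reference_class)
        others = [i for i in range(self.n_classes) if i != ref]
        eta[:, others] = x @ self.coefficients.T
        return eta

    def probabilities(self, design: DesignMatrix | np.ndarray) -> np.ndarray:
        eta = self.logits(design)
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        p /= p.sum(axis=1, keepdims=True)
        return p

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "coefficients": self.coefficients.tolist(),
            "class_names": list(self.class_names),
            "reference_class": self.reference_class,
            "feature_spec": self.feature_spec.to_dict(),
            "fit_metadata": _jsonable(self.fit_metadata),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PVMModel":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            class_names=list(d["class_names"]),
            reference_class=d["reference_class"],
            feature_spec=FeatureSpec.from_dict(d["feature_spec"]),
            fit_metadata=dict(d.get("fit_metadata", {})),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "PVMModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[k] = v
    return out


@dataclass
class FitMetrics:
    """Fit quality plus the reference baselines computed from class frequencies.

    baseline_random is the accuracy of assigning types at random in proportion
    to their observed frequencies (sum of squared frequencies);
    baseline_majority assigns every pixel the most common type;
    baseline_stochastic draws each pixel's type from the model's probability
    vector (closed form: mean model probability of the observed class).
    """

    proportion_correct: float
    average_max_probability: float
    baseline_random: float
    baseline_majority: float
    baseline_stochastic: float
    log_likelihood: float
    bic: float
    aic: float
    n_parameters: int
    n_observations: int

    def __post_init__(self) -> None:
        for name in ("proportion_correct", "average_max_probability",
                     "baseline_random", "baseline_majority", "baseline_stochastic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class ModelComparisonRow:
    """One row of a drop-one model comparison table."""

    model_label: str
    n_factors: int
    n_parameters: int
    delta_bic: float
    average_max_probability: float
    proportion_correct: float


def random_assignment_baseline(frequencies: Sequence[float]) -> float:
    """Expected accuracy of frequency-proportional random assignment: sum f_j^2."""
    f = np.asarray(frequencies, dtype=float)
    f = f / f.sum()
    return float(np.sum(f**2))


def majority_baseline(frequencies: Sequence[float]) -> float:
    """Accuracy of assigning every pixel the most common type: max f_j."""
    f = np.asarray(frequencies, dtype=float)
    f = f / f.sum()
    return float(f.max())


# ---------------------------------------------------------------------------
# likelihood machinery


def _softmax_from_free(x: np.ndarray, beta: np.ndarray, k: int) -> np.ndarray:
    """Probabilities with class 0 as reference; beta is (K-1, M)."""
    eta = np.zeros((x.shape[0], k))
    eta[:, 1:] = x @ beta.T
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _nll_grad(flat: np.ndarray, x: np.ndarray, onehot: np.ndarray,
              ridge: float, penalty_mask: np.ndarray):
    n, m = x.shape
    k = onehot.shape[1]
    beta = flat.reshape(k - 1, m)
    eta = np.zeros((n, k))
    eta[:, 1:] = x @ beta.T
    lse = logsumexp(eta, axis=1)
    ll = float(np.sum(eta[onehot.astype(bool)]) - lse.sum())
    p = np.exp(eta - lse[:, None])
    resid = p[:, 1:] - onehot[:, 1:]
    grad = resid.T @ x
    nll = -ll
    if ridge > 0:
        nll += 0.5 * ridge * float(np.sum((beta * penalty_mask) ** 2))
        grad = grad + ridge * beta * penalty_mask
    return nll, grad.ravel()


def _hessian(beta: np.ndarray, x: np.ndarray, k: int, ridge: float,
             penalty_mask: np.ndarray) -> np.ndarray:
    """Full Hessian of the penalized NLL, shape ((K-1)M, (K-1)M)."""
    n, m = x.shape
    p = _softmax_from_free(x, beta, k)
    h = np.empty(((k - 1) * m, (k - 1) * m))
    for a in range(1, k):
        for b in range(a, k):
            w = p[:, a] * ((1.0 if a == b else 0.0) - p[:, b])
            block = (x * w[:, None]).T @ x
            ia, ib = (a - 1) * m, (b - 1) * m
            h[ia:ia + m, ib:ib + m] = block
            if a != b:
                h[ib:ib + m, ia:ia + m] = block.T
    if ridge > 0:
        h[np.diag_indices_from(h)] += ridge * penalty_mask.ravel()
    return h


def _nll_only(beta, x, onehot, ridge, penalty_mask):
    return _nll_grad(beta.ravel(), x, onehot, ridge, penalty_mask)[0]


def fit(design: DesignMatrix, labels, options: FitOptions | None = None,
        class_names: Sequence[str] | None = None) -> PVMModel:
    """Fit the multinomial model by (penalized) maximum conditional likelihood.

    Parameters
    ----------
    design
        Expanded design matrix (first column must be the intercept).
    labels
        Integer class indices (0..K-1) or strings; every class must occur
        at least once.
    options
        Optimizer settings; see :class:`FitOptions`.
    class_names
        Optional explicit class naming.  With integer labels and no names,
        classes are named ``type_00`` ... in index order; the reference
        class is the first in sorted label order.

    Raises
    ------
    FitError
        On non-convergence (diagnostics attached), or on apparent complete
        separation with ridge = 0 (advises a positive ridge).
    """
    options = options or FitOptions()
    x = np.asarray(design.values, dtype=float)
    n, m = x.shape

    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("design rows must match labels")
    uniq = np.unique(labels)
    if class_names is None:
        if labels.dtype.kind in "iu":
            k = int(labels.max()) + 1
            class_names = [f"type_{i:02d}" for i in range(k)]
            idx = labels.astype(int)
        else:
            class_names = [str(u) for u in uniq]
            lookup = {u: i for i, u in enumerate(uniq)}
            idx = np.array([lookup[v] for v in labels])
            k = len(class_names)
    else:
        class_names = list(class_names)
        lookup = {c: i for i, c in enumerate(class_names)}
        if labels.dtype.kind in "iu":
            idx = labels.astype(int)
        else:
            idx = np.array([lookup[v] for v in labels])
        k = len(class_names)
    counts = np.bincount(idx, minlength=k)
    if np.any(counts == 0):
        empty = [class_names[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"every class needs at least one observation; empty: {empty}")

    onehot = np.zeros((n, k))
    onehot[np.arange(n), idx] = 1.0
    # penalize everything except intercepts
    penalty_mask = np.ones((k - 1, m))
    intercept_col = design.column_names.index("intercept") if "intercept" in design.column_names else 0
    penalty_mask[:, intercept_col] = 0.0

    beta0 = np.zeros((k - 1) * m)
    res = optimize.minimize(
        _nll_grad, beta0, args=(x, onehot, options.ridge, penalty_mask),
        jac=True, method="L-BFGS-B",
        options={
            "maxiter": options.max_iterations,
            "ftol": options.tolerance * 1e-4,
            "gtol": 1e-9 * n,
            "maxcor": 20,
        },
    )
    beta = res.x.reshape(k - 1, m)
    n_iter = int(res.nit)
    nll = float(res.fun)

    # Newton polish: a handful of exact steps drives the score equations
    # (column sums, with ridge = 0) to near machine precision.
    if options.newton_polish and (k - 1) * m <= 2000:
        for _ in range(30):
            cur, grad = _nll_grad(beta.ravel(), x, onehot, options.ridge, penalty_mask)
            gmax = np.abs(grad).max()
            if gmax < 1e-9 * n:
                break
            h = _hessian(beta, x, k, options.ridge, penalty_mask)
            try:
                step = np.linalg.solve(h + 1e-10 * n * np.eye(h.shape[0]), grad)
            except np.linalg.LinAlgError:
                break
            t = 1.0
            for _ls in range(40):
                trial = beta - t * step.reshape(k - 1, m)
                if _nll_only(trial, x, onehot, options.ridge, penalty_mask) <= cur + 1e-12 * abs(cur):
                    break
                t *= 0.5
            else:
                break
            beta = beta - t * step.reshape(k - 1, m)
            n_iter += 1
        nll = _nll_only(beta, x, onehot, options.ridge, penalty_mask)

    _, grad = _nll_grad(beta.ravel(), x, onehot, options.ridge, penalty_mask)
    gmax = float(np.abs(grad).max())
    converged = gmax < 1e-6 * n
    diagnostics = {
        "iterations": n_iter,
        "max_abs_gradient": gmax,
        "objective": nll,
        "lbfgs_status": str(res.message),
    }
    # with no penalty, separation sends coefficients to infinity; the softmax
    # saturates (logit 30 ~ probability 1 - 1e-13) so the gradient can look
    # converged — flag runaway coefficients explicitly
    if options.ridge == 0 and (np.abs(beta).max() > 30.0 or nll < 1e-4 * n):
        raise FitError(
            "likelihood appears unbounded (complete or quasi-complete "
            "separation); refit with a positive ridge penalty",
            diagnostics,
        )
    if not converged:
        raise FitError(
            f"optimizer did not converge within {options.max_iterations} iterations "
            f"(max |gradient| = {gmax:.3e})",
            diagnostics,
        )

    ll = -nll
    if options.ridge > 0:
        ll = ll + 0.5 * options.ridge * float(np.sum((beta * penalty_mask) ** 2))
    meta = {
        "n_train": n,
        "log_likelihood": float(ll),
        "converged": bool(converged),
        "ridge": options.ridge,
        "iterations": n_iter,
        "max_abs_gradient": gmax,
        "seed": options.seed,
    }
    return PVMModel(
        coefficients=beta,
        class_names=class_names,
        reference_class=class_names[0],
        feature_spec=design.spec,
        fit_metadata=meta,
    )


def predict_probabilities(model: PVMModel, design: DesignMatrix):
    """Per-pixel probability vectors for a design matrix built from the model's spec."""
    from .projection import ProbabilityField

    if isinstance(design, DesignMatrix):
        if design.spec.predictor_names != model.feature_spec.predictor_names or \
           design.spec.n_columns != model.feature_spec.n_columns:
            raise ValueError("design matrix was not built from the model's feature spec")
    p = model.probabilities(design)
    return ProbabilityField(values=p, class_names=list(model.class_names))


def evaluate(model: PVMModel, design: DesignMatrix, labels) -> FitMetrics:
    """Fit metrics and frequency-based baselines on labelled data."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty input")
    if labels.dtype.kind in "iu":
        idx = labels.astype(int)
    else:
        lookup = {c: i for i, c in enumerate(model.class_names)}
        idx = np.array([lookup[v] for v in labels])
    p = model.probabilities(design)
    n = p.shape[0]
    k = p.shape[1]

    vmax = np.argmax(p, axis=1)  # ties -> lowest class index
    proportion_correct = float(np.mean(vmax == idx))
    average_max_probability = float(p.max(axis=1).mean())
    f = np.bincount(idx, minlength=k) / n
    p_obs = p[np.arange(n), idx]
    ll = float(np.sum(np.log(np.clip(p_obs, 1e-300, None))))
    n_params = model.n_parameters
    return FitMetrics(
        proportion_correct=proportion_correct,
        average_max_probability=average_max_probability,
        baseline_random=random_assignment_baseline(f),
        baseline_majority=majority_baseline(f),
        baseline_stochastic=float(p_obs.mean()),
        log_likelihood=ll,
        bic=-2.0 * ll + n_params * np.log(n),
        aic=-2.0 * ll + 2.0 * n_params,
        n_parameters=n_params,
        n_observations=n,
    )


def drop_one_importance(
    samples: pd.DataFrame,
    labels,
    predictor_names: Sequence[str],
    options: FitOptions | None = None,
    *,
    climate_predictors: Sequence[str] | None = None,
    fixed_predictors: Sequence[str] | None = None,
    class_names: Sequence[str] | None = None,
) -> list[ModelComparisonRow]:
    """Rank predictors by the BIC cost of removing them.

    Fits the full model plus one reduced model per removed predictor (refit
    from scratch on the reduced basis), and, when predictor groups are given,
    climate-only and fixed-only models.  delta_bic is BIC(model) - BIC(full),
    so informative predictors have large positive values and removing an
    irrelevant predictor yields a negative value at large n.  Rows are the
    full model first, then drop-one rows sorted by decreasing delta_bic,
    then the group rows.
    """
    predictor_names = list(predictor_names)
    if len(predictor_names) < 2:
        raise ValueError("drop-one comparison needs at least 2 predictors")
    options = options or FitOptions()

    def fit_subset(names: Sequence[str]):
        spec = build_spec(names, samples)
        design = expand(spec, samples)
        model = fit(design, labels, options, class_names=class_names)
        metrics = evaluate(model, design, labels)
        return model, metrics

    _, full_metrics = fit_subset(predictor_names)

    def row(label: str, names: Sequence[str]) -> ModelComparisonRow:
        try:
            _, metrics = fit_subset(names)
        except FitError as err:
            raise FitError(f"fit failed for model {label!r}: {err}", err.diagnostics) from err
        return ModelComparisonRow(
            model_label=label,
            n_factors=len(names),
            n_parameters=metrics.n_parameters,
            delta_bic=float(metrics.bic - full_metrics.bic),
            average_max_probability=metrics.average_max_probability,
            proportion_correct=metrics.proportion_correct,
        )

    rows = [ModelComparisonRow(
        model_label="full",
        n_factors=len(predictor_names),
        n_parameters=full_metrics.n_parameters,
        delta_bic=0.0,
        average_max_probability=full_metrics.average_max_probability,
        proportion_correct=full_metrics.proportion_correct,
    )]
    dropped = [row(f"-{name}", [p for p in predictor_names if p != name])
               for name in predictor_names]
    rows += sorted(dropped, key=lambda r: -r.delta_bic)
    if climate_predictors:
        rows.append(row("climate only", [p for p in predictor_names if p in set(climate_predictors)]))
    if fixed_predictors:
        rows.append(row("fixed only", [p for p in predictor_names if p in set(fixed_predictors)]))
    return rows


def comparison_table(rows: Sequence[ModelComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a DataFrame (CSV-ready, one row per model)."""
    return pd.DataFrame(
        {
            "model": [r.model_label for r in rows],
            "n_factors": [r.n_factors for r in rows],
            "n_parameters": [r.n_parameters for r in rows],
            "delta_bic": [r.delta_bic for r in rows],
            "average_max_probability": [r.average_max_probability for r in rows],
            "proportion_correct": [r.proportion_correct for r in rows],
        }
    )
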