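"""Synthetic raster landscapes, truth models, and climate-scenario ensembles.

Everything downstream of the raw rasters — feature expansion, model fitting,
projection, impact decomposition — is exercised against landscapes built
here.  The generator emulates the statistical structure of a coastal
Mediterranean-climate study region:

* spatially autocorrelated predictor fields (Gaussian-smoothed white noise
  mixed through a Cholesky factor of a target correlation matrix, plus
  deterministic coast-to-interior and elevation gradients), with a strong
  negative precipitation-water-deficit cross-correlation by default;
* vegetation labels sampled pixelwise from a known multinomial probability
  surface, giving a ground truth for parameter-recovery tests;
* scenario ensembles in which summer/winter warming and water-deficit
  increases are strongly coupled to the regional mean-annual-temperature
  (MAT) change while precipitation change is independent of it, and local
  change fields vary smoothly around regional means.

MAT is operationalized as (DJF + JJA) / 2 on the synthetic grid; this is a
deliberate proxy for a mean over monthly minima and maxima, which the
synthetic grid does not carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .features import FeatureSpec
from .model import PVMModel

__all__ = [
    "PREDICTOR_NAMES", "CLIMATE_PREDICTORS", "FIXED_PREDICTORS",
    "LandscapeConfig", "EnvironmentalStack", "ClimateScenario",
    "ScenarioSuite", "VegetationMap",
    "generate_environment", "generate_true_model", "sample_vegetation",
    "generate_scenarios",
]

#: canonical predictor set: four climate layers + three fixed layers
CLIMATE_PREDICTORS = ("jja", "djf", "ppt", "cwd")
FIXED_PREDICTORS = ("soil_depth", "wind", "march_radiation")
PREDICTOR_NAMES = CLIMATE_PREDICTORS + FIXED_PREDICTORS

#: per-layer units and marginal (mean, sd) used to scale standardized fields
LAYER_UNITS = {
    "jja": "degC", "djf": "degC", "ppt": "mm", "cwd": "mm",
    "soil_depth": "m", "wind": "m s-1", "march_radiation": "Wh m-2",
}
_LAYER_SCALES = {
    "jja": (26.0, 4.0),
    "djf": (5.0, 2.0),
    "ppt": (800.0, 250.0),
    "cwd": (800.0, 150.0),
    "soil_depth": (0.9, 0.45),
    "wind": (4.2, 1.3),
    "march_radiation": (3475.0, 700.0),
}
_LAYER_FLOORS = {"ppt": 50.0, "cwd": 0.0, "soil_depth": 0.1,
                 "wind": 0.5, "march_radiation": 400.0}

# how strongly each layer loads on the (coast-distance, elevation) gradients:
# summers hotter and drier inland, winters milder at the coast, wetter uphill
_GRADIENT_LOADINGS = {
    "jja": (1.0, -0.3),
    "djf": (-0.8, -0.6),
    "ppt": (-0.6, 0.8),
    "cwd": (0.9, -0.5),
    "soil_depth": (0.2, -0.8),
    "wind": (-0.9, 0.5),
    "march_radiation": (0.3, 0.0),
}

_DEFAULT_TARGETS = (
    ("ppt", "cwd", -0.7),
    ("jja", "cwd", 0.62),
    ("jja", "djf", -0.61),
    ("jja", "ppt", -0.5),
)


@dataclass(frozen=True)
class LandscapeConfig:
    """Configuration of the synthetic landscape generator.

    cross_correlation_targets are (layer_a, layer_b, Pearson r) triples the
    realized fields must match within +-0.1; all |r| must stay below the
    collinearity ceiling of 0.8.  The grid must provide at least 50 pixels
    per vegetation type.
    """

    grid_rows: int = 120
    grid_cols: int = 120
    n_types: int = 8
    predictor_names: tuple[str, ...] = PREDICTOR_NAMES
    cross_correlation_targets: tuple[tuple[str, str, float], ...] = _DEFAULT_TARGETS
    autocorrelation_length: float = 6.0
    gradient_weight: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < self.n_types * 50:
            raise ValueError(
                f"grid too small: {self.grid_rows}x{self.grid_cols} pixels for "
                f"{self.n_types} types (need >= 50 per type)"
            )
        known = set(self.predictor_names)
        for a, b, r in self.cross_correlation_targets:
            if a not in known or b not in known:
                raise ValueError(f"correlation target names unknown layer: ({a}, {b})")
            if abs(r) >= 0.8:
                raise ValueError(
                    f"|target r| must stay below the collinearity ceiling 0.8: "
                    f"({a}, {b}, {r})"
                )
        if not 0.0 <= self.gradient_weight < 0.5:
            raise ValueError("gradient_weight must lie in [0, 0.5)")

    @property
    def n_pixels(self) -> int:
        return self.grid_rows * self.grid_cols


@dataclass
class EnvironmentalStack:
    """Named, co-registered raster layers for one climate state.

    ``elevation`` (m) and ``coast_distance`` (km) are reporting axes only and
    are never used as predictors.
    """

    layers: dict[str, np.ndarray]
    elevation: np.ndarray
    coast_distance: np.ndarray
    units: Mapping[str, str] = field(default_factory=lambda: dict(LAYER_UNITS))

    def __post_init__(self) -> None:
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"all layers must share one shape, got {shapes}")
        for name, arr in self.layers.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"layer {name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def n_pixels(self) -> int:
        r, c = self.shape
        return r * c

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.layers.keys())

    def samples(self, names: Sequence[str] | None = None) -> "pd.DataFrame":
        """Flatten layers (row-major) into a pixels x predictors table."""
        import pandas as pd

        names = tuple(names) if names is not None else self.predictor_names
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"stack is missing layers: {missing}")
        return pd.DataFrame({n: self.layers[n].ravel() for n in names})

    def copy(self) -> "EnvironmentalStack":
        return EnvironmentalStack(
            layers={k: v.copy() for k, v in self.layers.items()},
            elevation=self.elevation.copy(),
            coast_distance=self.coast_distance.copy(),
            units=dict(self.units),
        )


@dataclass
class ClimateScenario:
    """One climate state: perturbed climate layers over unchanged fixed layers."""

    label: str
    stack: EnvironmentalStack
    delta_mat: float
    delta_ppt_percent: float


@dataclass
class ScenarioSuite:
    """Ordered scenario ensemble with its regional change summaries."""

    baseline: EnvironmentalStack
    scenarios: list[ClimateScenario]
    exposure_pattern: np.ndarray  # zero-mean spatial pattern scaling local change

    @property
    def delta_mat(self) -> np.ndarray:
        return np.array([s.delta_mat for s in self.scenarios])

    @property
    def delta_ppt_percent(self) -> np.ndarray:
        return np.array([s.delta_ppt_percent for s in self.scenarios])

    def __len__(self) -> int:
        return len(self.scenarios)


@dataclass
class VegetationMap:
    """Categorical vegetation raster with class table and analysis mask."""

    labels: np.ndarray
    class_names: list[str]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.mask is None:
            self.mask = np.ones(self.labels.shape, dtype=bool)
        present = np.unique(self.labels[self.mask])
        if present.size and (present.min() < 0 or present.max() >= len(self.class_names)):
            raise ValueError("label values must index into class_names")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def frequencies(self) -> np.ndarray:
        lab = self.labels[self.mask]
        return np.bincount(lab.ravel(), minlength=self.n_classes) / lab.size


# ---------------------------------------------------------------------------
# field construction


def _smooth_standard_field(rng: np.random.Generator, shape, length: float) -> np.ndarray:
    """Gaussian-smoothed white noise, standardized to mean 0 / sd 1."""
    z = gaussian_filter(rng.standard_normal(shape), sigma=length, mode="reflect")
    z -= z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _correlation_matrix(config: LandscapeConfig) -> np.ndarray:
    names = config.predictor_names
    ix = {n: i for i, n in enumerate(names)}
    c = np.eye(len(names))
    for a, b, r in config.cross_correlation_targets:
        c[ix[a], ix[b]] = c[ix[b], ix[a]] = r
    return c


def _cholesky_or_explain(c: np.ndarray, config: LandscapeConfig) -> np.ndarray:
    try:
        return np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        # identify targets whose removal restores positive-definiteness
        offenders = []
        targets = list(config.cross_correlation_targets)
        for i, (a, b, _r) in enumerate(targets):
            reduced = replace(config, cross_correlation_targets=tuple(
                t for j, t in enumerate(targets) if j != i))
            try:
                np.linalg.cholesky(_correlation_matrix(reduced))
            except np.linalg.LinAlgError:
                continue
            offenders.append((a, b))
        detail = (f"; removing any one of {offenders} would fix it"
                  if offenders else "")
        raise ValueError(
            "cross_correlation_targets do not form a positive-definite "
            f"correlation structure{detail}"
        )


def generate_environment(config: LandscapeConfig) -> EnvironmentalStack:
    """Generate a deterministic, spatially autocorrelated predictor stack.

    Independent smoothed-noise fields are mixed through the Cholesky factor
    of the target correlation matrix, lightly blended with deterministic
    coast-to-interior and elevation gradients, then scaled to each layer's
    physical units.  Realized pairwise correlations land within +-0.1 of the
    configured targets; identical config and seed give bitwise-identical
    stacks.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    names = config.predictor_names

    corr = _correlation_matrix(config)
    chol = _cholesky_or_explain(corr, config)

    raw = np.stack([_smooth_standard_field(rng, shape, config.autocorrelation_length)
                    for _ in names])
    mixed = np.einsum("kl,lij->kij", chol, raw)

    # geography: coast on the west edge (column 0), elevation rising inland
    cols = np.linspace(0.0, 1.0, config.grid_cols)
    coast_base = np.broadcast_to(cols, shape).copy()
    coast_noise = _smooth_standard_field(rng, shape, config.autocorrelation_length)
    elev_noise = _smooth_standard_field(rng, shape, config.autocorrelation_length)
    coast_distance = 80.0 * np.clip(coast_base + 0.05 * coast_noise, 0.0, None)  # km
    elevation = np.clip(900.0 * (0.25 + 0.5 * coast_base + 0.35 * elev_noise), 0.0, None)

    def standardized(a: np.ndarray) -> np.ndarray:
        a = a - a.mean()
        return a / a.std()

    g_coast = standardized(coast_distance)
    g_elev = standardized(elevation)

    w = config.gradient_weight
    layers = {}
    for k, name in enumerate(names):
        z = mixed[k]
        if w > 0 and name in _GRADIENT_LOADINGS:
            a, b = _GRADIENT_LOADINGS[name]
            g = a * g_coast + b * g_elev
            gs = g.std()
            if gs > 0:
                z = np.sqrt(1.0 - w**2) * z + w * (g / gs)
        mu, sd = _LAYER_SCALES.get(name, (0.0, 1.0))
        vals = mu + sd * z
        if name in _LAYER_FLOORS:
            vals = np.maximum(vals, _LAYER_FLOORS[name])
        layers[name] = vals
    return EnvironmentalStack(layers=layers, elevation=elevation,
                              coast_distance=coast_distance)


def generate_true_model(
    n_types: int,
    feature_spec: FeatureSpec,
    coefficient_scale: float = 0.3,
    seed: int = 0,
    *,
    class_names: Sequence[str] | None = None,
) -> PVMModel:
    """Draw a ground-truth coefficient matrix for recovery experiments.

    Coefficients for the K-1 non-reference classes are drawn iid from
    N(0, coefficient_scale^2) over the full feature basis (reference class
    fixed at zero).  The default scale 0.3 yields mid-range assignment
    confidence on standardized predictors — most pixels plausible for
    several types, some near-certain — rather than a degenerate one-type-
    per-pixel landscape.  Logits are capped at magnitude 50 when sampling
    extreme surfaces, which already saturates the softmax.
    """
    if n_types < 2:
        raise ValueError("need at least 2 vegetation types")
    rng = np.random.default_rng(seed)
    m = feature_spec.n_columns
    coefs = rng.normal(0.0, coefficient_scale, size=(n_types - 1, m)) \
        if coefficient_scale > 0 else np.zeros((n_types - 1, m))
    names = list(class_names) if class_names is not None else \
        [f"type_{i:02d}" for i in range(n_types)]
    return PVMModel(
        coefficients=coefs,
        class_names=names,
        reference_class=names[0],
        feature_spec=feature_spec,
        fit_metadata={"source": "synthetic_truth", "seed": seed,
                      "coefficient_scale": coefficient_scale},
    )


def sample_vegetation(env: EnvironmentalStack, truth: PVMModel, seed: int = 0) -> VegetationMap:
    """Sample a vegetation map pixelwise from a truth model's probabilities."""
    from .features import expand

    design = expand(truth.feature_spec, env.samples(truth.feature_spec.predictor_names))
    p = truth.probabilities(design)
    rng = np.random.default_rng(seed)
    u = rng.random(p.shape[0])
    cum = np.cumsum(p, axis=1)
    labels = (u[:, None] > cum).sum(axis=1).astype(np.int64)
    labels = labels.reshape(env.shape)
    return VegetationMap(labels=labels, class_names=list(truth.class_names))


def generate_scenarios(
    baseline: EnvironmentalStack,
    n_scenarios: int = 54,
    dmat_range: tuple[float, float] = (0.69, 5.67),
    dppt_range: tuple[float, float] = (-23.0, 38.0),
    coupling: float = 0.95,
    spatial_amplitude: float = 0.2,
    autocorrelation_length: float = 10.0,
    seed: int = 0,
) -> ScenarioSuite:
    """Build an ensemble of future climate stacks around a baseline.

    Regional mean warming (delta MAT, degC) spans ``dmat_range`` with the
    endpoints included by construction; precipitation change (%) is uniform
    over ``dppt_range`` and statistically independent of warming.  Summer
    (JJA) and winter (DJF) warming are linear in delta MAT with JJA slightly
    steeper, and water deficit (CWD) increases with warming but responds
    weakly (negatively) to precipitation, so it rises in almost all
    scenarios.  ``coupling`` in (0, 1] sets the target ensemble correlation
    of these drivers with delta MAT.  Per-pixel change fields scale the
    regional change by (1 + spatial_amplitude * g) for a smooth zero-mean
    pattern g with max |g| = 1, giving local/regional warming slopes in
    [1 - a, 1 + a] (default [0.8, 1.2]).  Fixed layers are shared with the
    baseline unchanged.
    """
    if n_scenarios < 2:
        raise ValueError("need at least 2 scenarios")
    if not dmat_range[0] < dmat_range[1]:
        raise ValueError("empty dmat_range")
    if not dppt_range[0] < dppt_range[1]:
        raise ValueError("empty dppt_range")
    if coupling <= 0:
        raise ValueError("coupling must be positive")
    coupling = min(float(coupling), 0.999)
    if spatial_amplitude < 0:
        raise ValueError("spatial_amplitude must be nonnegative")

    rng = np.random.default_rng(seed)
    dmat = np.linspace(dmat_range[0], dmat_range[1], n_scenarios)
    dppt = rng.uniform(dppt_range[0], dppt_range[1], size=n_scenarios)

    # JJA warms slightly faster than DJF; the split is antisymmetric so the
    # two always average exactly to the nominal regional delta MAT
    gamma = 0.15
    noise_scale = dmat.std() * np.sqrt(1.0 / coupling**2 - 1.0)
    eps = rng.normal(0.0, noise_scale, size=n_scenarios)
    djja = (1.0 + gamma) * dmat + eps
    ddjf = (1.0 - gamma) * dmat - eps

    ppt_mean = float(baseline.layers["ppt"].mean())
    dppt_mm = dppt / 100.0 * ppt_mean
    # ~31 mm water deficit per degC of warming, weak negative PPT response
    cwd_noise = rng.normal(0.0, 5.0, size=n_scenarios)
    dcwd = 31.0 * dmat - 0.10 * dppt_mm + cwd_noise

    shape = baseline.shape
    if spatial_amplitude > 0:
        def pattern() -> np.ndarray:
            g = _smooth_standard_field(rng, shape, autocorrelation_length)
            g -= g.mean()
            return g / np.abs(g).max()
        g_mat = pattern()
        g_ppt = pattern()
        g_cwd = pattern()
    else:
        g_mat = g_ppt = g_cwd = np.zeros(shape)

    a = spatial_amplitude
    scenarios = []
    for s in range(n_scenarios):
        local = 1.0 + a * g_mat
        layers = {
            "jja": baseline.layers["jja"] + djja[s] * local,
            "djf": baseline.layers["djf"] + ddjf[s] * local,
            "ppt": np.maximum(
                baseline.layers["ppt"] * (1.0 + dppt[s] / 100.0 * (1.0 + a * g_ppt)),
                0.0),
            "cwd": np.maximum(baseline.layers["cwd"] + dcwd[s] * (1.0 + a * g_cwd), 0.0),
        }
        for name in baseline.predictor_names:
            if name not in layers:
                layers[name] = baseline.layers[name].copy()
        stack = EnvironmentalStack(
            layers=layers,
            elevation=baseline.elevation.copy(),
            coast_distance=baseline.coast_distance.copy(),
            units=dict(baseline.units),
        )
        scenarios.append(ClimateScenario(
            label=f"S{s:02d}_dMAT{dmat[s]:+.2f}C_dPPT{dppt[s]:+.0f}pct",
            stack=stack,
            delta_mat=float(dmat[s]),
            delta_ppt_percent=float(dppt[s]),
        ))
    return ScenarioSuite(baseline=baseline, scenarios=scenarios,
                         exposure_pattern=g_mat)
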