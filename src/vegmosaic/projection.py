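"""Projection of a fitted model onto climate stacks.

Projection applies the training-time feature scaling to a (baseline or
scenario) predictor stack and evaluates the fitted softmax, yielding an
N-pixel x K-type matrix of relative probabilities.  Extrapolation beyond
the training range is permitted — future climates routinely exceed it —
but the fraction of out-of-range ("non-analog") pixels is reported per
predictor rather than masked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .features import expand
from .landscape import ClimateScenario, EnvironmentalStack
from .model import PVMModel

__all__ = [
    "ProbabilityField", "AssignmentMap", "FrequencyVector",
    "project", "assignment", "frequency_vector", "type_cooccurrence",
]


@dataclass
class ProbabilityField:
    """N x K matrix of relative probabilities; each row sums to one."""

    values: np.ndarray
    class_names: list[str]
    grid_shape: tuple[int, int] | None = None
    extrapolation_fraction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("probability field must be a 2-D (pixels x types) matrix")
        if self.values.shape[1] != len(self.class_names):
            raise ValueError("column count must match class_names")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.values.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("every probability row must sum to 1 within 1e-9")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def raster(self, class_name: str) -> np.ndarray:
        """One class's probability reshaped to the grid (requires grid_shape)."""
        if self.grid_shape is None:
            raise ValueError("field carries no grid shape")
        j = self.class_names.index(class_name)
        return self.values[:, j].reshape(self.grid_shape)


@dataclass
class AssignmentMap:
    """Maximum-probability type per pixel and the winning probability."""

    vmax: np.ndarray
    pmax: np.ndarray
    class_names: list[str]
    pmax_histogram: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        k = len(self.class_names)
        if self.pmax.size and (self.pmax.min() < 1.0 / k - 1e-12 or self.pmax.max() > 1 + 1e-12):
            raise ValueError("pmax must lie in [1/K, 1]")


@dataclass
class FrequencyVector:
    """Regional relative frequencies of the K types (sums to one)."""

    f: np.ndarray
    class_names: list[str]
    n_pixels: int
    provenance: str = "modelled"

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if abs(self.f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1 within 1e-9")


def project(model: PVMModel, target: ClimateScenario | EnvironmentalStack,
            block_size: int = 200_000) -> ProbabilityField:
    """Project the model onto a climate stack.

    Probabilities are computed with the training-time scaling stored in the
    model's feature spec; output is identical regardless of ``block_size``
    (row blocks only bound peak memory).  The returned field reports, per
    predictor, the fraction of pixels whose z-score falls outside the
    training range (non-analog conditions).

    Raises
    ------
    KeyError
        If the stack is missing a predictor layer.
    """
    stack = target.stack if isinstance(target, ClimateScenario) else target
    spec = model.feature_spec
    samples = stack.samples(spec.predictor_names)

    extrap = {}
    for name in spec.predictor_names:
        z = (samples[name].to_numpy() - spec.means[name]) / spec.sds[name]
        lo, hi = spec.z_ranges.get(name, (-np.inf, np.inf))
        extrap[name] = float(np.mean((z < lo) | (z > hi)))

    n = len(samples)
    blocks = []
    for start in range(0, n, block_size):
        chunk = samples.iloc[start:start + block_size]
        design = expand(spec, chunk)
        blocks.append(model.probabilities(design))
    values = np.vstack(blocks)
    return ProbabilityField(
        values=values,
        class_names=list(model.class_names),
        grid_shape=stack.shape,
        extrapolation_fraction=extrap,
    )


def assignment(field: ProbabilityField, histogram_bins: int = 50) -> AssignmentMap:
    """Maximum-probability assignment with confidence (ties -> lowest index).

    Also returns the histogram of winning probabilities, whose bimodality
    distinguishes near-certain pixels from pixels plausible for several
    types.
    """
    vmax = np.argmax(field.values, axis=1)
    pmax = field.values.max(axis=1)
    counts, edges = np.histogram(pmax, bins=histogram_bins, range=(0.0, 1.0))
    if field.grid_shape is not None:
        vmax = vmax.reshape(field.grid_shape)
        pmax = pmax.reshape(field.grid_shape)
    return AssignmentMap(vmax=vmax, pmax=pmax,
                         class_names=list(field.class_names),
                         pmax_histogram=(counts, edges))


def frequency_vector(field: ProbabilityField, provenance: str = "modelled") -> FrequencyVector:
    """Regional frequency of each type: the column mean of the probability matrix."""
    f = field.values.mean(axis=0)
    return FrequencyVector(f=f, class_names=list(field.class_names),
                           n_pixels=field.n_pixels, provenance=provenance)


def type_cooccurrence(field: ProbabilityField) -> np.ndarray:
    """Pearson correlations between per-type probability columns.

    Symmetric with unit diagonal; K(K-1)/2 unordered pairs.  Columns with
    zero variance yield NaN correlations (reported, with a warning).
    """
    if field.n_pixels < 3:
        raise ValueError("co-occurrence needs at least 3 pixels")
    x = field.values
    sd = x.std(axis=0)
    degenerate = np.flatnonzero(sd == 0)
    if degenerate.size:
        warnings.warn(
            "zero-variance probability columns; correlations undefined for "
            f"classes {[field.class_names[i] for i in degenerate]}",
            RuntimeWarning,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(c, 1.0)
    c[degenerate, :] = np.nan
    c[:, degenerate] = np.nan
    return c
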