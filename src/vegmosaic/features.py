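"""Feature basis for the vegetation model.

Raw predictor values are z-scored against scaling captured from the training
data, then expanded into an intercept, linear, quadratic, and pairwise
interaction basis.  The scaling lives in the :class:`FeatureSpec` so that
projections onto future climates reuse the training-time standardization —
essential because future climate layers routinely exceed the training range
and the model must extrapolate on a consistent scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureSpec", "DesignMatrix", "build_spec", "expand"]

_FORMAT_VERSION = 1


def _interaction_pairs(names: Sequence[str]) -> list[tuple[str, str]]:
    """Unordered predictor pairs in lexicographic name order."""
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = sorted((names[i], names[j]))
            pairs.append((a, b))
    return sorted(pairs)


@dataclass(frozen=True)
class FeatureSpec:
    """Basis definition plus the training-data scaling needed to apply it.

    Parameters
    ----------
    predictor_names
        Ordered predictor names.
    include_quadratic, include_interactions
        Whether squared terms and pairwise products are part of the basis.
    means, sds
        Per-predictor mean and standard deviation from the training sample;
        every predictor is z-scored with these before squaring/multiplying.
    z_ranges
        Per-predictor (min, max) of training z-scores, used at projection
        time to flag non-analog (out-of-training-range) pixels.
    """

    predictor_names: tuple[str, ...]
    include_quadratic: bool = True
    include_interactions: bool = True
    means: Mapping[str, float] = field(default_factory=dict)
    sds: Mapping[str, float] = field(default_factory=dict)
    z_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(self.predictor_names)
        if len(set(names)) != len(names):
            raise ValueError("predictor names must be unique")
        for name, sd in self.sds.items():
            if not sd > 0:
                raise ValueError(f"scaling sd must be positive for predictor {name!r}")
        object.__setattr__(self, "predictor_names", names)

    @property
    def column_names(self) -> list[str]:
        names = ["intercept"]
        names += list(self.predictor_names)
        if self.include_quadratic:
            names += [f"{p}^2" for p in self.predictor_names]
        if self.include_interactions:
            names += [f"{a}:{b}" for a, b in _interaction_pairs(self.predictor_names)]
        return names

    @property
    def n_columns(self) -> int:
        p = len(self.predictor_names)
        n = 1 + p
        if self.include_quadratic:
            n += p
        if self.include_interactions:
            n += p * (p - 1) // 2
        return n

    def drop(self, predictor: str) -> "FeatureSpec":
        """Spec with one predictor removed (same scaling for the rest)."""
        return self.subset([p for p in self.predictor_names if p != predictor])

    def subset(self, names: Iterable[str]) -> "FeatureSpec":
        names = tuple(names)
        missing = set(names) - set(self.predictor_names)
        if missing:
            raise KeyError(f"unknown predictors: {sorted(missing)}")
        return FeatureSpec(
            predictor_names=names,
            include_quadratic=self.include_quadratic,
            include_interactions=self.include_interactions,
            means={p: self.means[p] for p in names},
            sds={p: self.sds[p] for p in names},
            z_ranges={p: self.z_ranges[p] for p in names if p in self.z_ranges},
        )

    def to_dict(self) -> dict:
        return {
            "format_version": _FORMAT_VERSION,
            "predictor_names": list(self.predictor_names),
            "include_quadratic": self.include_quadratic,
            "include_interactions": self.include_interactions,
            "means": {k: float(v) for k, v in self.means.items()},
            "sds": {k: float(v) for k, v in self.sds.items()},
            "z_ranges": {k: [float(v[0]), float(v[1])] for k, v in self.z_ranges.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSpec":
        return cls(
            predictor_names=tuple(d["predictor_names"]),
            include_quadratic=bool(d["include_quadratic"]),
            include_interactions=bool(d["include_interactions"]),
            means=dict(d["means"]),
            sds=dict(d["sds"]),
            z_ranges={k: (v[0], v[1]) for k, v in d.get("z_ranges", {}).items()},
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FeatureSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DesignMatrix:
    """Expanded N x M design matrix with its column names and source spec."""

    values: np.ndarray
    column_names: list[str]
    spec: FeatureSpec

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]


def _as_frame(samples) -> pd.DataFrame:
    if isinstance(samples, pd.DataFrame):
        return samples
    return pd.DataFrame({k: np.asarray(v).ravel() for k, v in samples.items()})


def build_spec(
    predictor_names: Sequence[str],
    training_samples,
    *,
    include_quadratic: bool = True,
    include_interactions: bool = True,
) -> FeatureSpec:
    """Capture per-predictor scaling from training samples.

    Raises
    ------
    ValueError
        If fewer than two samples are given or a predictor has zero variance
        (named in the message).
    KeyError
        If a predictor is absent from the samples.
    """
    frame = _as_frame(training_samples)
    if len(frame) < 2:
        raise ValueError("need at least 2 training samples to estimate scaling")
    means, sds, z_ranges = {}, {}, {}
    for name in predictor_names:
        if name not in frame.columns:
            raise KeyError(f"predictor {name!r} missing from training samples")
        col = np.asarray(frame[name], dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"predictor {name!r} contains non-finite values")
        mu = float(col.mean())
        sd = float(col.std(ddof=0))
        if not sd > 0:
            raise ValueError(f"predictor {name!r} has zero variance in the training sample")
        means[name], sds[name] = mu, sd
        z = (col - mu) / sd
        z_ranges[name] = (float(z.min()), float(z.max()))
    return FeatureSpec(
        predictor_names=tuple(predictor_names),
        include_quadratic=include_quadratic,
        include_interactions=include_interactions,
        means=means,
        sds=sds,
        z_ranges=z_ranges,
    )


def expand(spec: FeatureSpec, samples) -> DesignMatrix:
    """Expand predictor samples into the model's design matrix.

    Each predictor is z-scored with the spec's stored training scaling; the
    quadratic term is the squared z-score and interactions are products of
    z-scores.  Column order is intercept, linear terms in predictor order,
    quadratic terms in predictor order, then interactions sorted by
    lexicographic name pair.
    """
    frame = _as_frame(samples)
    n = len(frame)
    z = {}
    for name in spec.predictor_names:
        if name not in frame.columns:
            raise KeyError(f"predictor {name!r} missing from samples")
        col = np.asarray(frame[name], dtype=float)
        if not np.all(np.isfinite(col)):
            raise ValueError(f"predictor {name!r} contains non-finite values")
        z[name] = (col - spec.means[name]) / spec.sds[name]

    cols = [np.ones(n)]
    cols += [z[p] for p in spec.predictor_names]
    if spec.include_quadratic:
        cols += [z[p] ** 2 for p in spec.predictor_names]
    if spec.include_interactions:
        cols += [z[a] * z[b] for a, b in _interaction_pairs(spec.predictor_names)]
    values = np.column_stack(cols) if cols else np.ones((n, 1))
    return DesignMatrix(values=values, column_names=spec.column_names, spec=spec)
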