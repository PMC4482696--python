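"""Raster and table I/O.

Rasters are stored as multi-band TIFF (float32 for real-valued layers,
uint16 for categorical maps) with a JSON sidecar (``<file>.json``) carrying
band names, units, and class tables.  Write-then-read round-trips preserve
integer rasters exactly and real rasters to 32-bit float precision.

Coordinate convention: row-major, 0-based pixel indices, pixel-center
registration; synthetic grids carry no geographic CRS.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .landscape import EnvironmentalStack, VegetationMap
from .projection import ProbabilityField

__all__ = [
    "write_stack", "read_stack", "write_vegmap", "read_vegmap",
    "write_field", "read_field",
]

_GEOGRAPHY_BANDS = ("elevation", "coast_distance")


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def _write_sidecar(path, payload: dict) -> None:
    with open(_sidecar(path), "w") as fh:
        json.dump(payload, fh, indent=2)


def _read_sidecar(path) -> dict:
    sc = _sidecar(path)
    if not sc.exists():
        raise FileNotFoundError(f"missing sidecar manifest {sc}")
    with open(sc) as fh:
        return json.load(fh)


def write_stack(stack: EnvironmentalStack, path) -> None:
    """Write an environmental stack: one band per layer plus geography bands."""
    names = list(stack.predictor_names) + list(_GEOGRAPHY_BANDS)
    bands = [stack.layers[n] for n in stack.predictor_names]
    bands += [stack.elevation, stack.coast_distance]
    data = np.stack(bands).astype(np.float32)
    tifffile.imwrite(path, data, photometric="minisblack")
    _write_sidecar(path, {
        "kind": "environmental_stack",
        "bands": names,
        "units": {**dict(stack.units), "elevation": "m", "coast_distance": "km"},
        "shape": list(stack.shape),
    })


def read_stack(path) -> EnvironmentalStack:
    meta = _read_sidecar(path)
    if meta.get("kind") != "environmental_stack":
        raise ValueError(f"{path} is not an environmental stack")
    data = tifffile.imread(path)
    bands = meta["bands"]
    if data.shape[0] != len(bands):
        raise ValueError(
            f"{path}: sidecar declares {len(bands)} bands but file has {data.shape[0]}")
    arrays = {name: data[i].astype(np.float64) for i, name in enumerate(bands)}
    for required in _GEOGRAPHY_BANDS:
        if required not in arrays:
            raise ValueError(f"{path}: missing declared band {required!r}")
    layers = {n: arrays[n] for n in bands if n not in _GEOGRAPHY_BANDS}
    units = {k: v for k, v in meta.get("units", {}).items() if k in layers}
    return EnvironmentalStack(
        layers=layers,
        elevation=arrays["elevation"],
        coast_distance=arrays["coast_distance"],
        units=units,
    )


def write_vegmap(vegmap: VegetationMap, path) -> None:
    """Write a categorical vegetation raster with its class-name table."""
    if vegmap.n_classes > np.iinfo(np.uint16).max:
        raise ValueError("too many classes for uint16 storage")
    tifffile.imwrite(path, vegmap.labels.astype(np.uint16),
                     photometric="minisblack")
    _write_sidecar(path, {
        "kind": "vegetation_map",
        "class_names": list(vegmap.class_names),
        "shape": list(vegmap.labels.shape),
    })


def read_vegmap(path) -> VegetationMap:
    meta = _read_sidecar(path)
    if meta.get("kind") != "vegetation_map":
        raise ValueError(f"{path} is not a vegetation map")
    labels = tifffile.imread(path).astype(np.int64)
    return VegetationMap(labels=labels, class_names=list(meta["class_names"]))


def write_field(field: ProbabilityField, path) -> None:
    """Write a probability field as one float32 band per vegetation type."""
    if field.grid_shape is not None:
        data = field.values.T.reshape((field.n_classes, *field.grid_shape))
    else:
        data = field.values.T[:, :, None]
    tifffile.imwrite(path, data.astype(np.float32), photometric="minisblack")
    _write_sidecar(path, {
        "kind": "probability_field",
        "class_names": list(field.class_names),
        "grid_shape": list(field.grid_shape) if field.grid_shape else None,
        "extrapolation_fraction": field.extrapolation_fraction,
    })


def read_field(path) -> ProbabilityField:
    meta = _read_sidecar(path)
    if meta.get("kind") != "probability_field":
        raise ValueError(f"{path} is not a probability field")
    data = tifffile.imread(path).astype(np.float64)
    k = len(meta["class_names"])
    if data.shape[0] != k:
        raise ValueError(f"{path}: expected {k} bands, found {data.shape[0]}")
    values = data.reshape(k, -1).T
    # float32 storage perturbs row sums at ~1e-8; renormalize to the contract
    values /= values.sum(axis=1, keepdims=True)
    grid_shape = tuple(meta["grid_shape"]) if meta.get("grid_shape") else None
    return ProbabilityField(
        values=values,
        class_names=list(meta["class_names"]),
        grid_shape=grid_shape,
        extrapolation_fraction=dict(meta.get("extrapolation_fraction", {})),
    )
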