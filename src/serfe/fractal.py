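"""Fractal-based feature augmentation (FFA).

The box-counting dimension of each patient's binary tumor mask quantifies the
geometric complexity of the lesion boundary/texture support.  Occupied-box
counts N(eps) are taken on a fixed grid anchored at the array origin for box
edge lengths eps that are powers of two; the dimension is the least-squares
slope of log N(eps) against log(1/eps).  The fixed anchor keeps the estimate
deterministic and makes N(eps) exactly non-increasing in eps.

Downstream, every feature value of patient p is shifted by beta * D_f(p),
injecting the mask's morphological complexity into the feature table as an
additive offset (beta = 0 disables the stage).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FeatureMatrix
from .errors import AlignmentError, ROIError, ValidationError

MIN_SCALES = 4


@dataclass
class FractalEstimate:
    """Result of one box-counting fit."""

    dimension: float
    box_sizes: np.ndarray
    counts: np.ndarray
    fit_slope: float
    fit_intercept: float
    fit_r2: float


def _box_count(binary: np.ndarray, size: int) -> int:
    """Number of size^d grid boxes (anchored at the origin) holding >= 1 occupied cell."""
    occupied = binary
    for axis in range(binary.ndim):
        n = occupied.shape[axis]
        pad = (-n) % size
        if pad:
            width = [(0, 0)] * occupied.ndim
            width[axis] = (0, pad)
            occupied = np.pad(occupied, width)
        n = occupied.shape[axis]
        new_shape = (
            occupied.shape[:axis] + (n // size, size) + occupied.shape[axis + 1 :]
        )
        occupied = occupied.reshape(new_shape).any(axis=axis + 1)
    return int(occupied.sum())


def default_box_sizes(shape: tuple[int, ...]) -> list[int]:
    """Powers of two from 1 up to half the smallest array dimension."""
    limit = min(shape) // 2
    sizes = []
    s = 1
    while s <= limit:
        sizes.append(s)
        s *= 2
    return sizes


def box_counting_dimension(
    binary: np.ndarray, sizes: list[int] | None = None
) -> FractalEstimate:
    """Estimate the box-counting fractal dimension of a 2-D or 3-D binary array.

    Parameters
    ----------
    binary : array
        Nonzero entries mark occupied cells; must contain at least one.
    sizes : list of int, optional
        Box edge lengths in cells. Defaults to powers of two from 1 to half
        the smallest array dimension; at least 4 scales are required.
    """
    binary = np.asarray(binary) != 0
    if binary.ndim not in (2, 3):
        raise ValidationError("box counting expects a 2-D or 3-D array")
    if not binary.any():
        raise ROIError("box counting needs at least one occupied cell")
    if sizes is None:
        sizes = default_box_sizes(binary.shape)
    sizes = sorted({int(s) for s in sizes})
    if any(s < 1 for s in sizes):
        raise ValidationError("box sizes must be positive integers")
    if len(sizes) < MIN_SCALES:
        raise ValidationError(
            f"need >= {MIN_SCALES} box sizes for a stable fit, got {len(sizes)} "
            f"(array too small?)"
        )
    counts = np.array([_box_count(binary, s) for s in sizes], dtype=float)
    x = np.log(1.0 / np.array(sizes, dtype=float))
    y = np.log(counts)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return FractalEstimate(
        dimension=float(slope),
        box_sizes=np.array(sizes),
        counts=counts,
        fit_slope=float(slope),
        fit_intercept=float(intercept),
        fit_r2=r2,
    )


class FractalAugmenter:
    """Adds beta * D_f(patient) to every feature value of that patient.

    Not a column transform: the shift is per row, so transform() takes the
    per-patient dimension vector alongside the matrix.
    """

    def __init__(self, beta: float = 0.1):
        if beta < 0:
            raise ValidationError("beta must be >= 0")
        self.beta = beta

    def transform(self, X: np.ndarray, dims: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        dims = np.asarray(dims, dtype=float)
        if dims.shape != (X.shape[0],):
            raise AlignmentError(
                f"need one fractal dimension per patient: {dims.shape} vs {X.shape[0]} rows"
            )
        return X + self.beta * dims[:, None]

    def get_params(self, deep: bool = True) -> dict:
        return {"beta": self.beta}

    def set_params(self, **params) -> "FractalAugmenter":
        for k, v in params.items():
            if k != "beta":
                raise ValueError(f"unknown parameter {k!r}")
            self.beta = v
        return self


def fractal_augment(
    matrix: FeatureMatrix, dims: np.ndarray | dict[str, float], beta: float
) -> FeatureMatrix:
    """Shift every feature of patient p by beta * D_f(p); beta = 0 is the identity."""
    if isinstance(dims, dict):
        missing = [p for p in matrix.patient_ids if p not in dims]
        if missing:
            raise AlignmentError(f"no fractal dimension for patients: {missing}")
        dims = np.array([dims[p] for p in matrix.patient_ids], dtype=float)
    values = FractalAugmenter(beta).transform(matrix.values, dims)
    return matrix.with_values(values)
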