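"""Synthetic cohorts, replicate sets, fractal phantoms and tumor volumes.

Everything the pipeline consumes can be generated here with known ground
truth, so each stage is testable offline:

* ``generate_cohort`` draws Gaussian features in equicorrelated blocks, adds
  a standardized class mean-shift to the informative columns, plants
  high-correlation blocks (redundancy fodder), low-entropy spike columns,
  and builds replicate extractions whose within-subject noise variance is set
  from the target intraclass correlation (sigma_w^2 = sigma_b^2 (1-ICC)/ICC).
* ``generate_fractal_phantom`` builds binary sets with closed-form similarity
  dimension (line, square, cube, Sierpinski carpet and triangle), the oracles
  for box counting.
* ``generate_tumor_volume`` builds a blob-like textured mask + intensity
  volume for the image-feature extractor.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import FeatureMatrix, ReplicateSet, VolumeROI
from .errors import ValidationError

PHANTOM_DIMENSIONS = {
    "line": 1.0,
    "filled_square": 2.0,
    "filled_cube": 3.0,
    "sierpinski_carpet": float(np.log(8) / np.log(3)),
    "sierpinski_triangle": float(np.log(3) / np.log(2)),
}


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a synthetic radiomics cohort.

    Defaults mirror a 100-patient glioblastoma-vs-other cohort (57% positive
    class) with a compact 300-feature panel: 20 informative features with a
    standardized between-class shift d = 1.5, generic blocks of 5 features at
    within-block correlation 0.6, ten planted near-duplicate blocks at
    correlation 0.95, ten low-entropy spike columns, three replicate
    extractions per patient with a stable-feature ICC of 0.9 and 15% of
    features made unstable at ICC 0.3.
    """

    n_patients: int = 100
    n_features: int = 300
    n_informative: int = 20
    block_size: int = 5
    rho: float = 0.6
    n_redundant_blocks: int = 10
    redundant_rho: float = 0.95
    n_low_entropy: int = 10
    class_effect: float = 1.5
    pos_fraction: float = 0.57
    replicate_count: int = 3
    target_icc: float = 0.9
    unstable_fraction: float = 0.15
    unstable_icc: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValidationError("n_informative cannot exceed n_features")
        if not 0 <= self.rho < 1 or not 0 <= self.redundant_rho < 1:
            raise ValidationError("correlations must be in [0, 1)")
        if not 0 < self.target_icc < 1 or not 0 < self.unstable_icc < 1:
            raise ValidationError("target ICCs must be in (0, 1)")
        if self.replicate_count < 2:
            raise ValidationError("replicate_count must be >= 2")
        if not 0 < self.pos_fraction < 1:
            raise ValidationError("pos_fraction must be in (0, 1)")
        reserved = (
            self.n_informative
            + self.n_redundant_blocks * self.block_size
            + self.n_low_entropy
        )
        if reserved > self.n_features:
            raise ValidationError(
                "informative + redundant-block + low-entropy columns exceed n_features"
            )


@dataclass
class CohortTruth:
    """Ground-truth record of what the generator planted."""

    informative: list[str]
    redundant: list[str]  # members of high-correlation blocks beyond the first
    low_entropy: list[str]
    unstable: list[str]
    population_icc: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "informative": self.informative,
            "redundant": self.redundant,
            "low_entropy": self.low_entropy,
            "unstable": self.unstable,
        }


def _equicorrelated(rng: np.random.Generator, n: int, size: int, rho: float) -> np.ndarray:
    """n samples of `size` unit-variance features with pairwise correlation rho."""
    shared = rng.standard_normal((n, 1))
    own = rng.standard_normal((n, size))
    return np.sqrt(rho) * shared + np.sqrt(1 - rho) * own


def generate_cohort(
    spec: SyntheticCohortSpec | None = None,
) -> tuple[FeatureMatrix, np.ndarray, ReplicateSet, CohortTruth]:
    """Draw a full synthetic cohort: features, labels, replicates, truth."""
    spec = spec or SyntheticCohortSpec()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_patients, spec.n_features

    n_pos = int(round(n * spec.pos_fraction))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)

    names = [f"feat_{j:04d}" for j in range(m)]
    values = np.empty((n, m))
    informative_idx = list(range(spec.n_informative))
    cursor = spec.n_informative
    # informative features: mutually independent unit-variance columns
    values[:, :cursor] = rng.standard_normal((n, cursor))
    # planted near-duplicate blocks
    redundant_idx: list[int] = []
    for _ in range(spec.n_redundant_blocks):
        block = _equicorrelated(rng, n, spec.block_size, spec.redundant_rho)
        values[:, cursor : cursor + spec.block_size] = block
        redundant_idx.extend(range(cursor + 1, cursor + spec.block_size))
        cursor += spec.block_size
    # low-entropy spikes: constant columns with a handful of outlier patients
    low_entropy_idx = list(range(cursor, cursor + spec.n_low_entropy))
    for j in low_entropy_idx:
        col = np.zeros(n)
        outliers = rng.choice(n, size=3, replace=False)
        col[outliers] = rng.uniform(5.0, 10.0, size=3)
        values[:, j] = col
    cursor += spec.n_low_entropy
    # filler features in generic moderate-correlation blocks
    while cursor < m:
        size = min(spec.block_size, m - cursor)
        values[:, cursor : cursor + size] = _equicorrelated(rng, n, size, spec.rho)
        cursor += size
    # class signal: standardized mean shift on informative columns
    values[labels == 1, : spec.n_informative] += spec.class_effect

    # replicate extractions: base + homoscedastic within-subject noise,
    # sigma_w^2 chosen from the per-feature target ICC with sigma_b^2 = 1
    eligible = [
        j
        for j in range(m)
        if j not in set(informative_idx) and j not in set(low_entropy_idx)
    ]
    n_unstable = int(round(spec.unstable_fraction * m))
    unstable_idx = sorted(
        rng.choice(eligible, size=min(n_unstable, len(eligible)), replace=False).tolist()
    )
    icc_targets = np.full(m, spec.target_icc)
    icc_targets[unstable_idx] = spec.unstable_icc
    sigma_w = np.sqrt((1 - icc_targets) / icc_targets)
    k = spec.replicate_count
    noise = rng.standard_normal((n, m, k)) * sigma_w[None, :, None]
    replicate_values = values[:, :, None] + noise

    ids = [f"patient_{i:03d}" for i in range(n)]
    base = FeatureMatrix(ids, names, values, labels)
    replicates = ReplicateSet(base, replicate_values)
    truth = CohortTruth(
        informative=[names[j] for j in informative_idx],
        redundant=[names[j] for j in redundant_idx],
        low_entropy=[names[j] for j in low_entropy_idx],
        unstable=[names[j] for j in unstable_idx],
        population_icc={names[j]: float(icc_targets[j]) for j in range(m)},
    )
    return base, labels, replicates, truth


# ---------------------------------------------------------------------------
# Fractal phantoms
# ---------------------------------------------------------------------------

def _sierpinski_carpet(level: int) -> np.ndarray:
    size = 3**level
    i = np.arange(size)
    keep = np.ones((size, size), dtype=bool)
    for p in range(level):
        digit = (i // 3**p) % 3
        hole = digit == 1
        keep &= ~(hole[:, None] & hole[None, :])
    return keep


def _sierpinski_triangle(level: int) -> np.ndarray:
    size = 2**level
    i = np.arange(size)
    return (i[:, None] & i[None, :]) == 0  # Pascal triangle mod 2


def generate_fractal_phantom(kind: str, level_or_size: int) -> tuple[np.ndarray, float]:
    """Deterministic binary phantom plus its closed-form similarity dimension.

    kinds: line / filled_square (2-D, size = edge length), filled_cube (3-D),
    sierpinski_carpet (2-D, 3^level edge), sierpinski_triangle (2-D, 2^level).
    """
    if kind not in PHANTOM_DIMENSIONS:
        raise ValidationError(f"unknown phantom kind {kind!r}")
    v = int(level_or_size)
    if v < 1:
        raise ValidationError("level/size must be >= 1")
    if kind == "line":
        arr = np.zeros((v, v), dtype=bool)
        arr[0, :] = True
    elif kind == "filled_square":
        arr = np.ones((v, v), dtype=bool)
    elif kind == "filled_cube":
        arr = np.ones((v, v, v), dtype=bool)
    elif kind == "sierpinski_carpet":
        arr = _sierpinski_carpet(v)
    else:
        arr = _sierpinski_triangle(v)
    return arr, PHANTOM_DIMENSIONS[kind]


# ---------------------------------------------------------------------------
# Tumor-like volumes
# ---------------------------------------------------------------------------

def generate_tumor_volume(
    seed: int = 0, grid_size: int = 32, texture_contrast: float = 1.0
) -> VolumeROI:
    """Blob-like connected tumor mask with textured intensities.

    The mask is a sphere of radius grid_size/4 perturbed by smoothed Gaussian
    noise; intensities are a radial base profile plus smoothed noise texture
    scaled by ``texture_contrast`` (0 gives a constant in-mask intensity).
    """
    if grid_size < 16:
        raise ValidationError("grid_size must be >= 16")
    rng = np.random.default_rng(seed)
    ax = np.arange(grid_size) - (grid_size - 1) / 2
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(xx**2 + yy**2 + zz**2)
    bump = ndimage.gaussian_filter(rng.standard_normal((grid_size,) * 3), grid_size / 8)
    bump = bump / max(np.abs(bump).max(), 1e-12)
    mask = r <= grid_size / 4 * (1 + 0.4 * bump)
    if not mask.any():  # pathological noise draw; fall back to the pure sphere
        mask = r <= grid_size / 4
    texture = ndimage.gaussian_filter(rng.standard_normal((grid_size,) * 3), 1.0)
    intensities = 100.0 - r + texture_contrast * 10.0 * texture
    if texture_contrast == 0:
        intensities = np.full((grid_size,) * 3, 100.0)
    return VolumeROI(intensities, mask.astype(np.uint8), (1.0, 1.0, 1.0))
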