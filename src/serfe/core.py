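"""Shared data model and standard-format I/O.

The central container is :class:`FeatureMatrix`: a patients x features table
with unique feature names, opaque patient identifiers and an optional binary
label vector (1 = glioblastoma-like positive class).  Every refinement stage
consumes and produces FeatureMatrix objects; replicated extractions for
stability analysis live in :class:`ReplicateSet`, and image data enters
through :class:`VolumeROI` (NIfTI-backed intensities + binary mask).

Loaders validate strictly and reject malformed input — a missing or
non-numeric cell is an error, never silently imputed, because downstream
entropy estimates would be corrupted by invented values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    AlignmentError,
    FormatError,
    GeometryError,
    ROIError,
    ValidationError,
)

ID_COLUMN = "patient_id"
LABEL_COLUMN = "label"


@dataclass
class FeatureMatrix:
    """Patients x features numeric table.

    Parameters
    ----------
    patient_ids : list of str
        Opaque identifiers, one per row, unique.
    feature_names : list of str
        Unique column names.
    values : ndarray of shape (n_patients, n_features)
        Feature values; units are feature-specific.
    labels : ndarray of shape (n_patients,), optional
        Binary class labels (1 = positive class).
    """

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.patient_ids = [str(p) for p in self.patient_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D array")
        n, m = self.values.shape
        if n != len(self.patient_ids):
            raise ValidationError(
                f"{len(self.patient_ids)} patient ids but {n} rows of values"
            )
        if m != len(self.feature_names):
            raise ValidationError(
                f"{len(self.feature_names)} feature names but {m} value columns"
            )
        dup = _duplicates(self.feature_names)
        if dup:
            raise ValidationError(f"duplicate feature names: {sorted(dup)}")
        dup = _duplicates(self.patient_ids)
        if dup:
            raise ValidationError(f"duplicate patient ids: {sorted(dup)}")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                "non-finite value at patient "
                f"{self.patient_ids[bad[0]]!r}, feature {self.feature_names[bad[1]]!r}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValidationError("labels must have one entry per patient")
            uniq = set(np.unique(self.labels).tolist())
            if not uniq <= {0, 1}:
                raise ValidationError(f"labels must be binary 0/1, got {sorted(uniq)}")
            self.labels = self.labels.astype(int)

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            list(self.patient_ids),
            list(self.feature_names),
            self.values.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Same metadata, new value matrix (must keep the shape)."""
        return FeatureMatrix(
            list(self.patient_ids), list(self.feature_names), values, self.labels
        )

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        index = {f: i for i, f in enumerate(self.feature_names)}
        missing = [f for f in names if f not in index]
        if missing:
            raise AlignmentError(f"unknown features: {missing}")
        cols = [index[f] for f in names]
        return FeatureMatrix(
            list(self.patient_ids), list(names), self.values[:, cols], self.labels
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, ID_COLUMN, self.patient_ids)
        if self.labels is not None:
            df[LABEL_COLUMN] = self.labels
        return df


@dataclass
class ReplicateSet:
    """Repeated feature extractions for test–retest stability analysis.

    ``replicate_values`` is a patients x features x replicates array in the
    same patient/feature order as ``base``; the balanced design (equal
    replicate count per patient) is required by the one-way ANOVA estimator.
    """

    base: FeatureMatrix
    replicate_values: np.ndarray

    def __post_init__(self) -> None:
        self.replicate_values = np.asarray(self.replicate_values, dtype=float)
        if self.replicate_values.ndim != 3:
            raise ValidationError("replicate_values must be 3-D")
        n, m, k = self.replicate_values.shape
        if (n, m) != self.base.values.shape:
            raise ValidationError(
                "replicate_values shape inconsistent with base feature matrix"
            )
        if k < 2:
            raise ValidationError("at least 2 replicates are required")
        if not np.all(np.isfinite(self.replicate_values)):
            raise ValidationError("non-finite replicate value")

    @property
    def n_replicates(self) -> int:
        return self.replicate_values.shape[2]

    def select_features(self, names: Sequence[str]) -> "ReplicateSet":
        index = {f: i for i, f in enumerate(self.base.feature_names)}
        cols = [index[f] for f in names]
        return ReplicateSet(self.base.select_features(names), self.replicate_values[:, cols, :])


@dataclass
class VolumeROI:
    """A 3-D intensity volume with a binary tumor mask.

    Arrays are indexed (x, y, z) in voxel space; ``spacing`` holds the voxel
    edge lengths in mm so that all geometry (volume, surface area) is metric.
    """

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.intensities.ndim != 3 or self.mask.ndim != 3:
            raise ValidationError("intensities and mask must be 3-D arrays")
        if self.intensities.shape != self.mask.shape:
            raise GeometryError(
                f"image shape {self.intensities.shape} != mask shape {self.mask.shape}"
            )
        self.mask = (self.mask > 0).astype(np.uint8)
        if self.mask.sum() == 0:
            raise ROIError("mask is empty: no voxels in the region of interest")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValidationError(f"spacing must be 3 positive lengths, got {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def in_mask(self) -> np.ndarray:
        """In-mask intensities in fixed C-order scan order."""
        return self.intensities[self.mask.astype(bool)]


@dataclass
class PipelineConfig:
    """Tunable parameters of the refinement pipeline.

    alpha : exponent of the entropy weighting (0 disables it).
    beta : scale of the fractal-dimension shift added to every feature.
    gamma : sensitivity of the sigmoid adaptive weighting.
    entropy_bins : histogram bins for per-feature entropy on [0, 1].
    entropy_floor : minimum per-feature entropy in bits to survive the
        relevance filter.
    redundancy_threshold : absolute Pearson correlation above which a feature
        is redundant with an already-retained one.
    icc_threshold : intraclass correlation at or above which a feature counts
        as stable.
    cv_folds : folds of the stratified cross-validation.
    score_statistic : patient-to-feature aggregation for adaptive weighting
        ("mean" or "median").
    """

    alpha: float = 1.0
    beta: float = 0.1
    gamma: float = 4.0
    entropy_bins: int = 64
    entropy_floor: float = 0.5
    redundancy_threshold: float = 0.85
    icc_threshold: float = 0.75
    cv_folds: int = 5
    seed: int = 0
    score_statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError("alpha must be >= 0")
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if self.gamma <= 0:
            raise ValidationError("gamma must be > 0")
        if self.entropy_bins < 2:
            raise ValidationError("entropy_bins must be >= 2")
        if not 0 < self.redundancy_threshold <= 1:
            raise ValidationError("redundancy_threshold must be in (0, 1]")
        if not 0 < self.icc_threshold <= 1:
            raise ValidationError("icc_threshold must be in (0, 1]")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be >= 2")
        if self.entropy_floor < 0:
            raise ValidationError("entropy_floor must be >= 0")
        if self.score_statistic not in ("mean", "median"):
            raise ValidationError("score_statistic must be 'mean' or 'median'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise FormatError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _duplicates(items: Sequence[str]) -> set[str]:
    seen: set[str] = set()
    dup: set[str] = set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# CSV feature tables
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, label_column: str | None = None) -> FeatureMatrix:
    """Read a radiomics feature table from CSV.

    Row 1 is a header; column 1 holds the patient identifier. When
    ``label_column`` names an existing column it is removed from the feature
    set and stored as the binary label vector.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with open(path, newline="") as fh:
        header_line = fh.readline()
    header = [h.strip() for h in header_line.rstrip("\n").split(",")]
    dup = _duplicates(header[1:])
    if dup:
        raise FormatError(f"duplicate column names in {path}: {sorted(dup)}")
    df = pd.read_csv(path, dtype={header[0]: str})
    ids = df.iloc[:, 0].tolist()
    dup = _duplicates(ids)
    if dup:
        raise FormatError(f"duplicate patient ids in {path}: {sorted(dup)}")
    body = df.iloc[:, 1:]
    labels = None
    if label_column is not None:
        if label_column not in body.columns:
            raise FormatError(f"label column {label_column!r} not found in {path}")
        labels = body[label_column].to_numpy()
        body = body.drop(columns=[label_column])
    values = np.empty(body.shape, dtype=float)
    for j, col in enumerate(body.columns):
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = np.nonzero(converted.isna().to_numpy())[0]
        if bad.size:
            i = int(bad[0])
            raise FormatError(
                f"non-numeric or missing value in {path} at row {i + 2} "
                f"(patient {ids[i]!r}), column {col!r}"
            )
        values[:, j] = converted.to_numpy(dtype=float)
    try:
        return FeatureMatrix(ids, list(body.columns), values, labels)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_feature_table(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write a feature table to CSV (values kept to 17 significant digits so
    that a round trip reproduces them beyond 12 significant digits)."""
    if matrix.n_features == 0:
        raise ValidationError("refusing to write a feature table with no features")
    df = matrix.to_frame()
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------

def read_volume(image_path: str | Path, mask_path: str | Path) -> VolumeROI:
    """Load an image volume and its binary tumor mask from NIfTI files.

    Voxel spacing is taken from the image header; the mask is binarized
    (any value > 0 becomes 1) and must share the image grid exactly.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    msk = nib.load(str(mask_path))
    data = np.asarray(img.dataobj, dtype=float)
    mask = np.asarray(msk.dataobj)
    if data.shape != mask.shape:
        raise GeometryError(
            f"image grid {data.shape} does not match mask grid {mask.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeROI(data, mask, spacing)


def write_volume(roi: VolumeROI, image_path: str | Path, mask_path: str | Path) -> None:
    """Write a VolumeROI back to a NIfTI image/mask pair."""
    import nibabel as nib

    affine = np.diag(list(roi.spacing) + [1.0])
    nib.save(nib.Nifti1Image(roi.intensities, affine), str(image_path))
    nib.save(nib.Nifti1Image(roi.mask.astype(np.uint8), affine), str(mask_path))


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

class MinMaxNormalizer:
    """Column-wise affine map to [0, 1]; constant columns map to 0.

    A scikit-learn style transformer. Fitted attributes: ``min_``, ``range_``
    and ``constant_`` (boolean flags for zero-range columns). The transform is
    idempotent on its own output.
    """

    def fit(self, X: np.ndarray, y=None) -> "MinMaxNormalizer":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("min-max normalization needs >= 2 rows")
        self.min_ = X.min(axis=0)
        rng = X.max(axis=0) - self.min_
        self.constant_ = rng == 0
        self.range_ = np.where(self.constant_, 1.0, rng)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = (X - self.min_) / self.range_
        out[:, self.constant_] = 0.0
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "MinMaxNormalizer":
        return self


def min_max_normalize(matrix: FeatureMatrix) -> tuple[FeatureMatrix, np.ndarray]:
    """Min-max normalize each feature column to [0, 1].

    Returns the normalized matrix and a boolean flag vector marking constant
    columns (mapped to all-zero).
    """
    scaler = MinMaxNormalizer()
    values = scaler.fit_transform(matrix.values)
    return matrix.with_values(values), scaler.constant_.copy()
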