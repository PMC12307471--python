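"""Representative radiomics feature panel from a masked 3-D volume.

Families: first-order intensity statistics, gray-level co-occurrence texture
(3-D, 13 unique directions, restricted to voxel pairs inside the mask),
mask shape descriptors, and a spectral-entropy descriptor (Shannon entropy
of the in-mask intensity power spectrum).  The panel is deliberately compact
— the refinement stages are panel-agnostic and accept externally extracted
tables as well.

Conventions for degenerate regions: a constant region has variance 0,
skewness and excess kurtosis 0, histogram entropy 0, GLCM energy 1 and
contrast 0, spectral entropy 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import FeatureMatrix, VolumeROI
from .errors import ValidationError

# the 13 unique 3-D co-occurrence directions (first nonzero component positive)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)


@dataclass
class FeaturePanelSpec:
    """Extraction settings for the representative panel."""

    glcm_levels: int = 16
    glcm_distances: tuple[int, ...] = (1,)
    glcm_angles: tuple[tuple[int, int, int], ...] = DIRECTIONS_3D
    histogram_bins: int = 64
    include_first_order: bool = True
    include_glcm: bool = True
    include_shape: bool = True
    include_spectral: bool = True

    def __post_init__(self) -> None:
        if self.glcm_levels < 2:
            raise ValidationError("glcm_levels must be >= 2")
        if any(d < 1 for d in self.glcm_distances):
            raise ValidationError("glcm distances must be >= 1")
        if any(all(c == 0 for c in a) for a in self.glcm_angles):
            raise ValidationError("glcm directions must be nonzero")
        if self.histogram_bins < 2:
            raise ValidationError("histogram_bins must be >= 2")


def first_order_features(roi: VolumeROI, spec: FeaturePanelSpec | None = None) -> dict[str, float]:
    """Intensity statistics of the in-mask voxels (population moments)."""
    spec = spec or FeaturePanelSpec()
    x = roi.in_mask()
    mean = float(x.mean())
    var = float(x.var())  # population variance
    if var > 0:
        centered = x - mean
        skew = float((centered**3).mean() / var**1.5)
        kurt = float((centered**4).mean() / var**2 - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    counts, _ = np.histogram(x, bins=spec.histogram_bins)
    p = counts[counts > 0] / counts.sum()
    hist_entropy = float(-(p * np.log2(p)).sum())
    p10, p90 = np.percentile(x, [10, 90])
    return {
        "mean": mean,
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x**2).sum()),
        "histogram_entropy": hist_entropy,
        "median": float(np.median(x)),
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": float(x.max() - x.min()),
        "percentile10": float(p10),
        "percentile90": float(p90),
        "rms": float(np.sqrt((x**2).mean())),
    }


def _quantize(roi: VolumeROI, levels: int) -> np.ndarray:
    """Equal-width gray-level binning of the in-mask range; -1 outside mask."""
    mask = roi.mask.astype(bool)
    x = roi.intensities
    lo, hi = x[mask].min(), x[mask].max()
    q = np.full(x.shape, -1, dtype=np.int64)
    if hi == lo:
        q[mask] = 0
        return q
    scaled = (x[mask] - lo) / (hi - lo) * levels
    q[mask] = np.clip(scaled.astype(np.int64), 0, levels - 1)
    return q


def _cooccurrence(q: np.ndarray, offset: tuple[int, int, int], levels: int) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one offset; None if no pairs."""
    sl_a, sl_b = [], []
    for d, n in zip(offset, q.shape):
        if abs(d) >= n:
            return None
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    a = q[tuple(sl_a)].ravel()
    b = q[tuple(sl_b)].ravel()
    valid = (a >= 0) & (b >= 0)
    if not valid.any():
        return None
    counts = np.bincount(a[valid] * levels + b[valid], minlength=levels * levels)
    mat = counts.reshape(levels, levels).astype(float)
    mat = mat + mat.T  # symmetrize
    return mat / mat.sum()


def _glcm_stats(p: np.ndarray) -> dict[str, float]:
    levels = p.shape[0]
    i, j = np.meshgrid(np.arange(levels), np.arange(levels), indexing="ij")
    nz = p[p > 0]
    px = p.sum(axis=1)
    mu = float((np.arange(levels) * px).sum())
    sigma2 = float(((np.arange(levels) - mu) ** 2 * px).sum())
    if sigma2 > 0:
        corr = float((((i - mu) * (j - mu) * p).sum()) / sigma2)
    else:
        corr = 0.0
    return {
        "energy": float((p**2).sum()),
        "contrast": float((p * (i - j) ** 2).sum()),
        "homogeneity": float((p / (1.0 + np.abs(i - j))).sum()),
        "dissimilarity": float((p * np.abs(i - j)).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "correlation": corr,
    }


def glcm_features(roi: VolumeROI, spec: FeaturePanelSpec | None = None) -> dict[str, float]:
    """Angle-averaged co-occurrence texture features over in-mask voxel pairs."""
    spec = spec or FeaturePanelSpec()
    if int(roi.mask.sum()) < 2:
        raise ValidationError("GLCM needs >= 2 in-mask voxels")
    q = _quantize(roi, spec.glcm_levels)
    per_angle: list[dict[str, float]] = []
    for dist in spec.glcm_distances:
        for angle in spec.glcm_angles:
            offset = tuple(int(dist) * int(c) for c in angle)
            mat = _cooccurrence(q, offset, spec.glcm_levels)
            if mat is not None:
                per_angle.append(_glcm_stats(mat))
    if not per_angle:
        raise ValidationError("no in-mask voxel pairs for any GLCM direction")
    return {k: float(np.mean([s[k] for s in per_angle])) for k in per_angle[0]}


def shape_features(roi: VolumeROI) -> dict[str, float]:
    """Mask morphology: volume (mm^3), face-count surface area (mm^2),
    sphericity, elongation (second / first principal-axis length)."""
    mask = roi.mask.astype(bool)
    sx, sy, sz = roi.spacing
    n_vox = int(mask.sum())
    volume = n_vox * roi.voxel_volume
    face_areas = (sy * sz, sx * sz, sx * sy)
    area = 0.0
    for axis, fa in enumerate(face_areas):
        padded = np.pad(mask, 1)
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += float(np.abs(diff).sum()) * fa
    sphericity = np.pi ** (1 / 3) * (6 * volume) ** (2 / 3) / area
    coords = np.argwhere(mask).astype(float) * np.array(roi.spacing)
    if coords.shape[0] > 1:
        cov = np.cov(coords, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    else:
        elongation = 1.0
    return {
        "volume_mm3": volume,
        "surface_area_mm2": area,
        "sphericity": float(sphericity),
        "compactness": float(36 * np.pi * volume**2 / area**3),
        "elongation": elongation,
    }


def spectral_entropy(roi: VolumeROI, bins: int | None = None) -> float:
    """Shannon entropy (bits) of the normalized non-DC power spectrum of the
    mean-subtracted in-mask intensity sequence (fixed C-order scan order)."""
    x = roi.in_mask()
    x = x - x.mean()
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    power = spectrum[1:]  # exclude the (zero) DC term
    total = power.sum()
    if total <= 0 or power.size == 0:
        return 0.0
    p = power[power > 0] / total
    return float(-(p * np.log2(p)).sum())


def extract_panel(roi: VolumeROI, spec: FeaturePanelSpec | None = None) -> FeatureMatrix:
    """Extract the full panel as a one-row FeatureMatrix with stable
    family_statistic names and deterministic ordering."""
    spec = spec or FeaturePanelSpec()
    features: dict[str, float] = {}
    if spec.include_first_order:
        for k, v in first_order_features(roi, spec).items():
            features[f"firstorder_{k}"] = v
    if spec.include_glcm:
        for k, v in glcm_features(roi, spec).items():
            features[f"glcm_{k}"] = v
    if spec.include_shape:
        for k, v in shape_features(roi).items():
            features[f"shape_{k}"] = v
    if spec.include_spectral:
        features["spectral_entropy"] = spectral_entropy(roi)
    names = list(features)
    values = np.array([[features[k] for k in names]])
    return FeatureMatrix(["roi_0"], names, values)
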