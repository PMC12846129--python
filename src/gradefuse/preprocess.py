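"""Imaging and clinical preprocessing / augmentation operators.

Imaging side: trilinear spatial resampling to a target voxel spacing,
mask-based intensity normalisation to zero mean / unit variance, ROI
extraction by elementwise mask multiplication, artifact suppression
(frequency-domain Gaussian low-pass followed by a spatial median filter) and
stochastic augmentation (flips, rotation, noise, elastic deformation) applied
jointly to image and mask.

Clinical side: imputation (global-mean / k-NN mean for continuous, mode for
categoricals), training-set standardisation, one-hot encoding with a frozen
vocabulary, boxplot-rule outlier flagging, minority oversampling by linear
interpolation (per grade-by-response cell), and temporal alignment of imaging
and clinical records within a tolerance window.

All fitted statistics derive from the training split only and are captured in
a JSON-serialisable :class:`PreprocessState` whose fingerprint makes
train/test hygiene assertable.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .datatypes import VolumeImage
from .exceptions import (ConfigurationError, DegenerateStatisticsError,
                         InputError, InsufficientNeighborsError,
                         UnfittableVariableError)

__all__ = [
    "ResamplingSpec", "resample_trilinear", "normalize_intensity",
    "ROIVolume", "extract_roi", "suppress_artifacts", "ImputationModel",
    "StandardizationStats", "CategoricalEncoder", "flag_outliers",
    "apply_outlier_policy", "AugmentationSpec", "augment",
    "smote_oversample", "align_temporal", "AlignmentResult", "PreprocessState",
]


# ---------------------------------------------------------------------------
# Imaging operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResamplingSpec:
    source_spacing: tuple[float, float, float]
    target_spacing: tuple[float, float, float]

    def __post_init__(self):
        if any(s <= 0 for s in self.source_spacing + self.target_spacing):
            raise ConfigurationError("voxel spacings must be positive")


def resample_trilinear(volume: VolumeImage, spec: ResamplingSpec) -> VolumeImage:
    """Resample onto the target spacing by trilinear interpolation.

    Output voxel centers follow the half-pixel convention: world coordinate
    of output index i is ``(i + 1/2) * s'``, mapped into source index space
    as ``world / s - 1/2``.  Out-of-bounds queries clamp to the edge.
    """
    src = np.asarray(spec.source_spacing, dtype=float)
    tgt = np.asarray(spec.target_spacing, dtype=float)
    in_shape = np.asarray(volume.shape, dtype=float)
    out_shape = np.maximum(1, np.round(in_shape * src / tgt).astype(int))
    axes = [((np.arange(n) + 0.5) * t) / s - 0.5 for n, t, s in zip(out_shape, tgt, src)]
    coords = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(np.asarray(volume.data, dtype=float),
                                  np.stack(coords), order=1, mode="nearest")
    return VolumeImage(out, tuple(tgt), volume.modality, volume.timestamp)


def normalize_intensity(volume: VolumeImage, mask: VolumeImage,
                        whole_volume: bool = False) -> VolumeImage:
    """Zero-mean / unit-variance transform with statistics from the tumor
    region (mask support) by default; population standard deviation."""
    data = np.asarray(volume.data, dtype=float)
    region = np.ones_like(data, dtype=bool) if whole_volume else np.asarray(mask.data) > 0
    if region.sum() == 0:
        raise DegenerateStatisticsError("empty normalisation region")
    vals = data[region]
    mu, sd = float(vals.mean()), float(vals.std())
    if sd == 0.0:
        raise DegenerateStatisticsError("constant intensities in normalisation region")
    return volume.copy_with((data - mu) / sd)


@dataclass
class ROIVolume:
    image: VolumeImage
    mask: VolumeImage
    bbox: tuple | None = None   # ((lo, hi) per axis) when cropped
    margin: int = 0


def extract_roi(volume: VolumeImage, mask: VolumeImage,
                crop: bool = False, margin: int = 0) -> ROIVolume:
    """I_ROI = I ⊙ M, optionally cropped to the mask bounding box + margin."""
    img = np.asarray(volume.data, dtype=float)
    m = np.asarray(mask.data)
    if img.shape != m.shape:
        raise InputError(f"shape mismatch {img.shape} vs {m.shape}")
    roi = img * (m > 0)
    bbox = None
    if crop:
        idx = np.argwhere(m > 0)
        if idx.size == 0:
            raise InputError("cannot crop: empty mask")
        lo = np.maximum(idx.min(axis=0) - margin, 0)
        hi = np.minimum(idx.max(axis=0) + 1 + margin, m.shape)
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        roi = roi[sl]
        m = m[sl]
        bbox = tuple((int(a), int(b)) for a, b in zip(lo, hi))
    return ROIVolume(image=volume.copy_with(roi),
                     mask=mask.copy_with((m > 0).astype(float)),
                     bbox=bbox, margin=margin)


def suppress_artifacts(volume: VolumeImage, strength: float) -> VolumeImage:
    """Frequency-domain Gaussian low-pass followed by a 3³ median filter.

    ``strength`` scales the low-pass sigma (voxels); 0 is the identity.
    """
    if strength < 0:
        raise ConfigurationError("strength must be non-negative")
    if strength == 0:
        return volume.copy_with(np.array(volume.data, dtype=float, copy=True))
    data = np.asarray(volume.data, dtype=float)
    f = np.fft.fftn(data)
    f = ndimage.fourier_gaussian(f, sigma=strength)
    low = np.real(np.fft.ifftn(f))
    out = ndimage.median_filter(low, size=3, mode="nearest")
    return volume.copy_with(out)


# ---------------------------------------------------------------------------
# Clinical table operators
# ---------------------------------------------------------------------------

def _is_continuous(s: pd.Series) -> bool:
    return pd.api.types.is_numeric_dtype(s) and s.dropna().nunique() > 2


@dataclass
class ImputationModel:
    """Per-variable imputation statistic fitted on the training split.

    Continuous variables: conditional mean over the observed set — globally
    (default) or a k-nearest-neighbor mean.  Categoricals (including binary
    indicators): mode, ties broken toward the smaller value.
    """

    strategy: str = "global"          # "global" | "knn"
    k: int = 5
    fitted_on: str | None = None
    continuous_means: dict = field(default_factory=dict)
    categorical_modes: dict = field(default_factory=dict)
    _train_matrix: pd.DataFrame | None = None

    def fit(self, train: pd.DataFrame, split_id: str = "train") -> "ImputationModel":
        if self.strategy not in ("global", "knn"):
            raise ConfigurationError(f"unknown imputation strategy {self.strategy!r}")
        self.fitted_on = split_id
        for col in train.columns:
            s = train[col]
            obs = s.dropna()
            if obs.empty:
                raise UnfittableVariableError(f"variable {col!r} entirely missing in training data")
            if _is_continuous(s):
                self.continuous_means[col] = float(obs.mean())
            else:
                counts = obs.value_counts()
                top = counts[counts == counts.max()].index
                self.categorical_modes[col] = sorted(top, key=lambda v: str(v))[0]
        if self.strategy == "knn":
            self._train_matrix = train[list(self.continuous_means)].copy()
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        if self.strategy == "knn" and self.continuous_means:
            from sklearn.impute import KNNImputer
            cols = list(self.continuous_means)
            imp = KNNImputer(n_neighbors=self.k)
            imp.fit(self._train_matrix.to_numpy(dtype=float))
            out[cols] = imp.transform(out[cols].to_numpy(dtype=float))
        else:
            for col, mu in self.continuous_means.items():
                out[col] = out[col].fillna(mu)
        for col, mode in self.categorical_modes.items():
            if out[col].isna().any():
                out[col] = out[col].fillna(mode)
        return out


@dataclass
class StandardizationStats:
    """Per-variable (mu, sigma) from the training split; population SD."""

    drop_degenerate: bool = False
    fitted_on: str | None = None
    mu: dict = field(default_factory=dict)
    sigma: dict = field(default_factory=dict)
    dropped: list = field(default_factory=list)

    def fit(self, train: pd.DataFrame, columns=None, split_id: str = "train"):
        self.fitted_on = split_id
        cols = columns if columns is not None else [c for c in train.columns
                                                   if _is_continuous(train[c])]
        for col in cols:
            v = train[col].to_numpy(dtype=float)
            sd = float(np.std(v))
            if sd == 0.0:
                if self.drop_degenerate:
                    warnings.warn(f"dropping degenerate variable {col!r} (zero variance)")
                    self.dropped.append(col)
                    continue
                raise DegenerateStatisticsError(f"variable {col!r} has zero variance")
            self.mu[col] = float(np.mean(v))
            self.sigma[col] = sd
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col in self.dropped:
            if col in out:
                out = out.drop(columns=[col])
        for col, mu in self.mu.items():
            out[col] = (out[col].astype(float) - mu) / self.sigma[col]
        return out


@dataclass
class CategoricalEncoder:
    """One-hot encoding with vocabularies frozen on the training split.

    Unseen test-time categories map to an all-zero indicator row with a
    logged warning.
    """

    fitted_on: str | None = None
    vocab: dict = field(default_factory=dict)   # col -> sorted category list

    def fit(self, train: pd.DataFrame, columns=None, split_id: str = "train"):
        self.fitted_on = split_id
        cols = columns if columns is not None else [c for c in train.columns
                                                    if not _is_continuous(train[c])]
        for col in cols:
            self.vocab[col] = sorted(train[col].dropna().unique(), key=str)
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for col, levels in self.vocab.items():
            values = out[col]
            unseen = set(values.dropna().unique()) - set(levels)
            if unseen:
                warnings.warn(f"unseen categories in {col!r}: {sorted(map(str, unseen))} "
                              "mapped to all-zero indicators")
            for lv in levels:
                out[f"{col}={lv}"] = (values == lv).astype(float)
            out = out.drop(columns=[col])
        return out


def flag_outliers(table: pd.DataFrame, k: float = 1.5, columns=None) -> pd.DataFrame:
    """Boxplot-rule flags: cell outside [Q1 - k·IQR, Q3 + k·IQR].

    Zero IQR (constant column) flags nothing.
    """
    if k < 0:
        raise ConfigurationError("k must be non-negative")
    cols = columns if columns is not None else [c for c in table.columns
                                                if _is_continuous(table[c])]
    flags = pd.DataFrame(False, index=table.index, columns=cols)
    for col in cols:
        v = table[col].to_numpy(dtype=float)
        obs = v[~np.isnan(v)]
        if obs.size == 0:
            continue
        q1, q3 = np.percentile(obs, [25, 75])
        iqr = q3 - q1
        if iqr == 0 or not np.isfinite(k):
            continue
        lo, hi = q1 - k * iqr, q3 + k * iqr
        flags[col] = (v < lo) | (v > hi)
    return flags


def apply_outlier_policy(table: pd.DataFrame, flags: pd.DataFrame,
                         policy: str = "missing", k: float = 1.5) -> pd.DataFrame:
    """Set flagged cells to missing (for re-imputation) or winsorize to the fences."""
    out = table.copy()
    for col in flags.columns:
        sel = flags[col].to_numpy()
        if not sel.any():
            continue
        if policy == "missing":
            out.loc[sel, col] = np.nan
        elif policy == "winsorize":
            v = out[col].to_numpy(dtype=float)
            obs = v[~np.isnan(v)]
            q1, q3 = np.percentile(obs, [25, 75])
            iqr = q3 - q1
            out[col] = np.clip(v, q1 - k * iqr, q3 + k * iqr)
        else:
            raise ConfigurationError(f"unknown outlier policy {policy!r}")
    return out


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentationSpec:
    flip_axes: tuple[int, ...] = ()
    rotation_range: float = 0.0       # degrees, about the axial plane
    noise_sd: float = 0.0
    elastic_amplitude: float = 0.0    # voxels
    elastic_scale: float = 4.0        # smoothing sigma of the displacement field
    seed: int = 0


def augment(roi: ROIVolume, spec: AugmentationSpec) -> ROIVolume:
    """Random flips / rotation / noise / elastic deformation of an ROI.

    The mask is co-transformed with nearest-neighbor interpolation; the noise
    perturbation applies to the image only.  An identity spec returns a copy.
    """
    img = np.array(roi.image.data, dtype=float, copy=True)
    msk = np.array(roi.mask.data, dtype=float, copy=True)
    if spec.elastic_amplitude >= min(img.shape):
        raise ConfigurationError("elastic amplitude exceeds the volume extent")
    identity = (not spec.flip_axes and spec.rotation_range == 0
                and spec.noise_sd == 0 and spec.elastic_amplitude == 0)
    if identity:
        return ROIVolume(roi.image.copy_with(img), roi.mask.copy_with(msk),
                         roi.bbox, roi.margin)
    rng = np.random.default_rng(spec.seed)
    for ax in spec.flip_axes:
        if rng.random() < 0.5:
            img = np.flip(img, axis=ax)
            msk = np.flip(msk, axis=ax)
    if spec.rotation_range > 0:
        ang = float(rng.uniform(-spec.rotation_range, spec.rotation_range))
        img = ndimage.rotate(img, ang, axes=(1, 2), reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk, ang, axes=(1, 2), reshape=False, order=0, mode="nearest")
    if spec.elastic_amplitude > 0:
        disp = [spec.elastic_amplitude *
                ndimage.gaussian_filter(rng.standard_normal(img.shape), spec.elastic_scale)
                for _ in range(3)]
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in img.shape], indexing="ij")
        coords = np.stack([g + d for g, d in zip(grids, disp)])
        img = ndimage.map_coordinates(img, coords, order=1, mode="nearest")
        msk = ndimage.map_coordinates(msk, coords, order=0, mode="nearest")
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = img * (msk > 0)   # keep ROI support inside the transformed mask
    return ROIVolume(roi.image.copy_with(img), roi.mask.copy_with(msk),
                     roi.bbox, roi.margin)


# ---------------------------------------------------------------------------
# SMOTE and temporal alignment
# ---------------------------------------------------------------------------

def smote_oversample(features, labels, k_neighbors: int = 5,
                     target_counts: dict | None = None, seed: int = 0,
                     lam: float | None = None):
    """Minority oversampling by linear interpolation within grade×response cells.

    ``x_new = x_i + lam * (x_j - x_i)`` with ``lam ~ U(0, 1)`` and ``x_j``
    drawn among the k nearest same-cell neighbors (Euclidean on the given,
    already-standardised features).  ``lam`` may be pinned for testing.

    Returns ``(features_out, labels_out, synthetic_mask)``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    cells, counts = np.unique(y, return_counts=True)
    if target_counts is None:
        target = {c: int(counts.max()) for c in cells}
    else:
        target = dict(target_counts)
    new_rows, new_labels = [], []
    from sklearn.neighbors import NearestNeighbors
    for cell in cells:
        idx = np.flatnonzero(y == cell)
        want = target.get(cell, len(idx)) - len(idx)
        if want <= 0:
            continue
        if len(idx) < 2:
            raise InsufficientNeighborsError(f"cell {cell!r} has a single member")
        k = min(k_neighbors, len(idx) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(X[idx])
        _, nbr = nn.kneighbors(X[idx])
        for _ in range(want):
            a = int(rng.integers(len(idx)))
            b = int(nbr[a][1 + rng.integers(k)])    # skip self at position 0
            lam_i = float(rng.uniform(0.0, 1.0)) if lam is None else float(lam)
            new_rows.append(X[idx[a]] + lam_i * (X[idx[b]] - X[idx[a]]))
            new_labels.append(cell)
    if new_rows:
        X_out = np.vstack([X, np.asarray(new_rows)])
        y_out = np.concatenate([y, np.asarray(new_labels)])
    else:
        X_out, y_out = X.copy(), y.copy()
    synthetic = np.zeros(len(X_out), dtype=bool)
    synthetic[len(X):] = True
    return X_out, y_out, synthetic


@dataclass(frozen=True)
class AlignmentResult:
    pairs: tuple                 # (imaging_index, clinical_index) matches
    unmatched_imaging: tuple
    unmatched_clinical: tuple


def align_temporal(imaging_times, clinical_times, delta: float) -> AlignmentResult:
    """Match each imaging record to its nearest clinical record with
    |t_img - t_cli| <= delta (closed inequality); unmatched records reported."""
    if delta < 0:
        raise ConfigurationError("temporal tolerance must be non-negative")
    t_img = np.asarray(imaging_times, dtype=float)
    t_cli = np.asarray(clinical_times, dtype=float)
    pairs = []
    used = set()
    for i, ti in enumerate(t_img):
        gaps = np.abs(t_cli - ti)
        in_window = np.flatnonzero(gaps <= delta)
        if in_window.size:
            j = int(in_window[np.argmin(gaps[in_window])])
            pairs.append((i, j))
            used.add(j)
    matched_img = {i for i, _ in pairs}
    return AlignmentResult(
        pairs=tuple(pairs),
        unmatched_imaging=tuple(i for i in range(len(t_img)) if i not in matched_img),
        unmatched_clinical=tuple(j for j in range(len(t_cli)) if j not in used),
    )


# ---------------------------------------------------------------------------
# Fitted-state sidecar
# ---------------------------------------------------------------------------

@dataclass
class PreprocessState:
    """All training-split statistics needed to reproduce the transform."""

    imputation: ImputationModel | None = None
    standardization: StandardizationStats | None = None
    encoder: CategoricalEncoder | None = None
    outlier_k: float = 1.5

    def to_dict(self) -> dict:
        d: dict = {"outlier_k": self.outlier_k}
        if self.imputation is not None:
            d["imputation"] = {
                "strategy": self.imputation.strategy,
                "continuous_means": self.imputation.continuous_means,
                "categorical_modes": {k: str(v) for k, v in
                                      self.imputation.categorical_modes.items()},
                "fitted_on": self.imputation.fitted_on,
            }
        if self.standardization is not None:
            d["standardization"] = {"mu": self.standardization.mu,
                                    "sigma": self.standardization.sigma,
                                    "fitted_on": self.standardization.fitted_on}
        if self.encoder is not None:
            d["vocab"] = {k: [str(v) for v in vs] for k, vs in self.encoder.vocab.items()}
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    def fingerprint(self) -> str:
        """Stable hash of every fitted statistic (train/test hygiene checks)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
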