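"""Grading / treatment-response associated feature extraction.

Two families live here:

1. the hierarchical imaging-side operators — random region sampling, a
   shared-weight convolutional patch encoder with self-attention,
   attention-weighted region aggregation, grading/response feature
   disentanglement (z_g = W_g z_r, z_t = W_t z_r, z_gt = z_g ⊙ z_t) — plus
   the clinical-side relational encoder (variable graph from thresholded
   Pearson correlations, graph-convolutional refinement) and mutual-
   information feature selection with redundancy suppression;

2. the four fusion input branches with fixed widths: a residual CNN branch
   (512), a direct small-CNN branch (16), a unit-block encoded branch (32)
   and the clinical encoder (64), concatenating to a 624-vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.metrics import mutual_info_score

from . import nn
from .autodiff import Tensor, concat
from .exceptions import ConfigurationError, InputError

__all__ = [
    "PatchHierarchy", "sample_regions", "PatchEncoder", "RegionRepresentation",
    "AttentionAggregator", "DisentangledFeatures", "Disentangler",
    "build_adjacency", "GraphRefiner", "ClinicalEncoder", "alignment_penalty",
    "FeatureSelectionResult", "select_features", "cluster_units",
    "ResNetBranch", "DirectBranch", "EncodedBranch", "BranchEmbeddings",
]

BRANCH_WIDTHS = {"res": 512, "dir": 16, "enc": 32, "cli": 64}


# ---------------------------------------------------------------------------
# Hierarchical sampling
# ---------------------------------------------------------------------------

@dataclass
class PatchHierarchy:
    region_origins: tuple           # (row, col) per region
    regions: list                   # 2D arrays
    patches: list                   # (P, ph, pw) array per region
    patch_size: int


def sample_regions(image: np.ndarray, n_regions: int, region_size: int,
                   seed: int = 0, patch_size: int | None = None) -> PatchHierarchy:
    """Uniform random in-bounds regions, each tiled into fixed-size patches."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("sample_regions expects a 2D image")
    h, w = img.shape
    if region_size > h or region_size > w:
        raise ConfigurationError("region larger than image")
    patch_size = patch_size or region_size
    if region_size % patch_size != 0:
        raise ConfigurationError("region_size must be a multiple of patch_size")
    rng = np.random.default_rng(seed)
    origins, regions, patches = [], [], []
    for _ in range(n_regions):
        r = int(rng.integers(0, h - region_size + 1))
        c = int(rng.integers(0, w - region_size + 1))
        reg = img[r : r + region_size, c : c + region_size]
        origins.append((r, c))
        regions.append(reg)
        t = region_size // patch_size
        tiles = reg.reshape(t, patch_size, t, patch_size).transpose(0, 2, 1, 3)
        patches.append(tiles.reshape(t * t, patch_size, patch_size))
    return PatchHierarchy(region_origins=tuple(origins), regions=regions,
                          patches=patches, patch_size=patch_size)


# ---------------------------------------------------------------------------
# Patch encoding + aggregation
# ---------------------------------------------------------------------------

class PatchEncoder(nn.Module):
    """Shared-weight conv stack per patch followed by self-attention across
    the patches of a region.  With no positional encoding (the default) the
    operator is permutation-equivariant."""

    def __init__(self, dim: int = 32, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = nn.Conv2d(1, 8, 3, rng, pad=1)
        self.conv2 = nn.Conv2d(8, 16, 3, rng, pad=1)
        self.proj = nn.Linear(16, dim, rng)
        self.attn = nn.SelfAttention(dim, rng)
        self.dim = dim

    def encode(self, patches: np.ndarray) -> tuple[Tensor, Tensor]:
        """patches (P, h, w) -> (z_p (P, dim), z_a (P, dim))."""
        patches = np.asarray(patches, dtype=float)
        if patches.ndim != 3 or patches.shape[0] == 0:
            raise InputError("encode expects a non-empty (P, h, w) patch stack")
        x = Tensor(patches[:, None, :, :])
        x = self.conv1(x).relu()
        x = self.conv2(x).relu()
        feat = x.mean(axis=(2, 3))           # global average per patch
        z_p = self.proj(feat)
        z_a = self.attn(z_p)
        return z_p, z_a

    forward = encode


@dataclass
class RegionRepresentation:
    z_p: np.ndarray
    z_a: np.ndarray
    alpha: np.ndarray
    z_r: np.ndarray


class AttentionAggregator(nn.Module):
    """Softmax-normalised learned patch scores; z_r = Σ_i α_i z_i^a."""

    def __init__(self, dim: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.score = nn.Linear(dim, 1, rng or np.random.default_rng(0))

    def forward(self, z_a: Tensor) -> tuple[Tensor, Tensor]:
        s = self.score(z_a).reshape(-1)
        alpha = s.softmax(axis=-1)
        z_r = (alpha.reshape(-1, 1) * z_a).sum(axis=0)
        return alpha, z_r

    def aggregate(self, z_p: Tensor, z_a: Tensor) -> RegionRepresentation:
        alpha, z_r = self.forward(z_a)
        return RegionRepresentation(z_p=z_p.data.copy(), z_a=z_a.data.copy(),
                                    alpha=alpha.data.copy(), z_r=z_r.data.copy())


@dataclass
class DisentangledFeatures:
    z_g: np.ndarray
    z_t: np.ndarray
    z_gt: np.ndarray


class Disentangler(nn.Module):
    """Bias-free linear projections into grading / response subspaces and
    their elementwise interaction z_gt = z_g ⊙ z_t."""

    def __init__(self, dim_in: int, dim_out: int = 64,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w_g = nn.Linear(dim_in, dim_out, rng, bias=False)
        self.w_t = nn.Linear(dim_in, dim_out, rng, bias=False)

    def forward(self, z_r: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        z_g = self.w_g(z_r)
        z_t = self.w_t(z_r)
        return z_g, z_t, z_g * z_t

    def disentangle(self, z_r) -> DisentangledFeatures:
        z_g, z_t, z_gt = self.forward(z_r if isinstance(z_r, Tensor) else Tensor(z_r))
        return DisentangledFeatures(z_g=z_g.data.copy(), z_t=z_t.data.copy(),
                                    z_gt=z_gt.data.copy())


# ---------------------------------------------------------------------------
# Clinical relational encoding
# ---------------------------------------------------------------------------

def build_adjacency(train: "np.ndarray | object", threshold: float = 0.5):
    """Binary adjacency from |Pearson r| >= threshold with unit diagonal,
    then symmetric degree normalisation D^{-1/2} (A + I) D^{-1/2}.

    Zero-variance variables are excluded with a warning.  Returns
    ``(A_norm, kept_indices)``.
    """
    X = np.asarray(getattr(train, "values", train), dtype=float)
    if X.ndim != 2 or X.shape[1] < 2 or X.shape[0] < 3:
        raise InputError("adjacency needs >= 3 rows and >= 2 variables")
    sd = X.std(axis=0)
    kept = np.flatnonzero(sd > 0)
    if kept.size < X.shape[1]:
        warnings.warn("zero-variance variables excluded from the adjacency")
    corr = np.corrcoef(X[:, kept], rowvar=False)
    A = (np.abs(corr) >= threshold).astype(float)
    np.fill_diagonal(A, 1.0)
    d = A.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return A * dinv[:, None] * dinv[None, :], kept


class GraphRefiner(nn.Module):
    """Graph-convolutional refinement of variable-wise embeddings.

    ``rounds`` sweeps of H <- relu(Â H W), followed by mean pooling over the
    variable axis."""

    def __init__(self, dim: int, rounds: int = 2, rng: np.random.Generator | None = None,
                 pool: str = "mean"):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.rounds = rounds
        self.pool = pool
        for i in range(rounds):
            setattr(self, f"w{i}", nn.Linear(dim, dim, rng, bias=False))

    def forward(self, nodes: Tensor, adjacency: np.ndarray) -> Tensor:
        if adjacency.shape[0] != nodes.shape[-2]:
            raise InputError("adjacency size does not match the variable count")
        A = Tensor(adjacency)
        h = nodes
        for i in range(self.rounds):
            h = (A @ h @ getattr(self, f"w{i}").weight).relu()
        if self.pool == "mean":
            return h.mean(axis=-2)
        return h                                 # pool handled by the caller


class ClinicalEncoder(nn.Module):
    """Structured clinical encoder: per-variable embedding, relational
    graph refinement, concatenation pooling (variable identity preserved)
    and projection to the 64-wide fusion scale."""

    OUT_WIDTH = BRANCH_WIDTHS["cli"]

    def __init__(self, n_vars: int, embed_dim: int = 16, rounds: int = 1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_vars = n_vars
        self.embed_w = Tensor(rng.normal(0, 0.5, size=(n_vars, embed_dim)), requires_grad=True)
        self.embed_b = Tensor(np.zeros((n_vars, embed_dim)), requires_grad=True)
        self.refiner = GraphRefiner(embed_dim, rounds=rounds, rng=rng, pool="none")
        self.out = nn.Linear(n_vars * embed_dim, self.OUT_WIDTH, rng)
        self.adjacency = np.eye(n_vars)      # replaceable via fit_adjacency

    def fit_adjacency(self, train_table, threshold: float = 0.5):
        A, kept = build_adjacency(train_table, threshold)
        if kept.size != self.n_vars:
            raise InputError("adjacency variable count mismatch with encoder width")
        self.adjacency = A
        return self

    def forward(self, x: "np.ndarray | Tensor") -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        if x.shape[-1] != self.n_vars:
            raise InputError(f"expected {self.n_vars} clinical variables, got {x.shape[-1]}")
        # (N, V) -> variable-wise embeddings (N, V, d)
        nodes = x.reshape(*x.shape, 1) * self.embed_w + self.embed_b
        refined = self.refiner(nodes, self.adjacency)
        flat = refined.reshape(refined.shape[0], -1)
        return self.out(flat)


def alignment_penalty(z_c: np.ndarray, z_g: np.ndarray, z_t: np.ndarray) -> float:
    """1 − mean cosine similarity between the (already projected) clinical
    embedding and the stop-gradient imaging target [z_g; z_t].

    Zero vectors are excluded from the mean with a warning.
    """
    z_c = np.atleast_2d(np.asarray(z_c, dtype=float))
    target = np.atleast_2d(np.concatenate([np.asarray(z_g, dtype=float),
                                           np.asarray(z_t, dtype=float)], axis=-1))
    if z_c.shape != target.shape:
        raise InputError("projected clinical embedding must match [z_g; z_t] width")
    na = np.linalg.norm(z_c, axis=1)
    nb = np.linalg.norm(target, axis=1)
    ok = (na > 0) & (nb > 0)
    if not ok.all():
        warnings.warn("zero vectors excluded from the alignment penalty")
    if not ok.any():
        raise InputError("no nonzero pairs for the alignment penalty")
    cos = (z_c[ok] * target[ok]).sum(axis=1) / (na[ok] * nb[ok])
    return float(1.0 - cos.mean())


# ---------------------------------------------------------------------------
# Mutual-information feature selection (mRMR-style)
# ---------------------------------------------------------------------------

@dataclass
class FeatureSelectionResult:
    selected: tuple
    relevance: np.ndarray
    redundancy: np.ndarray


def _binned(x: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(len(x), dtype=int)
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(x, edges[1:-1]), 0, n_bins - 1)


def select_features(features: np.ndarray, grade_labels, response_labels,
                    k: int, n_bins: int = 16) -> FeatureSelectionResult:
    """Greedy mRMR selection with histogram mutual information.

    Score of a candidate = MI(f; grade) + MI(f; response)
    − mean MI(f; already selected); ties break toward the lower index.
    """
    X = np.asarray(features, dtype=float)
    n_feat = X.shape[1]
    if k > n_feat:
        raise ConfigurationError(f"k={k} exceeds the number of features {n_feat}")
    g = np.asarray(grade_labels)
    r = np.asarray(response_labels)
    codes = [_binned(X[:, j], n_bins) for j in range(n_feat)]
    relevance = np.array([mutual_info_score(c, g) + mutual_info_score(c, r)
                          for c in codes])
    selected: list[int] = []
    redundancy = np.zeros(n_feat)
    for _ in range(k):
        best, best_score = None, -np.inf
        for j in range(n_feat):
            if j in selected:
                continue
            red = (np.mean([mutual_info_score(codes[j], codes[s]) for s in selected])
                   if selected else 0.0)
            score = relevance[j] - red
            if score > best_score + 1e-12:      # strict improvement; lower index wins ties
                best, best_score = j, score
            redundancy[j] = red
        selected.append(best)
    return FeatureSelectionResult(selected=tuple(selected),
                                  relevance=relevance, redundancy=redundancy)


def cluster_units(unit_vectors: np.ndarray, k: int = 5, seed: int = 0) -> np.ndarray:
    """Unsupervised clustering of unit-level embeddings into putative
    histological components (tumor / stroma / vessel / immune / necrosis)."""
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    return km.fit_predict(np.asarray(unit_vectors, dtype=float))


# ---------------------------------------------------------------------------
# Fusion input branches (widths 512 / 16 / 32 / 64)
# ---------------------------------------------------------------------------

def _resize2d(img: np.ndarray, size: int) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.shape == (size, size):
        return img
    zoom = (size / img.shape[0], size / img.shape[1])
    return ndimage.zoom(img, zoom, order=1)


class _BasicBlock(nn.Module):
    def __init__(self, c_in, c_out, rng, stride=1):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, stride=stride, pad=1, bias=False)
        self.bn1 = nn.BatchNorm(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, pad=1, bias=False)
        self.bn2 = nn.BatchNorm(c_out)
        self.down = (nn.Conv2d(c_in, c_out, 1, rng, stride=stride, bias=False)
                     if stride != 1 or c_in != c_out else None)

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        skip = self.down(x) if self.down is not None else x
        return (out + skip).relu()


class ResNetBranch(nn.Module):
    """Residual CNN branch ending in global average pooling and a
    512-dimensional vector.  Depth 18 or 34 (both end at 512 channels);
    input tiles are resized to ``input_size`` square."""

    OUT_WIDTH = BRANCH_WIDTHS["res"]
    _BLOCKS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}

    def __init__(self, depth: int = 18, input_size: int = 224,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if depth not in self._BLOCKS:
            raise ConfigurationError("supported depths: 18, 34")
        rng = rng or np.random.default_rng(0)
        self.input_size = input_size
        self.stem = nn.Conv2d(1, 64, 7, rng, stride=2, pad=3, bias=False)
        self.stem_bn = nn.BatchNorm(64)
        widths = (64, 128, 256, 512)
        c_in = 64
        blocks = []
        for stage, (w, n) in enumerate(zip(widths, self._BLOCKS[depth])):
            for b in range(n):
                stride = 2 if (stage > 0 and b == 0) else 1
                blocks.append(_BasicBlock(c_in, w, rng, stride=stride))
                c_in = w
        self.blocks = nn.Sequential(*blocks)

    def forward(self, tile: np.ndarray) -> Tensor:
        """tile: (H, W) or (N, H, W) grayscale; returns (N, 512)."""
        tile = np.asarray(tile, dtype=float)
        if tile.ndim == 2:
            tile = tile[None]
        x = np.stack([_resize2d(t, self.input_size) for t in tile])[:, None]
        h = self.stem(Tensor(x))
        h = self.stem_bn(h).relu()
        from .autodiff import max_pool2d
        h = max_pool2d(h, 2)
        h = self.blocks(h)
        return h.mean(axis=(2, 3))


class DirectBranch(nn.Module):
    """Three Conv-BN-ReLU-Pool blocks (channels 8→16→32, 3×3 kernels,
    2×2 stride-2 pooling with floor division: 50→25→12→6) then two fully
    connected layers to a 16-vector."""

    OUT_WIDTH = BRANCH_WIDTHS["dir"]
    INPUT_SIZE = 50

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1, self.bn1 = nn.Conv2d(1, 8, 3, rng, pad=1), nn.BatchNorm(8)
        self.conv2, self.bn2 = nn.Conv2d(8, 16, 3, rng, pad=1), nn.BatchNorm(16)
        self.conv3, self.bn3 = nn.Conv2d(16, 32, 3, rng, pad=1), nn.BatchNorm(32)
        self.fc1 = nn.Linear(32 * 6 * 6, 64, rng)
        self.fc2 = nn.Linear(64, self.OUT_WIDTH, rng)

    def forward(self, tile: np.ndarray, return_maps: bool = False):
        from .autodiff import max_pool2d
        tile = np.asarray(tile, dtype=float)
        if tile.ndim == 2:
            tile = tile[None]
        x = np.stack([_resize2d(t, self.INPUT_SIZE) for t in tile])[:, None]
        h = Tensor(x)
        maps = []
        for conv, bn in ((self.conv1, self.bn1), (self.conv2, self.bn2),
                         (self.conv3, self.bn3)):
            h = max_pool2d(bn(conv(h)).relu(), 2)
            maps.append(h.shape)
        out = self.fc2(self.fc1(h.reshape(h.shape[0], -1)).relu())
        return (out, maps) if return_maps else out


class EncodedBranch(nn.Module):
    """Unit-level branch on 20×20×7 blocks: a padded 3×3 convolution to
    20×20×16, an unpadded one to 18×18×32, adaptive average pooling to
    1×1×32 and flattening to a 32-vector."""

    OUT_WIDTH = BRANCH_WIDTHS["enc"]
    UNIT_SHAPE = (20, 20, 7)

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = nn.Conv2d(7, 16, 3, rng, pad=1)
        self.conv2 = nn.Conv2d(16, 32, 3, rng, pad=0)

    def forward(self, unit: np.ndarray, return_maps: bool = False):
        unit = np.asarray(unit, dtype=float)
        if unit.ndim == 3:
            unit = unit[None]
        if unit.shape[1:] != self.UNIT_SHAPE:
            raise InputError(f"unit block must have shape {self.UNIT_SHAPE}")
        x = Tensor(unit.transpose(0, 3, 1, 2))      # depth-as-channels
        h1 = self.conv1(x).relu()
        h2 = self.conv2(h1).relu()
        out = h2.mean(axis=(2, 3))
        if return_maps:
            return out, [h1.shape, h2.shape]
        return out


@dataclass
class BranchEmbeddings:
    h_res: np.ndarray
    h_dir: np.ndarray
    h_enc: np.ndarray
    h_cli: np.ndarray

    def __post_init__(self):
        for name, width in BRANCH_WIDTHS.items():
            v = getattr(self, f"h_{name}")
            if np.asarray(v).shape[-1] != width:
                raise InputError(f"h_{name} must have width {width}")

    @property
    def h(self) -> np.ndarray:
        """Concatenated base feature vector (width 624)."""
        return np.concatenate([np.atleast_2d(self.h_res), np.atleast_2d(self.h_dir),
                               np.atleast_2d(self.h_enc), np.atleast_2d(self.h_cli)],
                              axis=-1)
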