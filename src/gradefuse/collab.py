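"""Collaborative modeling of grading and response subtypes.

Pipeline: a shared 3D residual encoder (four stride-2 stages, channels
32→64→96→128, spatial /16) produces a feature tensor F; a generic projector
P_a and a context-modulated specific projector P_d map channels to C_e = 64
position-wise; a learnable dictionary E (K rows) reconstructs a generic
representation x̃_i = a_i E with a_i = softmax(q_i Eᵀ / τ); a position-wise
gate g_i = σ(W₂ φ(W₁ X_d(i))) assembles y_i = x̃_i + g_i ⊙ (X_d(i) − x̃_i);
global average pooling of Y gives u (64), classified by a 64→32→G grading
head, while a prototype head soft-assigns u to M subtype centers.  The joint
objective is

    L = L_grade + λ Σ_m π_m ‖u − μ_m‖² + β ‖F − F̂‖₁,

with F̂ a position-wise feature reconstruction from Y.  Subtype-sensitive
maps S_m(p) = E[g_p π_m] localise positions whose gates co-activate with a
subtype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, conv3d
from .exceptions import ConfigurationError, InputError

__all__ = [
    "SharedEncoder3D", "encoder_output_shape", "GenericProjector",
    "SpecificProjector", "dictionary_query", "Dictionary", "GateMLP",
    "gated_assembly", "Decoder3D", "FeatureReconstructor", "GradingHead",
    "subtype_assign", "PrototypeHead", "LossBreakdown", "joint_loss",
    "subtype_map", "CollabModel", "C_FEAT", "C_EMBED", "CONTEXT_WIDTH",
]

C_FEAT = 128        # shared-encoder output channels
C_EMBED = 64        # C_e, projector / dictionary embedding width
CONTEXT_WIDTH = 64  # clinical context vector width
STAGE_WIDTHS = (32, 64, 96, 128)


def encoder_output_shape(input_shape) -> tuple[int, int, int, int]:
    """(C, D', H', W') after the four stride-2 stages; ceil-division matches
    the encoder's pad-to-divisible convention."""
    d, h, w = (int(v) for v in input_shape)
    return (C_FEAT, -(-d // 16), -(-h // 16), -(-w // 16))


class _ResBlock3d(nn.Module):
    def __init__(self, c_in, c_out, rng, stride=1):
        super().__init__()
        self.conv1 = nn.Conv3d(c_in, c_out, 3, rng, stride=stride, pad=1)
        self.conv2 = nn.Conv3d(c_out, c_out, 3, rng, pad=1)
        self.down = (nn.Conv3d(c_in, c_out, 1, rng, stride=stride)
                     if stride != 1 or c_in != c_out else None)

    def forward(self, x):
        h = self.conv2(self.conv1(x).relu())
        skip = self.down(x) if self.down is not None else x
        return (h + skip).relu()


class SharedEncoder3D(nn.Module):
    """Four-stage 3D residual backbone, two 3×3×3 convolutions per stage,
    stride-2 downsampling per stage, channels 32→64→96→128."""

    def __init__(self, in_channels: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        c_in = in_channels
        for i, w in enumerate(STAGE_WIDTHS):
            setattr(self, f"stage{i}", _ResBlock3d(c_in, w, rng, stride=2))
            c_in = w
        self.in_channels = in_channels

    def forward(self, x: "np.ndarray | Tensor") -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))
        if x.ndim != 5:
            raise InputError("expected (N, C, D, H, W) input")
        spatial = x.shape[2:]
        pads = [(-s) % 16 for s in spatial]
        if any(pads):
            warnings.warn(f"spatial dims {spatial} not divisible by 16; edge padding applied")
            xd = np.pad(x.data, ((0, 0), (0, 0), *((0, p) for p in pads)), mode="edge")
            x = Tensor(xd, requires_grad=False) if not x.requires_grad else _pad_tensor(x, pads)
        h = x
        for i in range(4):
            h = getattr(self, f"stage{i}")(h)
        return h


def _pad_tensor(x: Tensor, pads):
    # edge-padding as a differentiable op is unnecessary here: gradients of
    # padded rows fold back onto the edge voxels, which matters only for
    # non-divisible inputs; approximate by zero-grad constant padding
    return Tensor(np.pad(x.data, ((0, 0), (0, 0), *((0, p) for p in pads)), mode="edge"),
                  requires_grad=False)


def _positions(F: Tensor) -> Tensor:
    """(N, C, D', H', W') -> position sequence (N, Np, C)."""
    n, c = F.shape[0], F.shape[1]
    return F.reshape(n, c, -1).transpose(0, 2, 1)


class GenericProjector(nn.Module):
    """P_a: two position-wise (1×1×1) channel maps 128 → 128 → C_e."""

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(C_FEAT, C_FEAT, rng)
        self.fc2 = nn.Linear(C_FEAT, C_EMBED, rng)

    def forward(self, F: Tensor) -> Tensor:
        if F.shape[1] != C_FEAT:
            raise InputError(f"expected {C_FEAT} channels")
        x = _positions(F)
        return self.fc2(self.fc1(x).relu())


class SpecificProjector(nn.Module):
    """P_d: same position-wise structure as P_a plus conditional affine
    (FiLM-style) modulation generated from the clinical context c.

    The modulation biases are zero and the scale head starts at zero weight,
    so a zero context reproduces the unmodulated projection exactly (identity
    modulation); the shift head carries the context into the specific
    features from the first forward pass.  ``identity_init=True`` zeroes the
    shift head as well.
    """

    def __init__(self, rng: np.random.Generator | None = None,
                 identity_init: bool = False, context_weight: float = 2.0):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.context_weight = context_weight
        self.fc1 = nn.Linear(C_FEAT, C_FEAT, rng)
        self.fc2 = nn.Linear(C_FEAT, C_EMBED, rng)
        self.film_scale = nn.Linear(CONTEXT_WIDTH, C_EMBED, rng)
        self.film_shift = nn.Linear(CONTEXT_WIDTH, C_EMBED, rng)
        self.film_scale.weight.data[...] = 0.0
        if identity_init:
            self.film_shift.weight.data[...] = 0.0
        else:
            self.film_shift.weight.data[...] = rng.normal(0, 0.60,
                                                          size=(CONTEXT_WIDTH, C_EMBED))

    def forward(self, F: Tensor, c: "np.ndarray | Tensor") -> Tensor:
        if F.shape[1] != C_FEAT:
            raise InputError(f"expected {C_FEAT} channels")
        c = c if isinstance(c, Tensor) else Tensor(np.atleast_2d(np.asarray(c, dtype=float)))
        if c.shape[-1] != CONTEXT_WIDTH:
            raise InputError(f"context width must be {CONTEXT_WIDTH}")
        x = self.fc2(self.fc1(_positions(F)).relu())         # (N, Np, Ce)
        scale = self.film_scale(c) + 1.0                     # (N, Ce)
        shift = self.film_shift(c)
        n = scale.shape[0]
        x = x * scale.reshape(n, 1, C_EMBED)
        s_shift = float(np.sqrt(np.mean(shift.data ** 2)))
        if s_shift < 1e-12:
            return x + shift.reshape(n, 1, C_EMBED)
        # pin the context contribution at a fixed RMS ratio to the content
        # projection rather than a ratio set by initialisation chance
        s_base = float(np.sqrt(np.mean(x.data ** 2)) + 1e-12)
        gain = self.context_weight * s_base / s_shift
        return x + shift.reshape(n, 1, C_EMBED) * gain


def dictionary_query(X_s, E, tau: float):
    """Eq-style dictionary lookup: a_i = softmax(q_i Eᵀ / τ), x̃_i = a_i E."""
    if tau <= 0:
        raise ConfigurationError("temperature must be positive")
    tensors = isinstance(X_s, Tensor) or isinstance(E, Tensor)
    Xt = X_s if isinstance(X_s, Tensor) else Tensor(np.asarray(X_s, dtype=float))
    Et = E if isinstance(E, Tensor) else Tensor(np.asarray(E, dtype=float))
    ET = Et.transpose(1, 0)
    a = ((Xt @ ET) * (1.0 / tau)).softmax(axis=-1)
    x_tilde = a @ Et
    if tensors:
        return a, x_tilde
    return a.data, x_tilde.data


class Dictionary(nn.Module):
    """Learnable embedding dictionary E ∈ R^{K×C_e} with temperature τ."""

    def __init__(self, k: int = 256, c_e: int = C_EMBED, tau: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.E = Tensor(rng.normal(0, 0.5, size=(k, c_e)), requires_grad=True)
        if tau <= 0:
            raise ConfigurationError("temperature must be positive")
        self.tau = tau

    def forward(self, X_s: Tensor):
        return dictionary_query(X_s, self.E, self.tau)


class GateMLP(nn.Module):
    """Two-layer perceptron gate, hidden width 32: g = σ(W₂ φ(W₁ x))."""

    HIDDEN = 32

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.w1 = nn.Linear(C_EMBED, self.HIDDEN, rng)
        self.w2 = nn.Linear(self.HIDDEN, C_EMBED, rng)
        # gates start mildly open (sigma(1) ~ 0.73): specific cues pass from
        # the first epochs, with training free to close them at noisy sites
        self.w2.bias.data[...] = 1.0

    def forward(self, x_d: Tensor) -> Tensor:
        return self.w2(self.w1(x_d).relu()).sigmoid()


def gated_assembly(x_tilde, X_d, gate: "GateMLP | None" = None,
                   force_gate: float | None = None):
    """y_i = x̃_i + g_i ⊙ (X_d(i) − x̃_i); returns (g, y).

    ``force_gate`` pins the gate to a constant (test hook); otherwise the
    gate MLP computes it from X_d.
    """
    tensors = isinstance(x_tilde, Tensor) or isinstance(X_d, Tensor)
    xt = x_tilde if isinstance(x_tilde, Tensor) else Tensor(np.asarray(x_tilde, dtype=float))
    xd = X_d if isinstance(X_d, Tensor) else Tensor(np.asarray(X_d, dtype=float))
    if xt.shape != xd.shape:
        raise InputError("x̃ and X_d shapes must agree")
    if force_gate is not None:
        g = Tensor(np.full(xt.shape, float(force_gate)))
    elif gate is not None:
        g = gate(xd)
    else:
        raise InputError("either a gate module or force_gate is required")
    y = xt + g * (xd - xt)
    if tensors:
        return g, y
    return g.data, y.data


class FeatureReconstructor(nn.Module):
    """Position-wise map C_e → C giving the feature reconstruction F̂."""

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        self.fc = nn.Linear(C_EMBED, C_FEAT, rng or np.random.default_rng(0))

    def forward(self, y_seq: Tensor, grid: tuple[int, int, int]) -> Tensor:
        n = y_seq.shape[0]
        f_hat = self.fc(y_seq)                                # (N, Np, C)
        return f_hat.transpose(0, 2, 1).reshape(n, C_FEAT, *grid)


def _upsample_nearest3d(x: Tensor, f: int = 2) -> Tensor:
    n, c, d, h, w = x.shape
    y = x.reshape(n, c, d, 1, h, 1, w, 1) * Tensor(np.ones((1, 1, 1, f, 1, f, 1, f)))
    return y.reshape(n, c, d * f, h * f, w * f)


class Decoder3D(nn.Module):
    """Lightweight 3D upsampling decoder (visualization path): three ×2
    stages with channel progression 64→48→32→16, then a 1×1×1 projection to
    a single intensity channel."""

    CHANNELS = (64, 48, 32, 16)

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        chans = self.CHANNELS
        for i in range(3):
            setattr(self, f"conv{i}", nn.Conv3d(chans[i], chans[i + 1], 3, rng, pad=1))
        self.head = nn.Conv3d(chans[-1], 1, 1, rng)

    def forward(self, Y: Tensor) -> Tensor:
        h = Y
        for i in range(3):
            h = getattr(self, f"conv{i}")(_upsample_nearest3d(h)).relu()
        return self.head(h)


class GradingHead(nn.Module):
    """Global average pooling of Y to u ∈ R^64, then 64→32→G with softmax."""

    def __init__(self, n_grades: int = 2, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(C_EMBED, 32, rng)
        self.fc2 = nn.Linear(32, n_grades, rng)

    def forward(self, y_seq: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """y_seq (N, Np, C_e) -> (u, logits, posteriors)."""
        u = y_seq.mean(axis=1)
        logits = self.fc2(self.fc1(u).relu())
        return u, logits, logits.softmax(axis=-1)


def subtype_assign(u, prototypes, kappa_proto: float):
    """π_m = softmax_m(−‖u − μ_m‖² / κ_proto)."""
    if kappa_proto <= 0:
        raise ConfigurationError("kappa_proto must be positive")
    tensors = isinstance(u, Tensor) or isinstance(prototypes, Tensor)
    ut = u if isinstance(u, Tensor) else Tensor(np.atleast_2d(np.asarray(u, dtype=float)))
    mt = prototypes if isinstance(prototypes, Tensor) else Tensor(np.asarray(prototypes, dtype=float))
    n, d = ut.shape
    m = mt.shape[0]
    diff = ut.reshape(n, 1, d) - mt.reshape(1, m, d)
    d2 = (diff * diff).sum(axis=-1)
    pi = (d2 * (-1.0 / kappa_proto)).softmax(axis=-1)
    return pi if tensors else pi.data


class PrototypeHead(nn.Module):
    """M learnable subtype centers with Gaussian-kernel soft assignment."""

    def __init__(self, m: int = 2, dim: int = C_EMBED, kappa_proto: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if m < 2:
            raise ConfigurationError("need at least 2 prototypes")
        rng = rng or np.random.default_rng(0)
        self.mu = Tensor(rng.normal(0, 0.5, size=(m, dim)), requires_grad=True)
        self.kappa_proto = kappa_proto

    def forward(self, u: Tensor) -> Tensor:
        return subtype_assign(u, self.mu, self.kappa_proto)

    def init_from(self, u_data: np.ndarray, seed: int = 0,
                  response_labels: np.ndarray | None = None):
        """Initialise the centers from pooled representations.

        Without labels: k-means++.  With training response labels: centers
        start at the response-class means (the follow-up signal orients the
        subtype axis, which an unsupervised seeding cannot recover at small
        n) and are refined by a few k-means iterations before joint
        optimisation takes over.
        """
        from sklearn.cluster import KMeans
        u = np.asarray(u_data, dtype=float)
        m = self.mu.shape[0]
        if response_labels is not None and np.unique(response_labels).size >= 2:
            r = np.asarray(response_labels).astype(int)
            if m == 2:
                # class-mean difference denoised by projection onto the
                # leading principal subspace: the raw 64-dim mean difference
                # carries sampling noise comparable to the subtype axis at
                # this n, the leading-variance subspace retains the axis
                diff = u[r == 0].mean(axis=0) - u[r == 1].mean(axis=0)
                center = u.mean(axis=0)
                q = min(16, u.shape[1], max(2, u.shape[0] - 1))
                uc = u - center
                _, _, vt = np.linalg.svd(uc, full_matrices=False)
                basis = vt[:q]
                diff_dn = basis.T @ (basis @ diff)
                seeds_init = np.stack([center - diff_dn / 2, center + diff_dn / 2])
                # few refinement sweeps only: at borderline separation longer
                # unsupervised refinement drifts toward dominant-variance
                # splits and away from the response-oriented axis
                km = KMeans(n_clusters=m, init=seeds_init, n_init=1, max_iter=2,
                            random_state=seed).fit(u)
                self.mu.data[...] = km.cluster_centers_
                return self
        km = KMeans(n_clusters=m, n_init=1, init="k-means++",
                    random_state=seed).fit(u)
        self.mu.data[...] = km.cluster_centers_
        return self


@dataclass(frozen=True)
class LossBreakdown:
    l_grade: float
    compactness: float
    reconstruction: float
    lam: float
    beta: float

    @property
    def total(self) -> float:
        return self.l_grade + self.lam * self.compactness + self.beta * self.reconstruction


def joint_loss(posteriors, y_g, u, prototypes, pi, F, F_hat,
               lam: float = 0.1, beta: float = 0.05) -> LossBreakdown:
    """Numeric evaluation of L = L_grade + λ Σ_m π_m ‖u − μ_m‖² + β ‖F − F̂‖₁.

    L_grade is mean cross-entropy of the grade posteriors; compactness and
    reconstruction are batch means.
    """
    post = np.atleast_2d(np.asarray(posteriors, dtype=float))
    y = np.atleast_1d(np.asarray(y_g, dtype=int))
    l_grade = float(-np.mean(np.log(post[np.arange(len(y)), y] + 1e-300)))
    uu = np.atleast_2d(np.asarray(u, dtype=float))
    mu = np.asarray(prototypes, dtype=float)
    pp = np.atleast_2d(np.asarray(pi, dtype=float))
    d2 = ((uu[:, None, :] - mu[None]) ** 2).sum(axis=-1)
    compact = float(np.mean((pp * d2).sum(axis=-1)))
    recon = float(np.mean(np.abs(np.asarray(F, dtype=float) - np.asarray(F_hat, dtype=float))
                          .reshape(len(uu), -1).sum(axis=-1)))
    return LossBreakdown(l_grade=l_grade, compactness=compact,
                         reconstruction=recon, lam=lam, beta=beta)


def subtype_map(gates: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """S_m(p) = E[g_p π_m] over a patient set.

    ``gates``: (P, Np) scalar gate activity per position (channel-averaged);
    ``pi``: (P, M) soft subtype assignments.  Returns (M, Np) with values in
    [0, 1].
    """
    g = np.asarray(gates, dtype=float)
    p = np.asarray(pi, dtype=float)
    if g.ndim != 2 or p.ndim != 2 or g.shape[0] != p.shape[0]:
        raise InputError("gates (P, Np) and pi (P, M) must share the patient axis")
    return np.einsum("pn,pm->mn", g, p) / g.shape[0]


class CollabModel(nn.Module):
    """Full collaborative head: shared encoder → projectors → dictionary →
    gated assembly → heads, with the visualization decoder alongside."""

    def __init__(self, in_channels: int = 1, n_grades: int = 2, m_subtypes: int = 2,
                 k_dict: int = 256, tau: float = 1.0, kappa_proto: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.encoder = SharedEncoder3D(in_channels, rng)
        self.p_a = GenericProjector(rng)
        self.p_d = SpecificProjector(rng)
        self.dictionary = Dictionary(k_dict, C_EMBED, tau, rng)
        self.gate = GateMLP(rng)
        self.recon = FeatureReconstructor(rng)
        self.decoder = Decoder3D(rng)
        self.grading = GradingHead(n_grades, rng)
        self.prototypes = PrototypeHead(m_subtypes, C_EMBED, kappa_proto, rng)

    def forward(self, volumes, context, force_gate: float | None = None,
                precomputed_F: Tensor | None = None) -> dict:
        F = precomputed_F if precomputed_F is not None else self.encoder(volumes)
        grid = F.shape[2:]
        X_s = self.p_a(F)
        X_d = self.p_d(F, context)
        a, x_tilde = self.dictionary(X_s)
        g, y = gated_assembly(x_tilde, X_d, self.gate, force_gate=force_gate)
        u, logits, posteriors = self.grading(y)
        pi = self.prototypes(u)
        F_hat = self.recon(y, grid)
        n = y.shape[0]
        Y = y.transpose(0, 2, 1).reshape(n, C_EMBED, *grid)
        return {"F": F, "X_s": X_s, "X_d": X_d, "a": a, "x_tilde": x_tilde,
                "gate": g, "y_seq": y, "Y": Y, "u": u, "logits": logits,
                "posteriors": posteriors, "pi": pi, "F_hat": F_hat}

    def loss(self, out: dict, y_g, lam: float = 0.1, beta: float = 0.05) -> tuple[Tensor, LossBreakdown]:
        """Differentiable joint loss plus its numeric breakdown."""
        l_grade = nn.cross_entropy(out["logits"], y_g)
        u, mu, pi = out["u"], self.prototypes.mu, out["pi"]
        n, d = u.shape
        m = mu.shape[0]
        diff = u.reshape(n, 1, d) - mu.reshape(1, m, d)
        compact = (pi * (diff * diff).sum(axis=-1)).sum(axis=-1).mean()
        recon = (out["F"] - out["F_hat"]).abs().reshape(n, -1).sum(axis=-1).mean()
        total = l_grade + compact * lam + recon * beta
        breakdown = LossBreakdown(l_grade=float(l_grade.data),
                                  compactness=float(compact.data),
                                  reconstruction=float(recon.data),
                                  lam=lam, beta=beta)
        return total, breakdown
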