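"""Grade-guided multimodal fusion.

The four branch vectors (widths 512/16/32/64) are linearly aligned to a
common width D = 128.  A learnable embedding of the pathological grade
(width d_g = 32), optionally combined with a response-status embedding
during training, forms a conditional context g.  Conditional gated attention
scores each aligned modality as

    s_m = vᵀ tanh(A h̃_m + B g + c_bias),      α = softmax(s),

and fuses z = Σ_m α_m h̃_m, z_fus = ReLU(W_f z + b_f).  A residual pathway
carries the raw imaging concatenation u_fus (width 560 = 512 + 16 + 32,
optionally +64 clinical) alongside z_fus.  Entropy regularisation of α and
the convexity-based noise-variance bound Σ α² v ≤ Σ α v are provided as
standalone operations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .autodiff import Tensor, concat, stack
from .encoders import BRANCH_WIDTHS
from .exceptions import InputError

__all__ = [
    "GuidanceContext", "GradeEmbedding", "ModalityAligner", "GatedAttention",
    "FusionLayer", "residual_concat", "entropy_penalty", "fused_noise_variance",
    "D_ALIGNED", "D_GRADE", "IMAGING_RESIDUAL_WIDTH",
]

D_ALIGNED = 128
D_GRADE = 32
IMAGING_RESIDUAL_WIDTH = BRANCH_WIDTHS["res"] + BRANCH_WIDTHS["dir"] + BRANCH_WIDTHS["enc"]  # 560
MODALITY_ORDER = ("res", "dir", "enc", "cli")


@dataclass
class GuidanceContext:
    y_g: np.ndarray                    # grade labels (N,)
    context: Tensor                    # (N, 32)
    y_r: np.ndarray | None = None      # response labels, training only


class GradeEmbedding(nn.Module):
    """Learnable grade embedding (d_g = 32) plus, during training, a
    response-status embedding projected to the same width and added.
    At inference the response label is absent and the context degrades to
    grade-only."""

    def __init__(self, n_grades: int = 2, n_responses: int = 2,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.grade = nn.Embedding(n_grades, D_GRADE, rng)
        self.response = nn.Embedding(n_responses, D_GRADE, rng)
        self.resp_proj = nn.Linear(D_GRADE, D_GRADE, rng)

    def forward(self, y_g, y_r=None) -> GuidanceContext:
        y_g = np.atleast_1d(np.asarray(y_g, dtype=int))
        g = self.grade(y_g)
        if y_r is not None:
            y_r = np.atleast_1d(np.asarray(y_r, dtype=int))
            g = g + self.resp_proj(self.response(y_r))
        return GuidanceContext(y_g=y_g, context=g, y_r=y_r)


class ModalityAligner(nn.Module):
    """Affine maps h̃_m = W_m h_m + b_m to the unified width D = 128."""

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        for name, width in BRANCH_WIDTHS.items():
            setattr(self, f"w_{name}", nn.Linear(width, D_ALIGNED, rng))

    def forward(self, h_res, h_dir, h_enc, h_cli) -> Tensor:
        """Returns the aligned stack (N, 4, D) in order res, dir, enc, cli."""
        vecs = {"res": h_res, "dir": h_dir, "enc": h_enc, "cli": h_cli}
        aligned = []
        for name in MODALITY_ORDER:
            v = vecs[name]
            v = v if isinstance(v, Tensor) else Tensor(np.atleast_2d(np.asarray(v, dtype=float)))
            if v.shape[-1] != BRANCH_WIDTHS[name]:
                raise InputError(f"h_{name} must have width {BRANCH_WIDTHS[name]}, "
                                 f"got {v.shape[-1]}")
            aligned.append(getattr(self, f"w_{name}")(v))
        return stack(aligned, axis=1)


class GatedAttention(nn.Module):
    """Conditional gated attention: s_m = vᵀ tanh(A h̃_m + B g + c_bias).

    ``c_bias`` is the additive bias of the score (the fusion equations' c,
    renamed to avoid clashing with the collaborative module's clinical
    context vector).  A shared score vector v is used across modalities; a
    per-modality v is available behind ``per_modality_v``.
    """

    def __init__(self, d_attn: int = 32, per_modality_v: bool = False,
                 n_modalities: int = 4, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.A = Tensor(rng.normal(0, 0.2, size=(D_ALIGNED, d_attn)), requires_grad=True)
        self.B = Tensor(rng.normal(0, 0.2, size=(D_GRADE, d_attn)), requires_grad=True)
        self.c_bias = Tensor(np.zeros(d_attn), requires_grad=True)
        if per_modality_v:
            self.v = Tensor(rng.normal(0, 0.2, size=(n_modalities, d_attn)), requires_grad=True)
        else:
            self.v = Tensor(rng.normal(0, 0.2, size=(d_attn,)), requires_grad=True)
        self.per_modality_v = per_modality_v

    def forward(self, aligned: Tensor, context: Tensor | None) -> tuple[Tensor, Tensor]:
        """aligned (N, M, D), context (N, 32) or None -> (α (N, M), z (N, D))."""
        pre = aligned @ self.A                                   # (N, M, d_a)
        if context is not None:
            ctx = context if isinstance(context, Tensor) else Tensor(context)
            pre = pre + (ctx @ self.B).reshape(ctx.shape[0], 1, -1)
        pre = (pre + self.c_bias).tanh()
        if self.per_modality_v:
            s = (pre * self.v).sum(axis=-1)
        else:
            s = (pre * self.v.reshape(1, 1, -1)).sum(axis=-1)    # (N, M)
        alpha = s.softmax(axis=-1)
        z = (alpha.reshape(*alpha.shape, 1) * aligned).sum(axis=1)
        return alpha, z


class FusionLayer(nn.Module):
    """z_fus = ReLU(W_f z + b_f), width D."""

    def __init__(self, rng: np.random.Generator | None = None):
        super().__init__()
        self.w_f = nn.Linear(D_ALIGNED, D_ALIGNED, rng or np.random.default_rng(0))

    def forward(self, z: Tensor) -> Tensor:
        return self.w_f(z).relu()


def residual_concat(z_fus, h_res, h_dir, h_enc, h_cli=None,
                    include_clinical: bool = False):
    """Residual pathway: the raw imaging concatenation [h_res; h_dir; h_enc]
    of width 560, with the clinical 64-vector optionally appended.  z_fus is
    carried alongside (returned separately), not folded into the 560."""
    parts = [np.atleast_2d(np.asarray(h, dtype=float)) for h in (h_res, h_dir, h_enc)]
    if include_clinical:
        if h_cli is None:
            raise InputError("include_clinical requires h_cli")
        parts.append(np.atleast_2d(np.asarray(h_cli, dtype=float)))
    u_fus = np.concatenate(parts, axis=-1)
    z = z_fus.data if isinstance(z_fus, Tensor) else np.asarray(z_fus, dtype=float)
    return u_fus, z


def _check_simplex(alpha: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    if (alpha < -tol).any() or (np.abs(alpha.sum(axis=-1) - 1.0) > tol).any():
        raise InputError("attention weights must lie on the probability simplex")
    return alpha


def entropy_penalty(alpha, gamma: float) -> float:
    """L_gate = γ · E[−Σ_m α_m log α_m], with 0·log 0 ≡ 0."""
    if gamma < 0:
        raise InputError("gamma must be non-negative")
    a = _check_simplex(alpha)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(a > 0, a * np.log(a), 0.0)
    return float(gamma * np.mean(-terms.sum(axis=-1)))


def entropy_penalty_tensor(alpha: Tensor, gamma: float, eps: float = 1e-12) -> Tensor:
    """Differentiable variant of :func:`entropy_penalty` for training."""
    logs = (alpha + eps).log()
    return (alpha * logs).sum(axis=-1).mean() * (-gamma)


def fused_noise_variance(alpha, variances) -> tuple[np.ndarray, np.ndarray]:
    """Variance of the fused noise under convex weights.

    actual = Σ α_m² Var(ε_m) (independent noises); bound = Σ α_m Var(ε_m).
    The inequality actual ≤ bound holds because 0 ≤ α_m ≤ 1, with equality
    exactly at one-hot α (for nondegenerate variances).
    """
    a = _check_simplex(alpha)
    v = np.atleast_2d(np.asarray(variances, dtype=float))
    if (v < 0).any():
        raise InputError("variances must be non-negative")
    actual = (a ** 2 * v).sum(axis=-1)
    bound = (a * v).sum(axis=-1)
    if actual.size == 1:
        return float(actual[0]), float(bound[0])
    return actual, bound
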