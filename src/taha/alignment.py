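"""Cross-species attention alignment.

A frozen snapshot of the source-pretrained backbone provides reference
attention maps ``A_h^s`` on target-domain images; the live copy being
adapted produces ``A_h^t`` on the same images.  Two losses drive the
adaptation:

* the **domain alignment loss** (DAL) per head — KL divergence
  ``KL(A_h^s || A_h^t)`` averaged over query rows and over the batch,
  with additive 1e-8 smoothing inside the logs.  Each post-softmax row
  is a probability distribution over keys, so row-wise KL is the
  natural granularity.  The direction matters: the frozen source map is
  always the first (reference) argument;
* the **phenotypic consistency constraint** (PCC) — squared L2 error of
  a small MLP predicting standardized one-hot phenotype labels from the
  pooled, concatenated head outputs.  Only labeled target samples
  contribute, matching the semi-supervised protocol (10-15% target
  labels).

The total objective is ``mean_h DAL_h + lambda * PCC`` with ``lambda``
warmed up linearly from 0.1 so alignment dominates early and phenotype
preservation dominates late.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, Adam, concat, gelu
from .backbone import VisionTransformer

__all__ = ["MLPHead", "AlignmentState", "domain_alignment_loss", "kl_alignment_term",
           "phenotypic_consistency_loss", "standardized_one_hot", "lambda_schedule",
           "alignment_step"]

_EPS = 1e-8


def domain_alignment_loss(source_maps: np.ndarray, target_maps: np.ndarray) -> float:
    """Per-head DAL between stacked row-stochastic attention maps.

    Both arguments are ``(..., n, n)`` arrays (any leading batch axes);
    returns the scalar mean over batch and query rows of row-wise
    ``KL(source || target)``.
    """
    source_maps = np.asarray(source_maps, dtype=np.float64)
    target_maps = np.asarray(target_maps, dtype=np.float64)
    if source_maps.shape != target_maps.shape:
        raise ValueError(
            f"shape mismatch: {source_maps.shape} vs {target_maps.shape}"
        )
    if (source_maps < 0).any() or (target_maps < 0).any():
        raise ValueError("attention maps must be non-negative")
    p = source_maps + _EPS
    q = target_maps + _EPS
    kl_rows = np.sum(source_maps * (np.log(p) - np.log(q)), axis=-1)
    return float(kl_rows.mean())


def kl_alignment_term(source_maps: np.ndarray, target_att: Tensor) -> Tensor:
    """Differentiable DAL: constant source maps vs live target attention."""
    if source_maps.shape != target_att.shape:
        raise ValueError("shape mismatch between source and target maps")
    p = source_maps
    const = Tensor(np.sum(p * np.log(p + _EPS), axis=-1))  # entropy term, no grad
    cross = (Tensor(p) * (target_att + _EPS).log()).sum(axis=-1)
    return (const - cross).mean()


def standardized_one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """One-hot labels z-scored per class column over the given set.

    Constant columns (class absent or universal) are left at zero so
    they carry no gradient.
    """
    Y = np.zeros((len(labels), n_classes))
    Y[np.arange(len(labels)), labels] = 1.0
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    out = np.zeros_like(Y)
    nz = sd > 0
    out[:, nz] = (Y[:, nz] - mu[nz]) / sd[nz]
    return out


class MLPHead:
    """One-hidden-layer phenotypic predictor f_MLP."""

    def __init__(self, d_in: int, n_classes: int, hidden: int = 32, seed: int = 0):
        rng = np.random.default_rng(seed)
        lim1 = np.sqrt(6.0 / (d_in + hidden))
        lim2 = np.sqrt(6.0 / (hidden + n_classes))
        self.w1 = Tensor(rng.uniform(-lim1, lim1, (d_in, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(rng.uniform(-lim2, lim2, (hidden, n_classes)), requires_grad=True)
        self.b2 = Tensor(np.zeros(n_classes), requires_grad=True)

    def __call__(self, z: Tensor) -> Tensor:
        return gelu(z @ self.w1 + self.b1) @ self.w2 + self.b2

    def parameters(self) -> list[Tensor]:
        return [self.w1, self.b1, self.w2, self.b2]


def phenotypic_consistency_loss(Z: Tensor | np.ndarray, y: np.ndarray,
                                mlp_head: MLPHead, n_classes: int | None = None) -> Tensor:
    """Mean squared L2 distance between standardized one-hot targets and f_MLP(Z).

    ``Z`` holds pooled concatenated head outputs for *labeled* samples
    only; an empty labeled set is an error (insufficient supervision).
    """
    Z = Z if isinstance(Z, Tensor) else Tensor(Z)
    if Z.shape[0] == 0:
        raise ValueError("no labeled samples: PCC needs at least one label")
    if Z.shape[0] != len(y):
        raise ValueError("Z and y are not co-indexed")
    if n_classes is None:
        n_classes = int(mlp_head.b2.data.shape[0])
    targets = standardized_one_hot(np.asarray(y), n_classes)
    resid = mlp_head(Z) - Tensor(targets)
    return (resid**2).sum(axis=1).mean()


def lambda_schedule(step: int, warmup_steps: int,
                    lambda0: float = 0.1, lambda_max: float = 1.0) -> float:
    """Linear warmup of the PCC weight from lambda0 to lambda_max."""
    if warmup_steps <= 0:
        raise ValueError("warmup_steps must be positive")
    if step < 0:
        raise ValueError("step must be >= 0")
    if step >= warmup_steps:
        return float(lambda_max)
    return float(lambda0 + (lambda_max - lambda0) * step / warmup_steps)


@dataclass
class AlignmentState:
    """Mutable state of the alignment phase.

    The frozen source snapshot is never updated; only the live model's
    attention parameters and the MLP head receive gradients (the patch
    embedding is frozen by default, switchable via ``update_patch_embed``).
    """

    frozen_source_model: VisionTransformer
    live_target_model: VisionTransformer
    mlp_head: MLPHead
    lambda0: float = 0.1
    lambda_max: float = 1.0
    warmup_steps: int = 50
    lr: float = 3e-5
    update_patch_embed: bool = False
    step: int = 0
    optimizer: Adam = field(init=False)

    def __post_init__(self):
        params = self.live_target_model.attention_parameters() + self.mlp_head.parameters()
        if self.update_patch_embed:
            params += [self.live_target_model.patch_w, self.live_target_model.patch_b,
                       self.live_target_model.pos]
        self.optimizer = Adam(params, lr=self.lr)

    @property
    def lambda_now(self) -> float:
        return lambda_schedule(self.step, self.warmup_steps, self.lambda0, self.lambda_max)


def alignment_step(state: AlignmentState, target_images: np.ndarray,
                   target_labels: np.ndarray, labeled_mask: np.ndarray,
                   head_masks: list[list[bool]] | None = None) -> dict:
    """One gradient step on ``mean_h DAL_h + lambda * PCC``.

    Source maps come from the frozen snapshot, target maps from the live
    model, both evaluated on the same target-domain images.  Returns the
    per-head DAL values, the PCC value, lambda and the total loss.
    """
    lam = state.lambda_now
    # frozen reference maps (no gradients)
    _, src_rec, _ = state.frozen_source_model.forward(
        target_images, head_masks=head_masks, collect_records=True, domain_tag="source"
    )
    # live forward keeps the graph
    _, _, aux = state.live_target_model.forward(
        target_images, head_masks=head_masks, collect_records=False, domain_tag="target"
    )

    dal_terms: list[Tensor] = []
    per_head_dal: dict[tuple[int, int], float] = {}
    z_pieces: list[Tensor] = []
    for li, coll in enumerate(aux):
        for h in sorted(coll):
            att, z = coll[h]
            term = kl_alignment_term(src_rec.maps[(li, h)], att)
            dal_terms.append(term)
            per_head_dal[(li, h)] = float(term.data)
            z_pieces.append(z.mean(axis=1))

    mean_dal = dal_terms[0]
    for t in dal_terms[1:]:
        mean_dal = mean_dal + t
    mean_dal = mean_dal / float(len(dal_terms))

    labeled_idx = np.flatnonzero(labeled_mask)
    if labeled_idx.size == 0:
        raise ValueError("alignment batch contains no labeled target samples")
    Z = concat(z_pieces, axis=1)[labeled_idx, :]
    pcc = phenotypic_consistency_loss(Z, target_labels[labeled_idx], state.mlp_head)

    total = mean_dal + lam * pcc
    if not np.isfinite(total.data):
        raise FloatingPointError(f"non-finite alignment loss at step {state.step}")

    state.optimizer.zero_grad()
    total.backward()
    state.optimizer.step()
    state.step += 1
    return {
        "per_head_dal": per_head_dal,
        "mean_dal": float(mean_dal.data),
        "pcc": float(pcc.data),
        "lambda": lam,
        "total": float(total.data),
    }
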