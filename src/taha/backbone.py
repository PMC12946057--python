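"""Configurable Vision Transformer exposing per-head attention maps.

The backbone is a standard pre-norm ViT (patch embedding + learned
positions + optional class token, then ``depth`` blocks of multi-head
self-attention and a GELU MLP, each with residual connections).  What
distinguishes it from an off-the-shelf ViT is bookkeeping: every MHSA
layer stores its per-head projection blocks separately so that

* each head's post-softmax attention map ``A_h`` (row-stochastic,
  ``n_tokens x n_tokens``) and value-weighted output ``Z_h`` can be
  recorded during a forward pass,
* individual heads can be masked out of the forward pass, and
* heads can later be physically removed (see :mod:`taha.surgery`).

Attention maps include the class-token row/column whenever the class
token is enabled; downstream alignment losses consume the full
``n_tokens x n_tokens`` matrix uniformly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor, concat, softmax, log_softmax, gelu, layer_norm

__all__ = ["ModelConfig", "AttentionRecord", "VisionTransformer", "patch_embed_tokens",
           "save_checkpoint", "load_checkpoint"]


@dataclass
class ModelConfig:
    """Architecture hyperparameters; also drives pure cost accounting.

    ``heads_per_layer`` may become ragged after pruning; ``head_dim``
    stays fixed at its initialization value ``embed_dim // H_init`` so
    pruning changes head count only.
    """

    image_size: int = 32
    patch_size: int = 16
    channels: int = 3
    depth: int = 2
    heads_per_layer: list[int] = field(default_factory=lambda: [4, 4])
    embed_dim: int = 32
    head_dim: int | None = None
    mlp_dim: int = 64
    n_classes: int = 4
    use_cls_token: bool = True

    def __post_init__(self):
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if len(self.heads_per_layer) != self.depth:
            raise ValueError("heads_per_layer length must equal depth")
        if any(h < 1 for h in self.heads_per_layer):
            raise ValueError("every layer needs at least one head")
        if self.head_dim is None:
            # unpruned config: head width derives from the uniform head count
            h0 = self.heads_per_layer[0]
            if self.embed_dim % h0 != 0:
                raise ValueError("embed_dim must be divisible by the initial head count")
            self.head_dim = self.embed_dim // h0
        elif self.head_dim < 1:
            raise ValueError("head_dim must be >= 1")

    @property
    def n_patches(self) -> int:
        return (self.image_size // self.patch_size) ** 2

    @property
    def n_tokens(self) -> int:
        return self.n_patches + (1 if self.use_cls_token else 0)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        return cls(**json.loads(s))


@dataclass
class AttentionRecord:
    """Per-head attention maps and head outputs for one batch.

    ``maps[(layer, head)]`` is a ``(B, n_tokens, n_tokens)`` row-stochastic
    array; ``head_outputs[(layer, head)]`` is ``(B, n_tokens, d_v)``.
    Masked heads do not appear.
    """

    maps: dict[tuple[int, int], np.ndarray]
    head_outputs: dict[tuple[int, int], np.ndarray]
    domain_tag: str = "source"


def patch_embed_tokens(image: np.ndarray, config: ModelConfig) -> int:
    """Validate image shape against ``config``; return the token count.

    Shape-contract helper used by loaders; the learned embedding itself
    lives in :class:`VisionTransformer`.
    """
    if image.ndim != 3:
        raise ValueError(f"expected H x W x C image, got shape {image.shape}")
    H, W, C = image.shape
    if H != config.image_size or W != config.image_size or C != config.channels:
        raise ValueError(
            f"image shape {image.shape} does not match config "
            f"({config.image_size}, {config.image_size}, {config.channels})"
        )
    if H % config.patch_size != 0:
        raise ValueError("image size not divisible by patch size")
    return config.n_tokens


def _init_linear(rng: np.random.Generator, d_in: int, d_out: int) -> np.ndarray:
    # Glorot-uniform
    lim = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-lim, lim, size=(d_in, d_out))


class VisionTransformer:
    """Tiny ViT with per-head parameter storage and head masking."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        patch_dim = c.patch_size * c.patch_size * c.channels
        P = lambda a: Tensor(a, requires_grad=True)

        self.patch_w = P(_init_linear(rng, patch_dim, c.embed_dim))
        self.patch_b = P(np.zeros(c.embed_dim))
        self.pos = P(rng.normal(0, 0.02, size=(c.n_tokens, c.embed_dim)))
        self.cls = P(rng.normal(0, 0.02, size=(c.embed_dim,))) if c.use_cls_token else None

        self.layers: list[dict] = []
        for H in c.heads_per_layer:
            d, dk = c.embed_dim, c.head_dim
            layer = {
                "ln1_g": P(np.ones(d)), "ln1_b": P(np.zeros(d)),
                "wq": [P(_init_linear(rng, d, dk)) for _ in range(H)],
                "bq": [P(np.zeros(dk)) for _ in range(H)],
                "wk": [P(_init_linear(rng, d, dk)) for _ in range(H)],
                "bk": [P(np.zeros(dk)) for _ in range(H)],
                "wv": [P(_init_linear(rng, d, dk)) for _ in range(H)],
                "bv": [P(np.zeros(dk)) for _ in range(H)],
                "wo": P(_init_linear(rng, H * dk, d)),
                "bo": P(np.zeros(d)),
                "ln2_g": P(np.ones(d)), "ln2_b": P(np.zeros(d)),
                "mlp_w1": P(_init_linear(rng, d, c.mlp_dim)),
                "mlp_b1": P(np.zeros(c.mlp_dim)),
                "mlp_w2": P(_init_linear(rng, c.mlp_dim, d)),
                "mlp_b2": P(np.zeros(d)),
            }
            self.layers.append(layer)
        self.final_g = P(np.ones(c.embed_dim))
        self.final_b = P(np.zeros(c.embed_dim))
        self.cls_w = P(_init_linear(rng, c.embed_dim, c.n_classes))
        self.cls_b = P(np.zeros(c.n_classes))

    # -- parameter access --------------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        out = {"patch_w": self.patch_w, "patch_b": self.patch_b, "pos": self.pos,
               "final_g": self.final_g, "final_b": self.final_b,
               "cls_w": self.cls_w, "cls_b": self.cls_b}
        if self.cls is not None:
            out["cls"] = self.cls
        for li, layer in enumerate(self.layers):
            for k, v in layer.items():
                if isinstance(v, list):
                    for h, t in enumerate(v):
                        out[f"layer{li}.{k}{h}"] = t
                else:
                    out[f"layer{li}.{k}"] = v
        return out

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def attention_parameters(self) -> list[Tensor]:
        """Head parameters: Q/K/V blocks and the output projection."""
        ps: list[Tensor] = []
        for layer in self.layers:
            for k in ("wq", "bq", "wk", "bk", "wv", "bv"):
                ps.extend(layer[k])
            ps.extend([layer["wo"], layer["bo"]])
        return ps

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def copy(self) -> "VisionTransformer":
        other = VisionTransformer(self.config, seed=0)
        src, dst = self.named_parameters(), other.named_parameters()
        for k in src:
            dst[k].data = src[k].data.copy()
        return other

    # -- forward -----------------------------------------------------------
    def patch_embed(self, images: np.ndarray) -> Tensor:
        """(B, H, W, C) images in [0,1] -> (B, n_tokens, d) token sequences."""
        c = self.config
        if images.ndim != 4:
            raise ValueError(f"expected B x H x W x C batch, got shape {images.shape}")
        B, H, W, C = images.shape
        if (H, W, C) != (c.image_size, c.image_size, c.channels):
            raise ValueError(
                f"batch shape {images.shape[1:]} does not match config "
                f"({c.image_size}, {c.image_size}, {c.channels})"
            )
        p = c.patch_size
        g = c.image_size // p
        # (B, g, p, g, p, C) -> (B, g*g, p*p*C)
        patches = images.reshape(B, g, p, g, p, C).transpose(0, 1, 3, 2, 4, 5)
        patches = patches.reshape(B, g * g, p * p * C)
        x = Tensor(patches) @ self.patch_w + self.patch_b
        if self.cls is not None:
            cls_tok = self.cls.reshape(1, 1, c.embed_dim) * Tensor(np.ones((B, 1, 1)))
            x = concat([cls_tok, x], axis=1)
        return x + self.pos

    def mhsa(self, x: Tensor, layer_idx: int,
             mask: list[bool] | None = None,
             collect: dict | None = None) -> Tensor:
        """Multi-head self-attention for one layer on pre-normed input.

        ``mask[h]`` False excludes head ``h`` from the concatenation and
        the matching rows of the output projection (algebraically equal
        to zeroing its contribution).  ``collect``, when given, receives
        per-head attention-map and head-output Tensors keyed by head.
        """
        layer = self.layers[layer_idx]
        H = self.config.heads_per_layer[layer_idx]
        dk = self.config.head_dim
        if mask is None:
            mask = [True] * H
        if len(mask) != H:
            raise ValueError(f"mask length {len(mask)} != head count {H}")
        if not any(mask):
            raise ValueError("all heads masked: at least one head must remain")
        if np.isnan(x.data).any():
            raise ValueError("NaN in attention input")

        head_outs, wo_rows = [], []
        for h in range(H):
            if not mask[h]:
                continue
            q = x @ layer["wq"][h] + layer["bq"][h]
            k = x @ layer["wk"][h] + layer["bk"][h]
            v = x @ layer["wv"][h] + layer["bv"][h]
            att = softmax(q @ k.transpose(0, 2, 1) / np.sqrt(dk), axis=-1)
            z = att @ v
            if collect is not None:
                collect[h] = (att, z)
            head_outs.append(z)
            wo_rows.append(layer["wo"][h * dk:(h + 1) * dk, :])
        zcat = concat(head_outs, axis=-1)
        wo = concat(wo_rows, axis=0) if len(wo_rows) < H else layer["wo"]
        return zcat @ wo + layer["bo"]

    def forward(self, images: np.ndarray,
                head_masks: list[list[bool]] | None = None,
                collect_records: bool = False,
                domain_tag: str = "source"):
        """Full forward pass.

        Returns ``(scores, record, aux)`` where ``scores`` is a
        ``(B, n_classes)`` Tensor, ``record`` an :class:`AttentionRecord`
        (or None), and ``aux`` holds the live per-head attention/output
        Tensors per layer for differentiable alignment losses.
        """
        if images.shape[0] == 0:
            raise ValueError("empty batch")
        x = self.patch_embed(images)
        aux: list[dict] = []
        for li, layer in enumerate(self.layers):
            mask = head_masks[li] if head_masks is not None else None
            coll: dict = {}
            normed = layer_norm(x, layer["ln1_g"], layer["ln1_b"])
            x = x + self.mhsa(normed, li, mask=mask, collect=coll)
            aux.append(coll)
            normed2 = layer_norm(x, layer["ln2_g"], layer["ln2_b"])
            h = gelu(normed2 @ layer["mlp_w1"] + layer["mlp_b1"])
            x = x + (h @ layer["mlp_w2"] + layer["mlp_b2"])
        x = layer_norm(x, self.final_g, self.final_b)
        pooled = x[:, 0, :] if self.config.use_cls_token else x.mean(axis=1)
        scores = pooled @ self.cls_w + self.cls_b

        record = None
        if collect_records:
            maps, outs = {}, {}
            for li, coll in enumerate(aux):
                for h, (att, z) in coll.items():
                    maps[(li, h)] = att.data.copy()
                    outs[(li, h)] = z.data.copy()
            record = AttentionRecord(maps=maps, head_outputs=outs, domain_tag=domain_tag)
        return scores, record, aux

    def predict(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Class predictions (argmax over scores), no gradient tracking."""
        preds = []
        for i in range(0, len(images), batch_size):
            scores, _, _ = self.forward(images[i:i + batch_size])
            preds.append(np.argmax(scores.data, axis=1))
        return np.concatenate(preds)

    def concatenated_head_outputs(self, images: np.ndarray) -> np.ndarray:
        """Token-mean-pooled Z_h per head, concatenated in (layer, head) order.

        Returns a ``(B, total_heads * d_v)`` array; this is the pooled form
        of the concatenated head outputs used by the phenotypic MLP and
        the head-label correlation.
        """
        _, rec, _ = self.forward(images, collect_records=True)
        pieces = [rec.head_outputs[key].mean(axis=1) for key in sorted(rec.head_outputs)]
        return np.concatenate(pieces, axis=1)


def forward_with_records(model: VisionTransformer, images: np.ndarray,
                         domain_tag: str = "source"):
    """(scores, record, pooled concatenated head outputs Z) for a batch."""
    scores, record, _ = model.forward(images, collect_records=True, domain_tag=domain_tag)
    pieces = [record.head_outputs[k].mean(axis=1) for k in sorted(record.head_outputs)]
    Z = np.concatenate(pieces, axis=1)
    return scores, record, Z


def cross_entropy(scores: Tensor, labels: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from raw scores."""
    logp = log_softmax(scores, axis=-1)
    picked = logp[np.arange(len(labels)), labels]
    return -picked.mean()


# -- checkpoint I/O ---------------------------------------------------------

def save_checkpoint(model: VisionTransformer, path: str) -> None:
    arrays = {k: v.data for k, v in model.named_parameters().items()}
    arrays["__config__"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> VisionTransformer:
    with np.load(path) as npz:
        cfg = ModelConfig.from_json(bytes(npz["__config__"].tobytes()).decode())
        model = VisionTransformer(cfg, seed=0)
        params = model.named_parameters()
        for k in params:
            params[k].data = npz[k].copy()
    return model
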