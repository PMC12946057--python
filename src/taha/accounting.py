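"""Exact parameter and multiply-accumulate accounting for the backbone.

Costs are computed analytically from a :class:`~taha.backbone.ModelConfig`
(possibly with ragged per-layer head counts after pruning), so reports
can be produced without instantiating a model.  Conventions:

* 1 MAC is reported as 1 "FLOP", the vision-community convention for
  transformer cost tables; under it a 12-layer, 12-head, d=768 ViT at
  224x224 with 16-px patches comes out at 17.6 GFLOPs (3 significant
  figures).
* MACs count the patch-embedding projection, the Q/K/V projections,
  attention score and value-weighting matmuls, the output projection
  and the two MLP matmuls; softmax, layer norms, GELU and the
  classifier head are excluded.
* Parameter counts cover patch embedding, positions, class token, all
  block parameters and the final norm; the classifier is excluded by
  default (``include_classifier=True`` adds it).
* Percent reductions are ``100 * (1 - pruned/full)`` rounded half-up to
  one decimal; giga-scale counts are shown to 3 significant figures.

The attention MAC terms are linear in the head count at fixed token
count and head width — removing heads shrinks ``O(H n^2 d)`` to
``O(|H'| n^2 d)`` exactly proportionally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .backbone import ModelConfig

__all__ = ["CostReport", "count_params", "count_macs", "layer_attention_macs",
           "reduction_percent", "reduction_report", "vit_base_config", "giga"]


def vit_base_config(image_size: int = 224) -> ModelConfig:
    """The 12-layer / 12-head / d=768 backbone at 16-px patches."""
    return ModelConfig(
        image_size=image_size, patch_size=16, channels=3, depth=12,
        heads_per_layer=[12] * 12, embed_dim=768, head_dim=64,
        mlp_dim=3072, n_classes=1000, use_cls_token=True,
    )


def count_params(config: ModelConfig, include_classifier: bool = False) -> int:
    """Exact trainable-parameter count for ``config``."""
    d = config.embed_dim
    dk = config.head_dim
    patch_dim = config.patch_size**2 * config.channels
    total = patch_dim * d + d                       # patch projection + bias
    total += config.n_tokens * d                    # positional term
    if config.use_cls_token:
        total += d
    for H in config.heads_per_layer:
        total += 2 * d                              # ln1
        total += 3 * H * (d * dk + dk)              # Q/K/V blocks + biases
        total += H * dk * d + d                     # W_o' + bias
        total += 2 * d                              # ln2
        total += d * config.mlp_dim + config.mlp_dim
        total += config.mlp_dim * d + d
    total += 2 * d                                  # final norm
    if include_classifier:
        total += d * config.n_classes + config.n_classes
    return int(total)


def layer_attention_macs(n_tokens: int, n_heads: int, head_dim: int,
                         embed_dim: int) -> int:
    """MACs of one MHSA layer's attention arithmetic (no MLP, no norms).

    Q/K/V projections + score and weighting matmuls + output projection;
    linear in ``n_heads`` at fixed token count and head width — the
    operational form of the O(H n^2 d) attention cost.
    """
    n, H, dk, d = n_tokens, n_heads, head_dim, embed_dim
    return n * d * (3 * H * dk) + H * n * n * dk + H * n * n * dk + n * (H * dk) * d


def count_macs(config: ModelConfig, image_size: int | None = None) -> int:
    """Multiply-accumulate count of one forward pass (1 MAC = 1 "FLOP")."""
    if image_size is not None and image_size != config.image_size:
        config = ModelConfig(
            image_size=image_size, patch_size=config.patch_size,
            channels=config.channels, depth=config.depth,
            heads_per_layer=list(config.heads_per_layer),
            embed_dim=config.embed_dim, head_dim=config.head_dim,
            mlp_dim=config.mlp_dim, n_classes=config.n_classes,
            use_cls_token=config.use_cls_token,
        )
    d = config.embed_dim
    dk = config.head_dim
    n = config.n_tokens
    patch_dim = config.patch_size**2 * config.channels
    total = config.n_patches * patch_dim * d        # patch embedding
    for H in config.heads_per_layer:
        total += layer_attention_macs(n, H, dk, d)
        total += 2 * n * d * config.mlp_dim         # MLP
    return int(total)


def giga(x: float) -> float:
    """Value in units of 1e9, rounded to 3 significant figures."""
    g = x / 1e9
    if g == 0:
        return 0.0
    d = Decimal(repr(g))
    shift = d.adjusted()  # exponent of the leading digit
    quantum = Decimal(1).scaleb(shift - 2)
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def reduction_percent(full: float, pruned: float) -> float:
    """100 * (1 - pruned/full), half-up to 1 decimal; negative => invalid."""
    if full <= 0:
        raise ValueError("full cost must be positive")
    r = Decimal(repr(100.0 * (1.0 - pruned / full)))
    return float(r.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CostReport:
    heads_full: float
    heads_pruned_avg: float
    params_full: int
    params_pruned: int
    macs_full: int
    macs_pruned: int

    @property
    def heads_reduction(self) -> float:
        return reduction_percent(self.heads_full, self.heads_pruned_avg)

    @property
    def params_reduction(self) -> float:
        return reduction_percent(self.params_full, self.params_pruned)

    @property
    def macs_reduction(self) -> float:
        return reduction_percent(self.macs_full, self.macs_pruned)

    @property
    def valid(self) -> bool:
        return (self.heads_pruned_avg <= self.heads_full
                and self.params_pruned <= self.params_full
                and self.macs_pruned <= self.macs_full)

    def to_dict(self) -> dict:
        return {
            "heads_full": self.heads_full,
            "heads_pruned_avg": round(self.heads_pruned_avg, 1),
            "heads_reduction_pct": self.heads_reduction,
            "params_full": self.params_full,
            "params_pruned": self.params_pruned,
            "params_reduction_pct": self.params_reduction,
            "macs_full": self.macs_full,
            "macs_pruned": self.macs_pruned,
            "macs_full_g": giga(self.macs_full),
            "macs_pruned_g": giga(self.macs_pruned),
            "macs_reduction_pct": self.macs_reduction,
            "valid": self.valid,
        }

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(self.to_dict(), indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def to_table(self) -> pd.DataFrame:
        """Cost-breakdown table (component, full, pruned, reduction)."""
        rows = [
            ("Attention Heads", self.heads_full, round(self.heads_pruned_avg, 1),
             f"{self.heads_reduction}%"),
            ("FLOPs (G)", giga(self.macs_full), giga(self.macs_pruned),
             f"{self.macs_reduction}%"),
            ("Parameters", self.params_full, self.params_pruned,
             f"{self.params_reduction}%"),
        ]
        return pd.DataFrame(rows, columns=["component", "full", "pruned", "reduction"])


def reduction_report(full: ModelConfig, pruned: ModelConfig) -> CostReport:
    """Cost comparison between a full and a pruned configuration."""
    if full.depth != pruned.depth:
        raise ValueError("configs must share depth")
    heads_full = sum(full.heads_per_layer) / full.depth
    heads_pruned = sum(pruned.heads_per_layer) / pruned.depth
    return CostReport(
        heads_full=heads_full,
        heads_pruned_avg=heads_pruned,
        params_full=count_params(full),
        params_pruned=count_params(pruned),
        macs_full=count_macs(full),
        macs_pruned=count_macs(pruned),
    )
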