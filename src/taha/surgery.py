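"""Physical removal of pruned attention heads.

Pruning here means *surgery*, not masking: the retained heads' Q/K/V
projection blocks are copied (in their original order) into a smaller
layer and the output projection keeps only the row blocks that multiply
the retained heads' value slices, yielding the reduced matrix
``W_o' of shape (|H'| * d_v, d)``.  Because the dropped rows of ``W_o``
are exactly the rows that would have multiplied the dropped concat
slices, the compact model's forward pass is algebraically identical to
the original model with those heads' outputs zeroed — an equivalence
the test suite checks numerically.  The feature dimension ``d`` is
unchanged, so the compact layer drops into the same backbone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backbone import ModelConfig, VisionTransformer
from .transferability import PruneMask

__all__ = ["PrunedLayerSpec", "rebuild_pruned_layer", "prune_model"]


@dataclass
class PrunedLayerSpec:
    retained_heads: list[int]
    wq: list[np.ndarray]
    bq: list[np.ndarray]
    wk: list[np.ndarray]
    bk: list[np.ndarray]
    wv: list[np.ndarray]
    bv: list[np.ndarray]
    wo_prime: np.ndarray
    bo: np.ndarray


def rebuild_pruned_layer(layer: dict, retained_heads: list[int],
                         head_dim: int) -> PrunedLayerSpec:
    """Slice one MHSA layer down to its retained heads."""
    if len(retained_heads) == 0:
        raise ValueError("cannot prune every head of a layer")
    retained = sorted(retained_heads)
    wo_rows = [layer["wo"].data[h * head_dim:(h + 1) * head_dim, :] for h in retained]
    return PrunedLayerSpec(
        retained_heads=retained,
        wq=[layer["wq"][h].data.copy() for h in retained],
        bq=[layer["bq"][h].data.copy() for h in retained],
        wk=[layer["wk"][h].data.copy() for h in retained],
        bk=[layer["bk"][h].data.copy() for h in retained],
        wv=[layer["wv"][h].data.copy() for h in retained],
        bv=[layer["bv"][h].data.copy() for h in retained],
        wo_prime=np.concatenate(wo_rows, axis=0),
        bo=layer["bo"].data.copy(),
    )


def prune_model(model: VisionTransformer, mask: PruneMask) -> VisionTransformer:
    """Build the compact model with pruned heads physically removed.

    Raises if the mask does not cover the model's current architecture
    or would empty a layer.
    """
    cfg = model.config
    new_heads = []
    layer_specs: list[PrunedLayerSpec] = []
    for li in range(cfg.depth):
        H = cfg.heads_per_layer[li]
        keys = [(li, h) for h in range(H)]
        if any(k not in mask.retain for k in keys):
            raise ValueError(f"mask does not cover all heads of layer {li}")
        retained = [h for h in range(H) if mask.retain[(li, h)]]
        spec = rebuild_pruned_layer(model.layers[li], retained, cfg.head_dim)
        layer_specs.append(spec)
        new_heads.append(len(retained))

    new_cfg = ModelConfig(
        image_size=cfg.image_size, patch_size=cfg.patch_size, channels=cfg.channels,
        depth=cfg.depth, heads_per_layer=new_heads, embed_dim=cfg.embed_dim,
        head_dim=cfg.head_dim, mlp_dim=cfg.mlp_dim, n_classes=cfg.n_classes,
        use_cls_token=cfg.use_cls_token,
    )
    compact = VisionTransformer(new_cfg, seed=0)

    # copy non-attention parameters verbatim
    compact.patch_w.data = model.patch_w.data.copy()
    compact.patch_b.data = model.patch_b.data.copy()
    compact.pos.data = model.pos.data.copy()
    if model.cls is not None:
        compact.cls.data = model.cls.data.copy()
    compact.final_g.data = model.final_g.data.copy()
    compact.final_b.data = model.final_b.data.copy()
    compact.cls_w.data = model.cls_w.data.copy()
    compact.cls_b.data = model.cls_b.data.copy()

    for li, spec in enumerate(layer_specs):
        src, dst = model.layers[li], compact.layers[li]
        for k in ("ln1_g", "ln1_b", "ln2_g", "ln2_b",
                  "mlp_w1", "mlp_b1", "mlp_w2", "mlp_b2"):
            dst[k].data = src[k].data.copy()
        for j, _ in enumerate(spec.retained_heads):
            dst["wq"][j].data = spec.wq[j]
            dst["bq"][j].data = spec.bq[j]
            dst["wk"][j].data = spec.wk[j]
            dst["bk"][j].data = spec.bk[j]
            dst["wv"][j].data = spec.wv[j]
            dst["bv"][j].data = spec.bv[j]
        dst["wo"].data = spec.wo_prime
        dst["bo"].data = spec.bo
    return compact
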