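"""Backbone contracts: token counts, attention records, oracle equivalence."""

import numpy as np
import pytest

from taha import ModelConfig, VisionTransformer, forward_with_records
from taha.backbone import (cross_entropy, load_checkpoint, patch_embed_tokens,
                           save_checkpoint)


# -- token-count contract ---------------------------------------------------

@pytest.mark.parametrize("image_size,patch,cls,expected", [
    (224, 16, True, 197),
    (16, 4, False, 16),
    (32, 16, True, 5),
])
def test_patch_embed_token_count(image_size, patch, cls, expected):
    cfg = ModelConfig(image_size=image_size, patch_size=patch, depth=1,
                      heads_per_layer=[2], embed_dim=8, mlp_dim=8,
                      use_cls_token=cls)
    img = np.zeros((image_size, image_size, 3))
    assert patch_embed_tokens(img, cfg) == expected
    assert cfg.n_tokens == expected


def test_non_divisible_image_size_rejected():
    with pytest.raises(ValueError, match="divisible"):
        ModelConfig(image_size=30, patch_size=16, depth=1, heads_per_layer=[2],
                    embed_dim=8, mlp_dim=8)


def test_wrong_image_shape_rejected(tiny_model, rng):
    with pytest.raises(ValueError, match="shape"):
        tiny_model.forward(rng.random((2, 8, 8, 3)))


# -- attention degenerate cases --------------------------------------------

def test_single_token_attention_is_identity(rng):
    """With one key, every softmax row is the single value 1.0."""
    cfg = ModelConfig(image_size=4, patch_size=4, depth=1, heads_per_layer=[2],
                      embed_dim=8, mlp_dim=8, use_cls_token=False)
    model = VisionTransformer(cfg, seed=0)
    _, rec, _ = model.forward(rng.random((2, 4, 4, 3)), collect_records=True)
    for m in rec.maps.values():
        np.testing.assert_allclose(m, 1.0)


def test_identical_keys_give_uniform_rows():
    """Identical tokens have identical keys, so attention is uniform."""
    cfg = ModelConfig(image_size=16, patch_size=8, depth=1, heads_per_layer=[2],
                      embed_dim=8, mlp_dim=16, use_cls_token=False)
    model = VisionTransformer(cfg, seed=0)
    model.pos.data[:] = 0.0  # strip positions so every token is identical
    flat = np.full((1, cfg.image_size, cfg.image_size, cfg.channels), 0.5)
    _, rec, _ = model.forward(flat, collect_records=True)
    for m in rec.maps.values():
        np.testing.assert_allclose(m, 1.0 / cfg.n_tokens, atol=1e-12)


# -- oracle equivalence -----------------------------------------------------

def naive_mhsa(x, layer, head_dim, mask=None):
    """Independent dense attention oracle (pure numpy, per-head loop)."""
    H = len(layer["wq"])
    mask = mask or [True] * H
    outs = []
    wo_rows = []
    for h in range(H):
        if not mask[h]:
            continue
        q = x @ layer["wq"][h].data + layer["bq"][h].data
        k = x @ layer["wk"][h].data + layer["bk"][h].data
        v = x @ layer["wv"][h].data + layer["bv"][h].data
        logits = q @ np.swapaxes(k, -1, -2) / np.sqrt(head_dim)
        e = np.exp(logits - logits.max(-1, keepdims=True))
        att = e / e.sum(-1, keepdims=True)
        outs.append(att @ v)
        wo_rows.append(layer["wo"].data[h * head_dim:(h + 1) * head_dim])
    z = np.concatenate(outs, axis=-1)
    return z @ np.concatenate(wo_rows, axis=0) + layer["bo"].data


@pytest.mark.parametrize("trial", range(20))
def test_mhsa_matches_dense_oracle(trial):
    """mhsa layer output equals an independently coded softmax-attention oracle."""
    rng = np.random.default_rng(1000 + trial)
    cfg = ModelConfig(image_size=8, patch_size=4, depth=1,
                      heads_per_layer=[int(rng.integers(1, 4))],
                      embed_dim=8, head_dim=4, mlp_dim=8,
                      use_cls_token=bool(rng.integers(2)))
    model = VisionTransformer(cfg, seed=trial)
    from taha.autodiff import Tensor
    x = rng.normal(size=(2, cfg.n_tokens, cfg.embed_dim))
    H = cfg.heads_per_layer[0]
    mask = [True] * H
    if H > 1 and trial % 3 == 0:
        mask[int(rng.integers(H))] = False
    got = model.mhsa(Tensor(x), 0, mask=mask)
    want = naive_mhsa(x, model.layers[0], cfg.head_dim, mask)
    np.testing.assert_allclose(got.data, want, atol=1e-6)


def test_head_permutation_leaves_output_unchanged(rng):
    """Permuting heads together with W_o row blocks preserves the layer output."""
    from taha.autodiff import Tensor
    cfg = ModelConfig(image_size=8, patch_size=4, depth=1, heads_per_layer=[4],
                      embed_dim=8, mlp_dim=8, use_cls_token=False)
    model = VisionTransformer(cfg, seed=3)
    x = Tensor(rng.normal(size=(2, cfg.n_tokens, cfg.embed_dim)))
    base = model.mhsa(x, 0).data.copy()
    perm = [2, 0, 3, 1]
    layer = model.layers[0]
    dk = cfg.head_dim
    for key in ("wq", "bq", "wk", "bk", "wv", "bv"):
        layer[key] = [layer[key][p] for p in perm]
    layer["wo"].data = np.concatenate(
        [layer["wo"].data[p * dk:(p + 1) * dk] for p in perm], axis=0)
    np.testing.assert_allclose(model.mhsa(x, 0).data, base, atol=1e-6)


# -- records and invariants -------------------------------------------------

def test_rows_are_stochastic_for_random_inputs(tiny_model, rng):
    for _ in range(5):
        imgs = rng.random((2, 16, 16, 3))
        _, rec, _ = tiny_model.forward(imgs, collect_records=True)
        for m in rec.maps.values():
            assert (m >= 0).all()
            np.testing.assert_allclose(m.sum(-1), 1.0, atol=1e-5)


def test_forward_with_records_shapes_and_determinism(tiny_model, tiny_batch):
    scores, rec, Z = forward_with_records(tiny_model, tiny_batch)
    cfg = tiny_model.config
    assert scores.shape == (3, cfg.n_classes)
    assert len(rec.maps) == sum(cfg.heads_per_layer)
    assert Z.shape == (3, sum(cfg.heads_per_layer) * cfg.head_dim)
    scores2, _, Z2 = forward_with_records(tiny_model, tiny_batch)
    assert np.array_equal(scores.data, scores2.data)  # bitwise
    assert np.array_equal(Z, Z2)


def test_masked_head_absent_from_records(tiny_model, tiny_batch):
    masks = [[True, False], [True, True]]
    _, rec, _ = tiny_model.forward(tiny_batch, head_masks=masks,
                                   collect_records=True)
    assert (0, 1) not in rec.maps
    assert (0, 0) in rec.maps and (1, 1) in rec.maps


def test_all_heads_masked_rejected(tiny_model, tiny_batch):
    with pytest.raises(ValueError, match="head"):
        tiny_model.forward(tiny_batch, head_masks=[[False, False], [True, True]])


def test_nan_input_rejected(tiny_model, tiny_batch):
    bad = tiny_batch.copy()
    bad[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="NaN"):
        tiny_model.forward(bad)


def test_empty_batch_rejected(tiny_model):
    with pytest.raises(ValueError, match="empty"):
        tiny_model.forward(np.zeros((0, 16, 16, 3)))


def test_cross_entropy_matches_closed_form(rng):
    from taha.autodiff import Tensor
    scores = Tensor(rng.normal(size=(4, 3)))
    labels = np.array([0, 2, 1, 2])
    p = np.exp(scores.data) / np.exp(scores.data).sum(-1, keepdims=True)
    want = -np.mean(np.log(p[np.arange(4), labels]))
    assert abs(float(cross_entropy(scores, labels).data) - want) < 1e-12


def test_checkpoint_roundtrip(tmp_path, tiny_model, tiny_batch):
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, str(path))
    loaded = load_checkpoint(str(path))
    assert loaded.config == tiny_model.config
    a, _, _ = tiny_model.forward(tiny_batch)
    b, _, _ = loaded.forward(tiny_batch)
    assert np.array_equal(a.data, b.data)
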