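"""Alignment losses: KL closed forms, PCC, lambda schedule, update step."""

import hashlib

import numpy as np
import pytest

from taha import RunConfig, make_transfer_pair, pretrain_source
from taha.alignment import (AlignmentState, MLPHead, alignment_step,
                            domain_alignment_loss, kl_alignment_term,
                            lambda_schedule, phenotypic_consistency_loss,
                            standardized_one_hot)
from taha.autodiff import Tensor


def random_stochastic(rng, shape):
    m = rng.random(shape) + 1e-3
    return m / m.sum(-1, keepdims=True)


# -- domain alignment loss --------------------------------------------------

def test_dal_zero_for_identical_maps(rng):
    m = random_stochastic(rng, (3, 5, 5))
    assert domain_alignment_loss(m, m) < 1e-6


def test_dal_onehot_vs_uniform_is_log_p():
    """KL(one-hot || uniform over P tokens) = ln P per row."""
    P = 4
    onehot = np.zeros((1, P, P))
    onehot[0, np.arange(P), 0] = 1.0
    uniform = np.full((1, P, P), 1.0 / P)
    assert abs(domain_alignment_loss(onehot, uniform) - np.log(P)) < 1e-5


def test_dal_is_batch_mean(rng):
    a = random_stochastic(rng, (1, 6, 6))
    b = random_stochastic(rng, (1, 6, 6))
    t = random_stochastic(rng, (1, 6, 6))
    la = domain_alignment_loss(a, t)
    lb = domain_alignment_loss(b, t)
    both = domain_alignment_loss(np.concatenate([a, b]), np.concatenate([t, t]))
    assert abs(both - (la + lb) / 2) < 1e-12


def test_dal_nonnegative_and_asymmetric(rng):
    for _ in range(10):
        p = random_stochastic(rng, (2, 4, 4))
        q = random_stochastic(rng, (2, 4, 4))
        fwd = domain_alignment_loss(p, q)
        rev = domain_alignment_loss(q, p)
        assert fwd >= 0 and rev >= 0
        assert abs(fwd - rev) > 1e-12  # generic matrices: KL is asymmetric


def test_dal_rejects_bad_inputs(rng):
    p = random_stochastic(rng, (1, 3, 3))
    with pytest.raises(ValueError, match="shape"):
        domain_alignment_loss(p, random_stochastic(rng, (1, 4, 4)))
    neg = p.copy()
    neg[0, 0, 0] = -0.1
    with pytest.raises(ValueError, match="negative|non-negative"):
        domain_alignment_loss(neg, p)


def test_differentiable_dal_matches_scoring_dal(rng):
    p = random_stochastic(rng, (2, 5, 5))
    q = random_stochastic(rng, (2, 5, 5))
    got = float(kl_alignment_term(p, Tensor(q)).data)
    assert abs(got - domain_alignment_loss(p, q)) < 1e-10


# -- phenotypic consistency -------------------------------------------------

def test_standardized_one_hot_columns_are_zscored():
    y = np.array([0, 0, 1, 2, 2, 2])
    Y = standardized_one_hot(y, 3)
    np.testing.assert_allclose(Y.mean(0), 0, atol=1e-12)
    np.testing.assert_allclose(Y.std(0), 1, atol=1e-12)


def test_pcc_is_mean_squared_distance_to_standardized_targets():
    """With a constant predictor, PCC equals mean ||targets - c||^2 exactly."""
    y = np.array([0, 1, 0, 1, 1])
    targets = standardized_one_hot(y, 2)
    mlp = MLPHead(d_in=3, n_classes=2, seed=0)
    for p in mlp.parameters():
        p.data[:] = 0
    # zeroed MLP predicts 0 for every sample
    loss0 = phenotypic_consistency_loss(np.ones((5, 3)), y, mlp)
    assert abs(float(loss0.data) - (targets**2).sum(1).mean()) < 1e-12
    # constant bias c: residuals shift by c, and a perfect constant match
    # (single-sample set) drives the loss to zero
    mlp.b2.data[:] = targets[0]
    one = phenotypic_consistency_loss(np.ones((2, 3)), np.array([0, 1]), mlp)
    want = ((standardized_one_hot(np.array([0, 1]), 2) - targets[0]) ** 2).sum(1).mean()
    assert abs(float(one.data) - want) < 1e-12


def test_pcc_mean_squared_residual_arithmetic():
    """Predicting 0 for z-scored two-class targets gives loss 2 = 1^2 + 1^2."""
    y = np.array([0, 1])
    mlp = MLPHead(d_in=3, n_classes=2, seed=0)
    for p in mlp.parameters():
        p.data[:] = 0
    loss = phenotypic_consistency_loss(np.ones((2, 3)), y, mlp)
    assert abs(float(loss.data) - 2.0) < 1e-12


def test_pcc_requires_labeled_samples():
    mlp = MLPHead(d_in=3, n_classes=2, seed=0)
    with pytest.raises(ValueError, match="label"):
        phenotypic_consistency_loss(np.zeros((0, 3)), np.zeros(0, dtype=int), mlp)


# -- lambda schedule --------------------------------------------------------

@pytest.mark.parametrize("step,expected", [(0, 0.1), (25, 0.55), (50, 1.0), (80, 1.0)])
def test_lambda_schedule_linear_warmup(step, expected):
    assert lambda_schedule(step, warmup_steps=50) == pytest.approx(expected)


def test_lambda_schedule_monotone_nondecreasing():
    vals = [lambda_schedule(s, 37) for s in range(80)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))


def test_lambda_schedule_rejects_bad_warmup():
    with pytest.raises(ValueError):
        lambda_schedule(0, warmup_steps=0)


# -- alignment step ---------------------------------------------------------

@pytest.fixture(scope="module")
def small_pair_and_model():
    cfg = RunConfig(seed=5)
    cfg.data.n_source, cfg.data.n_target = 96, 96
    cfg.data.labeled_fraction = 0.25
    cfg.pretrain_steps = 40
    source, target = make_transfer_pair(
        shift_magnitude=cfg.data.shift_magnitude, labeled_fraction=0.25,
        n_source=96, n_target=96, seed=cfg.seed + 100,
        n_classes=cfg.data.n_classes, image_size=32, source_glyph=True)
    model = pretrain_source(cfg, source)
    return cfg, source, target, model


def _params_hash(model):
    h = hashlib.sha256()
    for k, p in sorted(model.named_parameters().items()):
        h.update(p.data.tobytes())
    return h.hexdigest()


def test_alignment_step_components_and_frozen_immutability(small_pair_and_model):
    cfg, _, target, model = small_pair_and_model
    frozen, live = model.copy(), model.copy()
    mlp = MLPHead(sum(cfg.model.heads_per_layer) * cfg.model.head_dim,
                  cfg.data.n_classes, seed=0)
    state = AlignmentState(frozen_source_model=frozen, live_target_model=live,
                           mlp_head=mlp, warmup_steps=10, lr=1e-3)
    before = _params_hash(frozen)
    idx = np.arange(32)
    stats = alignment_step(state, target.images[idx], target.labels[idx],
                           target.labeled_mask[idx])
    # identical weights at step 0: every per-head DAL is (numerically) zero
    assert stats["mean_dal"] < 1e-8
    assert all(v < 1e-8 for v in stats["per_head_dal"].values())
    assert stats["pcc"] > 0
    assert stats["total"] == pytest.approx(
        stats["mean_dal"] + stats["lambda"] * stats["pcc"])
    for _ in range(5):
        alignment_step(state, target.images[idx], target.labels[idx],
                       target.labeled_mask[idx])
    assert _params_hash(frozen) == before  # frozen source is never touched
    assert state.step == 6


def test_alignment_training_reduces_total_loss(small_pair_and_model):
    """A short seeded alignment run lowers the combined objective."""
    cfg, _, target, model = small_pair_and_model
    frozen, live = model.copy(), model.copy()
    mlp = MLPHead(sum(cfg.model.heads_per_layer) * cfg.model.head_dim,
                  cfg.data.n_classes, seed=0)
    state = AlignmentState(frozen_source_model=frozen, live_target_model=live,
                           mlp_head=mlp, warmup_steps=1, lambda_max=1.0, lr=3e-3)
    idx = np.arange(48)
    first = None
    for _ in range(30):
        stats = alignment_step(state, target.images[idx], target.labels[idx],
                               target.labeled_mask[idx])
        if first is None:
            first = stats["total"]
    assert stats["total"] < first


def test_alignment_step_requires_labels(small_pair_and_model):
    cfg, _, target, model = small_pair_and_model
    state = AlignmentState(frozen_source_model=model.copy(),
                           live_target_model=model.copy(),
                           mlp_head=MLPHead(sum(cfg.model.heads_per_layer)
                                            * cfg.model.head_dim,
                                            cfg.data.n_classes, seed=0),
                           warmup_steps=10)
    idx = np.arange(8)
    with pytest.raises(ValueError, match="label"):
        alignment_step(state, target.images[idx], target.labels[idx],
                       np.zeros(8, dtype=bool))
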