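"""End-to-end orchestration of the align -> score -> prune -> fine-tune loop.

A run proceeds in phases:

1. **Pre-train** the backbone on the fully labeled source domain by
   cross-entropy.
2. Repeat up to ``max_outer_iters`` times:
   (a) **align** — gradient steps on ``mean_h DAL_h + lambda * PCC``
   against the frozen source snapshot, with lambda on its linear
   warmup; (b) **score** every live head (DAL on a held target batch,
   label correlation on the labeled target subset) and compute the
   dynamic threshold; (c) **prune** heads below the threshold by
   physical surgery (optimizer state is discarded because parameter
   shapes change); (d) **fine-tune** the remaining heads and the
   classifier on the labeled target fraction.
   The loop stops early when an iteration prunes nothing — pruning is
   the only irreversible state change, so a prune-free iteration means
   the head set has converged.
3. **Report** cost accounting for full vs compact model, the per-head
   score trajectory, and a DAL-vs-correlation scatter table.

One master seed derives per-stage seeds by fixed offsets, so a run is
bitwise reproducible on one machine.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .accounting import CostReport, reduction_report
from .alignment import AlignmentState, MLPHead, alignment_step, domain_alignment_loss
from .autodiff import Adam
from .backbone import ModelConfig, VisionTransformer, cross_entropy, save_checkpoint
from .surgery import prune_model
from .synthetic_data import (LabeledImageSet, glyph_token_indices, make_transfer_pair)
from .transferability import (HeadScoreTable, PruneMask, head_label_correlation,
                              select_heads)

__all__ = ["DataConfig", "RunConfig", "RunArtifacts", "pretrain_source",
           "run_taha", "report", "glyph_attention_mass"]


@dataclass
class DataConfig:
    n_classes: int = 4
    image_size: int = 32
    shift_magnitude: float = 1.0
    labeled_fraction: float = 0.125
    n_source: int = 320
    n_target: int = 400
    source_glyph: bool = True


@dataclass
class RunConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    data: DataConfig = field(default_factory=DataConfig)
    lr: float = 3e-3
    pretrain_lr: float = 1e-3
    batch_size: int = 32
    alpha: float = 0.6
    beta: float = 1.5
    lambda0: float = 0.1
    lambda_max: float = 1.0
    warmup_steps: int = 50
    pretrain_steps: int = 400
    steps_per_phase: int = 80
    max_outer_iters: int = 5
    min_outer_iters: int = 2
    min_heads_per_layer: int = 1
    record_every: int = 10
    seed: int = 0
    output_dir: str = "taha_run"

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "model" in raw:
            raw["model"] = ModelConfig(**raw["model"])
        if "data" in raw:
            raw["data"] = DataConfig(**raw["data"])
        return cls(**raw)


@dataclass
class RunArtifacts:
    config: RunConfig
    source: LabeledImageSet
    target: LabeledImageSet
    source_model: VisionTransformer     # unpruned source-pretrained snapshot
    frozen_model: VisionTransformer
    final_model: VisionTransformer
    control_model: VisionTransformer     # aligned + fine-tuned, never pruned
    score_tables: list[HeadScoreTable]
    masks: list[PruneMask]
    cost_report: CostReport
    metrics: pd.DataFrame                # per alignment step
    trajectory: pd.DataFrame             # hts per live head per recorded step
    head_origin: list[list[int]]         # current index -> original head id
    n_outer_iters: int


def _batches(rng: np.random.Generator, n: int, batch_size: int):
    """Endless shuffled minibatch index stream."""
    while True:
        order = rng.permutation(n)
        for i in range(0, n, batch_size):
            chunk = order[i:i + batch_size]
            if len(chunk) > 1:
                yield chunk


def pretrain_source(config: RunConfig, source: LabeledImageSet,
                    steps: int | None = None) -> VisionTransformer:
    """Train the backbone + classifier on the source domain by cross-entropy."""
    if not source.labeled_mask.all():
        raise ValueError("source domain must be fully labeled for pre-training")
    steps = config.pretrain_steps if steps is None else steps
    model = VisionTransformer(config.model, seed=config.seed + 11)
    if steps == 0:
        return model
    opt = Adam(model.parameters(), lr=config.pretrain_lr)
    rng = np.random.default_rng(config.seed + 22)
    gen = _batches(rng, len(source), config.batch_size)
    for _ in range(steps):
        idx = next(gen)
        scores, _, _ = model.forward(source.images[idx])
        loss = cross_entropy(scores, source.labels[idx])
        if not np.isfinite(loss.data):
            raise FloatingPointError("pre-training diverged (non-finite loss)")
        opt.zero_grad()
        loss.backward()
        opt.step()
    return model


def _finetune(model: VisionTransformer, images: np.ndarray, labels: np.ndarray,
              steps: int, lr: float, batch_size: int, seed: int) -> None:
    """Supervised fine-tuning of attention + classifier parameters."""
    params = model.attention_parameters() + [model.cls_w, model.cls_b,
                                             model.final_g, model.final_b]
    opt = Adam(params, lr=lr)
    rng = np.random.default_rng(seed)
    gen = _batches(rng, len(images), min(batch_size, len(images)))
    for _ in range(steps):
        idx = next(gen)
        scores, _, _ = model.forward(images[idx])
        loss = cross_entropy(scores, labels[idx])
        opt.zero_grad()
        loss.backward()
        opt.step()


def _score_heads(frozen: VisionTransformer, live: VisionTransformer,
                 eval_images: np.ndarray, labeled_images: np.ndarray,
                 labeled_labels: np.ndarray, alpha: float) -> HeadScoreTable:
    """DAL + label correlation + HTS for every live head."""
    _, src_rec, _ = frozen.forward(eval_images, collect_records=True)
    _, tgt_rec, _ = live.forward(eval_images, collect_records=True)
    _, lab_rec, _ = live.forward(labeled_images, collect_records=True)
    table = HeadScoreTable()
    for (li, h) in sorted(tgt_rec.maps):
        dal = domain_alignment_loss(src_rec.maps[(li, h)], tgt_rec.maps[(li, h)])
        corr = head_label_correlation(lab_rec.head_outputs[(li, h)], labeled_labels)
        table.add(li, h, dal=dal, corr=corr, alpha=alpha)
    return table


def run_taha(config: RunConfig, write_artifacts: bool = True) -> RunArtifacts:
    """Execute the full adaptation loop; returns all run artifacts."""
    out = config.output_dir
    if write_artifacts:
        os.makedirs(out, exist_ok=True)

    d = config.data
    source, target = make_transfer_pair(
        shift_magnitude=d.shift_magnitude, labeled_fraction=d.labeled_fraction,
        n_source=d.n_source, n_target=d.n_target, seed=config.seed + 100,
        n_classes=d.n_classes, image_size=d.image_size,
        source_glyph=d.source_glyph,
    )

    model = pretrain_source(config, source)
    source_model = model
    frozen = model.copy()
    live = model.copy()
    if write_artifacts:
        save_checkpoint(frozen, os.path.join(out, "source_pretrained.npz"))

    lab_idx = np.flatnonzero(target.labeled_mask)
    lab_images = target.images[lab_idx]
    lab_labels = target.labels[lab_idx]
    eval_idx = np.arange(min(64, len(target)))
    eval_images = target.images[eval_idx]

    total_heads = sum(config.model.heads_per_layer)
    d_head = config.model.head_dim
    mlp = MLPHead(total_heads * d_head, d.n_classes, seed=config.seed + 33)

    head_origin = [list(range(H)) for H in config.model.heads_per_layer]
    metrics_rows: list[dict] = []
    traj_rows: list[dict] = []
    score_tables: list[HeadScoreTable] = []
    masks: list[PruneMask] = []
    control: VisionTransformer | None = None

    rng = np.random.default_rng(config.seed + 44)
    gen = _batches(rng, len(target), config.batch_size)
    global_step = 0
    n_outer = 0
    for outer in range(config.max_outer_iters):
        n_outer += 1
        # ---- (a) alignment phase -------------------------------------
        state = AlignmentState(
            frozen_source_model=frozen, live_target_model=live, mlp_head=mlp,
            lambda0=config.lambda0, lambda_max=config.lambda_max,
            warmup_steps=config.warmup_steps, lr=config.lr,
        )
        state.step = global_step  # lambda warmup continues across iterations
        for s in range(config.steps_per_phase):
            idx = next(gen)
            if not target.labeled_mask[idx].any():
                # guarantee supervision in every batch
                idx = np.concatenate([idx[:-1], rng.choice(lab_idx, size=1)])
            stats = alignment_step(state, target.images[idx], target.labels[idx],
                                   target.labeled_mask[idx])
            metrics_rows.append({
                "outer_iter": outer, "step": state.step - 1,
                "lambda": stats["lambda"], "mean_DAL": stats["mean_dal"],
                "PCC": stats["pcc"], "total_loss": stats["total"],
            })
            if s % config.record_every == 0 or s == config.steps_per_phase - 1:
                tbl = _score_heads(frozen, live, eval_images, lab_images,
                                   lab_labels, config.alpha)
                for row in tbl.rows:
                    traj_rows.append({
                        "outer_iter": outer, "step": state.step - 1,
                        "layer": row["layer"],
                        "head": head_origin[row["layer"]][row["head"]],
                        "dal": row["dal"], "corr": row["corr"], "hts": row["hts"],
                    })
        global_step = state.step

        if control is None:
            control = live.copy()  # aligned, never-pruned reference

        # ---- (b) score + threshold -----------------------------------
        table = _score_heads(frozen, live, eval_images, lab_images, lab_labels,
                             config.alpha)
        score_tables.append(table)
        mask = select_heads(table, beta=config.beta,
                            min_heads_per_layer=config.min_heads_per_layer)
        masks.append(mask)
        if write_artifacts:
            table.to_csv(os.path.join(out, f"head_scores_iter{outer}.csv"))
            mask.to_json(os.path.join(out, f"prune_mask_iter{outer}.json"))

        n_pruned = sum(1 for v in mask.retain.values() if not v)
        if n_pruned > 0:
            # ---- (c) surgery -----------------------------------------
            live = prune_model(live, mask)
            frozen = prune_model(frozen, mask)
            new_origin = []
            for li, ids in enumerate(head_origin):
                H = len(ids)
                new_origin.append([ids[h] for h in range(H)
                                   if mask.retain[(li, h)]])
            head_origin = new_origin
            mlp = MLPHead(sum(live.config.heads_per_layer) * d_head, d.n_classes,
                          seed=config.seed + 33 + outer)
        # ---- (d) fine-tune remaining heads on labeled target ---------
        _finetune(live, lab_images, lab_labels, config.steps_per_phase,
                  config.pretrain_lr, config.batch_size,
                  seed=config.seed + 55 + outer)
        if n_pruned == 0 and outer + 1 >= config.min_outer_iters:
            # convergence: nothing pruned in a post-warmup iteration
            break

    # control gets the same supervised budget as the pruned branch
    assert control is not None
    _finetune(control, lab_images, lab_labels, config.steps_per_phase,
              config.pretrain_lr, config.batch_size, seed=config.seed + 55)

    cost = reduction_report(config.model, live.config)
    metrics = pd.DataFrame(metrics_rows)
    trajectory = pd.DataFrame(traj_rows)
    artifacts = RunArtifacts(
        config=config, source=source, target=target,
        source_model=source_model, frozen_model=frozen,
        final_model=live, control_model=control, score_tables=score_tables,
        masks=masks, cost_report=cost, metrics=metrics, trajectory=trajectory,
        head_origin=head_origin, n_outer_iters=n_outer,
    )
    if write_artifacts:
        save_checkpoint(live, os.path.join(out, "final_compact.npz"))
        metrics.to_csv(os.path.join(out, "metrics.csv"), index=False)
        trajectory.to_csv(os.path.join(out, "hts_trajectory.csv"), index=False)
        cost.to_json(os.path.join(out, "cost_report.json"))
        report(artifacts, out)
    return artifacts


def report(artifacts: RunArtifacts, out_dir: str | None = None) -> dict:
    """Summary: cost table, scatter table, accuracies on the labeled subset."""
    if not artifacts.score_tables:
        raise ValueError("run artifacts contain no score tables")
    first = artifacts.score_tables[0].to_frame()
    mask0 = artifacts.masks[0]
    scatter = first.copy()
    scatter["retained"] = [mask0.retain[(int(r.layer), int(r.head))]
                           for r in first.itertuples()]

    lab = np.flatnonzero(artifacts.target.labeled_mask)
    imgs = artifacts.target.images[lab]
    ys = artifacts.target.labels[lab]
    acc_final = float((artifacts.final_model.predict(imgs) == ys).mean())
    acc_control = float((artifacts.control_model.predict(imgs) == ys).mean())

    summary = {
        "cost": artifacts.cost_report.to_dict(),
        "n_outer_iters": artifacts.n_outer_iters,
        "heads_initial": sum(artifacts.config.model.heads_per_layer),
        "heads_final": sum(artifacts.final_model.config.heads_per_layer),
        "labeled_target_accuracy_pruned": acc_final,
        "labeled_target_accuracy_unpruned": acc_control,
    }
    if out_dir is not None:
        scatter.to_csv(os.path.join(out_dir, "dal_corr_scatter.csv"), index=False)
        artifacts.cost_report.to_table().to_csv(
            os.path.join(out_dir, "cost_table.csv"), index=False)
        with open(os.path.join(out_dir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
    return summary


def planted_recovery_run(seed: int, config: RunConfig | None = None) -> dict:
    """One planted-structure recovery experiment.

    Runs the full loop on the glyph-planted transfer pair and reports
    which originally present heads were pruned, which heads of the
    source-pretrained model were glyph-attending (cls-row attention
    mass on glyph tokens above twice the uniform share, measured on
    source images of glyph-carrying classes), and the labeled-target
    accuracy of the pruned model versus the never-pruned aligned
    control.
    """
    cfg = config if config is not None else RunConfig()
    cfg.seed = seed
    art = run_taha(cfg, write_artifacts=False)
    present = art.source.labels % 2 == 0  # glyph-carrying classes
    masses = glyph_attention_mass(art.source_model, art.source.images[present][:48])
    n_tok = art.source_model.config.n_tokens
    toks = glyph_token_indices(cfg.model.image_size, cfg.model.patch_size,
                               cfg.model.use_cls_token)
    share = len(toks) / n_tok
    glyph_heads = {k for k, v in masses.items() if v > 2 * share}
    surviving = {(li, h) for li, ids in enumerate(art.head_origin) for h in ids}
    all_heads = {(li, h) for li, H in enumerate(cfg.model.heads_per_layer)
                 for h in range(H)}
    pruned = all_heads - surviving
    summary = report(art)
    hts0 = {(int(r["layer"]), int(r["head"])): r["hts"]
            for r in art.score_tables[0].rows}
    other = [v for k, v in hts0.items() if k not in glyph_heads]
    gmean = float(np.mean([hts0[k] for k in glyph_heads])) if glyph_heads else float("nan")
    return {
        "seed": seed,
        "n_pruned": len(pruned),
        "glyph_heads": sorted(glyph_heads),
        "pruned_heads": sorted(pruned),
        "n_glyph_pruned": len(pruned & glyph_heads),
        "acc_pruned": summary["labeled_target_accuracy_pruned"],
        "acc_unpruned": summary["labeled_target_accuracy_unpruned"],
        "glyph_mean_hts": gmean,
        "other_mean_hts": float(np.mean(other)) if other else float("nan"),
        "heads_final": summary["heads_final"],
        "cost": summary["cost"],
    }


def glyph_attention_mass(model: VisionTransformer, images: np.ndarray,
                         rows: str = "cls") -> dict:
    """Mean attention mass on glyph-overlapping tokens per (layer, head).

    With ``rows="cls"`` (default) only the class-token query row is
    read — that row feeds the classifier, so mass there identifies the
    heads that route the glyph shortcut into the prediction.
    ``rows="all"`` averages over every query row.  Compare against the
    uniform share ``len(glyph_tokens) / n_tokens`` (e.g. call a head
    glyph-attending above twice that share).
    """
    cfg = model.config
    toks = glyph_token_indices(cfg.image_size, cfg.patch_size, cfg.use_cls_token)
    _, rec, _ = model.forward(images, collect_records=True)
    if rows == "cls":
        if not cfg.use_cls_token:
            raise ValueError('rows="cls" requires a class token')
        return {key: float(rec.maps[key][:, 0, toks].sum(axis=-1).mean())
                for key in sorted(rec.maps)}
    return {key: float(rec.maps[key][..., toks].sum(axis=-1).mean())
            for key in sorted(rec.maps)}


def foreground_attention_mass(model: VisionTransformer, images: np.ndarray,
                              threshold: float = 0.6) -> dict:
    """Mean cls-row attention mass on bright (leaf-blob) tokens.

    Identifies shape-attending heads: patches whose mean intensity
    exceeds ``threshold`` are treated as foreground.  Returns the mass
    normalized by each image's foreground token share, so values > 1
    mean preferential attention to the blob.
    """
    cfg = model.config
    if not cfg.use_cls_token:
        raise ValueError("requires a class token")
    p = cfg.patch_size
    g = cfg.image_size // p
    gray = images.mean(axis=-1)
    patches = gray.reshape(len(images), g, p, g, p).mean(axis=(2, 4))
    fg = patches.reshape(len(images), -1) > threshold  # (B, n_patches)
    _, rec, _ = model.forward(images, collect_records=True)
    out = {}
    for key in sorted(rec.maps):
        cls_row = rec.maps[key][:, 0, 1:]  # attention to patch tokens
        share = fg.mean(axis=1)
        mass = (cls_row * fg).sum(axis=1)
        ok = share > 0
        out[key] = float((mass[ok] / share[ok]).mean())
    return out
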