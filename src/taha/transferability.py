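"""Head transferability scoring and dynamic threshold selection.

Each retained head gets a Head Transferability Score

    HTS_h = alpha * exp(-DAL_h) + (1 - alpha) * Corr(Z_h, y)

combining how well its attention aligned across domains (the
exponential maps the KL loss into (0, 1]) with how predictive its
output is of the phenotype labels.  Heads are pruned when their score
falls below the dynamic threshold

    tau = mean(HTS) - beta * std(HTS)

computed over the global pool of all currently retained heads
(population standard deviation: the head set is the entire population
being thresholded).  Ties at tau are retained.  A per-layer floor
prevents any layer from losing all of its heads; floor-forced
retentions are flagged.

The label correlation for a multivariate head output against a
categorical label is reduced to a single [0, 1] scalar: token-mean pool
each sample, Pearson-correlate every feature dimension with every
standardized one-hot label column, take |r|, max over label columns,
then mean over feature dimensions.  Constant features contribute 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import standardized_one_hot

__all__ = ["HeadScoreTable", "PruneMask", "head_label_correlation",
           "head_transferability_score", "prune_threshold", "select_heads"]


@dataclass
class HeadScoreTable:
    """Per-(layer, head) DAL, correlation and HTS rows."""

    rows: list[dict] = field(default_factory=list)

    def add(self, layer: int, head: int, dal: float, corr: float, alpha: float = 0.6):
        self.rows.append({
            "layer": layer, "head": head, "dal": float(dal), "corr": float(corr),
            "hts": head_transferability_score(dal, corr, alpha),
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["layer", "head", "dal", "corr", "hts"])

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str) -> "HeadScoreTable":
        df = pd.read_csv(path)
        return cls(rows=df.to_dict("records"))


@dataclass
class PruneMask:
    """Boolean retain decision per (layer, head)."""

    retain: dict[tuple[int, int], bool]
    tau: float
    beta: float
    forced: list[tuple[int, int]] = field(default_factory=list)

    def layer_mask(self, layer: int, n_heads: int) -> list[bool]:
        return [self.retain.get((layer, h), False) for h in range(n_heads)]

    def n_retained(self) -> int:
        return sum(self.retain.values())

    def to_json(self, path: str | None = None) -> str:
        layers = sorted({k[0] for k in self.retain})
        payload = {
            str(li): [h for (l, h), keep in sorted(self.retain.items())
                      if l == li and keep]
            for li in layers
        }
        payload["tau"] = self.tau
        payload["beta"] = self.beta
        payload["forced"] = [list(t) for t in self.forced]
        s = json.dumps(payload, indent=1)
        if path:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def head_label_correlation(Z_h: np.ndarray, y: np.ndarray) -> float:
    """Label relevance of one head's output, in [0, 1].

    ``Z_h`` is ``(n, n_tokens, d_v)`` or already-pooled ``(n, d_v)``;
    ``y`` categorical labels for the same ``n`` (labeled) samples.
    """
    Z_h = np.asarray(Z_h, dtype=np.float64)
    y = np.asarray(y)
    if Z_h.ndim == 3:
        Z_h = Z_h.mean(axis=1)  # token-mean pooling
    n = Z_h.shape[0]
    if n < 3:
        raise ValueError("need at least 3 labeled samples for a correlation")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes present among labeled samples")
    Ystd = standardized_one_hot(y, int(classes.max()) + 1)
    Ystd = Ystd[:, Ystd.std(axis=0) > 0]

    Zc = Z_h - Z_h.mean(axis=0)
    zsd = Zc.std(axis=0)
    Yc = Ystd - Ystd.mean(axis=0)
    ysd = Yc.std(axis=0)
    # |Pearson r| matrix dims x classes; constant feature dims contribute 0
    r = np.zeros((Z_h.shape[1], Ystd.shape[1]))
    nz = zsd > 0
    if nz.any():
        r[nz, :] = np.abs(
            (Zc[:, nz].T @ Yc) / n / np.outer(zsd[nz], ysd)
        )
    return float(np.clip(r.max(axis=1).mean(), 0.0, 1.0))


def head_transferability_score(dal: float, corr: float, alpha: float = 0.6) -> float:
    """alpha * exp(-dal) + (1 - alpha) * corr."""
    if dal < 0:
        raise ValueError("dal must be >= 0")
    if not (0.0 <= corr <= 1.0):
        raise ValueError("corr must lie in [0, 1]")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    return float(alpha * np.exp(-dal) + (1.0 - alpha) * corr)


def prune_threshold(hts_values, beta: float = 1.5) -> float:
    """tau = mean(HTS) - beta * population-std(HTS)."""
    v = np.asarray(list(hts_values), dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 HTS values for a threshold")
    return float(v.mean() - beta * v.std(ddof=0))


def select_heads(table: HeadScoreTable, beta: float = 1.5,
                 min_heads_per_layer: int = 1,
                 pooling: str = "global") -> PruneMask:
    """Retain heads with HTS >= tau; enforce the per-layer floor.

    With global pooling (default) one tau is computed over every
    retained head in the model; ``pooling="per_layer"`` computes a
    separate tau per layer.
    """
    df = table.to_frame()
    if df.empty:
        raise ValueError("empty score table")

    retain: dict[tuple[int, int], bool] = {}
    forced: list[tuple[int, int]] = []
    if pooling == "global":
        tau = prune_threshold(df["hts"], beta)
        taus = {li: tau for li in df["layer"].unique()}
    elif pooling == "per_layer":
        taus = {li: prune_threshold(g["hts"], beta)
                for li, g in df.groupby("layer")}
        tau = float(np.mean(list(taus.values())))
    else:
        raise ValueError(f"unknown pooling {pooling!r}")

    for li, g in df.groupby("layer"):
        t = taus[li]
        keep = g["hts"] >= t
        if keep.sum() < min_heads_per_layer:
            # force-retain the top-HTS heads of this layer
            top = g.sort_values("hts", ascending=False).head(min_heads_per_layer)
            for _, row in g.iterrows():
                key = (int(row["layer"]), int(row["head"]))
                retain[key] = False
            for _, row in top.iterrows():
                key = (int(row["layer"]), int(row["head"]))
                retain[key] = True
                forced.append(key)
        else:
            for (_, row), k in zip(g.iterrows(), keep):
                retain[(int(row["layer"]), int(row["head"]))] = bool(k)
    return PruneMask(retain=retain, tau=float(tau), beta=float(beta), forced=forced)
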