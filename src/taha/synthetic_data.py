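"""Procedural two-domain plant-image benchmark.

Real cross-species transfer datasets pair species that share gross
morphology (leaf outline, venation) while differing in surface texture
and imaging background.  This module emulates that structure with fully
controllable ground truth:

* the **shape channel** is class-conditional and species-invariant — an
  elliptical "leaf" blob whose axis lengths are drawn from per-class
  ranges, crossed by a class-dependent number of darker "vein" lines;
* the **texture channel** is species-specific and label-independent —
  background intensity, pixel noise, and a high-frequency grating whose
  amplitude grows with ``shift_magnitude``, so the spectral discrepancy
  between two domains is monotone in that single knob;
* an optional **source-only glyph** — a corner marker rendered only in
  source-domain images, with intensity coding the class label — plants a
  discriminative cue that cannot transfer, giving head-pruning
  experiments a verifiable ground truth for "source-specific" heads.

Everything is reproducible from the spec seed.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

__all__ = ["DomainSpec", "LabeledImageSet", "default_shape_params", "generate_domain",
           "make_transfer_pair", "bandpass_energy", "glyph_token_indices",
           "save_npz", "load_npz", "save_png_dir"]

GLYPH_SIZE = 8  # pixels; square top-left corner marker
_GRATING_FREQ = 10.0  # cycles per image side, well above blob scale


def default_shape_params(n_classes: int, image_size: int = 32) -> dict:
    """Disjoint per-class ellipse-axis ranges plus vein counts.

    Axis ranges are separated by construction so a trivial
    foreground-area threshold can recover the class, which keeps the
    classification task learnable by very small backbones.
    """
    lo, hi = 0.10 * image_size, 0.28 * image_size
    edges = np.linspace(lo, hi, n_classes + 1)
    params = {}
    for k in range(n_classes):
        width = edges[k + 1] - edges[k]
        params[k] = {
            "axis_range": (float(edges[k] + 0.15 * width), float(edges[k + 1] - 0.15 * width)),
            "n_veins": 2 + k,
        }
    return params


@dataclass
class DomainSpec:
    """One species/domain of the synthetic benchmark."""

    species_id: str
    n_classes: int
    shape_params: dict
    texture_params: dict = field(default_factory=lambda: {"background": 0.25, "noise_std": 0.05})
    shift_magnitude: float = 0.0
    image_size: int = 32
    seed: int = 0
    glyph: bool = False
    corner_clutter: bool = False

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.shift_magnitude < 0:
            raise ValueError("shift_magnitude must be >= 0")


@dataclass
class LabeledImageSet:
    images: np.ndarray   # (n, H, W, 3) in [0, 1]
    labels: np.ndarray   # (n,) int
    labeled_mask: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return len(self.images)


def _render_image(rng: np.random.Generator, label: int, spec: DomainSpec) -> np.ndarray:
    s = spec.image_size
    tp = spec.texture_params
    img = np.full((s, s), tp.get("background", 0.25), dtype=np.float64)
    img += rng.normal(0.0, tp.get("noise_std", 0.05), size=(s, s))

    # species-specific high-frequency grating; amplitude set by shift_magnitude
    if spec.shift_magnitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:s, 0:s]
        img += 0.25 * spec.shift_magnitude * np.sin(
            2 * np.pi * _GRATING_FREQ * (xx + yy) / (2 * s) + phase
        )

    # class-conditional leaf blob
    cp = spec.shape_params[label]
    a = rng.uniform(*cp["axis_range"])
    b = a * rng.uniform(0.6, 0.9)
    theta = rng.uniform(0, np.pi)
    # blob sits in the lower-right interior, spatially disjoint from the
    # glyph corner so the planted cue is separable from morphology
    cy = 0.62 * s + rng.uniform(-0.05, 0.05) * s
    cx = 0.62 * s + rng.uniform(-0.05, 0.05) * s
    yy, xx = np.mgrid[0:s, 0:s]
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    img[blob] = 0.8 + rng.normal(0, 0.02, size=int(blob.sum()))

    # vein lines through the blob centre
    for i in range(cp.get("n_veins", 2)):
        ang = theta + np.pi * i / max(cp.get("n_veins", 2), 1) + rng.uniform(-0.1, 0.1)
        t = np.linspace(-1, 1, 4 * s)
        py = np.clip(np.round(cy + t * a * np.sin(ang)).astype(int), 0, s - 1)
        px = np.clip(np.round(cx + t * a * np.cos(ang)).astype(int), 0, s - 1)
        inside = blob[py, px]
        img[py[inside], px[inside]] = 0.45

    # source-only glyph: bright top-left marker present for half the
    # classes (presence/absence code).  Reading it requires attention
    # anchored to that corner — which finds only constant background in
    # the target domain, where the glyph never appears.
    if spec.glyph and label % 2 == 0:
        g = min(GLYPH_SIZE, s)
        img[:g, :g] = 1.0
    # label-independent corner clutter (a background trait of the domain):
    # the corner is randomly bright or dark per image, so heads that
    # learned to read the glyph corner pick up pure label-independent
    # variance
    if spec.corner_clutter:
        g = min(GLYPH_SIZE, s)
        img[:g, :g] = rng.uniform(0.1, 0.9)

    out = np.stack([img, img, img], axis=-1)
    out += rng.normal(0, 0.01, size=out.shape)  # per-channel sensor noise
    return np.clip(out, 0.0, 1.0)


def _stratified_mask(rng: np.random.Generator, labels: np.ndarray,
                     fraction: float) -> np.ndarray:
    """Labeled mask hitting round(fraction*n) with every class represented."""
    n = len(labels)
    n_lab = int(round(fraction * n))
    n_lab = min(max(n_lab, 0), n)
    mask = np.zeros(n, dtype=bool)
    if n_lab == 0:
        return mask
    classes = np.unique(labels)
    chosen: list[int] = []
    # one per class first (when budget allows), then proportional fill
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(chosen) < n_lab:
            chosen.append(int(rng.choice(idx)))
    remaining = np.setdiff1d(np.arange(n), np.array(chosen))
    extra = n_lab - len(chosen)
    if extra > 0:
        chosen.extend(rng.choice(remaining, size=extra, replace=False).tolist())
    mask[np.array(chosen[:n_lab])] = True
    return mask


def generate_domain(spec: DomainSpec, n: int, labeled_fraction: float = 1.0) -> LabeledImageSet:
    """Draw ``n`` images of one domain, reproducibly from ``spec.seed``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(spec.seed)
    s = spec.image_size
    if n == 0:
        return LabeledImageSet(
            images=np.zeros((0, s, s, 3)), labels=np.zeros(0, dtype=int),
            labeled_mask=np.zeros(0, dtype=bool),
        )
    labels = rng.integers(0, spec.n_classes, size=n)
    images = np.stack([_render_image(rng, int(y), spec) for y in labels])
    mask = _stratified_mask(rng, labels, labeled_fraction)
    return LabeledImageSet(images=images, labels=labels, labeled_mask=mask)


def make_transfer_pair(shape_params: dict | None = None,
                       shift_magnitude: float = 1.0,
                       labeled_fraction: float = 0.125,
                       n_source: int = 240,
                       n_target: int = 240,
                       seed: int = 0,
                       n_classes: int = 2,
                       image_size: int = 32,
                       source_glyph: bool = False) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Source/target domain pair sharing morphology, differing in texture.

    The source is fully labeled; a ``labeled_fraction`` of the target is
    labeled (semi-supervised transfer uses 10-15% by default).  With
    ``source_glyph=True`` the source images additionally carry the
    corner marker (see module docstring).
    """
    if not (0.0 < labeled_fraction <= 1.0):
        raise ValueError("labeled_fraction must be in (0, 1]")
    if shape_params is None:
        shape_params = default_shape_params(n_classes, image_size)
    src_spec = DomainSpec(
        species_id="source", n_classes=n_classes, shape_params=shape_params,
        shift_magnitude=0.0, image_size=image_size, seed=seed, glyph=source_glyph,
    )
    tgt_spec = DomainSpec(
        species_id="target", n_classes=n_classes, shape_params=shape_params,
        shift_magnitude=shift_magnitude, image_size=image_size, seed=seed + 1,
        glyph=False, corner_clutter=source_glyph,
    )
    source = generate_domain(src_spec, n_source, labeled_fraction=1.0)
    target = generate_domain(tgt_spec, n_target, labeled_fraction=labeled_fraction)
    return source, target


def bandpass_energy(images: np.ndarray, f_lo: float = 0.2, f_hi: float = 0.45) -> float:
    """Mean high-band spectral energy of a grayscale reduction of ``images``.

    A fixed statistic used to measure texture discrepancy between
    domains; frequencies are in cycles/pixel of the 2-D DFT.
    """
    gray = images.mean(axis=-1)
    n = gray.shape[-1]
    F = np.fft.fft2(gray, axes=(-2, -1))
    fy = np.fft.fftfreq(n)
    fr = np.sqrt(fy[:, None] ** 2 + fy[None, :] ** 2)
    band = (fr >= f_lo) & (fr <= f_hi)
    return float(np.mean(np.abs(F[..., band]) ** 2))


def glyph_token_indices(image_size: int, patch_size: int, use_cls_token: bool = True) -> list[int]:
    """Token indices whose patches overlap the top-left glyph region."""
    g = image_size // patch_size
    out = []
    for row in range(g):
        for col in range(g):
            y0, x0 = row * patch_size, col * patch_size
            if y0 < GLYPH_SIZE and x0 < GLYPH_SIZE:
                out.append(row * g + col + (1 if use_cls_token else 0))
    return out


# -- serialization ----------------------------------------------------------

def save_npz(dataset: LabeledImageSet, path: str) -> None:
    np.savez_compressed(path, images=dataset.images, labels=dataset.labels,
                        labeled_mask=dataset.labeled_mask)


def load_npz(path: str) -> LabeledImageSet:
    with np.load(path) as npz:
        return LabeledImageSet(images=npz["images"], labels=npz["labels"],
                               labeled_mask=npz["labeled_mask"])


def save_png_dir(dataset: LabeledImageSet, directory: str) -> None:
    """Per-image PNGs plus a labels.csv (filename,label,labeled)."""
    from PIL import Image

    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "labels.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label", "labeled"])
        for i, (img, y, lab) in enumerate(
            zip(dataset.images, dataset.labels, dataset.labeled_mask)
        ):
            name = f"img_{i:05d}.png"
            Image.fromarray((img * 255).astype(np.uint8)).save(
                os.path.join(directory, name)
            )
            writer.writerow([name, int(y), int(lab)])
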