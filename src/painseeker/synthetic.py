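"""Procedural grimace-like image generator: the desk-scale benchmark.

Each subject gets a fixed, subject-specific background texture (identity
nuisance). Four disjoint axis-aligned square patches at canonical positions
stand in for the four grimace-scale action-unit regions (ears, orbital,
nose/cheek, whiskers). Pain shifts the intensity statistics inside the
patches — a mean shift plus a high-frequency grating, scaled by
``pain_effect`` (severe pain scales the effect 1.5×) — while no-pain images
carry the patches at their baseline appearance. Head pose is simulated the
way it hurts real scoring: a *moderate* pose translates all patches by a
common offset, an *extreme* pose translates further and occludes each patch
(replaces it with background) independently with probability
``occlusion_fraction``. Pixel noise is additive Gaussian.

Every image therefore has known ground truth: label, pose tag, and the
pixel boxes of its visible AU patches, against which attention maps can be
scored (`localization_score`).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import ratspain
from .exceptions import DimensionError, LayoutError
from .model import AttentionScores, FacialImage, PainLabel, PoseTag

# canonical (row, col) top-left corners as fractions of the image side
AU_LAYOUT = {
    "ears": (0.05, 0.12),
    "orbital": (0.16, 0.58),
    "nose_cheek": (0.55, 0.40),
    "whiskers": (0.66, 0.08),
}
AU_SIZE = 0.20          # patch side as a fraction of the image side
SEVERE_EFFECT_SCALE = 1.5

DEFAULT_POSE_WEIGHTS = {"frontal": 0.4, "moderate": 0.4, "extreme": 0.2}


def table2_counts(scale: float = 1.0) -> dict[str, tuple[int, int]]:
    """Per-subject (no-pain, pain) counts with the published per-rat imbalance,
    optionally scaled down (each count rounded, floor 1)."""
    return {s: (max(1, round(no * scale)), max(1, round(pain * scale)))
            for s, (no, pain) in ratspain.binary_counts().items()}


@dataclasses.dataclass
class SyntheticConfig:
    n_subjects: int = 6
    counts_per_subject: Optional[dict[str, tuple[int, int]]] = None
    image_size: int = 64
    pain_effect: float = 0.15
    noise_sd: float = 0.05
    pose_weights: Optional[dict[str, float]] = None
    occlusion_fraction: float = 0.5
    severe_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.counts_per_subject is None:
            # published per-rat imbalance at 1/8 size: desk-scale default
            full = table2_counts(scale=0.125)
            self.counts_per_subject = dict(list(full.items())[: self.n_subjects])
        if self.pose_weights is None:
            self.pose_weights = dict(DEFAULT_POSE_WEIGHTS)
        if abs(sum(self.pose_weights.values()) - 1.0) > 1e-9:
            raise LayoutError("pose_weights must sum to 1")
        if set(self.pose_weights) - {"frontal", "moderate", "extreme"}:
            raise LayoutError(f"unknown pose tags in {sorted(self.pose_weights)}")
        if any(n <= 0 for pair in self.counts_per_subject.values() for n in pair):
            raise LayoutError("per-subject counts must be positive")
        if self.pain_effect < 0 or self.noise_sd < 0:
            raise LayoutError("pain_effect and noise_sd must be nonnegative")
        if not 0 <= self.occlusion_fraction <= 1:
            raise LayoutError("occlusion_fraction must be in [0, 1]")
        _patch_boxes(self.image_size)  # validates the layout fits


def _patch_boxes(image_size: int) -> dict[str, tuple[int, int, int]]:
    """Pixel (row0, col0, side) of each canonical AU patch; checks disjointness."""
    side = int(round(AU_SIZE * image_size))
    if side < 4:
        raise LayoutError(f"image_size {image_size} too small for AU patches")
    boxes = {au: (int(round(r * image_size)), int(round(c * image_size)), side)
             for au, (r, c) in AU_LAYOUT.items()}
    items = list(boxes.items())
    for i, (au_a, (ra, ca, s)) in enumerate(items):
        if ra < 0 or ca < 0 or ra + s > image_size or ca + s > image_size:
            raise LayoutError(f"patch {au_a} falls outside the image")
        for au_b, (rb, cb, s2) in items[i + 1:]:
            if ra < rb + s2 and rb < ra + s and ca < cb + s2 and cb < ca + s:
                raise LayoutError(f"patches {au_a} and {au_b} overlap")
    return boxes


@dataclasses.dataclass
class SyntheticDataset:
    images: list[FacialImage]
    manifest: pd.DataFrame      # image_id, subject_id, label, pose_tag
    masks: dict                 # image_id -> list of patch dicts (au, box, visible)
    config: SyntheticConfig


def _subject_background(subject_idx: int, size: int, seed: int) -> np.ndarray:
    """Subject identity is a unique smooth texture pattern, not a brightness
    level: all subjects share the same mean gray, so identity cannot act as a
    linear shortcut for the label."""
    rng = np.random.default_rng([seed, 7919, subject_idx])
    texture = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 10.0)
    texture = texture - texture.mean()
    texture = 0.10 * texture / (np.abs(texture).max() + 1e-9)
    return np.clip(0.42 + texture, 0.05, 0.95)


def _au_grating(au_idx: int, side: int) -> np.ndarray:
    """Unit-amplitude pattern marking a painful AU (orientation varies per AU)."""
    rr, cc = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    phase = (rr if au_idx % 2 == 0 else cc) + (au_idx // 2) * (rr + cc) / 2.0
    return np.sin(2 * np.pi * phase / 4.0)


def _pose_shift(pose: str, size: int, rng: np.random.Generator) -> tuple[int, int]:
    mag = {"frontal": 0.0, "moderate": 0.10, "extreme": 0.18}[pose]
    span = int(round(mag * size))
    if span == 0:
        return 0, 0
    return int(rng.integers(-span, span + 1)), int(rng.integers(-span, span + 1))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Render the full synthetic panel, reproducibly from ``cfg.seed``."""
    size = cfg.image_size
    boxes = _patch_boxes(size)
    au_names = list(AU_LAYOUT)
    pose_names = sorted(cfg.pose_weights)
    pose_p = np.array([cfg.pose_weights[p] for p in pose_names])

    images: list[FacialImage] = []
    rows = []
    masks: dict = {}
    rng = np.random.default_rng([cfg.seed, 104729])

    for s_idx, (subject, (n_no, n_pain)) in enumerate(cfg.counts_per_subject.items()):
        background = _subject_background(s_idx, size, cfg.seed)
        patch_base = 0.14  # patch tint relative to the background mean
        ordinals = [0] * n_no + [1] * n_pain
        for k, ordinal in enumerate(ordinals):
            if ordinal == 1 and rng.random() < cfg.severe_fraction:
                ordinal = 2
            pose = pose_names[rng.choice(len(pose_names), p=pose_p)]
            dr, dc = _pose_shift(pose, size, rng)
            canvas = background.copy()
            patch_records = []
            for a_idx, au in enumerate(au_names):
                r0, c0, side = boxes[au]
                r0 = int(np.clip(r0 + dr, 0, size - side))
                c0 = int(np.clip(c0 + dc, 0, size - side))
                visible = not (pose == "extreme" and rng.random() < cfg.occlusion_fraction)
                if visible:
                    patch = np.full((side, side), np.clip(background.mean() - patch_base, 0, 1))
                    if ordinal > 0:
                        effect = cfg.pain_effect * (SEVERE_EFFECT_SCALE if ordinal == 2 else 1.0)
                        patch = patch + effect * (0.8 + 0.5 * _au_grating(a_idx, side))
                    canvas[r0:r0 + side, c0:c0 + side] = np.clip(patch, 0, 1)
                patch_records.append({"au": au, "row0": r0, "col0": c0,
                                      "size": side, "visible": bool(visible)})
            rgb = np.stack([canvas, canvas * 0.96, canvas * 0.92], axis=-1)
            rgb = np.clip(rgb + rng.normal(0.0, cfg.noise_sd, rgb.shape), 0.0, 1.0)
            image_id = f"{subject}_{k:04d}"
            images.append(FacialImage(pixels=rgb, subject_id=subject,
                                      pose_tag=PoseTag(pose),
                                      label=PainLabel(ordinal), image_id=image_id))
            rows.append({"image_id": image_id, "subject_id": subject,
                         "label": ordinal, "pose_tag": pose})
            masks[image_id] = patch_records

    manifest = pd.DataFrame(rows).sort_values("image_id").reset_index(drop=True)
    images = sorted(images, key=lambda im: im.image_id)
    return SyntheticDataset(images=images, manifest=manifest, masks=masks, config=cfg)


def grid_cell_mask(patches: list[dict], grid_side: int, image_size: int) -> np.ndarray:
    """Boolean (M, M) mask of grid cells overlapping any visible AU patch."""
    mask = np.zeros((grid_side, grid_side), dtype=bool)
    cell = image_size / grid_side
    for p in patches:
        if not p.get("visible", True):
            continue
        r0, c0, side = p["row0"], p["col0"], p["size"]
        rc0, rc1 = int(np.floor(r0 / cell)), int(np.ceil((r0 + side) / cell))
        cc0, cc1 = int(np.floor(c0 / cell)), int(np.ceil((c0 + side) / cell))
        mask[rc0:rc1, cc0:cc1] = True
    return mask


def localization_score(attention: AttentionScores, patches: list[dict],
                       grid_side: int, image_size: int) -> float:
    """Fraction of attention mass β on grid cells overlapping visible AU patches."""
    scores = attention.scores if isinstance(attention, AttentionScores) else np.asarray(attention)
    if scores.size != grid_side**2:
        raise DimensionError(
            f"{scores.size} attention scores do not fill a {grid_side}×{grid_side} grid")
    mask = grid_cell_mask(patches, grid_side, image_size)
    return float(scores.reshape(grid_side, grid_side)[mask].sum())


def write_dataset(ds: SyntheticDataset, root) -> None:
    """Image folder + manifest.csv + masks.json (the layout the reader consumes)."""
    from PIL import Image

    root = Path(root)
    (root / "images").mkdir(parents=True, exist_ok=True)
    for im in ds.images:
        arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(root / "images" / f"{im.image_id}.png")
    manifest = ds.manifest.copy()
    manifest["image_path"] = manifest["image_id"].map(lambda i: f"images/{i}.png")
    manifest.to_csv(root / "manifest.csv", index=False)
    meta = {"image_size": ds.config.image_size,
            "masks": ds.masks}
    (root / "masks.json").write_text(json.dumps(meta))
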