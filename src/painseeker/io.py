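"""Dataset reading/writing, attention heat-map export, run metadata.

On-disk layout (written by the synthetic generator, readable for any
conforming dataset, including a mapped copy of the public RatsPain release):

    root/
      manifest.csv      # image_path, image_id, subject_id, label[, pose_tag]
      images/*.png
      masks.json        # optional ground-truth AU patch boxes (synthetic data)
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .exceptions import DimensionError, SchemaError
from .model import AttentionScores, FacialImage, PainLabel, PoseTag


@dataclasses.dataclass
class Dataset:
    images: list[FacialImage]
    manifest: pd.DataFrame
    root: Path
    masks: Optional[dict] = None
    image_size: Optional[int] = None

    def __len__(self):
        return len(self.images)


def load_dataset(root, manifest_csv: str = "manifest.csv") -> Dataset:
    """Load an image-folder dataset; deterministic ordering by image_id."""
    root = Path(root)
    manifest_path = root / manifest_csv
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    manifest = pd.read_csv(manifest_path, dtype={"image_id": str, "subject_id": str})
    required = {"image_path", "image_id", "subject_id", "label"}
    if not required.issubset(manifest.columns):
        raise SchemaError(
            f"manifest missing columns {sorted(required - set(manifest.columns))}")
    for line_no, row in enumerate(manifest.itertuples(index=False), start=2):
        if pd.isna(row.subject_id) or not str(row.subject_id):
            raise SchemaError(f"manifest line {line_no}: empty subject_id")
        if int(row.label) not in (0, 1, 2):
            raise SchemaError(f"manifest line {line_no}: label {row.label!r} not in 0/1/2")

    missing = [str(root / p) for p in manifest["image_path"] if not (root / p).exists()]
    if missing:
        raise FileNotFoundError(
            "missing image files:\n" + "\n".join(missing))

    manifest = manifest.sort_values("image_id").reset_index(drop=True)
    has_pose = "pose_tag" in manifest.columns
    images = []
    for row in manifest.itertuples(index=False):
        arr = np.asarray(Image.open(root / row.image_path).convert("RGB"),
                         dtype=np.float64) / 255.0
        pose = PoseTag(row.pose_tag) if has_pose else PoseTag.UNKNOWN
        images.append(FacialImage(pixels=arr, subject_id=str(row.subject_id),
                                  pose_tag=pose, label=PainLabel(int(row.label)),
                                  image_id=str(row.image_id)))
    masks = None
    image_size = None
    masks_path = root / "masks.json"
    if masks_path.exists():
        meta = json.loads(masks_path.read_text())
        masks, image_size = meta.get("masks"), meta.get("image_size")
    return Dataset(images=images, manifest=manifest, root=root,
                   masks=masks, image_size=image_size)


def export_heatmap(attention: AttentionScores, grid_side: int,
                   image: FacialImage, out_path=None,
                   alpha: float = 0.45) -> np.ndarray:
    """Overlay the M×M attention map on the image (bilinear upsampling).

    The colour scale is normalised per image to [min β, max β]; a uniform map
    renders as a constant overlay. Returns the blended RGB array in [0, 1].
    """
    scores = attention.scores if isinstance(attention, AttentionScores) else np.asarray(attention)
    if scores.size != grid_side**2:
        raise DimensionError(
            f"{scores.size} attention scores do not fill a {grid_side}×{grid_side} grid")
    import matplotlib

    grid = scores.reshape(grid_side, grid_side)
    span = grid.max() - grid.min()
    norm = (grid - grid.min()) / span if span > 0 else np.zeros_like(grid)
    h, w = image.pixels.shape[:2]
    up = _sk_resize(norm, (h, w), order=1, mode="edge",
                    anti_aliasing=False, preserve_range=True)
    heat = matplotlib.colormaps["jet"](up)[..., :3]
    blended = np.clip((1 - alpha) * image.pixels + alpha * heat, 0, 1)
    if out_path is not None:
        Image.fromarray(np.round(blended * 255).astype(np.uint8)).save(out_path)
    return blended


def manifest_hash(manifest_path) -> str:
    return hashlib.sha256(Path(manifest_path).read_bytes()).hexdigest()


def write_run_metadata(run_dir, config: dict, seed: int,
                       manifest_path=None) -> Path:
    """Record everything needed to reproduce a run bit-exactly."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    meta = {"config": config, "seed": int(seed)}
    if manifest_path is not None:
        meta["data_manifest_sha256"] = manifest_hash(manifest_path)
    path = run_dir / "run_metadata.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return path
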