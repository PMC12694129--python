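"""Annotation I/O: YOLO label text files and COCO-style JSON.

Both dialects round-trip losslessly up to float formatting.  YOLO stores
normalized (class, cx, cy, w, h) per line; COCO stores absolute
(x, y, w, h) with top-left origin.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .errors import ParseError
from .synthetic import HealthState, SceneSample

__all__ = ["read_annotations", "write_annotations", "yolo_to_coco_box",
           "coco_to_yolo_box", "parse_yolo_labels"]


def yolo_to_coco_box(cx: float, cy: float, w: float, h: float,
                     img_w: int, img_h: int) -> tuple[float, float, float, float]:
    return ((cx - w / 2) * img_w, (cy - h / 2) * img_h, w * img_w, h * img_h)


def coco_to_yolo_box(x: float, y: float, w: float, h: float,
                     img_w: int, img_h: int) -> tuple[float, float, float, float]:
    return ((x + w / 2) / img_w, (y + h / 2) / img_h, w / img_w, h / img_h)


def parse_yolo_labels(path: Path) -> list[tuple[HealthState, float, float, float, float]]:
    boxes = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParseError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
        except ValueError as e:
            raise ParseError(f"{path}:{ln}: {e}") from None
        boxes.append((HealthState(cls), cx, cy, w, h))
    return boxes


def read_annotations(path: str | Path, dialect: str,
                     split: str = "train", load_images: bool = True
                     ) -> list[SceneSample]:
    """Load a split of annotated scenes.

    yolo_txt:  ``path`` is the dataset root containing images/<split>/ and
               labels/<split>/.
    coco_json: ``path`` is the dataset root containing
               annotations/<split>.json and images/<split>/.
    """
    root = Path(path)
    samples = []
    if dialect == "yolo_txt":
        img_dir = root / "images" / split
        for img_path in sorted(img_dir.glob("*.png")):
            label_path = root / "labels" / split / (img_path.stem + ".txt")
            boxes = parse_yolo_labels(label_path) if label_path.exists() else []
            image = np.asarray(Image.open(img_path)) if load_images else None
            samples.append(SceneSample(image=image, boxes=boxes, seed=-1))
    elif dialect == "coco_json":
        doc = json.loads((root / "annotations" / f"{split}.json").read_text())
        by_image: dict[int, list] = {im["id"]: [] for im in doc["images"]}
        for ann in doc["annotations"]:
            if ann["image_id"] not in by_image:
                raise ParseError(
                    f"{root}: annotation {ann['id']} references unknown image "
                    f"{ann['image_id']}")
            by_image[ann["image_id"]].append(ann)
        for im in doc["images"]:
            boxes = []
            for ann in by_image[im["id"]]:
                x, y, w, h = ann["bbox"]
                cx, cy, wn, hn = coco_to_yolo_box(x, y, w, h,
                                                  im["width"], im["height"])
                boxes.append((HealthState(ann["category_id"]), cx, cy, wn, hn))
            img_path = root / "images" / split / im["file_name"]
            image = (np.asarray(Image.open(img_path))
                     if load_images and img_path.exists() else None)
            samples.append(SceneSample(image=image, boxes=boxes, seed=-1))
    else:
        raise ParseError(f"unknown annotation dialect: {dialect!r}")
    return samples


def write_annotations(samples: list[SceneSample], path: str | Path,
                      dialect: str, split: str = "train",
                      image_size: int | None = None):
    """Write annotations (labels only; images are written by the generator)."""
    root = Path(path)
    if dialect == "yolo_txt":
        out_dir = root / "labels" / split
        out_dir.mkdir(parents=True, exist_ok=True)
        for i, s in enumerate(samples):
            lines = [f"{int(st)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
                     for (st, cx, cy, w, h) in s.boxes]
            (out_dir / f"scene_{i:06d}.txt").write_text(
                "\n".join(lines) + ("\n" if lines else ""))
    elif dialect == "coco_json":
        size = image_size or (samples[0].image.shape[0] if samples else 0)
        images, annotations = [], []
        ann_id = 1
        for i, s in enumerate(samples):
            images.append({"id": i + 1, "file_name": f"scene_{i:06d}.png",
                           "width": size, "height": size})
            for (st, cx, cy, w, h) in s.boxes:
                x, y, bw, bh = yolo_to_coco_box(cx, cy, w, h, size, size)
                annotations.append({"id": ann_id, "image_id": i + 1,
                                    "category_id": int(st),
                                    "bbox": [x, y, bw, bh], "area": bw * bh,
                                    "iscrowd": 0})
                ann_id += 1
        (root / "annotations").mkdir(parents=True, exist_ok=True)
        doc = {"images": images, "annotations": annotations,
               "categories": [{"id": int(s), "name": s.name.lower()}
                              for s in HealthState]}
        (root / "annotations" / f"{split}.json").write_text(json.dumps(doc))
    else:
        raise ParseError(f"unknown annotation dialect: {dialect!r}")
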