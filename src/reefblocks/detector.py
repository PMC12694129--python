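"""Detection harness: a small CSP-style backbone + PANet-style neck hosting
the dynamic downsampling, Monte Carlo attention and holistic-attention head
blocks, with an anchor-free (FCOS-style) assigner, the scale-aware dynamic
box loss, AdamW training and COCO-protocol evaluation.

The backbone is deliberately generic: the novel blocks are
placement-parameterized, so any host topology that emits a stride-8/16/32
pyramid works.  Feature flags toggle each block independently, which makes
the full ablation grid mechanically expressible.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
from scipy.special import expit

from .cocoeval import box_iou_xywh, evaluate_coco
from .errors import ConfigurationError, DataError
from .hab import HABHead
from .mcattention import MCAttention, MCAttentionConfig
from .nn import AdamW, Conv2d, ConvBlock, Module, Tensor, cosine_lr, functional as F
from .sdloss import sd_loss_tensor
from .sfdconv import SFDConv, SFDConvConfig
from .synthetic import SceneSample

__all__ = ["ModelConfig", "TrainConfig", "Detection", "Detector", "build_model",
           "train", "evaluate_detector", "nms", "samples_to_coco_gt"]

STRIDES = (8, 16, 32)


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    width: int = 16
    n_classes: int = 4
    input_size: int = 640
    use_hab_head: bool = True
    use_mcattention: bool = True
    use_sfdconv: bool = True
    use_sdloss: bool = True
    head_stacks: int = 2
    lga_patches: tuple[int, ...] = (2, 4)
    sfd_placements: tuple[str, ...] = ("down2", "down3", "down4")
    mcatt_backbone_stages: tuple[str, ...] = ("stage3", "stage4")
    mcatt_neck: bool = True
    mcatt: MCAttentionConfig = dataclasses.field(default_factory=MCAttentionConfig)
    sfd: SFDConvConfig = dataclasses.field(default_factory=SFDConvConfig)

    def validate(self):
        if self.width < 1 or self.n_classes < 1:
            raise ConfigurationError("width and n_classes must be positive")
        valid = {"down1", "down2", "down3", "down4"}
        if not set(self.sfd_placements) <= valid:
            raise ConfigurationError(
                f"invalid sfd placements: {set(self.sfd_placements) - valid}")
        if not set(self.mcatt_backbone_stages) <= {"stage3", "stage4"}:
            raise ConfigurationError("mcattention backbone stages must be stage3/stage4")


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    lr0: float = 1e-3
    lrf: float = 0.01
    warmup_epochs: float = 5.0
    batch_size: int = 16
    weight_decay: float = 5e-4
    momentum: float = 0.937
    box_weight: float = 7.5
    cls_weight: float = 0.5
    delta: float = 0.5
    augment_fliplr: float = 0.0
    augment_hsv: float = 0.0
    #: epoch after which batch-norm statistics are pinned (train/eval
    #: consistency in small-batch regimes); None disables freezing
    freeze_bn_after: int | None = None
    seed: int = 0


@dataclasses.dataclass
class Detection:
    box: tuple[float, float, float, float]  # absolute (x, y, w, h)
    class_label: int
    score: float


class _PlainHead(Module):
    """Conventional per-level head: two conv blocks then 1x1 cls/reg."""

    def __init__(self, level_channels, n_classes, *, rng):
        super().__init__()
        self.towers, self.cls_convs, self.reg_convs = [], [], []
        for i, c in enumerate(level_channels):
            tower = [ConvBlock(c, c, 3, rng=rng), ConvBlock(c, c, 3, rng=rng)]
            self.towers.append(tower)
            cls_conv = Conv2d(c, n_classes, k=1, rng=rng)
            cls_conv.bias.data[:] = -np.log(99.0)  # focal prior: p0 ~ 0.01
            reg_conv = Conv2d(c, 4, k=1, rng=rng)
            reg_conv.bias.data[:] = 0.0
            self.cls_convs.append(cls_conv)
            self.reg_convs.append(reg_conv)
            self._modules[f"tower{i}.0"] = tower[0]
            self._modules[f"tower{i}.1"] = tower[1]
            self._modules[f"cls{i}"] = self.cls_convs[i]
            self._modules[f"reg{i}"] = self.reg_convs[i]

    def forward(self, levels):
        out = []
        for i, x in enumerate(levels):
            for blk in self.towers[i]:
                x = blk(x)
            out.append((self.cls_convs[i](x), self.reg_convs[i](x)))
        return out


class Detector(Module):
    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        w = cfg.width
        c1, c2, c3, c4, c5 = w, 2 * w, 2 * w, 3 * w, 4 * w

        def down(name, cin, cout):
            if cfg.use_sfdconv and name in cfg.sfd_placements:
                return SFDConv(cin, cout, cfg.sfd, rng=rng)
            return ConvBlock(cin, cout, 3, stride=2, rng=rng)

        self.stem = ConvBlock(3, c1, 3, stride=2, rng=rng)      # /2
        self.down1 = down("down1", c1, c2)                       # /4
        self.block1 = ConvBlock(c2, c2, 3, rng=rng)
        self.down2 = down("down2", c2, c3)                       # /8
        self.block2 = ConvBlock(c3, c3, 3, rng=rng)
        self.down3 = down("down3", c3, c4)                       # /16
        self.block3 = ConvBlock(c4, c4, 3, rng=rng)
        self.down4 = down("down4", c4, c5)                       # /32
        self.block4 = ConvBlock(c5, c5, 3, rng=rng)
        if cfg.use_mcattention:
            if "stage3" in cfg.mcatt_backbone_stages:
                self.att3 = MCAttention(c4, cfg.mcatt, rng=rng)
            if "stage4" in cfg.mcatt_backbone_stages:
                self.att4 = MCAttention(c5, cfg.mcatt, rng=rng)
        # PANet-style neck
        self.lat4 = ConvBlock(c5 + c4, c4, 3, rng=rng)
        self.lat3 = ConvBlock(c4 + c3, c3, 3, rng=rng)
        self.down_p3 = ConvBlock(c3, c3, 3, stride=2, rng=rng)
        self.out4 = ConvBlock(c3 + c4, c4, 3, rng=rng)
        self.down_p4 = ConvBlock(c4, c4, 3, stride=2, rng=rng)
        self.out5 = ConvBlock(c4 + c5, c5, 3, rng=rng)
        if cfg.use_mcattention and cfg.mcatt_neck:
            self.natt3 = MCAttention(c3, cfg.mcatt, rng=rng)
            self.natt4 = MCAttention(c4, cfg.mcatt, rng=rng)
            self.natt5 = MCAttention(c5, cfg.mcatt, rng=rng)
        self.level_channels = (c3, c4, c5)
        if cfg.use_hab_head:
            self.head = HABHead(self.level_channels, cfg.n_classes,
                                stacks=cfg.head_stacks,
                                lga_patch_sizes=cfg.lga_patches, rng=rng)
        else:
            self.head = _PlainHead(self.level_channels, cfg.n_classes, rng=rng)

    # ---- feature extraction ------------------------------------------------
    def _maybe(self, name, x, rng):
        mod = getattr(self, name, None)
        return mod(x, rng=rng) if mod is not None else x

    def _dyn(self, mod, x, rng):
        return mod(x, rng=rng) if isinstance(mod, SFDConv) else mod(x)

    def pyramid(self, images: Tensor, rng: np.random.Generator | None = None):
        """Neck pyramid (P3, P4, P5) at strides 8/16/32."""
        x = self.stem(images)
        x = self.block1(self._dyn(self.down1, x, rng))
        c3 = self.block2(self._dyn(self.down2, x, rng))
        c4 = self.block3(self._dyn(self.down3, c3, rng))
        c4 = self._maybe("att3", c4, rng)
        c5 = self.block4(self._dyn(self.down4, c4, rng))
        c5 = self._maybe("att4", c5, rng)
        t4 = self.lat4(F.concatenate([F.upsample_nearest2d(c5), c4], axis=1))
        p3 = self.lat3(F.concatenate([F.upsample_nearest2d(t4), c3], axis=1))
        p4 = self.out4(F.concatenate([self.down_p3(p3), t4], axis=1))
        p5 = self.out5(F.concatenate([self.down_p4(p4), c5], axis=1))
        p3 = self._maybe("natt3", p3, rng)
        p4 = self._maybe("natt4", p4, rng)
        p5 = self._maybe("natt5", p5, rng)
        return p3, p4, p5

    def forward(self, images: Tensor, rng: np.random.Generator | None = None):
        """Raw per-level (class logits, box regression) maps."""
        return self.head(self.pyramid(images, rng))

    def extract_p4(self, images: Tensor) -> Tensor:
        """The stride-16 neck level (P4) — the forecasting feature contract."""
        return self.pyramid(images)[1]


def build_model(cfg: ModelConfig, seed: int = 0) -> Detector:
    model = Detector(cfg, seed=seed)
    return model


# --------------------------------------------------------------------------
# assignment and loss
# --------------------------------------------------------------------------

def _level_grids(input_size: int):
    grids = []
    for s in STRIDES:
        n = input_size // s
        cx = (np.arange(n) + 0.5) * s
        gx, gy = np.meshgrid(cx, cx)
        grids.append((n, gx, gy))
    return grids


def assign_targets(samples: list[SceneSample], input_size: int,
                   n_classes: int):
    """Anchor-free one-to-many assignment.

    Each box goes to exactly one pyramid level, chosen so the bounded
    decode can represent it: level 0 for max side <= 3*8 px, level 1 for
    <= 3*16, level 2 otherwise (the decode caps sizes at 4*stride, leaving
    headroom).  At that level every cell whose center lies inside the box
    is a positive; ambiguity resolves to the smallest box, and a box that
    covers no cell center falls back to the nearest cell of its level.

    Returns (cls_targets [per level (B,n_cls,n,n)], box_targets list of
    (b, level, iy, ix, x1, y1, x2, y2)).
    """
    B = len(samples)
    grids = _level_grids(input_size)
    cls_t = [np.zeros((B, n_classes, n, n), dtype=np.float32) for n, _, _ in grids]
    # smallest-area wins: track assigned area per cell
    area_t = [np.full((B, n, n), np.inf) for n, _, _ in grids]
    cell_gt = [np.full((B, n, n), -1, dtype=int) for n, _, _ in grids]
    flat_boxes = []
    for b, s in enumerate(samples):
        for (state, cx, cy, w, h) in s.boxes:
            x1, y1 = (cx - w / 2) * input_size, (cy - h / 2) * input_size
            x2, y2 = (cx + w / 2) * input_size, (cy + h / 2) * input_size
            flat_boxes.append((b, int(state), x1, y1, x2, y2))
    box_targets = []
    for gi, (b, cls, x1, y1, x2, y2) in enumerate(flat_boxes):
        area = (x2 - x1) * (y2 - y1)
        side = max(x2 - x1, y2 - y1)
        lv = 0 if side <= 3 * STRIDES[0] else (1 if side <= 3 * STRIDES[1] else 2)
        n, gx, gy = grids[lv]
        inside = (gx > x1) & (gx < x2) & (gy > y1) & (gy < y2)
        ys, xs = np.nonzero(inside)
        assigned = False
        for iy, ix in zip(ys, xs):
            if area < area_t[lv][b, iy, ix]:
                area_t[lv][b, iy, ix] = area
                cell_gt[lv][b, iy, ix] = gi
                assigned = True
        if not assigned:
            # nearest cell of the level keeps tiny objects learnable
            d2 = (gx - (x1 + x2) / 2) ** 2 + (gy - (y1 + y2) / 2) ** 2
            iy, ix = np.unravel_index(np.argmin(d2), d2.shape)
            if area < area_t[lv][b, iy, ix]:
                area_t[lv][b, iy, ix] = area
                cell_gt[lv][b, iy, ix] = gi
    for lv, (n, gx, gy) in enumerate(grids):
        bs, ys, xs = np.nonzero(cell_gt[lv] >= 0)
        for b, iy, ix in zip(bs, ys, xs):
            gi = cell_gt[lv][b, iy, ix]
            _, cls, x1, y1, x2, y2 = flat_boxes[gi]
            cls_t[lv][b, cls, iy, ix] = 1.0
            box_targets.append((b, lv, iy, ix, x1, y1, x2, y2))
    return cls_t, box_targets


def _cls_bce(logits: Tensor, targets: np.ndarray,
             pos_weight: float = 5.0) -> Tensor:
    """Sigmoid binary cross-entropy, summed (normalized by positives
    outside) — the YOLO-family classification objective.  ``pos_weight``
    counteracts the extreme foreground/background cell imbalance."""
    t = Tensor(targets)
    log_p = -F.softplus(-logits)          # log sigmoid(x)
    log_q = -F.softplus(logits)           # log (1 - sigmoid(x))
    return -(t * log_p * pos_weight + (1.0 - t) * log_q).sum()


def detection_loss(model: Detector, images: Tensor, samples: list[SceneSample],
                   tc: TrainConfig, rng: np.random.Generator):
    input_size = images.shape[2]
    preds = model(images, rng=rng)
    cls_t, box_targets = assign_targets(samples, input_size, model.cfg.n_classes)
    n_pos = max(len(box_targets), 1)
    cls_loss = Tensor(0.0)
    for (cls_map, _), tgt in zip(preds, cls_t):
        cls_loss = cls_loss + _cls_bce(cls_map, tgt)
    cls_loss = cls_loss * (1.0 / n_pos)
    if box_targets:
        # gather per-level regression predictions at assigned cells
        pred_boxes_parts, gt_parts = [], []
        by_level: dict[int, list] = {}
        for bt in box_targets:
            by_level.setdefault(bt[1], []).append(bt)
        for lv, bts in sorted(by_level.items()):
            _, reg_map = preds[lv]
            stride = STRIDES[lv]
            bidx = np.array([bt[0] for bt in bts])
            iy = np.array([bt[2] for bt in bts])
            ix = np.array([bt[3] for bt in bts])
            raw = reg_map.transpose(0, 2, 3, 1)[bidx, iy, ix]  # (N, 4)
            cx = ((ix + 0.5) * stride).astype(np.float32)
            cy = ((iy + 0.5) * stride).astype(np.float32)
            # bounded center-offset + size decode: the box need not contain
            # the cell center, which keeps sub-stride objects representable
            bcx = Tensor(cx) + (F.sigmoid(raw[:, 0]) * 2.0 - 1.0) * float(stride)
            bcy = Tensor(cy) + (F.sigmoid(raw[:, 1]) * 2.0 - 1.0) * float(stride)
            bw = (F.sigmoid(raw[:, 2]) * 2.0) ** 2 * float(stride)
            bh = (F.sigmoid(raw[:, 3]) * 2.0) ** 2 * float(stride)
            x1 = bcx - bw * 0.5
            y1 = bcy - bh * 0.5
            x2 = bcx + bw * 0.5
            y2 = bcy + bh * 0.5
            pred_boxes_parts.append(F.concatenate(
                [x1.reshape(-1, 1), y1.reshape(-1, 1),
                 x2.reshape(-1, 1), y2.reshape(-1, 1)], axis=1))
            gt_parts.append(np.array([bt[4:] for bt in bts], dtype=np.float32))
        pred_boxes = F.concatenate(pred_boxes_parts, axis=0)
        gt_boxes = np.concatenate(gt_parts, axis=0)
        box_loss = sd_loss_tensor(pred_boxes, gt_boxes, input_size,
                                  delta=tc.delta,
                                  dynamic=model.cfg.use_sdloss)
    else:
        box_loss = Tensor(0.0)
    total = tc.cls_weight * cls_loss + tc.box_weight * box_loss
    return total, {"cls": float(cls_loss.data), "box": float(box_loss.data),
                   "total": float(total.data), "n_pos": len(box_targets)}


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float = 0.65) -> list[int]:
    """Greedy non-maximum suppression on (N, 4) xywh boxes."""
    order = np.argsort(-scores, kind="mergesort")
    keep = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        ious = box_iou_xywh(boxes[i], boxes[order[1:]])[0]
        order = order[1:][ious <= iou_thr]
    return keep


def predict(model: Detector, images: np.ndarray, score_thr: float = 0.05,
            iou_thr: float = 0.65, max_dets: int = 100) -> list[list[Detection]]:
    """Run eval-mode inference on (B, H, W, 3) uint8 images."""
    model.eval()
    x = Tensor(images.astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
    preds = model(x)
    input_size = images.shape[1]
    B = images.shape[0]
    all_dets: list[list[Detection]] = [[] for _ in range(B)]
    for lv, (cls_map, reg_map) in enumerate(preds):
        stride = STRIDES[lv]
        n = cls_map.shape[2]
        scores = expit(cls_map.data)          # (B, nc, n, n)
        raw = reg_map.data
        cxy = (np.arange(n) + 0.5) * stride
        gx, gy = np.meshgrid(cxy, cxy)
        bcx = gx + (expit(raw[:, 0]) * 2 - 1) * stride
        bcy = gy + (expit(raw[:, 1]) * 2 - 1) * stride
        bw = (expit(raw[:, 2]) * 2) ** 2 * stride
        bh = (expit(raw[:, 3]) * 2) ** 2 * stride
        x1 = bcx - bw / 2
        y1 = bcy - bh / 2
        x2 = bcx + bw / 2
        y2 = bcy + bh / 2
        for b in range(B):
            cand_cls, cand_y, cand_x = np.nonzero(scores[b] > score_thr)
            for c, iy, ix in zip(cand_cls, cand_y, cand_x):
                bx1 = float(np.clip(x1[b, iy, ix], 0, input_size))
                by1 = float(np.clip(y1[b, iy, ix], 0, input_size))
                bx2 = float(np.clip(x2[b, iy, ix], 0, input_size))
                by2 = float(np.clip(y2[b, iy, ix], 0, input_size))
                if bx2 <= bx1 or by2 <= by1:
                    continue
                all_dets[b].append(Detection(
                    box=(bx1, by1, bx2 - bx1, by2 - by1),
                    class_label=int(c), score=float(scores[b, c, iy, ix])))
    final = []
    for dets in all_dets:
        kept: list[Detection] = []
        for c in range(model.cfg.n_classes):
            cdets = [d for d in dets if d.class_label == c]
            if not cdets:
                continue
            boxes = np.array([d.box for d in cdets])
            sc = np.array([d.score for d in cdets])
            kept.extend(cdets[i] for i in nms(boxes, sc, iou_thr))
        kept.sort(key=lambda d: -d.score)
        final.append(kept[:max_dets])
    return final


# --------------------------------------------------------------------------
# training loop and evaluation
# --------------------------------------------------------------------------

def _hsv_jitter(img: np.ndarray, rng: np.random.Generator, strength: float):
    gain = 1.0 + strength * (rng.random(3) * 2 - 1)
    return np.clip(img.astype(np.float32) * gain, 0, 255).astype(np.uint8)


def train(model: Detector, samples: list[SceneSample], tc: TrainConfig,
          out_dir: str | Path | None = None, log=None) -> list[dict]:
    """Train the detector; returns the per-epoch metric log."""
    if not samples:
        raise DataError("empty dataset")
    rng = np.random.default_rng(tc.seed)
    model.train()
    opt = AdamW(model.parameters(), lr=tc.lr0, betas=(tc.momentum, 0.999),
                weight_decay=tc.weight_decay)
    history = []
    n = len(samples)
    for epoch in range(tc.epochs):
        if tc.freeze_bn_after is not None and epoch == tc.freeze_bn_after:
            model.freeze_bn_stats()
        opt.lr = cosine_lr(epoch, tc.epochs, tc.lr0, tc.lrf, tc.warmup_epochs)
        order = rng.permutation(n)
        epoch_loss, t0 = 0.0, time.time()
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            batch = [samples[i] for i in idx]
            imgs = []
            batch_aug = []
            for s in batch:
                img, boxes = s.image, s.boxes
                if tc.augment_fliplr and rng.random() < tc.augment_fliplr:
                    img = img[:, ::-1]
                    boxes = [(st, 1.0 - cx, cy, w, h) for (st, cx, cy, w, h) in boxes]
                if tc.augment_hsv:
                    img = _hsv_jitter(img, rng, tc.augment_hsv)
                imgs.append(img)
                batch_aug.append(SceneSample(image=img, boxes=boxes, seed=s.seed))
            x = Tensor(np.stack(imgs).astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
            loss, parts = detection_loss(model, x, batch_aug, tc, rng)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += parts["total"] * len(batch)
        row = {"epoch": epoch, "loss": epoch_loss / n, "lr": opt.lr,
               "time_s": round(time.time() - t0, 2)}
        history.append(row)
        if log:
            log(row)
    recalibrate_bn(model, samples)
    model.train()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "checkpoint.npz", **model.state_dict())
        (out / "config.json").write_text(json.dumps(dataclasses.asdict(model.cfg)))
        (out / "metrics.json").write_text(json.dumps(history))
        (out / "train.log").write_text("\n".join(
            f"epoch {r['epoch']:4d}  loss {r['loss']:.6f}  lr {r['lr']:.6f}"
            for r in history) + "\n")
    return history


def recalibrate_bn(model: Detector, samples: list[SceneSample],
                   max_images: int = 16):
    """Re-estimate batch-norm statistics under the final weights.

    Running averages lag the weights they normalize for; one forward pass in
    batch-statistics mode (attention and dynamic blocks kept in their
    deterministic eval behavior) pins the statistics to the trained model,
    closing the train/eval normalization gap."""
    from .nn.modules import BatchNorm2d

    model.eval()
    bns = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [(bn.momentum, bn.training) for bn in bns]
    for bn in bns:
        bn.training, bn.momentum, bn.freeze_stats = True, 1.0, False
    imgs = np.stack([s.image for s in samples[:max_images]])
    x = Tensor(imgs.astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
    model.head(model.pyramid(x))
    for bn, (mom, tr) in zip(bns, saved):
        bn.momentum, bn.training = mom, tr


def samples_to_coco_gt(samples: list[SceneSample], input_size: int) -> dict:
    images, annotations = [], []
    ann_id = 1
    for i, s in enumerate(samples):
        images.append({"id": i + 1, "file_name": f"{i:06d}.png",
                       "width": input_size, "height": input_size})
        for (state, cx, cy, w, h) in s.boxes:
            annotations.append({
                "id": ann_id, "image_id": i + 1, "category_id": int(state),
                "bbox": [(cx - w / 2) * input_size, (cy - h / 2) * input_size,
                         w * input_size, h * input_size],
                "area": w * h * input_size * input_size, "iscrowd": 0})
            ann_id += 1
    cats = [{"id": c, "name": str(c)} for c in range(4)]
    return {"images": images, "annotations": annotations, "categories": cats}


def evaluate_detector(model: Detector, samples: list[SceneSample],
                      score_thr: float = 0.05, batch_size: int = 8,
                      nms_iou: float = 0.65) -> dict:
    """COCO-protocol AP of the model on a list of annotated scenes."""
    input_size = samples[0].image.shape[0]
    det_records = []
    for start in range(0, len(samples), batch_size):
        chunk = samples[start:start + batch_size]
        imgs = np.stack([s.image for s in chunk])
        dets = predict(model, imgs, score_thr=score_thr, iou_thr=nms_iou)
        for j, dlist in enumerate(dets):
            for d in dlist:
                det_records.append({"image_id": start + j + 1,
                                    "category_id": d.class_label,
                                    "bbox": list(d.box), "score": d.score})
    gt = samples_to_coco_gt(samples, input_size)
    return evaluate_coco(det_records, gt)
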