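"""Temporal coral-health forecasting.

Pipeline: per site, the two observed years' images pass through a frozen
detector (P4 neck features, stride 16 — 40x40 maps for 640 inputs); a
two-layer ConvLSTM (3x3 kernels) consumes the two-step feature sequence;
a 1x1 prediction head with channel-wise softmax emits a probabilistic
forecast map over the four health states for the following year.  Ground
truth is the year-3 annotation rasterized onto the feature grid with
severity-priority overlap resolution (Dead > Bleached > Sub-healthy >
Healthy); background cells are excluded from the loss and all metrics.

Two reference predictors calibrate the learned model: a persistence
baseline (year 3 = year 2) and a first-order Markov chain estimated from
per-cell state transitions on the training sites.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.metrics import precision_recall_fscore_support

from .errors import ConfigurationError, DataError
from .nn import AdamW, Conv2d, Module, Parameter, Tensor, cosine_lr, functional as F
from .synthetic import SEVERITY_ORDER, SiteSeries

__all__ = [
    "BACKGROUND", "rasterize", "ConvLSTMCell", "ConvLSTM", "ForecastModel",
    "FrozenFeatureExtractor", "ForecastTrainConfig", "train_forecaster",
    "naive_baseline", "MarkovBaseline", "markov_baseline", "forecast_metrics",
    "forecast", "site_features_and_targets", "check_split_integrity",
]

BACKGROUND = 255
N_STATES = 4

#: transition groups reported for ecological state changes
TRANSITION_GROUPS = {
    "Healthy->Healthy": lambda y1, y2: (y1 == 0) & (y2 == 0),
    "Healthy->Sub-healthy": lambda y1, y2: (y1 == 0) & (y2 == 1),
    "Sub-healthy->Bleached": lambda y1, y2: (y1 == 1) & (y2 == 2),
    "Bleached->Dead": lambda y1, y2: (y1 == 2) & (y2 == 3),
    "Stable Bleached": lambda y1, y2: (y1 == 2) & (y2 == 2),
    "Recovery (any->Healthy)": lambda y1, y2: (y1 != 0) & (y1 != BACKGROUND) & (y2 == 0),
}


def rasterize(boxes, grid: int = 40) -> np.ndarray:
    """Rasterize normalized (state, cx, cy, w, h) boxes onto a grid.

    A cell takes a box's label iff the box contains the cell center;
    overlaps resolve by severity (worst state wins); cells outside every box
    are background.
    """
    out = np.full((grid, grid), BACKGROUND, dtype=np.uint8)
    centers = (np.arange(grid) + 0.5) / grid
    gx, gy = np.meshgrid(centers, centers)
    # paint from least to most severe so severe states overwrite
    for state in reversed(SEVERITY_ORDER):
        for (st, cx, cy, w, h) in boxes:
            if int(st) != int(state):
                continue
            inside = ((gx > cx - w / 2) & (gx < cx + w / 2)
                      & (gy > cy - h / 2) & (gy < cy + h / 2))
            out[inside] = int(st)
    return out


class ConvLSTMCell(Module):
    """One ConvLSTM layer: all four gates as 3x3 convolutions over the input
    and the previous hidden state."""

    def __init__(self, in_channels: int, hidden: int, k: int = 3, *,
                 rng: np.random.Generator):
        super().__init__()
        self.hidden = hidden
        self.wx = Conv2d(in_channels, 4 * hidden, k=k, rng=rng)       # with bias
        self.wh = Conv2d(hidden, 4 * hidden, k=k, bias=False, rng=rng)

    def init_state(self, b: int, h: int, w: int):
        z = np.zeros((b, self.hidden, h, w), dtype=np.float32)
        return Tensor(z), Tensor(z.copy())

    def step(self, x: Tensor, state: tuple[Tensor, Tensor]):
        h_prev, c_prev = state
        z = self.wx(x) + self.wh(h_prev)
        n = self.hidden
        i = F.sigmoid(z[:, 0 * n:1 * n])
        f = F.sigmoid(z[:, 1 * n:2 * n])
        o = F.sigmoid(z[:, 2 * n:3 * n])
        g = F.tanh(z[:, 3 * n:4 * n])
        c = f * c_prev + i * g
        h = o * F.tanh(c)
        return h, c


class ConvLSTM(Module):
    def __init__(self, in_channels: int, hidden: int = 256, layers: int = 2, *,
                 rng: np.random.Generator):
        super().__init__()
        self.cells = [ConvLSTMCell(in_channels if i == 0 else hidden, hidden,
                                   rng=rng) for i in range(layers)]

    def forward(self, seq: list[Tensor]) -> Tensor:
        """Run the sequence; returns the final hidden state of the last layer."""
        b, _, h, w = seq[0].shape
        states = [cell.init_state(b, h, w) for cell in self.cells]
        out = None
        for x in seq:
            inp = x
            for li, cell in enumerate(self.cells):
                states[li] = cell.step(inp, states[li])
                inp = states[li][0]
            out = inp
        return out


class ForecastModel(Module):
    """ConvLSTM encoder + 1x1 prediction head + channel softmax."""

    def __init__(self, in_channels: int, hidden: int = 256, layers: int = 2, *,
                 rng: np.random.Generator):
        super().__init__()
        self.encoder = ConvLSTM(in_channels, hidden, layers, rng=rng)
        self.head = Conv2d(hidden, N_STATES, k=1, rng=rng)

    def logits(self, seq: list[Tensor]) -> Tensor:
        return self.head(self.encoder(seq))

    def forward(self, seq: list[Tensor]) -> Tensor:
        return F.softmax(self.logits(seq), axis=1)


def forecast(seq: list[Tensor], model: ForecastModel) -> Tensor:
    """Probabilistic forecast map (B, 4, H, W); channels sum to 1 per pixel."""
    return model(seq)


class FrozenFeatureExtractor:
    """Wraps a trained detector as a fixed P4 feature source.

    Output tensors are detached, so no gradient can reach the detector; the
    detector is put in eval mode (deterministic attention contexts)."""

    def __init__(self, detector):
        self.detector = detector
        detector.eval()

    def __call__(self, images: np.ndarray) -> Tensor:
        x = Tensor(images.astype(np.float32).transpose(0, 3, 1, 2) / 255.0)
        return self.detector.extract_p4(x).detach()

    def assert_frozen(self):
        bad = [n for n, p in self.detector.named_parameters() if p.grad is not None]
        if bad:
            raise AssertionError(f"gradient reached frozen extractor: {bad[:3]}")


@dataclasses.dataclass(frozen=True)
class ForecastTrainConfig:
    epochs: int = 100
    lr0: float = 1e-4
    lrf: float = 0.01
    hidden: int = 256
    layers: int = 2
    batch_size: int = 8
    weight_decay: float = 5e-4
    seed: int = 0


def site_features_and_targets(sites: list[SiteSeries],
                              extractor: FrozenFeatureExtractor,
                              batch_size: int = 8):
    """Per site: ([F(year1), F(year2)], year-3 raster on the feature grid).

    Also returns the year-1 and year-2 rasters for baselines/metrics."""
    feats, targets, rasters12 = [], [], []
    for start in range(0, len(sites), batch_size):
        chunk = sites[start:start + batch_size]
        f1 = extractor(np.stack([s.frames[0].image for s in chunk]))
        f2 = extractor(np.stack([s.frames[1].image for s in chunk]))
        grid = f1.shape[2]
        for j, s in enumerate(chunk):
            feats.append([Tensor(f1.data[j:j + 1]), Tensor(f2.data[j:j + 1])])
            targets.append(rasterize(s.frames[2].boxes, grid))
            rasters12.append((rasterize(s.frames[0].boxes, grid),
                              rasterize(s.frames[1].boxes, grid)))
    return feats, targets, rasters12


def masked_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Pixel-wise CE over the four state channels, background ignored."""
    mask = (target != BACKGROUND)
    n = max(int(mask.sum()), 1)
    onehot = np.zeros(logits.shape, dtype=np.float32)
    b_idx, y_idx, x_idx = np.nonzero(mask)
    onehot[b_idx, target[mask].astype(int), y_idx, x_idx] = 1.0
    lp = F.log_softmax(logits, axis=1)
    return -(lp * Tensor(onehot)).sum() * (1.0 / n)


def check_split_integrity(*site_groups: list[SiteSeries]):
    """Raise if any site id appears in more than one split."""
    seen: dict[str, int] = {}
    for gi, group in enumerate(site_groups):
        for s in group:
            if s.site_id in seen and seen[s.site_id] != gi:
                raise DataError(f"site {s.site_id} appears in two splits")
            seen[s.site_id] = gi


def train_forecaster(train_sites: list[SiteSeries],
                     extractor: FrozenFeatureExtractor,
                     tc: ForecastTrainConfig,
                     val_sites: list[SiteSeries] | None = None,
                     log=None):
    """Train the ConvLSTM forecaster on frozen detector features.

    Only the ConvLSTM and prediction-head parameters are optimized; the
    extractor is asserted gradient-free every epoch."""
    if not train_sites:
        raise DataError("empty site dataset")
    if val_sites:
        check_split_integrity(train_sites, val_sites)
    rng = np.random.default_rng(tc.seed)
    feats, targets, _ = site_features_and_targets(train_sites, extractor)
    in_channels = feats[0][0].shape[1]
    model = ForecastModel(in_channels, tc.hidden, tc.layers, rng=rng)
    opt = AdamW(model.parameters(), lr=tc.lr0, betas=(0.9, 0.999),
                weight_decay=tc.weight_decay)
    history = []
    n = len(train_sites)
    for epoch in range(tc.epochs):
        opt.lr = cosine_lr(epoch, tc.epochs, tc.lr0, tc.lrf)
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, tc.batch_size):
            idx = order[start:start + tc.batch_size]
            seq = [F.concatenate([feats[i][t] for i in idx], axis=0)
                   for t in range(2)]
            tgt = np.stack([targets[i] for i in idx])
            logits = model.logits(seq)
            loss = masked_cross_entropy(logits, tgt)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
        extractor.assert_frozen()
        row = {"epoch": epoch, "loss": total / n, "lr": opt.lr}
        history.append(row)
        if log:
            log(row)
    return model, history


def predict_rasters(model: ForecastModel, feats) -> np.ndarray:
    """Argmax state raster per site, (N, H, W)."""
    model.eval()
    out = []
    for seq in feats:
        probs = model([Tensor(s.data) for s in seq])
        out.append(np.argmax(probs.data[0], axis=0).astype(np.uint8))
    return np.stack(out)


def naive_baseline(year2_raster: np.ndarray) -> np.ndarray:
    """Persistence: predicted year-3 state equals the year-2 state."""
    return year2_raster.copy()


class MarkovBaseline:
    def __init__(self, matrix: np.ndarray):
        self.matrix = matrix
        # row-argmax with ties broken toward higher severity
        self.prediction_rule = np.array(
            [max(np.flatnonzero(row == row.max())) for row in matrix])

    def predict(self, year2_raster: np.ndarray) -> np.ndarray:
        out = year2_raster.copy()
        fg = out != BACKGROUND
        out[fg] = self.prediction_rule[out[fg].astype(int)]
        return out


def markov_baseline(raster_pairs: list[tuple[np.ndarray, np.ndarray]]
                    ) -> MarkovBaseline:
    """Estimate a first-order 4x4 transition matrix from per-cell state
    transitions (cells background in either year are skipped); rows with no
    observations fall back to uniform."""
    counts = np.zeros((N_STATES, N_STATES))
    for a, b in raster_pairs:
        valid = (a != BACKGROUND) & (b != BACKGROUND)
        np.add.at(counts, (a[valid].astype(int), b[valid].astype(int)), 1)
    rows = counts.sum(axis=1, keepdims=True)
    matrix = np.where(rows > 0, counts / np.maximum(rows, 1), 1.0 / N_STATES)
    return MarkovBaseline(matrix)


def forecast_metrics(pred: np.ndarray, truth: np.ndarray,
                     year1: np.ndarray | None = None,
                     year2: np.ndarray | None = None) -> dict:
    """PFA, per-class precision/recall/F1, macro-F1, ordinal MAE and
    transition-specific accuracy.

    All metrics are computed over cells whose ground truth is foreground.
    A background prediction at a labeled cell counts as an error for PFA
    and the per-class scores; ordinal MAE is computed where both sides are
    labeled states.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise DataError("prediction/truth raster shapes differ")
    mask = truth != BACKGROUND
    n = int(mask.sum())
    p, t = pred[mask].astype(int), truth[mask].astype(int)
    pfa = 100.0 * float((p == t).mean()) if n else float("nan")
    # background predictions become an out-of-range label for scoring
    p_scored = np.where(p == BACKGROUND, -1, p)
    prec, rec, f1, _ = precision_recall_fscore_support(
        t, p_scored, labels=list(range(N_STATES)), zero_division=0)
    both = mask & (pred != BACKGROUND)
    mae = float(np.abs(pred[both].astype(float) - truth[both]).mean()) if both.any() else float("nan")
    out = {
        "PFA": pfa,
        "Macro_F1": 100.0 * float(f1.mean()),
        "MAE": mae,
        "per_class": {
            name: {"precision": 100.0 * float(prec[i]),
                   "recall": 100.0 * float(rec[i]),
                   "f1": 100.0 * float(f1[i])}
            for i, name in enumerate(
                ["Healthy", "Sub-healthy", "Bleached", "Dead"])
        },
    }
    if year1 is not None and year2 is not None:
        trans = {}
        for name, fn in TRANSITION_GROUPS.items():
            grp = fn(year1, year2) & mask & (year1 != BACKGROUND) & (year2 != BACKGROUND)
            trans[name] = (100.0 * float((pred[grp] == truth[grp]).mean())
                           if grp.any() else float("nan"))
        out["transitions"] = trans
    return out
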