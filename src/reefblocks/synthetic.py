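"""Synthetic coral reef scenes with health-state annotations.

Generates the two kinds of fixtures the rest of the package consumes:

* single detection scenes — textured seabed backgrounds with elliptical
  colony blobs in one of four ordinal health states (Healthy, Sub-healthy,
  Bleached, Dead), tightly boxed, with a configurable bias toward small
  objects (the area histogram of real reef survey data is strongly
  small-object heavy);
* multi-year site series — the same colony layout re-rendered for three
  consecutive years, with per-colony health states evolving by a first-order
  Markov chain, emulating bleaching trajectories.

Everything is a pure function of (config, seed): the same pair reproduces a
sample bit-exactly.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError

__all__ = [
    "HealthState", "SceneConfig", "SceneSample", "SiteSeries", "SEVERITY_ORDER",
    "generate_scene", "generate_site_series", "degrade", "write_dataset",
    "SMALL_OBJECT_AREA_FRACTION",
]


class HealthState(enum.IntEnum):
    """Ordinal coral health state; the integer value is the severity rank."""

    HEALTHY = 0
    SUB_HEALTHY = 1
    BLEACHED = 2
    DEAD = 3


#: Rasterization priority: worse states win overlaps.
SEVERITY_ORDER = (HealthState.DEAD, HealthState.BLEACHED,
                  HealthState.SUB_HEALTHY, HealthState.HEALTHY)

#: COCO small-object cutoff (32 px at 640) as a normalized area.
SMALL_OBJECT_AREA_FRACTION = (32.0 / 640.0) ** 2

# Base RGB palettes per state (healthy corals are brown-green, sub-healthy
# pale, bleached white, dead algae-covered gray).
_PALETTES = {
    HealthState.HEALTHY: (110, 120, 60),
    HealthState.SUB_HEALTHY: (190, 175, 140),
    HealthState.BLEACHED: (240, 240, 235),
    HealthState.DEAD: (120, 120, 120),
}


@dataclasses.dataclass(frozen=True)
class SceneConfig:
    image_size: int = 320
    colony_count_range: tuple[int, int] = (3, 8)
    state_mixture: tuple[float, float, float, float] = (0.4, 0.25, 0.2, 0.15)
    small_object_fraction: float = 0.6
    #: normalized footprint side-length range for small / large objects;
    #: the gap between the ranges keeps the small-object bias crisp against
    #: the COCO area < 32^2 cutoff after pixel snapping
    small_side_range: tuple[float, float] = (0.015, 0.04)
    large_side_range: tuple[float, float] = (0.1, 0.35)
    n_lobes_range: tuple[int, int] = (1, 3)

    def validate(self):
        if self.image_size < 64:
            raise ConfigurationError("image_size must be >= 64")
        if self.colony_count_range[0] < 0:
            raise ConfigurationError("colony count must be >= 0")
        if abs(sum(self.state_mixture) - 1.0) > 1e-6:
            raise ConfigurationError(
                f"state_mixture must sum to 1, got {sum(self.state_mixture)}")
        if not 0.0 <= self.small_object_fraction <= 1.0:
            raise ConfigurationError("small_object_fraction must be in [0,1]")


@dataclasses.dataclass
class SceneSample:
    image: np.ndarray  # (H, W, 3) uint8
    boxes: list[tuple[HealthState, float, float, float, float]]  # (state, cx, cy, w, h)
    seed: int


@dataclasses.dataclass
class SiteSeries:
    site_id: str
    frames: list[SceneSample]  # years 1..3
    colony_states: np.ndarray  # (n_colonies, 3) int
    transition_matrix: np.ndarray  # (4, 4)


def _value_noise(rng: np.random.Generator, size: int) -> np.ndarray:
    """Low-frequency value noise in [0,1]: coarse grid, smooth upsample."""
    coarse = rng.random((8, 8))
    noise = ndimage.zoom(coarse, size / 8.0, order=3)[:size, :size]
    fine = rng.random((size, size)) * 0.08
    out = noise + fine
    return (out - out.min()) / max(out.max() - out.min(), 1e-9)


def _lobe_extents(lobes):
    """Half-extents of a set of ellipse lobes along x and y (analytic)."""
    ex = ey = 0.0
    cx0, cy0 = lobes[0][0], lobes[0][1]
    for (cx, cy, a, b, theta) in lobes:
        ct, st = np.cos(theta), np.sin(theta)
        half_x = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
        half_y = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
        ex = max(ex, abs(cx - cx0) + half_x)
        ey = max(ey, abs(cy - cy0) + half_y)
    return ex, ey


def _sample_colony_geometry(rng: np.random.Generator, cfg: SceneConfig):
    """Draw a colony footprint: 1-3 overlapping ellipse lobes (branching).

    Lobes are rescaled so the larger half-extent equals half the drawn
    footprint side, giving direct control over the bounding-box scale.
    """
    if rng.random() < cfg.small_object_fraction:
        lo, hi = cfg.small_side_range
    else:
        lo, hi = cfg.large_side_range
    side = lo + (hi - lo) * rng.random()
    cx, cy = 0.08 + 0.84 * rng.random(), 0.08 + 0.84 * rng.random()
    n_lobes = rng.integers(cfg.n_lobes_range[0], cfg.n_lobes_range[1] + 1)
    raw = []
    for i in range(n_lobes):
        # first lobe centered; extra lobes offset within the footprint
        off = (rng.random(2) - 0.5) * (0.0 if i == 0 else 0.8)
        a = 0.5 * (0.6 + 0.4 * rng.random())
        b = 0.5 * (0.6 + 0.4 * rng.random())
        theta = rng.random() * np.pi
        raw.append((off[0], off[1], a, b, theta))
    ex, ey = _lobe_extents([(ox, oy, a, b, th) for (ox, oy, a, b, th) in raw])
    scale = (side / 2) / max(ex, ey, 1e-9)
    return [(cx + ox * scale, cy + oy * scale, a * scale, b * scale, th)
            for (ox, oy, a, b, th) in raw]


def _render_colony_mask(lobes, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    xn = (xx + 0.5) / size
    yn = (yy + 0.5) / size
    mask = np.zeros((size, size), dtype=bool)
    for (cx, cy, a, b, theta) in lobes:
        ct, st = np.cos(theta), np.sin(theta)
        u = (xn - cx) * ct + (yn - cy) * st
        v = -(xn - cx) * st + (yn - cy) * ct
        mask |= (u / max(a, 1e-6)) ** 2 + (v / max(b, 1e-6)) ** 2 <= 1.0
    return mask


def _mask_box(mask: np.ndarray, size: int):
    """Tight normalized (cx, cy, w, h) box around a boolean mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    x0, x1 = xs.min(), xs.max() + 1
    y0, y1 = ys.min(), ys.max() + 1
    return ((x0 + x1) / 2 / size, (y0 + y1) / 2 / size,
            (x1 - x0) / size, (y1 - y0) / size)


def _render(colonies, states, size: int, rng: np.random.Generator) -> SceneSample:
    bg = _value_noise(rng, size)
    # sandy-blue seabed gradient modulated by noise
    img = np.empty((size, size, 3), dtype=np.float32)
    img[..., 0] = 40 + 60 * bg
    img[..., 1] = 70 + 70 * bg
    img[..., 2] = 90 + 80 * bg
    texture = 0.75 + 0.5 * _value_noise(rng, size)
    boxes = []
    for lobes, state in zip(colonies, states):
        mask = _render_colony_mask(lobes, size)
        box = _mask_box(mask, size)
        if box is None:
            continue
        base = np.array(_PALETTES[HealthState(state)], dtype=np.float32)
        for c in range(3):
            img[..., c] = np.where(mask, base[c] * texture, img[..., c])
        boxes.append((HealthState(state), *box))
    return np.clip(img, 0, 255).astype(np.uint8), boxes


def generate_scene(cfg: SceneConfig, seed: int) -> SceneSample:
    """Render one annotated reef scene; deterministic in (cfg, seed)."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    n = int(rng.integers(cfg.colony_count_range[0], cfg.colony_count_range[1] + 1))
    colonies = [_sample_colony_geometry(rng, cfg) for _ in range(n)]
    states = rng.choice(4, size=n, p=np.asarray(cfg.state_mixture))
    image, boxes = _render(colonies, states, cfg.image_size, rng)
    return SceneSample(image=image, boxes=boxes, seed=seed)


def _check_stochastic(matrix: np.ndarray):
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ConfigurationError("transition matrix must be 4x4")
    if np.any(matrix < -1e-12) or np.any(np.abs(matrix.sum(axis=1) - 1.0) > 1e-9):
        raise ConfigurationError("transition matrix rows must sum to 1")
    return matrix


def generate_site_series(cfg: SceneConfig, transition_matrix: np.ndarray,
                         seed: int, *, n_years: int = 3,
                         initial_distribution=None,
                         jitter: float = 0.02,
                         site_id: str | None = None) -> SiteSeries:
    """A 3-year series of the same site with Markov health transitions.

    Colony identities and positions persist across years (jitter <= 2% of the
    image by default); year-1 states follow ``initial_distribution`` (uniform
    over the four states when omitted) and later years follow the chain.
    """
    cfg.validate()
    M = _check_stochastic(transition_matrix)
    if initial_distribution is None:
        initial_distribution = np.full(4, 0.25)
    rng = np.random.default_rng(seed)
    n = int(rng.integers(cfg.colony_count_range[0], cfg.colony_count_range[1] + 1))
    base_colonies = [_sample_colony_geometry(rng, cfg) for _ in range(n)]
    states = np.zeros((n, n_years), dtype=int)
    if n:
        states[:, 0] = rng.choice(4, size=n, p=np.asarray(initial_distribution))
        for t in range(1, n_years):
            for i in range(n):
                states[i, t] = rng.choice(4, p=M[states[i, t - 1]])
    frames = []
    for t in range(n_years):
        jit = rng.uniform(-jitter, jitter, size=(n, 2)) if n else np.zeros((0, 2))
        colonies_t = [
            [(cx + jit[i, 0], cy + jit[i, 1], a, b, th) for (cx, cy, a, b, th) in lobes]
            for i, lobes in enumerate(base_colonies)
        ]
        image, boxes = _render(colonies_t, states[:, t], cfg.image_size, rng)
        frames.append(SceneSample(image=image, boxes=boxes, seed=seed))
    return SiteSeries(site_id=site_id or f"site_{seed:06d}", frames=frames,
                      colony_states=states, transition_matrix=M)


def degrade(image: np.ndarray, mode: str, strength: float,
            seed: int = 0) -> np.ndarray:
    """Apply an underwater degradation; strength 0 returns the input unchanged.

    ``turbid``     Gaussian blur plus contrast reduction (suspended sediment).
    ``low_light``  multiplicative illumination gradient across the frame.
    ``color_cast`` attenuation of red (and mildly green) channels, emulating
                   the wavelength-selective absorption of seawater.
    """
    if not 0.0 <= strength <= 1.0:
        raise ConfigurationError("strength must be in [0,1]")
    if strength == 0.0:
        return image.copy()
    img = image.astype(np.float32)
    rng = np.random.default_rng(seed)
    if mode == "turbid":
        sigma = 0.5 + 4.0 * strength
        for c in range(3):
            img[..., c] = ndimage.gaussian_filter(img[..., c], sigma)
        mean = img.mean()
        img = mean + (img - mean) * (1.0 - 0.6 * strength)
    elif mode == "low_light":
        h, w = img.shape[:2]
        angle = rng.random() * 2 * np.pi
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (np.cos(angle) * xx / w + np.sin(angle) * yy / h)
        ramp = (ramp - ramp.min()) / max(ramp.max() - ramp.min(), 1e-9)
        gain = 1.0 - strength * (0.3 + 0.6 * ramp)
        img *= gain[..., None]
    elif mode == "color_cast":
        img[..., 0] *= 1.0 - 0.7 * strength   # red absorbed fastest
        img[..., 1] *= 1.0 - 0.2 * strength
        # blue left untouched
    else:
        raise ConfigurationError(f"unknown degradation mode: {mode!r}")
    return np.clip(img, 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# dataset export
# --------------------------------------------------------------------------

def _write_yolo_labels(path: Path, sample: SceneSample):
    lines = [f"{int(s)} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}"
             for (s, cx, cy, w, h) in sample.boxes]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _coco_dict(samples: list[SceneSample], names: list[str], size: int) -> dict:
    images, annotations = [], []
    ann_id = 1
    for i, s in enumerate(samples):
        images.append({"id": i + 1, "file_name": names[i],
                       "width": size, "height": size})
        for (state, cx, cy, w, h) in s.boxes:
            annotations.append({
                "id": ann_id, "image_id": i + 1, "category_id": int(state),
                "bbox": [round((cx - w / 2) * size, 3), round((cy - h / 2) * size, 3),
                         round(w * size, 3), round(h * size, 3)],
                "area": round(w * size * h * size, 3), "iscrowd": 0,
            })
            ann_id += 1
    categories = [{"id": int(s), "name": s.name.lower()} for s in HealthState]
    return {"images": images, "annotations": annotations, "categories": categories}


def write_dataset(out_dir: str | Path, cfg: SceneConfig, *, n_scenes: int = 0,
                  n_sites: int = 0, transition_matrix=None, seed: int = 0,
                  split: str = "train") -> Path:
    """Write a detection split (PNG + YOLO txt + COCO JSON) and optionally a
    site manifest with 3-year series for forecasting."""
    out = Path(out_dir)
    (out / "images" / split).mkdir(parents=True, exist_ok=True)
    (out / "labels" / split).mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    samples, names = [], []
    for i in range(n_scenes):
        s = generate_scene(cfg, seed + i)
        name = f"scene_{seed + i:06d}.png"
        Image.fromarray(s.image).save(out / "images" / split / name)
        _write_yolo_labels(out / "labels" / split / (name[:-4] + ".txt"), s)
        samples.append(s)
        names.append(name)
    (out / "annotations" / f"{split}.json").write_text(
        json.dumps(_coco_dict(samples, names, cfg.image_size)))
    if n_sites:
        if transition_matrix is None:
            raise ConfigurationError("site export requires a transition matrix")
        manifest = []
        for i in range(n_sites):
            series = generate_site_series(cfg, transition_matrix, seed + 10_000 + i)
            site_dir = out / "sites" / series.site_id
            site_dir.mkdir(parents=True, exist_ok=True)
            entry = {"site_id": series.site_id, "frames": []}
            for year, frame in enumerate(series.frames, start=1):
                img_name = f"year{year}.png"
                Image.fromarray(frame.image).save(site_dir / img_name)
                _write_yolo_labels(site_dir / f"year{year}.txt", frame)
                entry["frames"].append({"year": year,
                                        "image": str(site_dir / img_name),
                                        "labels": str(site_dir / f"year{year}.txt")})
            manifest.append(entry)
        (out / "sites.json").write_text(json.dumps(manifest, indent=1))
    return out
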