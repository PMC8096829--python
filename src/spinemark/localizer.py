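"""The three networks and the two-step inference pipeline.

Step I works on the whole (resized, intensity-normalized) radiograph:
a presence classifier emits 24 sigmoid probabilities (one per level,
binary cross-entropy training) and a global corner localizer emits
24 x 4 heatmaps read out by a DSNT head into a 24 x 4 x 2 coordinate
matrix.  Step II crops each detected vertebra (tight corner box grown
by 70%), resizes the crop, and a refiner network with a single 1 x 4 x 2
DSNT head re-localizes the corners; the inverse crop transform maps them
back to original-image pixels.

Backbones are compact strided convolution stacks with coordinate
channels, sized to train on a single CPU; width, depth and input size
are configurable.  Per-level identity is carried purely by channel
index: the presence vector selects which of the 24 corner blocks are
read out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import dsnt, nn
from .annotations import (
    AnnotatedImage, CornerSet, VertebraLevel, N_LEVELS, N_CORNERS,
    presence_from_landmarks,
)
from .augment import AugmentConfig, elastic_and_noise, random_caudal_crop, random_rotate_flip
from .geometry import BoundingBox, CropTransform, GeometryError, crop_resize
from .synthetic_spine import GroundTruthRecord

__all__ = [
    "BackboneConfig", "TrainSchedule", "Detection", "Checkpoint",
    "PresenceNet", "CornerNet",
    "train_presence", "train_corners_global", "train_refiner",
    "build_refiner_crops", "infer", "detections_to_landmarks",
    "default_schedule",
]

_FAMILIES = {
    # family: ((channels, stride) per conv stage)
    "tiny": ((16, 2), (24, 2), (32, 2)),
    "tiny-fine": ((16, 2), (24, 2), (32, 1)),   # finer heatmap (stride 4)
    "small": ((16, 2), (32, 2), (48, 2), (64, 2)),
}


@dataclass
class BackboneConfig:
    """Architecture of a feature extractor + head.

    ``family`` selects a strided-conv stack ("tiny": total stride 8,
    "tiny-fine": stride 4 for finer heatmaps, "small": stride 16).
    ``input_size`` is the square network input in pixels; the heatmap
    resolution is ``input_size / stride``.  Pretrained weights are not
    supported in this implementation and are rejected explicitly.
    """

    family: str = "tiny"
    input_size: int = 96
    heatmap_channels: int = N_LEVELS * N_CORNERS
    pretrained: bool = False
    freeze_until: Optional[str] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown backbone family {self.family!r}; "
                             f"choose from {sorted(_FAMILIES)}")
        if self.pretrained:
            raise ValueError("pretrained backbones are not available in this "
                             "implementation; train from random initialization")
        if self.input_size % self.stride:
            raise ValueError(f"input_size must be a multiple of {self.stride}")

    @property
    def stages(self) -> tuple:
        return _FAMILIES[self.family]

    @property
    def channels(self) -> tuple:
        return tuple(c for c, _ in _FAMILIES[self.family])

    @property
    def stride(self) -> int:
        out = 1
        for _, s in _FAMILIES[self.family]:
            out *= s
        return out

    @property
    def heatmap_size(self) -> int:
        return self.input_size // self.stride


@dataclass
class TrainSchedule:
    """Optimization schedule: Adam, plateau LR decay, best-val checkpoint.

    The learning rate is multiplied by ``plateau_factor`` when the
    validation loss has not improved for ``plateau_patience`` epochs in a
    row; the returned checkpoint holds the parameters of the epoch with
    the lowest validation loss.
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 200
    plateau_factor: float = 0.1
    plateau_patience: int = 10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


def default_schedule(stage: str) -> TrainSchedule:
    """Published hyperparameters per stage: presence/refine lr 1e-4 batch 16;
    global corner localization lr 1e-3 batch 8."""
    if stage in ("presence", "refine"):
        return TrainSchedule(learning_rate=1e-4, batch_size=16)
    if stage == "global":
        return TrainSchedule(learning_rate=1e-3, batch_size=8)
    raise ValueError(f"unknown stage {stage!r}")


def _build_features(cfg: BackboneConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: list = [nn.CoordChannels()]
    c_in = 3  # gray + 2 coordinate channels
    for c_out, stride in cfg.stages:
        layers += [nn.Conv2d(c_in, c_out, k=3, stride=stride, rng=rng), nn.ReLU()]
        c_in = c_out
    return nn.Sequential(*layers)


class PresenceNet:
    """24-way multi-label vertebra presence classifier (sigmoid outputs)."""

    kind = "presence"

    def __init__(self, cfg: BackboneConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.features = _build_features(cfg, rng)
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(cfg.channels[-1], N_LEVELS, rng=rng)

    def params(self) -> list:
        return self.features.params() + self.fc.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        """(N, 1, H, W) -> (N, 24) logits."""
        return self.fc.forward(self.pool.forward(self.features.forward(x)))

    def backward(self, dlogits: np.ndarray) -> None:
        self.features.backward(self.pool.backward(self.fc.backward(dlogits)))

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.sigmoid(self.forward(x))


class CornerNet:
    """Heatmap + DSNT corner localizer.

    With ``heatmap_channels = 96`` this is the global step-I localizer
    (24 levels x 4 corners); with 4 channels it is the step-II
    single-vertebra refiner.  ``forward`` returns coordinates of shape
    (N, channels/4, 4, 2) in normalized [-1, 1] units.
    """

    kind = "corners"

    def __init__(self, cfg: BackboneConfig, rng: Optional[np.random.Generator] = None):
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.features = _build_features(cfg, rng)
        # coordinate channels again at heatmap resolution: the 1x1 head can
        # then shape spatial logits directly from position, which speeds up
        # convergence of the DSNT expectation considerably
        self.head_coords = nn.CoordChannels()
        self.head = nn.Sequential(
            nn.Conv2d(cfg.channels[-1] + 2, 48, k=1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(48, cfg.heatmap_channels, k=1, rng=rng),
        )
        self._probs: Optional[np.ndarray] = None

    def params(self) -> list:
        return self.features.params() + self.head.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        logits = self.head.forward(self.head_coords.forward(self.features.forward(x)))
        self._probs = dsnt.spatial_softmax(logits)
        pred = dsnt.expect_batch(self._probs)  # (N, K, 2)
        n, k, _ = pred.shape
        return pred.reshape(n, k // N_CORNERS, N_CORNERS, 2)

    def backward(self, dpred: np.ndarray) -> None:
        n = dpred.shape[0]
        dflat = dpred.reshape(n, -1, 2)
        dlogits = dsnt.dsnt_backward(self._probs, dflat)
        self.features.backward(self.head_coords.backward(self.head.backward(dlogits)))

    @property
    def heatmaps(self) -> Optional[np.ndarray]:
        """Normalized heatmaps of the last forward pass (N, K, h, w)."""
        return self._probs


@dataclass
class Detection:
    """One detected vertebra with corners in original-image pixels."""

    level: VertebraLevel
    presence_prob: float
    corners: CornerSet
    provenance: str = "refined"  # or "step-I-only"
    crop_transform: Optional[CropTransform] = None
    corners_step1: Optional[CornerSet] = None  # pre-refinement audit record


@dataclass
class Checkpoint:
    """Serializable snapshot of a trained network plus its history."""

    kind: str
    config: BackboneConfig
    values: list
    history: list = field(default_factory=list)
    seed: int = 0

    def build(self):
        net_cls = PresenceNet if self.kind == "presence" else CornerNet
        net = net_cls(self.config, np.random.default_rng(self.seed))
        for p, v in zip(net.params(), self.values):
            p.value[...] = v
        return net

    def save(self, path) -> None:
        meta = {"kind": self.kind, "config": asdict(self.config),
                "history": self.history, "seed": self.seed}
        arrays = {f"p{i}": v for i, v in enumerate(self.values)}
        np.savez(Path(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(Path(path), allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            values = [data[f"p{i}"] for i in range(len(data.files) - 1)]
        return cls(kind=meta["kind"], config=BackboneConfig(**meta["config"]),
                   values=values, history=meta["history"], seed=meta["seed"])


# ---------------------------------------------------------------------------
# sample preparation
# ---------------------------------------------------------------------------

def _full_box(image: np.ndarray) -> BoundingBox:
    h, w = image.shape
    return BoundingBox(0.0, 0.0, float(w), float(h))


def _standardize(arr: np.ndarray) -> np.ndarray:
    """Per-image zero-mean/unit-variance network input.

    Radiograph brightness varies wildly (exposure, collimation,
    washed-out images); standardizing each input removes that nuisance
    scale so the small backbones need not learn it."""
    return (arr - arr.mean()) / (arr.std() + 1e-6)


def _resize_to_input(img: AnnotatedImage, size: int):
    arr, tf = crop_resize(img.pixels, _full_box(img.pixels), (size, size))
    return arr, tf


def _step1_sample(img: AnnotatedImage, input_size: int):
    """Resized input plus presence vector, normalized corner targets, mask."""
    arr, tf = _resize_to_input(img, input_size)
    arr = _standardize(arr)
    presence = presence_from_landmarks(img.landmarks).astype(float)
    targets = np.zeros((N_LEVELS, N_CORNERS, 2))
    mask = np.zeros((N_LEVELS, N_CORNERS), dtype=bool)
    for lvl, cs in img.landmarks.items():
        o = VertebraLevel(lvl).ordinal
        pts = tf.forward(np.where(cs.valid_mask[:, None], cs.points, 0.0))
        targets[o] = dsnt.normalize_pixel(pts, (input_size, input_size))
        mask[o] = cs.valid_mask
    return arr[None], presence, targets, mask


def _augment_step1(img: AnnotatedImage, aug: AugmentConfig,
                   rng: np.random.Generator, caudal: bool) -> AnnotatedImage:
    out = img
    if caudal and aug.caudal_crop_prob > 0 and rng.random() < aug.caudal_crop_prob:
        out = random_caudal_crop(out, aug, rng)
    out = random_rotate_flip(out, aug, rng)
    if aug.elastic_alpha > 0 or aug.noise_sd > 0:
        out = elastic_and_noise(out, aug, rng)
    return out


def _crop_box(points: np.ndarray, extension: float, image_size,
              rng: Optional[np.random.Generator] = None,
              jitter: float = 0.0) -> BoundingBox:
    """Single-vertebra crop box: tight box, minimum-extent fix, 70% growth.

    S1 carries only its upper endplate, whose tight box can be nearly
    flat; each axis span is therefore floored at 40% of the other
    (grown mostly caudally for the y axis, where the sacral body
    continues).  Optional jitter shifts/scales the box to emulate the
    noise of step-I localization when building refiner training crops.
    """
    pts = np.asarray(points, float).reshape(-1, 2)
    if pts.shape[0] < 2:
        raise GeometryError("need at least 2 points for a crop box")
    x_min, y_min = pts.min(axis=0)
    x_max, y_max = pts.max(axis=0)
    span_x, span_y = x_max - x_min, y_max - y_min
    if span_x <= 0 and span_y <= 0:
        raise GeometryError("crop points are coincident")
    if span_y < 0.4 * span_x:
        deficit = 0.4 * span_x - span_y
        y_max += 0.7 * deficit
        y_min -= 0.3 * deficit
        span_y = y_max - y_min
    if span_x < 0.4 * span_y:
        deficit = 0.4 * span_y - span_x
        x_min -= 0.5 * deficit
        x_max += 0.5 * deficit
        span_x = x_max - x_min
    if jitter > 0 and rng is not None:
        x_min += rng.uniform(-jitter, jitter) * span_x
        x_max += rng.uniform(-jitter, jitter) * span_x
        y_min += rng.uniform(-jitter, jitter) * span_y
        y_max += rng.uniform(-jitter, jitter) * span_y
        span_x, span_y = x_max - x_min, y_max - y_min
    mx, my = 0.5 * extension * span_x, 0.5 * extension * span_y
    box = BoundingBox(x_min - mx, y_min - my, x_max + mx, y_max + my).clipped(image_size)
    if box.width < 4 or box.height < 4:
        raise GeometryError("crop box too small")
    return box


def build_refiner_crops(records: Sequence[GroundTruthRecord], crop_size: int,
                        extension: float = 0.7, jitter: float = 0.12,
                        rng: Optional[np.random.Generator] = None,
                        max_crops: Optional[int] = None):
    """Single-vertebra training crops from ground-truth corners.

    Returns ``(x, targets, masks)`` with x of shape (M, 1, s, s), targets
    (M, 1, 4, 2) in crop-frame normalized coordinates, masks (M, 1, 4).
    """
    rng = rng or np.random.default_rng(0)
    xs, ts, ms = [], [], []
    for rec in records:
        img = rec.image
        for lvl, cs in img.landmarks.items():
            try:
                box = _crop_box(cs.valid_points, extension, img.size, rng, jitter)
                crop, tf = crop_resize(img.pixels, box, (crop_size, crop_size))
            except GeometryError:
                continue
            pts = tf.forward(np.where(cs.valid_mask[:, None], cs.points, 0.0))
            t = dsnt.normalize_pixel(pts, (crop_size, crop_size))
            xs.append(_standardize(crop)[None])
            ts.append(t[None])
            ms.append(cs.valid_mask[None].copy())
    x = np.stack(xs)
    t = np.stack(ts)
    m = np.stack(ms)
    if max_crops is not None and x.shape[0] > max_crops:
        idx = rng.permutation(x.shape[0])[:max_crops]
        x, t, m = x[idx], t[idx], m[idx]
    return x, t, m


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

def _train_loop(net, schedule: TrainSchedule, n_train: int,
                batch_fn, val_fn, rng: np.random.Generator) -> Checkpoint:
    """Generic epoch loop: Adam, plateau LR decay, best-validation snapshot."""
    opt = nn.Adam(net.params(), lr=schedule.learning_rate)
    best_val = np.inf
    best_values = [p.value.copy() for p in net.params()]
    stall = 0
    history = []
    for epoch in range(schedule.max_epochs):
        order = rng.permutation(n_train)
        train_losses = []
        for s in range(0, n_train, schedule.batch_size):
            idx = order[s:s + schedule.batch_size]
            opt.zero_grad()
            loss = batch_fn(idx, rng)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch}")
            train_losses.append(loss)
            opt.step()
        val_loss = val_fn()
        history.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                        "val_loss": float(val_loss), "lr": opt.lr})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_values = [p.value.copy() for p in net.params()]
            stall = 0
        else:
            stall += 1
            if stall >= schedule.plateau_patience:
                opt.lr *= schedule.plateau_factor
                stall = 0
    return Checkpoint(kind=net.kind, config=net.cfg, values=best_values,
                      history=history)


def train_presence(train_records: Sequence[GroundTruthRecord],
                   val_records: Sequence[GroundTruthRecord],
                   cfg: BackboneConfig,
                   schedule: Optional[TrainSchedule] = None,
                   augment: Optional[AugmentConfig] = None,
                   seed: int = 0) -> Checkpoint:
    """Train the 24-way presence classifier with binary cross-entropy."""
    if not train_records:
        raise ValueError("empty training set")
    schedule = schedule or default_schedule("presence")
    rng = np.random.default_rng(seed)
    net = PresenceNet(cfg, np.random.default_rng(seed))
    size = cfg.input_size

    val = [_step1_sample(r.image, size) for r in val_records]
    vx = np.stack([v[0] for v in val])
    vt = np.stack([v[1] for v in val])

    def batch_fn(idx, brng):
        xs, ts = [], []
        for i in idx:
            img = train_records[i].image
            if augment is not None:
                img = _augment_step1(img, augment, brng, caudal=True)
            x, presence, _, _ = _step1_sample(img, size)
            xs.append(x)
            ts.append(presence)
        z = net.forward(np.stack(xs))
        loss, dz = nn.bce_with_logits(z, np.stack(ts))
        net.backward(dz)
        return loss

    def val_fn():
        z = net.forward(vx)
        loss, _ = nn.bce_with_logits(z, vt)
        return loss

    ckpt = _train_loop(net, schedule, len(train_records), batch_fn, val_fn, rng)
    ckpt.seed = seed
    return ckpt


def train_corners_global(train_records: Sequence[GroundTruthRecord],
                         val_records: Sequence[GroundTruthRecord],
                         cfg: BackboneConfig,
                         schedule: Optional[TrainSchedule] = None,
                         augment: Optional[AugmentConfig] = None,
                         seed: int = 0) -> Checkpoint:
    """Train the global 24 x 4 x 2 DSNT corner localizer.

    Absent levels and invalid corners are masked out of the Euclidean
    coordinate loss rather than given fabricated targets.
    """
    if not train_records:
        raise ValueError("empty training set")
    schedule = schedule or default_schedule("global")
    rng = np.random.default_rng(seed)
    net = CornerNet(cfg, np.random.default_rng(seed))
    size = cfg.input_size

    val = [_step1_sample(r.image, size) for r in val_records]
    vx = np.stack([v[0] for v in val])
    vt = np.stack([v[2] for v in val])
    vm = np.stack([v[3] for v in val])

    def batch_fn(idx, brng):
        xs, ts, ms = [], [], []
        for i in idx:
            img = train_records[i].image
            if augment is not None:
                img = _augment_step1(img, augment, brng, caudal=True)
            x, _, targets, mask = _step1_sample(img, size)
            xs.append(x)
            ts.append(targets)
            ms.append(mask)
        t = np.stack(ts)
        m = np.stack(ms)
        pred = net.forward(np.stack(xs))
        loss = dsnt.coord_loss(pred, t, m)
        net.backward(dsnt.coord_loss_grad(pred, t, m))
        return loss

    def val_fn():
        pred = net.forward(vx)
        return dsnt.coord_loss(pred, vt, vm)

    ckpt = _train_loop(net, schedule, len(train_records), batch_fn, val_fn, rng)
    ckpt.seed = seed
    return ckpt


def train_refiner(train_records: Sequence[GroundTruthRecord],
                  val_records: Sequence[GroundTruthRecord],
                  cfg: BackboneConfig,
                  schedule: Optional[TrainSchedule] = None,
                  extension: float = 0.7,
                  crop_jitter: float = 0.12,
                  max_crops: Optional[int] = None,
                  seed: int = 0) -> Checkpoint:
    """Train the single-vertebra 1 x 4 x 2 refiner on extended-box crops."""
    if not train_records:
        raise ValueError("empty training set")
    if cfg.heatmap_channels != N_CORNERS:
        cfg = BackboneConfig(family=cfg.family, input_size=cfg.input_size,
                             heatmap_channels=N_CORNERS)
    schedule = schedule or default_schedule("refine")
    rng = np.random.default_rng(seed)
    net = CornerNet(cfg, np.random.default_rng(seed))

    tx, tt, tm = build_refiner_crops(train_records, cfg.input_size, extension,
                                     crop_jitter, rng, max_crops)
    vx, vt, vm = build_refiner_crops(val_records, cfg.input_size, extension,
                                     0.0, rng)

    def batch_fn(idx, brng):
        pred = net.forward(tx[idx])
        loss = dsnt.coord_loss(pred, tt[idx], tm[idx])
        net.backward(dsnt.coord_loss_grad(pred, tt[idx], tm[idx]))
        return loss

    def val_fn():
        losses = []
        for s in range(0, vx.shape[0], 64):
            pred = net.forward(vx[s:s + 64])
            losses.append(dsnt.coord_loss(pred, vt[s:s + 64], vm[s:s + 64]))
        return float(np.mean(losses))

    ckpt = _train_loop(net, schedule, tx.shape[0], batch_fn, val_fn, rng)
    ckpt.seed = seed
    return ckpt


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def _as_net(obj):
    return obj.build() if isinstance(obj, Checkpoint) else obj


def infer(image, presence_model, global_model, refiner_model,
          threshold: float = 0.5, extension: float = 0.7) -> list:
    """Run the full two-step pipeline on one radiograph.

    Returns one :class:`Detection` per level whose presence probability
    reaches ``threshold``; corners are refined by step II when the crop
    succeeds, otherwise the step-I corners are kept (provenance
    "step-I-only").  An empty list is a valid output.
    """
    pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image, float)
    presence_net = _as_net(presence_model)
    global_net = _as_net(global_model)
    refiner_net = _as_net(refiner_model)

    size1 = presence_net.cfg.input_size
    x1, tf1 = crop_resize(pixels, _full_box(pixels), (size1, size1))
    probs = presence_net.predict_proba(_standardize(x1)[None, None])[0]

    size_g = global_net.cfg.input_size
    if size_g == size1:
        xg, tfg = x1, tf1
    else:
        xg, tfg = crop_resize(pixels, _full_box(pixels), (size_g, size_g))
    norm = global_net.forward(_standardize(xg)[None, None])[0]   # (24, 4, 2)
    px = dsnt.denormalize(norm, (size_g, size_g))
    orig = tfg.inverse(px)                            # (24, 4, 2) original frame

    h, w = pixels.shape
    size_r = refiner_net.cfg.input_size
    detections = []
    for o in np.flatnonzero(probs >= threshold):
        lvl = VertebraLevel(int(o))
        valid = np.array([True, True, lvl != VertebraLevel.S1, lvl != VertebraLevel.S1])
        step1_pts = orig[o]
        det_pts = np.where(valid[:, None], step1_pts, np.nan)
        provenance, tf2 = "step-I-only", None
        try:
            box = _crop_box(step1_pts[valid], extension, (w, h))
            crop, tf2 = crop_resize(pixels, box, (size_r, size_r))
            rnorm = refiner_net.forward(_standardize(crop)[None, None])[0, 0]  # (4, 2)
            rpx = dsnt.denormalize(rnorm, (size_r, size_r))
            det_pts = np.where(valid[:, None], tf2.inverse(rpx), np.nan)
            provenance = "refined"
        except GeometryError:
            tf2 = None
        det_pts = np.clip(det_pts, 0.0, [w - 1.0, h - 1.0])
        s1_pts = np.clip(np.where(valid[:, None], step1_pts, np.nan),
                         0.0, [w - 1.0, h - 1.0])
        detections.append(Detection(
            level=lvl, presence_prob=float(probs[o]),
            corners=CornerSet(det_pts, valid),
            provenance=provenance, crop_transform=tf2,
            corners_step1=CornerSet(s1_pts, valid)))
    return detections


def detections_to_landmarks(detections: Sequence[Detection]) -> dict:
    """Landmark map ``{level: CornerSet}`` from a detection list."""
    return {d.level: d.corners for d in detections}
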