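"""Synthetic sagittal spine radiograph generator with exact ground truth.

Renders vertebral bodies as bright, slightly irregular convex
quadrilaterals along a smooth sagittal curve whose endplate tilts
realize sampled target angles (L1-L5 lordosis, L1-S1 lordosis, sacral
slope), then adds radiograph-like nuisances: intensity noise, black
collimation borders, global brightness extremes, and optional bright
rod/screw-like instrumentation strokes.

The angle targets are sampled from truncated normals whose means and
supports match the descriptive statistics of a large clinical lumbar
radiograph population (means 36.3 / 49.9 / 35.8 degrees; supports
[0.1, 86.8] / [0.1, 89.9] / [0, 89.4] for L1-L5 / L1-S1 / SS).  Field of
view varies by sampling the most cranial rendered level (T9..L1, with
lumbar-heavy census weights) and image resolution varies by a per-image
canvas scale factor.  Every corner is stored exactly where it was
rendered, so recomputing the angles from the stored landmarks recovers
the sampled targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import truncnorm
from skimage.draw import polygon as _draw_polygon
from skimage.draw import disk as _draw_disk

from .annotations import (
    AnnotatedImage,
    CornerSet,
    VertebraLevel,
    write_annotations,
    write_image,
)
from .geometry import AngleReport, angles_from_corners

__all__ = ["SpineSimConfig", "GroundTruthRecord", "LayoutError",
           "simulate_image", "simulate_dataset"]


class LayoutError(RuntimeError):
    """The requested levels cannot be fit into the canvas."""


# census weights for the most cranial visible level (lumbar-heavy,
# thoracic levels increasingly rare toward T9)
_CRANIAL_CENSUS = {
    VertebraLevel.T9: 0.08,
    VertebraLevel.T10: 0.26,
    VertebraLevel.T11: 0.37,
    VertebraLevel.T12: 0.26,
    VertebraLevel.L1: 0.03,
}


@dataclass
class SpineSimConfig:
    """Simulator parameters.

    Angle fields give (mean, sd) of a truncated normal over the stated
    support.  ``vertebra_base_size`` is the lumbar vertebral-body width
    in pixels at the base canvas size; more cranial bodies shrink by
    ``size_gradient`` per level.  Artifact probabilities are per image.
    """

    image_height: int = 112
    image_width: int = 112
    levels_range: tuple = (VertebraLevel.T9, VertebraLevel.S1)
    lordosis_l1l5_mean: float = 36.3
    lordosis_l1l5_sd: float = 15.0
    lordosis_l1l5_support: tuple = (0.1, 86.8)
    l1s1_support: tuple = (0.1, 89.9)
    disc_wedge_mean: float = 13.6   # L5-S1 disc wedge: L1-S1 minus L1-L5
    disc_wedge_sd: float = 4.0
    sacral_slope_mean: float = 35.8
    sacral_slope_sd: float = 14.0
    sacral_slope_support: tuple = (0.0, 89.4)
    vertebra_base_size: float = 11.0
    size_gradient: float = 0.015
    noise_sd: float = 0.03
    black_border_prob: float = 0.30
    brightness_extreme_prob: float = 0.15
    instrumentation_prob: float = 0.10
    resolution_jitter: tuple = (0.85, 1.25)
    keep_clean: bool = False       # stash the artifact-free rendering for checks
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.black_border_prob, self.brightness_extreme_prob,
                  self.instrumentation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("artifact probabilities must lie in [0, 1]")
        for lo, hi in (self.lordosis_l1l5_support, self.l1s1_support,
                       self.sacral_slope_support, self.resolution_jitter):
            if not lo < hi:
                raise ValueError("ranges must be non-degenerate (lo < hi)")
        if self.image_height < 32 or self.image_width < 32:
            raise ValueError("canvas too small")
        lo, hi = self.levels_range
        if VertebraLevel(lo) >= VertebraLevel(hi):
            raise ValueError("levels_range must run cranial to caudal")


@dataclass
class GroundTruthRecord:
    """One simulated radiograph with its exact ground truth."""

    image: AnnotatedImage
    true_angles: AngleReport
    generator_params: dict = field(default_factory=dict)


def _trunc_sample(rng, mean, sd, lo, hi) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _unit_endplate(phi_deg: float) -> np.ndarray:
    """Endplate direction for tilt ``phi`` (degrees from horizontal)."""
    r = np.radians(phi_deg)
    return np.array([np.cos(r), np.sin(r)])


def _unit_cranial(phi_deg: float) -> np.ndarray:
    """Spine-axis direction (cranial) perpendicular to an endplate tilt."""
    r = np.radians(phi_deg)
    return np.array([np.sin(r), -np.cos(r)])


def _endplate_tilts(ss: float, l1s1: float, l1l5: float, rng) -> dict:
    """Tilt (degrees from horizontal) for every endplate from S1 up to C2.

    Anchored exactly at S1-upper (= ss), L1-upper (= ss - l1s1) and
    L5-lower (= L1-upper + l1l5); linear in between, gently drifting
    kyphotic above L1 with small jitter on non-anchor endplates.
    """
    phi_s1u = ss
    phi_l1u = ss - l1s1
    phi_l5l = phi_l1u + l1l5
    tilts: dict = {(VertebraLevel.S1, "u"): phi_s1u}
    # L5 lower .. L1 upper: 9 linear steps across the lumbar endplates
    lumbar = []
    for lvl in (VertebraLevel.L5, VertebraLevel.L4, VertebraLevel.L3,
                VertebraLevel.L2, VertebraLevel.L1):
        lumbar += [(lvl, "l"), (lvl, "u")]
    for j, key in enumerate(lumbar):
        phi = phi_l5l + (phi_l1u - phi_l5l) * j / (len(lumbar) - 1)
        if key not in ((VertebraLevel.L5, "l"), (VertebraLevel.L1, "u")):
            phi += rng.normal(0.0, 0.8)
        tilts[key] = phi
    # thoracic and cervical: drift toward mild kyphosis
    phi = phi_l1u
    for o in range(VertebraLevel.T12.ordinal, VertebraLevel.C2.ordinal - 1, -1):
        lvl = VertebraLevel(o)
        for which in ("l", "u"):
            phi -= 1.0 + rng.normal(0.0, 0.4)
            tilts[(lvl, which)] = float(np.clip(phi, -45.0, 89.0))
    return tilts


def _sample_most_cranial(config: SpineSimConfig, rng) -> VertebraLevel:
    lo = VertebraLevel(config.levels_range[0])
    allowed = [(lvl, w) for lvl, w in _CRANIAL_CENSUS.items() if lvl >= lo]
    if not allowed:
        return lo
    levels, weights = zip(*allowed)
    p = np.array(weights) / sum(weights)
    return levels[int(rng.choice(len(levels), p=p))]


def simulate_image(config: SpineSimConfig, rng: np.random.Generator,
                   image_id: str = "sim") -> GroundTruthRecord:
    """Render one synthetic radiograph with exact corner ground truth."""
    u = float(rng.uniform(*config.resolution_jitter))
    H = int(round(config.image_height * u))
    W = int(round(config.image_width * u))

    ss = _trunc_sample(rng, config.sacral_slope_mean, config.sacral_slope_sd,
                       *config.sacral_slope_support)
    l1l5 = _trunc_sample(rng, config.lordosis_l1l5_mean, config.lordosis_l1l5_sd,
                         *config.lordosis_l1l5_support)
    wedge = rng.normal(config.disc_wedge_mean, config.disc_wedge_sd)
    l1s1 = float(np.clip(l1l5 + wedge, *config.l1s1_support))
    tilts = _endplate_tilts(ss, l1s1, l1l5, rng)

    most_cranial = _sample_most_cranial(config, rng)
    most_caudal = VertebraLevel(config.levels_range[1])
    levels = [VertebraLevel(o) for o in
              range(most_cranial.ordinal, most_caudal.ordinal + 1)]

    base = config.vertebra_base_size * u
    anchor = np.array([0.55 * W, 0.86 * H]) + rng.normal(0, [0.02 * W, 0.015 * H])

    landmarks: dict = {}
    render_polys: list = []  # (polygon points, intensity)

    def body_size(lvl: VertebraLevel) -> tuple:
        shrink = 1.0 - config.size_gradient * (VertebraLevel.S1.ordinal - lvl.ordinal)
        w = base * max(shrink, 0.5)
        return w, 0.62 * w

    # --- sacrum (S1): only the upper endplate is annotated -----------------
    if most_caudal == VertebraLevel.S1:
        w_s1 = 1.15 * base
        e = _unit_endplate(tilts[(VertebraLevel.S1, "u")])
        a = _unit_cranial(tilts[(VertebraLevel.S1, "u")])
        ua = anchor + 0.5 * w_s1 * e
        up = anchor - 0.5 * w_s1 * e
        h_s1 = 1.5 * 0.62 * w_s1
        la = ua - h_s1 * a - 0.45 * w_s1 * e
        lp = up - h_s1 * a - 0.55 * w_s1 * e
        render_polys.append((np.array([ua, up, lp, la]), float(rng.uniform(0.55, 0.80))))
        pts = np.full((4, 2), np.nan)
        pts[0], pts[1] = ua, up
        landmarks[VertebraLevel.S1] = (pts, np.array([True, True, False, False]))
        prev_center = anchor
        prev_tilt = tilts[(VertebraLevel.S1, "u")]
        bodies = [lvl for lvl in levels if lvl != VertebraLevel.S1]
    else:
        prev_center = anchor
        prev_tilt = tilts[(most_caudal, "l")]
        bodies = levels

    # --- vertebral bodies, caudal to cranial -------------------------------
    for lvl in reversed(bodies):
        w_k, h_k = body_size(lvl)
        gap = 0.32 * h_k * float(rng.uniform(0.85, 1.15))
        phi_l, phi_u = tilts[(lvl, "l")], tilts[(lvl, "u")]
        lower_center = prev_center + gap * _unit_cranial(0.5 * (prev_tilt + phi_l))
        upper_center = lower_center + h_k * _unit_cranial(0.5 * (phi_l + phi_u))
        e_l, e_u = _unit_endplate(phi_l), _unit_endplate(phi_u)
        # per-corner slide along the endplate direction keeps line angles exact
        s = rng.uniform(-0.35, 0.35, size=4)
        ua = upper_center + (0.5 * w_k + s[0]) * e_u
        upo = upper_center - (0.5 * w_k + s[1]) * e_u
        la = lower_center + (0.5 * w_k + s[2]) * e_l
        lp = lower_center - (0.5 * w_k + s[3]) * e_l
        quad = np.array([ua, upo, lp, la])
        render_polys.append((quad, float(rng.uniform(0.55, 0.80))))
        landmarks[lvl] = (np.array([ua, upo, la, lp]), np.ones(4, bool))
        prev_center = upper_center
        prev_tilt = phi_u

    # --- fit to canvas (uniform scale + shift preserves all angles) --------
    all_pts = np.vstack([p for p, _ in render_polys])
    margin = 3.0
    ext = all_pts.max(axis=0) - all_pts.min(axis=0)
    s_fit = min(1.0, (W - 2 * margin) / ext[0], (H - 2 * margin) / ext[1])
    if s_fit < 0.35:
        raise LayoutError(
            f"cannot fit levels {most_cranial.name}..{most_caudal.name} "
            f"in a {W}x{H} canvas at base size {config.vertebra_base_size}")

    def _fit(p: np.ndarray) -> np.ndarray:
        return anchor + s_fit * (p - anchor)

    render_polys = [(_fit(p), i) for p, i in render_polys]
    all_pts = np.vstack([p for p, _ in render_polys])
    lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
    shift = np.maximum(margin - lo, 0.0) - np.maximum(hi - (np.array([W, H]) - margin), 0.0)
    render_polys = [(p + shift, i) for p, i in render_polys]
    fitted_landmarks = {}
    for lvl, (pts, mask) in landmarks.items():
        fpts = np.where(mask[:, None], _fit(pts) + shift, np.nan)
        fitted_landmarks[lvl] = CornerSet(fpts, mask)

    # --- render -------------------------------------------------------------
    yy = np.linspace(0.0, 1.0, H)[:, None]
    img = 0.10 + 0.08 * yy + 0.05 * gaussian_filter(rng.standard_normal((H, W)), 12.0)
    img = np.clip(img, 0.0, None) * np.ones((H, W))
    for quad, inten in render_polys:
        rr, cc = _draw_polygon(quad[:, 1], quad[:, 0], shape=(H, W))
        img[rr, cc] = np.maximum(img[rr, cc], inten)
    img = gaussian_filter(img, 0.7)
    clean = img.copy() if config.keep_clean else None

    params = {
        "ss": ss, "l1l5": l1l5, "l1s1": l1s1,
        "most_cranial": most_cranial.name, "most_caudal": most_caudal.name,
        "canvas": (W, H), "fit_scale": s_fit, "resolution_factor": u,
        "instrumented": False, "black_border": False, "brightness_extreme": False,
    }

    lmk_pts = np.vstack([cs.valid_points for cs in fitted_landmarks.values()])

    if rng.random() < config.instrumentation_prob and len(bodies) >= 4:
        params["instrumented"] = True
        post = [fitted_landmarks[lvl].points[1] for lvl in
                (bodies[-1], bodies[max(0, len(bodies) - 5)])]
        p0, p1 = np.asarray(post[1]), np.asarray(post[0])
        off = np.array([-0.45 * base * s_fit, 0.0])
        d = p1 - p0
        nrm = np.array([-d[1], d[0]])
        nrm = nrm / (np.hypot(*nrm) + 1e-9) * 1.1
        strip = np.array([p0 + off + nrm, p1 + off + nrm, p1 + off - nrm, p0 + off - nrm])
        rr, cc = _draw_polygon(strip[:, 1], strip[:, 0], shape=(H, W))
        img[rr, cc] = 0.95
        for c in (p0 + off, 0.5 * (p0 + p1) + off, p1 + off):
            rr, cc = _draw_disk((c[1], c[0]), 1.6, shape=(H, W))
            img[rr, cc] = 0.97

    if rng.random() < config.black_border_prob:
        params["black_border"] = True
        x_lo, y_lo = lmk_pts.min(axis=0)
        x_hi, y_hi = lmk_pts.max(axis=0)
        if rng.random() < 0.8:
            bw = int(min(rng.uniform(0.04, 0.16) * W, max(x_lo - 3, 0)))
            img[:, :bw] = 0.02
        if rng.random() < 0.8:
            bw = int(min(rng.uniform(0.04, 0.16) * W, max(W - x_hi - 3, 0)))
            if bw > 0:
                img[:, W - bw:] = 0.02
        if rng.random() < 0.4:
            bh = int(min(rng.uniform(0.03, 0.10) * H, max(H - y_hi - 3, 0)))
            if bh > 0:
                img[H - bh:, :] = 0.02

    if rng.random() < config.brightness_extreme_prob:
        params["brightness_extreme"] = True
        if rng.random() < 0.5:
            img = img * rng.uniform(0.45, 0.65)
        else:
            img = img * 0.5 + rng.uniform(0.35, 0.45)

    if config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    if clean is not None:
        params["clean_pixels"] = clean

    image = AnnotatedImage(img, fitted_landmarks, image_id)
    return GroundTruthRecord(image=image,
                             true_angles=angles_from_corners(fitted_landmarks),
                             generator_params=params)


def simulate_dataset(config: SpineSimConfig, n_images: int, split_fractions,
                     out_dir=None, id_prefix: str = "sim") -> dict:
    """Simulate ``n_images`` radiographs and split into train/val/test.

    Per-image seeds derive deterministically from ``config.seed`` (one
    spawned child stream per image), so the dataset is reproducible and
    splits are disjoint by construction.  With ``out_dir`` set, PNG
    images, one annotation CSV per split and a manifest YAML are written.
    """
    fr = np.asarray(split_fractions, dtype=float)
    if fr.size != 3 or abs(fr.sum() - 1.0) > 1e-9 or (fr < 0).any():
        raise ValueError("split_fractions must be 3 non-negative values summing to 1")
    if n_images < 3:
        raise ValueError("need at least 3 images to build 3 splits")
    counts = np.floor(fr * n_images).astype(int)
    rem = fr * n_images - counts
    for _ in range(n_images - counts.sum()):
        i = int(np.argmax(rem))
        counts[i] += 1
        rem[i] = -1
    for i in range(3):  # every split non-empty
        if counts[i] == 0:
            counts[int(np.argmax(counts))] -= 1
            counts[i] += 1

    children = np.random.SeedSequence(config.seed).spawn(n_images)
    records = [
        simulate_image(config, np.random.default_rng(children[i]),
                       image_id=f"{id_prefix}_{i:05d}")
        for i in range(n_images)
    ]
    names = ("train", "val", "test")
    splits, start = {}, 0
    for name, c in zip(names, counts):
        splits[name] = records[start:start + int(c)]
        start += int(c)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for name in names:
            lmap = {}
            for rec in splits[name]:
                write_image(rec.image.pixels, out / "images" / f"{rec.image.image_id}.png")
                lmap[rec.image.image_id] = rec.image.landmarks
            write_annotations(lmap, out / f"{name}.csv")
        import yaml

        cfg = asdict(config)
        cfg["levels_range"] = [VertebraLevel(l).name for l in config.levels_range]
        manifest = {"config": cfg, "n_images": n_images,
                    "split_sizes": {n: int(c) for n, c in zip(names, counts)}}
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))
    return splits
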