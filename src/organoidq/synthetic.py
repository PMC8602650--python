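"""Synthetic brightfield organoid scenes with exact ground truth.

Generates z-stacks that look the way an EVOS2-style brightfield well does to
the segmentation pipeline: a light background with a mild illumination
gradient, organoids drawn as dark-rimmed objects with a brighter lumen,
debris as small dark specks, per-plane defocus blur growing with distance
from the focus plane, and Gaussian read-out noise.  The renderer makes no
claim of optical realism — its purpose is to exercise edge-based
segmentation, watershed splitting and morphology classification with exact
per-object ground truth (masks, classes, centers, areas).

Object shapes
-------------
* spheroid — an ellipse with axis ratio 1–1.3 (round, no lobes);
* budding  — a body ellipse plus 2–5 smaller lobes protruding from its rim,
  giving the convex pockets the classifier counts;
* junk     — small specks far below the organoid size scale.

Everything is drawn from one ``numpy.random.default_rng(seed)`` stream, so a
config fully determines the scene down to the noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .classification import ClassifierModel, classify, compute_features, extract_crop
from .config import PipelineParams
from .errors import InputError, PlacementError
from .io import ZStack
from .segmentation import (
    SegmentationResult,
    min_projection,
    object_center,
    segment_field,
)

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "generate_scene",
    "generate_labeled_crops",
    "run_recovery_benchmark",
    "match_objects",
]


@dataclass
class SceneConfig:
    """Parameters of one synthetic field.

    Geometry is in pixels at an EVOS2-like scale where a typical organoid
    spans 40–80 px.  ``overlap_fraction`` is the fraction of non-junk
    objects placed as overlapping pairs (each pair overlaps 10–40% of the
    smaller member's area); the rest are placed disjointly.
    """

    shape: tuple[int, int] = (512, 512)
    n_spheroid: int = 6
    n_budding: int = 5
    n_junk: int = 4
    radius_range: tuple[float, float] = (18.0, 36.0)
    axis_ratio_range: tuple[float, float] = (1.0, 1.3)
    lobe_count_range: tuple[int, int] = (2, 5)
    lobe_radius_frac: tuple[float, float] = (0.18, 0.26)
    junk_radius_range: tuple[float, float] = (5.0, 9.0)
    overlap_fraction: float = 0.0
    n_planes: int = 5
    focus_plane: int = 2
    per_object_focus: bool = True
    defocus_sigma_per_plane: float = 1.2
    noise_sd: float = 3.0
    illumination_amplitude: float = 10.0
    background: float = 205.0
    rim_intensity: float = 70.0
    lumen_intensity: float = 160.0
    junk_intensity: float = 95.0
    rim_width: int = 3
    placement_margin: int = 12
    min_gap_px: float = 10.0
    max_attempts: int = 2000
    pixel_size_um: Optional[float] = 3.0
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_spheroid, self.n_budding, self.n_junk) < 0:
            raise InputError("object counts must be >= 0")
        if not (0 < self.radius_range[0] <= self.radius_range[1]):
            raise InputError("radius range must be positive and ordered")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise InputError("overlap_fraction must be in [0, 1]")
        if self.n_planes < 1 or not (0 <= self.focus_plane < self.n_planes):
            raise InputError("need n_planes >= 1 and a valid focus_plane")


@dataclass
class GroundTruth:
    """Exact per-object truth for one generated scene.

    ``label_image`` assigns every object pixel to exactly one object; where
    a forced overlap makes two masks share pixels, the shared pixels belong
    to the object whose center is nearer.  ``masks`` keeps each object's
    full (possibly overlapping) support.
    """

    label_image: np.ndarray
    masks: dict[int, np.ndarray]
    classes: dict[int, str]
    centers: dict[int, tuple[int, int]]
    areas: dict[int, int]
    overlap_pairs: list[tuple[int, int]] = dc_field(default_factory=list)

    @property
    def object_ids(self) -> list[int]:
        return sorted(self.masks)

    def nonjunk_ids(self) -> list[int]:
        return [i for i in self.object_ids if self.classes[i] != "junk"]


# ---------------------------------------------------------------------------
# Shape rasterization
# ---------------------------------------------------------------------------

def _ellipse_mask(shape, center, a, b, theta) -> np.ndarray:
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _spheroid_mask(shape, center, radius, axis_ratio, theta) -> np.ndarray:
    # keep the mean radius equal to `radius` so area ~ pi r^2
    a = radius * math.sqrt(axis_ratio)
    b = radius / math.sqrt(axis_ratio)
    return _ellipse_mask(shape, center, a, b, theta)


def _budding_mask(shape, center, radius, n_lobes, lobe_frac, rng) -> np.ndarray:
    """Body ellipse plus lobes protruding from its rim."""
    theta = rng.uniform(0, math.pi)
    ratio = rng.uniform(1.0, 1.15)
    mask = _spheroid_mask(shape, center, radius, ratio, theta)
    phase = rng.uniform(0, 2 * math.pi)
    for k in range(n_lobes):
        ang = phase + 2 * math.pi * k / n_lobes + rng.uniform(-0.25, 0.25)
        lr = radius * rng.uniform(*lobe_frac)
        dist = radius + 0.55 * lr  # lobe center just outside the body rim
        lc = (center[0] + dist * math.sin(ang), center[1] + dist * math.cos(ang))
        mask |= _ellipse_mask(shape, lc, lr, lr, 0.0)
    return mask


def _paint_object(img: np.ndarray, kind: str, mask: np.ndarray, cfg: "SceneConfig") -> None:
    if kind == "junk":
        img[mask] = cfg.junk_intensity
    else:
        interior = ndi.binary_erosion(mask, iterations=cfg.rim_width)
        img[mask] = cfg.rim_intensity
        img[interior] = cfg.lumen_intensity


def _object_patch(kind: str, mask: np.ndarray, cfg: "SceneConfig", pad: int):
    """In-focus rendering of one object on constant background, cropped to
    its padded bounding box.  Returns (row slice, col slice, patch)."""
    rows, cols = np.nonzero(mask)
    r0 = max(0, rows.min() - pad)
    r1 = min(mask.shape[0], rows.max() + 1 + pad)
    c0 = max(0, cols.min() - pad)
    c1 = min(mask.shape[1], cols.max() + 1 + pad)
    sl = (slice(r0, r1), slice(c0, c1))
    patch = np.full((r1 - r0, c1 - c0), cfg.background, dtype=np.float64)
    _paint_object(patch, kind, mask[sl], cfg)
    return sl, patch


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------

def _sample_center(rng, shape, radius, margin):
    lo_r = radius + margin
    hi_r = shape[0] - radius - margin
    lo_c = radius + margin
    hi_c = shape[1] - radius - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError("object radius too large for the image")
    return (rng.uniform(lo_r, hi_r), rng.uniform(lo_c, hi_c))


def _far_enough(center, radius, placed, min_gap):
    return all(
        math.hypot(center[0] - c[0], center[1] - c[1]) > radius + r + min_gap
        for c, r in placed
    )


def _overlap_distance(r1, r2, target, rng):
    """Center distance giving the target overlap fraction for two discs.

    Overlap fraction is intersection area over the smaller disc's area;
    solved by bisection on the two-disc lens area (monotone in distance).
    """
    small = min(r1, r2)

    def lens(d):
        if d >= r1 + r2:
            return 0.0
        if d <= abs(r1 - r2):
            return math.pi * small**2
        t1 = r1**2 * math.acos((d**2 + r1**2 - r2**2) / (2 * d * r1))
        t2 = r2**2 * math.acos((d**2 + r2**2 - r1**2) / (2 * d * r2))
        t3 = 0.5 * math.sqrt(
            max(0.0, (-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2))
        )
        return t1 + t2 - t3

    target_area = target * math.pi * small**2
    lo, hi = abs(r1 - r2) + 1e-6, r1 + r2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if lens(mid) > target_area:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_scene(config: SceneConfig) -> tuple[ZStack, GroundTruth]:
    """Render one synthetic z-stack with exact ground truth.

    Fully determined by ``config`` (including ``config.seed``): calling
    twice with the same config yields bit-identical stacks and truth.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)

    # --- decide object inventory ------------------------------------------
    kinds = ["spheroid"] * cfg.n_spheroid + ["budding"] * cfg.n_budding
    radii = [rng.uniform(*cfg.radius_range) for _ in kinds]
    n_nonjunk = len(kinds)
    n_pairs = int(round(cfg.overlap_fraction * n_nonjunk / 2.0))
    pair_members: list[tuple[int, int]] = []
    if n_pairs > 0:
        # overlapping pairs are drawn spheroid-first: crowded cyst-like
        # objects are how near-round organoids actually touch in a well
        sph = [i for i, k in enumerate(kinds) if k == "spheroid"]
        bud = [i for i, k in enumerate(kinds) if k == "budding"]
        order = [int(i) for i in rng.permutation(sph)] + [int(i) for i in rng.permutation(bud)]
        for p in range(n_pairs):
            pair_members.append((order[2 * p], order[2 * p + 1]))

    placed: list[tuple[tuple[float, float], float]] = []  # (center, radius)
    centers: dict[int, tuple[float, float]] = {}
    paired = {i for pair in pair_members for i in pair}

    # --- place overlapping pairs ------------------------------------------
    for i, j in pair_members:
        ri, rj = radii[i], radii[j]
        target = rng.uniform(0.10, 0.40)
        d = _overlap_distance(ri, rj, target, rng)
        ok = False
        for _ in range(cfg.max_attempts):
            ci = _sample_center(rng, shape, ri + d, cfg.placement_margin)
            ang = rng.uniform(0, 2 * math.pi)
            cj = (ci[0] + d * math.sin(ang), ci[1] + d * math.cos(ang))
            if not (
                rj + cfg.placement_margin <= cj[0] < shape[0] - rj - cfg.placement_margin
                and rj + cfg.placement_margin <= cj[1] < shape[1] - rj - cfg.placement_margin
            ):
                continue
            if _far_enough(ci, ri, placed, cfg.min_gap_px) and _far_enough(cj, rj, placed, cfg.min_gap_px):
                ok = True
                break
        if not ok:
            raise PlacementError(
                "could not place an overlapping pair; reduce object counts"
            )
        centers[i], centers[j] = ci, cj
        placed.extend([(ci, ri), (cj, rj)])

    # --- place remaining non-junk objects disjointly ----------------------
    for i in range(n_nonjunk):
        if i in paired:
            continue
        r = radii[i]
        for _ in range(cfg.max_attempts):
            c = _sample_center(rng, shape, r * 1.35, cfg.placement_margin)
            if _far_enough(c, r * 1.35, placed, cfg.min_gap_px):
                centers[i] = c
                placed.append((c, r * 1.35))
                break
        else:
            raise PlacementError("could not place all objects; reduce counts")

    # --- junk specks -------------------------------------------------------
    junk_specs = []
    for _ in range(cfg.n_junk):
        r = rng.uniform(*cfg.junk_radius_range)
        for _ in range(cfg.max_attempts):
            c = _sample_center(rng, shape, r, cfg.placement_margin)
            if _far_enough(c, r, placed, cfg.min_gap_px):
                junk_specs.append((c, r))
                placed.append((c, r))
                break
        else:
            raise PlacementError("could not place junk specks; reduce counts")

    # --- rasterize ---------------------------------------------------------
    specs: dict[int, tuple[str, np.ndarray]] = {}
    oid = 1
    overlap_pairs: list[tuple[int, int]] = []
    index_to_oid: dict[int, int] = {}
    for i, kind in enumerate(kinds):
        c, r = centers[i], radii[i]
        if kind == "spheroid":
            ratio = rng.uniform(*cfg.axis_ratio_range)
            theta = rng.uniform(0, math.pi)
            mask = _spheroid_mask(shape, c, r, ratio, theta)
        else:
            n_lobes = int(rng.integers(cfg.lobe_count_range[0], cfg.lobe_count_range[1] + 1))
            mask = _budding_mask(shape, c, r, n_lobes, cfg.lobe_radius_frac, rng)
        specs[oid] = (kind, mask)
        index_to_oid[i] = oid
        oid += 1
    for c, r in junk_specs:
        specs[oid] = ("junk", _ellipse_mask(shape, c, r, r, 0.0))
        oid += 1
    overlap_pairs = [(index_to_oid[i], index_to_oid[j]) for i, j in pair_members]

    masks = {o: m for o, (_k, m) in specs.items()}
    # each object sits at its own focal depth (as in a real well), so its rim
    # is sharp in one plane and progressively blurred in the others
    if cfg.per_object_focus and cfg.n_planes > 1:
        focus_of = {o: int(rng.integers(0, cfg.n_planes)) for o in specs}
    else:
        focus_of = {o: cfg.focus_plane for o in specs}

    # --- ground-truth label image (overlaps -> nearer center) --------------
    label_image = np.zeros(shape, dtype=np.int32)
    dist_best = np.full(shape, np.inf)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for o, (kind, mask) in specs.items():
        cen = _mask_centroid(mask)
        d = (rr - cen[0]) ** 2 + (cc - cen[1]) ** 2
        take = mask & (d < dist_best)
        label_image[take] = o
        dist_best[take] = d[take]

    gt_centers = {o: object_center(m) for o, m in masks.items()}
    truth = GroundTruth(
        label_image=label_image,
        masks=masks,
        classes={o: kind for o, (kind, _) in specs.items()},
        centers=gt_centers,
        areas={o: int(m.sum()) for o, m in masks.items()},
        overlap_pairs=overlap_pairs,
    )

    # --- optics: defocus per plane, illumination gradient, noise -----------
    grad_dir = rng.uniform(0, 2 * math.pi)
    ramp = (
        (cc / max(1, shape[1] - 1) - 0.5) * math.cos(grad_dir)
        + (rr / max(1, shape[0] - 1) - 0.5) * math.sin(grad_dir)
    ) * cfg.illumination_amplitude
    max_sigma = cfg.defocus_sigma_per_plane * max(1, cfg.n_planes - 1)
    pad = int(math.ceil(3 * max_sigma)) + cfg.rim_width
    patches = {o: _object_patch(kind, masks[o], cfg, pad) for o, (kind, _m) in specs.items()}
    planes = []
    for z in range(cfg.n_planes):
        plane = np.full(shape, cfg.background, dtype=np.float64)
        for o in specs:
            sl, patch = patches[o]
            sigma = cfg.defocus_sigma_per_plane * abs(z - focus_of[o])
            blurred = ndi.gaussian_filter(patch, sigma) if sigma > 0 else patch
            np.minimum(plane[sl], blurred, out=plane[sl])
        plane = plane + ramp + rng.normal(0.0, cfg.noise_sd, shape)
        planes.append(np.clip(np.rint(plane), 0, 255).astype(np.uint8))

    stack = ZStack(
        planes=planes,
        pixel_size_um=cfg.pixel_size_um,
        field_id=f"synthetic-{cfg.seed}",
        condition="synthetic",
    )
    return stack, truth


def _mask_centroid(mask: np.ndarray) -> tuple[float, float]:
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


# ---------------------------------------------------------------------------
# Labeled crops for classifier training
# ---------------------------------------------------------------------------

def generate_labeled_crops(n_per_class: int, seed: int = 0, canvas: int = 160):
    """Render isolated objects and return (crops, labels, features).

    One object per small canvas, rendered with the same optics as full
    scenes (focus-plane appearance), cropped through the standard crop
    extractor.  Used to train and evaluate classifier backends without
    segmenting full fields.
    """
    from .classification import Crop  # local import to avoid cycle at import time

    rng = np.random.default_rng(seed)
    crops: list[Crop] = []
    labels: list[str] = []
    feats = []
    base = SceneConfig()
    shape = (canvas, canvas)
    for k in range(n_per_class * 3):
        kind = ("spheroid", "budding", "junk")[k % 3]
        sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
        center = (canvas / 2 + sub.uniform(-4, 4), canvas / 2 + sub.uniform(-4, 4))
        if kind == "spheroid":
            r = sub.uniform(18, 30)
            mask = _spheroid_mask(shape, center, r, sub.uniform(1.0, 1.3),
                                  sub.uniform(0, math.pi))
        elif kind == "budding":
            r = sub.uniform(18, 28)
            n_lobes = int(sub.integers(2, 6))
            mask = _budding_mask(shape, center, r, n_lobes,
                                 base.lobe_radius_frac, sub)
        else:
            r = sub.uniform(5, 9)
            mask = _ellipse_mask(shape, center, r, r, 0.0)
        img = np.full(shape, base.background)
        if kind == "junk":
            img[mask] = base.junk_intensity
        else:
            interior = ndi.binary_erosion(mask, iterations=base.rim_width)
            img[mask] = base.rim_intensity
            img[interior] = base.lumen_intensity
        img = img + sub.normal(0, base.noise_sd, shape)
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        crops.append(extract_crop(img, mask, (f"train-{seed}", k)))
        labels.append(kind)
        feats.append(compute_features(mask))
    return crops, labels, feats


# ---------------------------------------------------------------------------
# Recovery benchmark
# ---------------------------------------------------------------------------

def match_objects(
    seg: SegmentationResult, truth: GroundTruth
) -> dict[int, Optional[int]]:
    """Match ground-truth objects to predictions by center proximity.

    Greedy nearest-center matching: a truth object matches the closest
    predicted center within half its equivalent radius; each prediction is
    used at most once.  Unmatched predictions count as false positives.
    """
    pred_centers = {o.object_id: o.center for o in seg.objects}
    pairs = []
    for t in truth.object_ids:
        tc = truth.centers[t]
        r_eq = math.sqrt(truth.areas[t] / math.pi)
        for p, pc in pred_centers.items():
            d = math.hypot(tc[0] - pc[0], tc[1] - pc[1])
            if d <= 0.5 * r_eq:
                pairs.append((d, t, p))
    pairs.sort()
    matched: dict[int, Optional[int]] = {t: None for t in truth.object_ids}
    used: set[int] = set()
    for d, t, p in pairs:
        if matched[t] is None and p not in used:
            matched[t] = p
            used.add(p)
    return matched


def run_recovery_benchmark(
    config: SceneConfig,
    params: Optional[PipelineParams] = None,
    seeds: tuple[int, ...] = (1, 2, 3, 4, 5),
    model: Optional[ClassifierModel] = None,
) -> dict:
    """Segment and classify generated scenes; score against ground truth.

    Reports, pooled over ``seeds``: the fraction of non-junk truth objects
    recovered (count recovery), the mean absolute relative area error of
    matched non-junk objects, the number of false-positive predictions, the
    classification confusion matrix over matched objects, and — when the
    config forces overlaps — the fraction of overlapping pairs split into
    two distinct predicted objects.
    """
    import dataclasses as _dc

    params = params or PipelineParams()
    model = model or ClassifierModel()
    n_truth = n_matched = n_fp = 0
    area_errors: list[float] = []
    pairs_total = pairs_split = 0
    confusion: dict[tuple[str, str], int] = {}
    per_scene = []
    for s in seeds:
        cfg = _dc.replace(config, seed=int(s))
        stack, truth = generate_scene(cfg)
        seg = segment_field(stack, params.segmentation)
        proj = min_projection(stack, params.segmentation)
        from .classification import classify_objects

        classify_objects(seg, proj, model, stack.field_id, params.classification)
        matching = match_objects(seg, truth)
        nonjunk = truth.nonjunk_ids()
        matched_nonjunk = [t for t in nonjunk if matching[t] is not None]
        n_truth += len(nonjunk)
        n_matched += len(matched_nonjunk)
        used = {p for p in matching.values() if p is not None}
        fps = [
            o for o in seg.objects
            if o.object_id not in used and o.class_label != "junk"
        ]
        n_fp += len(fps)
        for t in matched_nonjunk:
            rec = seg.get(matching[t])
            area_errors.append(abs(rec.area_px - truth.areas[t]) / truth.areas[t])
            key = (truth.classes[t], rec.class_label)
            confusion[key] = confusion.get(key, 0) + 1
        for t in truth.object_ids:
            if truth.classes[t] == "junk" and matching[t] is not None:
                rec = seg.get(matching[t])
                key = ("junk", rec.class_label)
                confusion[key] = confusion.get(key, 0) + 1
        for a, b in truth.overlap_pairs:
            pairs_total += 1
            if (
                matching[a] is not None
                and matching[b] is not None
                and matching[a] != matching[b]
            ):
                pairs_split += 1
        per_scene.append({
            "seed": int(s),
            "n_truth_nonjunk": len(nonjunk),
            "n_matched_nonjunk": len(matched_nonjunk),
            "n_false_positive": len(fps),
        })
    return {
        "n_scenes": len(seeds),
        "n_truth_nonjunk": n_truth,
        "n_matched_nonjunk": n_matched,
        "count_recovery_pct": 100.0 * n_matched / n_truth if n_truth else float("nan"),
        "mean_abs_area_error_pct": 100.0 * float(np.mean(area_errors)) if area_errors else float("nan"),
        "n_false_positive_nonjunk": n_fp,
        "overlap_pairs_total": pairs_total,
        "overlap_pairs_split": pairs_split,
        "overlap_split_pct": 100.0 * pairs_split / pairs_total if pairs_total else float("nan"),
        "confusion": confusion,
        "per_scene": per_scene,
    }
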