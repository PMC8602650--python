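"""Morphology classification of segmented organoids.

Each object is cut out as a standardized 120x120 crop on a white background
and assigned one of three classes: *junk* (debris, bubbles, specks),
*budding* (organoid with protruding crypt-like lobes, the homeostatic
morphology) or *spheroid* (round cyst-like morphology).

The default backend is a deterministic shape-feature classifier: small or
ragged objects are junk; round objects without lobes are spheroids;
everything else is budding.  Probabilities come from sharp logistic scores
on the decisive feature margins, chained so that they always sum to 1.  Two
trainable backends share the same interface: multinomial logistic regression
on the shape features, and a small multilayer-perceptron neural network on
downsampled crop pixels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, transform

from .config import ClassificationParams
from .errors import InputError, StateError
from .segmentation import CLASS_NAMES, OrganoidRecord

__all__ = [
    "Crop",
    "ShapeFeatures",
    "ClassifierModel",
    "extract_crop",
    "compute_features",
    "classify",
    "train_classifier",
]

FEATURE_NAMES = (
    "area_px",
    "perimeter_px",
    "circularity",
    "solidity",
    "lobe_count",
    "eccentricity",
    "radial_variance",
)


@dataclass
class Crop:
    """A 120x120 8-bit cut-out of one object on a white background.

    Object pixels keep their (rescaled) intensity; every non-object pixel is
    white (255).  The object is isotropically rescaled so its longer side is
    116 px and centered, leaving at least a 2 px white margin.
    """

    image: np.ndarray
    mask: np.ndarray  # bool, object support inside the crop
    scale_factor: float  # original px per crop px
    provenance: tuple[str, int] = ("", 0)


@dataclass
class ShapeFeatures:
    """Scale-bearing and dimensionless shape descriptors of one mask.

    ``circularity`` is the isoperimetric quotient 4*pi*A/P^2 (1 for a perfect
    disc, lower for lobed shapes); ``solidity`` is area over convex-hull
    area; ``lobe_count`` counts significant convexity defects, i.e. concave
    pockets whose depth exceeds ``defect_depth_frac`` times the equivalent
    radius; ``radial_variance`` is the squared coefficient of variation of
    the centroid-to-boundary distance.
    """

    area_px: float
    perimeter_px: float
    circularity: float
    solidity: float
    lobe_count: int
    eccentricity: float
    radial_variance: float

    def vector(self) -> np.ndarray:
        return np.array(
            [
                self.area_px,
                self.perimeter_px,
                self.circularity,
                self.solidity,
                self.lobe_count,
                self.eccentricity,
                self.radial_variance,
            ],
            dtype=np.float64,
        )


def extract_crop(
    zstack_projection: np.ndarray,
    mask: np.ndarray,
    provenance: tuple[str, int] = ("", 0),
    params: Optional[ClassificationParams] = None,
) -> Crop:
    """Extract a standardized white-background crop of one object.

    The bounding box of ``mask`` is cut from the minimum-intensity
    projection, non-object pixels are set to white, and the cut-out is
    isotropically rescaled so the object's longer side is 116 px, centered
    on a 120x120 white canvas (leaving at least a 2 px white margin).
    """
    p = params or ClassificationParams()
    img = np.asarray(zstack_projection)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != img.shape:
        raise InputError(
            f"mask shape {mask.shape} does not match image shape {img.shape}"
        )
    if not mask.any():
        raise InputError("cannot crop an empty mask")
    rows, cols = np.nonzero(mask)
    r0, r1 = int(rows.min()), int(rows.max()) + 1
    c0, c1 = int(cols.min()), int(cols.max()) + 1
    sub = np.where(mask[r0:r1, c0:c1], img[r0:r1, c0:c1].astype(np.float64), 255.0)
    submask = mask[r0:r1, c0:c1]

    # the object's longer side maps to crop_object_side; the canvas border
    # supplies the white margin (everything off-object is white anyway)
    scale = p.crop_object_side / max(sub.shape)
    out_shape = (
        max(1, int(round(sub.shape[0] * scale))),
        max(1, int(round(sub.shape[1] * scale))),
    )
    resized = transform.resize(sub, out_shape, order=1, anti_aliasing=scale < 1,
                               preserve_range=True)
    rmask = transform.resize(submask.astype(np.float64), out_shape, order=1,
                             anti_aliasing=scale < 1, preserve_range=True) > 0.5
    resized = np.where(rmask, resized, 255.0)

    canvas = np.full((p.crop_size, p.crop_size), 255.0)
    cmask = np.zeros((p.crop_size, p.crop_size), dtype=bool)
    off_r = (p.crop_size - out_shape[0]) // 2
    off_c = (p.crop_size - out_shape[1]) // 2
    canvas[off_r:off_r + out_shape[0], off_c:off_c + out_shape[1]] = resized
    cmask[off_r:off_r + out_shape[0], off_c:off_c + out_shape[1]] = rmask
    return Crop(
        image=np.clip(np.rint(canvas), 0, 255).astype(np.uint8),
        mask=cmask,
        scale_factor=1.0 / scale,
        provenance=provenance,
    )


def _lobe_count(mask: np.ndarray, defect_depth_frac: float) -> int:
    """Count convexity defects deeper than a fraction of the equivalent radius.

    A defect is an 8-connected component of (convex hull minus mask); its
    depth is the largest distance from any of its pixels to the mask.
    """
    hull = morphology.convex_hull_image(mask)
    defects = hull & ~mask
    if not defects.any():
        return 0
    # distance from every pixel to the nearest object pixel
    dist_to_mask = ndi.distance_transform_edt(~mask)
    r_eq = math.sqrt(mask.sum() / math.pi)
    lab, n = ndi.label(defects, structure=np.ones((3, 3), dtype=int))
    count = 0
    for i in range(1, n + 1):
        depth = dist_to_mask[lab == i].max()
        if depth >= defect_depth_frac * r_eq:
            count += 1
    return count


def compute_features(
    mask: np.ndarray, params: Optional[ClassificationParams] = None
) -> ShapeFeatures:
    """Shape descriptors of one connected object mask."""
    p = params or ClassificationParams()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InputError("cannot compute features of an empty mask")
    lab = measure.label(mask, connectivity=2)
    props = measure.regionprops(lab)
    if len(props) > 1:
        props = [max(props, key=lambda r: r.area)]
    rp = props[0]
    area = float(rp.area)
    perimeter = float(max(rp.perimeter, 1.0))
    circularity = 4.0 * math.pi * area / perimeter**2
    solidity = float(rp.solidity)
    eccentricity = float(rp.eccentricity)

    contour_pts = measure.find_contours(np.pad(mask.astype(float), 1), 0.5)
    boundary = max(contour_pts, key=len) - 1.0
    centroid = np.array(rp.centroid)
    d = np.linalg.norm(boundary - centroid, axis=1)
    mean_d = d.mean() if d.size else 1.0
    radial_variance = float(d.var() / mean_d**2) if mean_d > 0 else 0.0

    return ShapeFeatures(
        area_px=area,
        perimeter_px=perimeter,
        circularity=min(circularity, 1.1),
        solidity=solidity,
        lobe_count=_lobe_count(mask, p.defect_depth_frac),
        eccentricity=eccentricity,
        radial_variance=radial_variance,
    )


# ---------------------------------------------------------------------------
# Classifier backends
# ---------------------------------------------------------------------------

@dataclass
class ClassifierModel:
    """Predicts a (junk, budding, spheroid) probability triple.

    ``backend`` is ``"features"`` (deterministic rules when unfitted, a
    multinomial logistic regression on shape features when trained) or
    ``"mlp"`` (a small neural network on 24x24 downsampled crop pixels;
    must be trained before use).
    """

    backend: str = "features"
    params: ClassificationParams = field(default_factory=ClassificationParams)
    estimator: object = None  # fitted sklearn pipeline, if trained
    seed: Optional[int] = None
    n_train: int = 0
    holdout_accuracy: Optional[float] = None

    @property
    def is_trained(self) -> bool:
        return self.estimator is not None


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def _rule_probabilities(f: ShapeFeatures, p: ClassificationParams) -> np.ndarray:
    """Chained logistic scores consistent with the classification rules.

    junk if area < junk_area or solidity < junk_solidity; otherwise spheroid
    if circularity >= spheroid_circularity and lobe_count <= spheroid_max_lobes,
    else budding.  Each decision uses a sharp logistic on its margin; the
    junk score gates the budding/spheroid split so the triple sums to 1.
    """
    z_area = _sigmoid((p.junk_area_px - f.area_px) / (0.02 * p.junk_area_px))
    z_sol = _sigmoid((p.junk_solidity - f.solidity) / 0.02)
    z_junk = max(z_area, z_sol)
    q_circ = _sigmoid((f.circularity - p.spheroid_circularity) / 0.02)
    q_lobe = _sigmoid((p.spheroid_max_lobes + 0.5 - f.lobe_count) / 0.25)
    q_sph = min(q_circ, q_lobe)
    probs = np.array(
        [z_junk, (1 - z_junk) * (1 - q_sph), (1 - z_junk) * q_sph]
    )
    return probs / probs.sum()


def _downsample_crop(crop: Crop, side: int = 24) -> np.ndarray:
    img = transform.resize(crop.image.astype(np.float64) / 255.0, (side, side),
                           order=1, anti_aliasing=True, preserve_range=True)
    return img.ravel()


def classify(
    crop: Optional[Crop],
    features: ShapeFeatures,
    model: Optional[ClassifierModel] = None,
    area_um2: Optional[float] = None,
) -> tuple[str, tuple[float, float, float]]:
    """Assign a class label and probability triple to one object.

    The label is the argmax of the probabilities; exact ties break
    conservatively in the order junk > budding > spheroid.  ``area_um2`` is
    carried for provenance only — the rules operate in pixel units so they
    stay aligned with the segmentation thresholds.
    """
    model = model or ClassifierModel()
    if model.backend == "features":
        if model.is_trained:
            probs = model.estimator.predict_proba(
                features.vector().reshape(1, -1)
            )[0]
            probs = _order_probs(probs, model)
        else:
            probs = _rule_probabilities(features, model.params)
    elif model.backend == "mlp":
        if not model.is_trained:
            raise StateError("mlp backend must be trained before classify()")
        if crop is None:
            raise InputError("mlp backend requires the crop image")
        probs = model.estimator.predict_proba(
            _downsample_crop(crop).reshape(1, -1)
        )[0]
        probs = _order_probs(probs, model)
    else:
        raise InputError(f"unknown backend: {model.backend}")
    probs = np.asarray(probs, dtype=np.float64)
    probs = probs / probs.sum()
    # argmax with conservative tie order junk > budding > spheroid
    best = max(range(3), key=lambda i: (probs[i], -i))
    return CLASS_NAMES[best], tuple(float(x) for x in probs)


def _order_probs(probs: np.ndarray, model: ClassifierModel) -> np.ndarray:
    """Reorder sklearn's class-sorted probabilities to (junk, budding, spheroid)."""
    classes = list(model.estimator.classes_)
    return np.array([probs[classes.index(c)] for c in CLASS_NAMES])


def train_classifier(
    crops: Sequence[Crop],
    labels: Sequence[str],
    backend: str = "features",
    seed: int = 0,
    features: Optional[Sequence[ShapeFeatures]] = None,
    params: Optional[ClassificationParams] = None,
) -> ClassifierModel:
    """Train a classifier backend on labeled crops.

    A seeded 20% stratified hold-out split is used to record the model's
    held-out accuracy.  The ``features`` backend (logistic regression) is
    fully deterministic given the seed; the ``mlp`` backend (neural network
    on downsampled pixels) records the seed and is deterministic for a fixed
    scikit-learn build.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    p = params or ClassificationParams()
    labels = [str(l) for l in labels]
    present = set(labels)
    missing = [c for c in CLASS_NAMES if c not in present]
    if missing:
        raise InputError(f"training set is missing classes: {missing}")
    unknown = present - set(CLASS_NAMES)
    if unknown:
        raise InputError(f"unknown class labels: {sorted(unknown)}")

    if backend == "features":
        if features is None:
            features = [compute_features(c.mask, p) for c in crops]
        X = np.stack([f.vector() for f in features])
        est = make_pipeline(
            StandardScaler(),
            LogisticRegression(max_iter=2000, C=10.0, random_state=seed),
        )
    elif backend == "mlp":
        counts = {c: labels.count(c) for c in CLASS_NAMES}
        low = [c for c, n in counts.items() if n < 50]
        if low:
            raise InputError(
                f"mlp backend needs >= 50 examples per class, short: {low}"
            )
        X = np.stack([_downsample_crop(c) for c in crops])
        est = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=(64,), max_iter=400,
                          random_state=seed),
        )
    else:
        raise InputError(f"unknown backend: {backend}")

    y = np.array(labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=y
    )
    est.fit(X_tr, y_tr)
    acc = float((est.predict(X_te) == y_te).mean())
    return ClassifierModel(
        backend=backend,
        params=p,
        estimator=est,
        seed=seed,
        n_train=len(y_tr),
        holdout_accuracy=acc,
    )


def classify_objects(
    seg,
    projection: np.ndarray,
    model: Optional[ClassifierModel] = None,
    field_id: str = "",
    params: Optional[ClassificationParams] = None,
) -> None:
    """Classify every object of a segmentation result in place."""
    p = params or (model.params if model else ClassificationParams())
    for rec in seg.objects:
        mask = seg.mask_of(rec.object_id)
        crop = extract_crop(projection, mask, (field_id, rec.object_id), p)
        feats = compute_features(mask, p)
        label, probs = classify(crop, feats, model, rec.area_um2)
        rec.class_label = label
        rec.class_probs = probs
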