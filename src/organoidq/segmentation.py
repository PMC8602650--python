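"""Edge-projection segmentation of brightfield organoid z-stacks.

The pipeline turns one z-stack into a label image of candidate organoid
objects:

1. each plane is contrast-stretched to 8-bit (:func:`organoidq.io.autoscale`);
2. a Canny detector runs on every plane (organoid rims are in focus in
   different planes, so no single plane sees every edge);
3. small edge fragments (noise speckle) are removed per plane;
4. the per-plane edge maps are combined by a minimal projection — for dark
   edges this is simply their pixelwise union;
5. the projected contours are closed, filled, and size-filtered into objects;
6. touching/overlapping objects are split by a marker-based watershed on the
   Euclidean distance transform, and each object's center is defined as the
   pixel furthest from its edge.

All stages are deterministic given the parameter set.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import feature, filters, measure, morphology, segmentation as sk_seg

from .config import SegmentationParams
from .errors import FormatError, InputError
from .io import ZStack, autoscale

__all__ = [
    "EdgeMap",
    "OrganoidRecord",
    "SegmentationResult",
    "detect_edges",
    "remove_small_components",
    "project_edges",
    "contours_to_objects",
    "object_center",
    "split_touching",
    "segment_field",
    "min_projection",
]

CLASS_NAMES = ("junk", "budding", "spheroid")


@dataclass
class EdgeMap:
    """Binary edge raster for one z-plane."""

    data: np.ndarray  # bool, same shape as the source plane
    plane_index: int = 0


@dataclass
class OrganoidRecord:
    """One segmented object.

    ``center`` is the pixel of the object furthest from its edge (argmax of
    the Euclidean distance transform, ties broken toward smaller row then
    smaller column).  ``class_probs`` is a (junk, budding, spheroid) triple
    summing to 1 once the object has been classified.
    """

    object_id: int
    center: tuple[int, int]
    area_px: int
    contour: np.ndarray  # (n, 2) ordered boundary coordinates (row, col)
    area_um2: Optional[float] = None
    class_label: str = "unclassified"
    class_probs: Optional[tuple[float, float, float]] = None
    on_border: bool = False
    human_labeled: bool = False


@dataclass
class SegmentationResult:
    """Label image plus per-object records for one field."""

    labels: np.ndarray  # int32, 0 = background
    objects: list[OrganoidRecord]
    params: dict = dc_field(default_factory=dict)

    def mask_of(self, object_id: int) -> np.ndarray:
        return self.labels == object_id

    @property
    def object_ids(self) -> list[int]:
        return [o.object_id for o in self.objects]

    def get(self, object_id: int) -> OrganoidRecord:
        for o in self.objects:
            if o.object_id == object_id:
                return o
        raise InputError(f"no object with id {object_id}")


def _as_float01(plane: np.ndarray) -> np.ndarray:
    plane = np.asarray(plane)
    if plane.dtype == np.uint8:
        return plane.astype(np.float64) / 255.0
    if plane.dtype == np.uint16:
        return plane.astype(np.float64) / 65535.0
    p = plane.astype(np.float64)
    m = p.max()
    return p / m if m > 1 else p


def _filter_small(arr: np.ndarray, min_px: int) -> np.ndarray:
    """Keep 8-connected components of at least ``min_px`` pixels (exact)."""
    lab, n = ndi.label(arr, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return arr.copy()
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return sizes[lab] >= min_px


def detect_edges(
    plane: np.ndarray,
    sigma: float = 2.0,
    t_low: Optional[float] = None,
    t_high: Optional[float] = None,
    plane_index: int = 0,
) -> EdgeMap:
    """Canny edge detection on one plane.

    Gaussian smoothing at ``sigma``, Sobel gradient, non-maximum suppression
    and double-threshold hysteresis.  When thresholds are not given, the high
    threshold is set by Otsu's method on the gradient-magnitude histogram and
    the low threshold to half of it, which adapts to the contrast of each
    plane.  Thresholds are on the gradient of the image scaled to [0, 1].
    """
    plane = np.asarray(plane)
    if plane.ndim != 2:
        raise InputError(f"expected a 2-D plane, got shape {plane.shape}")
    img = _as_float01(plane)
    if t_low is None or t_high is None:
        smoothed = ndi.gaussian_filter(img, sigma)
        grad = np.hypot(ndi.sobel(smoothed, axis=0), ndi.sobel(smoothed, axis=1))
        if grad.max() <= 0:
            return EdgeMap(np.zeros(plane.shape, dtype=bool), plane_index)
        if t_high is None:
            t_high = float(filters.threshold_otsu(grad))
        if t_low is None:
            t_low = 0.5 * t_high
    if not t_low < t_high:
        raise InputError(f"need t_low < t_high, got {t_low}, {t_high}")
    edges = feature.canny(img, sigma=sigma, low_threshold=t_low, high_threshold=t_high)
    return EdgeMap(edges, plane_index)


def remove_small_components(edges: EdgeMap, min_px: int = 10) -> EdgeMap:
    """Drop 8-connected edge components smaller than ``min_px`` pixels."""
    if min_px < 1:
        raise InputError("min_px must be >= 1")
    return EdgeMap(_filter_small(edges.data.astype(bool), min_px), edges.plane_index)


def project_edges(edge_maps: Sequence[EdgeMap]) -> np.ndarray:
    """Minimal projection of per-plane edges.

    For binary edges (rendered dark on white) the minimum-intensity
    projection across planes is exactly the pixelwise union, which is what is
    computed here: a pixel is an edge iff it is an edge in at least one plane.
    """
    if len(edge_maps) == 0:
        raise InputError("need at least one edge map")
    shape = edge_maps[0].data.shape
    for em in edge_maps:
        if em.data.shape != shape:
            raise FormatError(
                f"edge map for plane {em.plane_index} has shape "
                f"{em.data.shape}, expected {shape}"
            )
    return np.logical_or.reduce([em.data.astype(bool) for em in edge_maps])


def _boundary_contour(mask: np.ndarray) -> np.ndarray:
    """Ordered boundary pixels of a mask (longest outer contour)."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return np.zeros((0, 2), dtype=np.intp)
    longest = max(contours, key=len)
    pts = np.rint(longest).astype(np.intp) - 1
    np.clip(pts[:, 0], 0, mask.shape[0] - 1, out=pts[:, 0])
    np.clip(pts[:, 1], 0, mask.shape[1] - 1, out=pts[:, 1])
    # drop consecutive duplicates introduced by rounding
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    return pts[keep]


def object_center(mask: np.ndarray) -> tuple[int, int]:
    """Pixel of ``mask`` furthest from the object edge.

    Computed as the argmax of the Euclidean distance transform (distance to
    the nearest background pixel, with everything outside the image treated
    as background).  Plateau ties are broken deterministically toward the
    smallest row, then the smallest column.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise InputError("cannot compute the center of an empty mask")
    padded = np.pad(mask, 1)
    dist = ndi.distance_transform_edt(padded)
    flat = int(np.argmax(dist))  # row-major argmax == (min row, min col) tie rule
    r, c = np.unravel_index(flat, padded.shape)
    return int(r) - 1, int(c) - 1


def _records_from_labels(
    labels: np.ndarray, pixel_size_um: Optional[float] = None
) -> list[OrganoidRecord]:
    records = []
    h, w = labels.shape
    for oid in np.unique(labels):
        if oid == 0:
            continue
        mask = labels == oid
        rows, cols = np.nonzero(mask)
        on_border = bool(
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        area = int(mask.sum())
        records.append(
            OrganoidRecord(
                object_id=int(oid),
                center=object_center(mask),
                area_px=area,
                area_um2=(area * pixel_size_um**2) if pixel_size_um else None,
                contour=_boundary_contour(mask),
                on_border=on_border,
            )
        )
    return records


def contours_to_objects(
    projected: np.ndarray,
    close_radius: int = 3,
    min_object_area: int = 200,
    pixel_size_um: Optional[float] = None,
) -> SegmentationResult:
    """Fill projected contours into candidate objects (pre-split).

    Edge gaps up to ``2 * close_radius`` are bridged by dilating with a disc
    of ``close_radius``, filling enclosed regions (4-connected background,
    so diagonal leaks do not empty a hole), and eroding by the same disc —
    plain closing cannot reconnect a broken one-pixel contour, while
    dilate/fill/erode reduces exactly to hole filling for contours that are
    already closed.  8-connected components with at least
    ``min_object_area`` pixels become objects.
    """
    if close_radius < 0:
        raise InputError("close_radius must be >= 0")
    proj = np.asarray(projected).astype(bool)
    if close_radius > 0:
        disk = morphology.disk(close_radius)
        grown = morphology.dilation(proj, disk)
        filled = ndi.binary_fill_holes(grown)  # 4-connected background
        filled = morphology.erosion(filled, disk)
    else:
        filled = ndi.binary_fill_holes(proj)
    filled = _filter_small(filled, min_object_area)
    labels = measure.label(filled, connectivity=2).astype(np.int32)
    return SegmentationResult(
        labels=labels,
        objects=_records_from_labels(labels, pixel_size_um),
        params={"close_radius": close_radius, "min_object_area": min_object_area},
    )


def _distance_peaks(
    mask: np.ndarray, min_separation: int, min_height: float,
    rel_height: float = 0.5,
) -> np.ndarray:
    """Watershed marker candidates from the distance transform of one mask.

    All small-scale local maxima at least ``min_height`` from the edge are
    collected, then greedily thinned in order of decreasing height so that
    accepted peaks are pairwise at least ``min_separation`` apart.  (Plain
    window-based non-maximum suppression would discard a genuine second
    organoid's peak whenever the rising slope toward a taller neighbour
    enters its window.)  Candidates lower than ``rel_height`` times the
    tallest peak are dropped: they are lobes or boundary plateaus of the
    same object, not separate organoids.
    """
    padded = np.pad(mask, 1)
    dist = ndi.distance_transform_edt(padded)
    cand = feature.peak_local_max(
        dist,
        min_distance=2,
        threshold_abs=min_height,
        exclude_border=False,
        labels=padded.astype(np.int32),
    )
    if len(cand) == 0:
        return cand
    vals = dist[tuple(cand.T)]
    order = np.lexsort((cand[:, 1], cand[:, 0], -vals))
    top = vals[order[0]]
    accepted: list[np.ndarray] = []
    for idx in order:
        if vals[idx] < rel_height * top:
            break
        p = cand[idx]
        if all(np.hypot(*(p - q)) >= min_separation for q in accepted):
            accepted.append(p)
    return np.array(accepted) - 1  # unpad


def split_touching(
    seg: SegmentationResult,
    min_peak_separation: int = 15,
    min_peak_height: float = 5.0,
    min_object_area: int = 200,
    pixel_size_um: Optional[float] = None,
) -> SegmentationResult:
    """Split touching objects by marker-based watershed.

    Per object, local maxima of the Euclidean distance transform (at least
    ``min_peak_height`` px from the edge, pairwise separation at least
    ``min_peak_separation`` px) become watershed markers on the negated
    distance transform.  Objects with fewer than two markers pass through
    unchanged.  Children smaller than ``min_object_area`` are merged into
    their largest sibling, so the total foreground never changes.
    """
    out = np.zeros_like(seg.labels, dtype=np.int32)
    next_id = 1
    for oid in sorted({o.object_id for o in seg.objects}):
        mask = seg.labels == oid
        peaks = _distance_peaks(mask, min_peak_separation, min_peak_height)
        if len(peaks) < 2:
            out[mask] = next_id
            next_id += 1
            continue
        dist = ndi.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
        markers = np.zeros_like(seg.labels, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        ws = sk_seg.watershed(-dist, markers=markers, mask=mask)
        # merge undersized children into the largest sibling
        child_ids, counts = np.unique(ws[ws > 0], return_counts=True)
        largest = int(child_ids[np.argmax(counts)])
        keep = [int(cid) for cid, n in zip(child_ids, counts) if n >= min_object_area]
        if len(keep) < 2:
            out[mask] = next_id
            next_id += 1
            continue
        for cid, n in zip(child_ids, counts):
            if int(cid) not in keep:
                ws[ws == cid] = largest
        for cid in keep:
            out[ws == cid] = next_id
            next_id += 1
    return SegmentationResult(
        labels=out,
        objects=_records_from_labels(out, pixel_size_um),
        params={
            **seg.params,
            "min_peak_separation": min_peak_separation,
            "min_peak_height": min_peak_height,
        },
    )


def min_projection(zstack: ZStack, params: Optional[SegmentationParams] = None) -> np.ndarray:
    """Minimum-intensity projection of the autoscaled stack (8-bit).

    This is the raster crops are extracted from: organoid rims are dark, so
    the pixelwise minimum keeps every rim in focus regardless of plane.
    """
    p = params or SegmentationParams()
    scaled = [autoscale(pl, p.autoscale_p_low, p.autoscale_p_high) for pl in zstack.planes]
    return np.minimum.reduce(scaled)


def _stack_canny_thresholds(
    scaled_planes: list[np.ndarray], sigma: float, floor_mult: float
) -> tuple[Optional[float], Optional[float]]:
    """Hysteresis thresholds shared by all planes of one stack.

    The high threshold is Otsu's threshold on the pooled gradient-magnitude
    histogram of every plane, floored at ``floor_mult`` times the pooled
    median gradient (the median is dominated by background texture, so the
    floor keeps pure-noise planes from yielding edges); the low threshold is
    half the high one.  Using one threshold pair for the whole stack means
    an object's sharp rim in its own focal plane sets the bar, and the
    smeared-out rims it casts into defocused planes fall below it instead of
    inflating the projected contour.
    """
    grads = []
    for pl in scaled_planes:
        img = pl.astype(np.float64) / 255.0
        sm = ndi.gaussian_filter(img, sigma)
        grads.append(np.hypot(ndi.sobel(sm, axis=0), ndi.sobel(sm, axis=1)).ravel())
    g = np.concatenate(grads)
    if g.max() <= 0:
        return None, None  # flat stack: no edges anywhere
    floor = floor_mult * float(np.median(g))
    t_high = max(float(filters.threshold_otsu(g)), floor)
    # second Otsu pass on the above-threshold population: separates sharp
    # in-focus rims from the wider, weaker halos the same objects cast into
    # defocused planes, which would otherwise inflate every contour
    edge_pop = g[g > t_high]
    if edge_pop.size > 100 and edge_pop.max() > edge_pop.min():
        t_high = max(float(filters.threshold_otsu(edge_pop)), t_high)
    return 0.5 * t_high, t_high


def segment_field(zstack: ZStack, params: Optional[SegmentationParams] = None) -> SegmentationResult:
    """Full segmentation of one z-stack.

    Composition of autoscale -> per-plane Canny -> small-component removal ->
    minimal edge projection -> contour filling -> watershed splitting.  The
    hysteresis thresholds (unless fixed in ``params``) are shared across the
    stack, from the pooled gradient histogram.  Deterministic given
    ``params``.
    """
    p = params or SegmentationParams()
    scaled_planes = [
        autoscale(plane, p.autoscale_p_low, p.autoscale_p_high)
        for plane in zstack.planes
    ]
    t_low, t_high = p.canny_low, p.canny_high
    if t_low is None or t_high is None:
        t_low, t_high = _stack_canny_thresholds(scaled_planes, p.canny_sigma, p.canny_floor_mult)
    edge_maps = []
    for i, scaled in enumerate(scaled_planes):
        if t_high is None:
            em = EdgeMap(np.zeros(scaled.shape, dtype=bool), i)
        else:
            em = detect_edges(scaled, sigma=p.canny_sigma, t_low=t_low,
                              t_high=t_high, plane_index=i)
        edge_maps.append(remove_small_components(em, p.min_edge_component_px))
    projected = project_edges(edge_maps)
    pre = contours_to_objects(
        projected, p.close_radius, p.min_object_area, zstack.pixel_size_um
    )
    if p.boundary_erosion_px > 0:
        # The filled contour reaches the outer envelope of the projected
        # edge band; the band straddles the true object boundary, so the
        # boundary is pulled back by a fixed calibration offset (set for the
        # default detector scale and plane spacing, config-tunable).
        fg = pre.labels > 0
        dist = ndi.distance_transform_edt(fg)
        eroded = _filter_small(fg & (dist > p.boundary_erosion_px), p.min_object_area)
        labels = measure.label(eroded, connectivity=2).astype(np.int32)
        pre = SegmentationResult(
            labels=labels,
            objects=_records_from_labels(labels, zstack.pixel_size_um),
            params=pre.params,
        )
    result = split_touching(
        pre, p.min_peak_separation, p.min_peak_height, p.min_object_area,
        zstack.pixel_size_um,
    )
    result.params = {
        "autoscale_p_low": p.autoscale_p_low,
        "autoscale_p_high": p.autoscale_p_high,
        "canny_sigma": p.canny_sigma,
        "canny_low": p.canny_low,
        "canny_high": p.canny_high,
        "min_edge_component_px": p.min_edge_component_px,
        "close_radius": p.close_radius,
        "min_object_area": p.min_object_area,
        "min_peak_separation": p.min_peak_separation,
        "min_peak_height": p.min_peak_height,
    }
    return result
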