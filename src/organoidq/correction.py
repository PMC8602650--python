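"""Blinded human correction round-trip.

The interactive classification editor of the original workflow is replaced
by a CSV round-trip with the same information content: the pipeline exports
object crops under blinded IDs in a randomized order (treatment and field
information hidden), a reviewer edits a correction table, and the pipeline
applies the table — deleting objects, overriding class labels, and
re-splitting any foreground region that ends up holding two or more
corrected centers with a marker-based watershed seeded exactly at those
centers.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, segmentation as sk_seg

from .classification import Crop
from .errors import ConsistencyError, FormatError, InputError
from .io import BlindingManifest
from .segmentation import OrganoidRecord, SegmentationResult, _records_from_labels

__all__ = [
    "CorrectionRecord",
    "CorrectionSet",
    "export_review",
    "apply_corrections",
]

ACTIONS = ("keep", "relabel", "add_center", "delete")
VALID_CLASSES = ("junk", "budding", "spheroid")

CORRECTIONS_COLUMNS = [
    "blinded_id", "action", "new_class", "new_center_row", "new_center_col",
]


@dataclass
class CorrectionRecord:
    blinded_id: str
    action: str = "keep"
    new_class: Optional[str] = None
    new_center: Optional[tuple[int, int]] = None


@dataclass
class CorrectionSet:
    """Reviewer-supplied corrections, keyed by blinded IDs."""

    records: list[CorrectionRecord]
    manifest_seed: Optional[int] = None

    def __post_init__(self) -> None:
        for r in self.records:
            if r.action not in ACTIONS:
                raise InputError(f"{r.blinded_id}: unknown action {r.action!r}")
            if r.action == "relabel" and r.new_class not in VALID_CLASSES:
                raise InputError(
                    f"{r.blinded_id}: relabel requires a valid class, got {r.new_class!r}"
                )
            if r.action == "add_center" and r.new_center is None:
                raise InputError(f"{r.blinded_id}: add_center requires coordinates")

    def save(self, path: str | Path) -> None:
        rows = []
        for r in self.records:
            rows.append({
                "blinded_id": r.blinded_id,
                "action": r.action,
                "new_class": r.new_class or "",
                "new_center_row": "" if r.new_center is None else r.new_center[0],
                "new_center_col": "" if r.new_center is None else r.new_center[1],
            })
        pd.DataFrame(rows, columns=CORRECTIONS_COLUMNS).to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "CorrectionSet":
        df = pd.read_csv(path, dtype={"blinded_id": str, "action": str})
        missing = [c for c in CORRECTIONS_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"corrections file {path} missing columns: {missing}")
        records = []
        for row in df.itertuples():
            center = None
            if not pd.isna(row.new_center_row) and str(row.new_center_row) != "":
                center = (int(row.new_center_row), int(row.new_center_col))
            new_class = None
            if isinstance(row.new_class, str) and row.new_class.strip():
                new_class = row.new_class.strip()
            records.append(CorrectionRecord(
                blinded_id=str(row.blinded_id),
                action=str(row.action).strip() or "keep",
                new_class=new_class,
                new_center=center,
            ))
        return cls(records=records)


def export_review(
    seg: SegmentationResult,
    crops: dict[int, Crop],
    blinding: BlindingManifest,
    out_dir: str | Path,
    field_id: str = "",
) -> list[Path]:
    """Write the blinded review bundle for one field.

    Crops are written as ``<blinded_id>.png`` in the manifest's permuted
    presentation order, together with a template correction table and a
    review manifest.  No condition or field identifier appears in any file
    the reviewer sees; the keyfile resolving blinded IDs must be stored
    elsewhere (see :meth:`BlindingManifest.save_key`).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    items = {blinding.key[b]: b for b in blinding.order}
    for rec in seg.objects:
        if (field_id, rec.object_id) not in items:
            raise ConsistencyError(
                f"object ({field_id}, {rec.object_id}) missing from blinding manifest"
            )
    written: list[Path] = []
    template_rows = []
    manifest_rows = []
    for bid in blinding.order:
        fid, oid = blinding.key[bid]
        if fid != field_id or oid not in crops:
            continue
        crop_path = out_dir / f"{bid}.png"
        iio.imwrite(crop_path, crops[oid].image)
        written.append(crop_path)
        manifest_rows.append({"blinded_id": bid, "crop_path": crop_path.name})
        template_rows.append({
            "blinded_id": bid, "action": "keep", "new_class": "",
            "new_center_row": "", "new_center_col": "",
        })
    pd.DataFrame(manifest_rows, columns=BlindingManifest.REVIEW_COLUMNS).to_csv(
        out_dir / "review_manifest.csv", index=False
    )
    pd.DataFrame(template_rows, columns=CORRECTIONS_COLUMNS).to_csv(
        out_dir / "corrections_template.csv", index=False
    )
    return written


def apply_corrections(
    seg: SegmentationResult,
    corrections: CorrectionSet,
    blinding: BlindingManifest,
    field_id: str = "",
    projected_foreground: Optional[np.ndarray] = None,
    pixel_size_um: Optional[float] = None,
) -> SegmentationResult:
    """Apply reviewer corrections to one field's segmentation.

    Deleted objects are removed from the label image.  Any 8-connected
    foreground region that a correction touched and that holds two or more
    corrected centers (surviving objects' centers, possibly moved, plus
    reviewer-added centers) is re-partitioned
    by a marker-based watershed on the negated distance transform, seeded
    exactly at those centers.  Children seeded by an existing object's
    center keep that object's ID, class and flags; children seeded by an
    added center receive fresh IDs and start unclassified.  Relabelled
    classes override the classifier output and are flagged ``human_labeled``.
    Foreground pixels are conserved except under deletions.
    """
    labels = seg.labels.copy()
    records = {o.object_id: _copy_record(o) for o in seg.objects}

    # resolve corrections for this field
    deletions: list[int] = []
    relabels: dict[int, str] = {}
    moved: dict[int, tuple[int, int]] = {}
    added: list[tuple[str, tuple[int, int]]] = []
    for r in corrections.records:
        fid, oid = blinding.resolve(r.blinded_id)
        if fid != field_id:
            continue
        if r.action == "delete":
            deletions.append(oid)
        elif r.action == "relabel":
            relabels[oid] = r.new_class  # type: ignore[assignment]
            if r.new_center is not None:
                moved[oid] = r.new_center
        elif r.action == "add_center":
            added.append((r.blinded_id, r.new_center))  # type: ignore[arg-type]
        elif r.action == "keep" and r.new_center is not None:
            moved[oid] = r.new_center

    for oid in deletions:
        labels[labels == oid] = 0
        records.pop(oid, None)

    foreground = labels > 0
    # collect corrected centers: surviving objects' (possibly moved) centers
    # plus reviewer-added centers
    centers: list[tuple[tuple[int, int], Optional[int], str]] = []
    for oid, rec in records.items():
        c = moved.get(oid, rec.center)
        centers.append((tuple(int(v) for v in c), oid, f"object {oid}"))
    for bid, c in added:
        centers.append((tuple(int(v) for v in c), None, bid))

    seen: dict[tuple[int, int], str] = {}
    for c, _oid, name in centers:
        if not (0 <= c[0] < labels.shape[0] and 0 <= c[1] < labels.shape[1]) or not foreground[c]:
            raise InputError(f"corrected center {c} ({name}) lies in background")
        if c in seen:
            raise InputError(
                f"two corrected centers at identical coordinates {c}: "
                f"{seen[c]} and {name}"
            )
        seen[c] = name

    regions = measure.label(foreground, connectivity=2)
    next_id = (int(labels.max()) + 1) if labels.any() else 1
    new_labels = np.zeros_like(labels)
    new_records: dict[int, OrganoidRecord] = {}

    for region_id in np.unique(regions):
        if region_id == 0:
            continue
        region_mask = regions == region_id
        in_region = [(c, oid) for c, oid, _ in centers if region_mask[c]]
        # only regions a correction actually touched (added or moved center)
        # are re-partitioned; untouched objects keep IDs and labels exactly
        dirty = any(oid is None or oid in moved for _c, oid in in_region)
        if len(in_region) < 2 or not dirty:
            # untouched partitioning: keep existing labels in this region
            new_labels[region_mask] = labels[region_mask]
            for oid in np.unique(labels[region_mask]):
                if oid != 0 and oid in records:
                    new_records[int(oid)] = records[int(oid)]
            continue
        dist = ndi.distance_transform_edt(np.pad(region_mask, 1))[1:-1, 1:-1]
        markers = np.zeros_like(labels)
        marker_owner: dict[int, Optional[int]] = {}
        for i, (c, oid) in enumerate(in_region, start=1):
            markers[c] = i
            marker_owner[i] = oid
        ws = sk_seg.watershed(-dist, markers=markers, mask=region_mask)
        for marker_idx, oid in marker_owner.items():
            child = ws == marker_idx
            if oid is None:
                oid_new = next_id
                next_id += 1
                rec = OrganoidRecord(
                    object_id=oid_new, center=(0, 0), area_px=0,
                    contour=np.zeros((0, 2), dtype=np.intp),
                )
            else:
                oid_new = oid
                rec = records[oid]
            new_labels[child] = oid_new
            rec = _refresh_geometry(rec, child, pixel_size_um)
            rec.object_id = oid_new
            new_records[oid_new] = rec

    for oid, cls in relabels.items():
        if oid in new_records:
            new_records[oid].class_label = cls
            new_records[oid].class_probs = None
            new_records[oid].human_labeled = True

    objects = [new_records[oid] for oid in sorted(new_records)]
    return SegmentationResult(labels=new_labels, objects=objects, params=dict(seg.params))


def _copy_record(o: OrganoidRecord) -> OrganoidRecord:
    return OrganoidRecord(
        object_id=o.object_id, center=o.center, area_px=o.area_px,
        contour=o.contour.copy(), area_um2=o.area_um2,
        class_label=o.class_label, class_probs=o.class_probs,
        on_border=o.on_border, human_labeled=o.human_labeled,
    )


def _refresh_geometry(
    rec: OrganoidRecord, mask: np.ndarray, pixel_size_um: Optional[float]
) -> OrganoidRecord:
    from .segmentation import _boundary_contour, object_center

    rec.area_px = int(mask.sum())
    rec.area_um2 = rec.area_px * pixel_size_um**2 if pixel_size_um else None
    rec.center = object_center(mask)
    rec.contour = _boundary_contour(mask)
    h, w = mask.shape
    rows, cols = np.nonzero(mask)
    rec.on_border = bool(
        rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
    )
    return rec
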