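"""Reading and writing pipeline artifacts.

Covers brightfield z-stacks (single- or multi-page TIFF), plate manifests,
per-object tables, and the blinded-review manifest used during human
correction.  All tables are plain CSV so that the complete state of a run can
be inspected and versioned as text.

Coordinates are 0-based ``(row, col)``; label images use 0 for background.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, InputError

__all__ = [
    "ZStack",
    "PlateManifest",
    "ManifestEntry",
    "BlindingManifest",
    "load_zstack",
    "autoscale",
    "build_blinding_manifest",
]


@dataclass
class ZStack:
    """An ordered set of co-registered 2-D brightfield planes.

    Parameters
    ----------
    planes
        List of 2-D intensity rasters of identical shape, index 0 = first
        focal plane (TIFF page order; no focal metadata is assumed).
    pixel_size_um
        Physical width of one pixel in micrometres, if known.
    field_id
        Opaque identifier of the imaged field/well.
    condition
        Treatment label (e.g. ``"ENR"``, ``"ENR+MuscleSN"``).
    """

    planes: list[np.ndarray]
    pixel_size_um: Optional[float] = None
    field_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.planes) < 1:
            raise InputError("a z-stack needs at least one plane")
        shape = self.planes[0].shape
        for i, p in enumerate(self.planes):
            if p.ndim != 2:
                raise FormatError(f"plane {i} is not 2-D (shape {p.shape})")
            if p.shape != shape:
                raise FormatError(
                    f"plane {i} has shape {p.shape}, expected {shape}"
                )
            if np.issubdtype(p.dtype, np.signedinteger) and p.min() < 0:
                raise InputError(f"plane {i} contains negative intensities")
        if self.pixel_size_um is not None and not self.pixel_size_um > 0:
            raise InputError("pixel_size_um must be positive when present")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes[0].shape

    @property
    def n_planes(self) -> int:
        return len(self.planes)


@dataclass
class ManifestEntry:
    field_id: str
    path: str
    condition: str
    pixel_size_um: Optional[float] = None


@dataclass
class PlateManifest:
    """Maps field identifiers to image files and treatment conditions."""

    entries: list[ManifestEntry]
    experiment_id: str = ""

    COLUMNS = ["field_id", "path", "condition", "pixel_size_um"]

    def __post_init__(self) -> None:
        ids = [e.field_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate field_ids in manifest: {dupes}")

    def save(self, path: str | Path) -> None:
        rows = [
            {
                "field_id": e.field_id,
                "path": e.path,
                "condition": e.condition,
                "pixel_size_um": e.pixel_size_um,
            }
            for e in self.entries
        ]
        pd.DataFrame(rows, columns=self.COLUMNS).to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, experiment_id: str = "") -> "PlateManifest":
        df = pd.read_csv(path)
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"manifest {path} is missing columns: {missing}")
        base = Path(path).parent
        entries = []
        for _, row in df.iterrows():
            p = Path(str(row["path"]))
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise InputError(f"manifest path does not resolve: {p}")
            px = row["pixel_size_um"]
            entries.append(
                ManifestEntry(
                    field_id=str(row["field_id"]),
                    path=str(p),
                    condition=str(row["condition"]),
                    pixel_size_um=None if pd.isna(px) else float(px),
                )
            )
        return cls(entries=entries, experiment_id=experiment_id)


def load_zstack(path: str | Path, manifest_entry: Optional[ManifestEntry] = None) -> ZStack:
    """Load a single- or multi-page TIFF into a :class:`ZStack`.

    Pages are taken in file order (page 0 = plane 0).  RGB pages are
    converted to grayscale by the channel average.  Metadata (field id,
    condition, pixel size) is copied from ``manifest_entry`` when given.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            pages = [p.asarray() for p in tif.pages]
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise InputError(f"cannot read TIFF {path}: {exc}") from exc
    if not pages:
        raise InputError(f"TIFF {path} contains no pages")
    planes = []
    for i, arr in enumerate(pages):
        if arr.ndim == 3 and arr.shape[-1] in (3, 4):
            arr = arr[..., :3].mean(axis=-1)
        if arr.ndim != 2:
            raise FormatError(f"page {i} of {path} is not a 2-D raster")
        planes.append(arr)
    shape = planes[0].shape
    for i, p in enumerate(planes):
        if p.shape != shape:
            raise FormatError(
                f"page {i} of {path} has shape {p.shape}, expected {shape}"
            )
    kw = {}
    if manifest_entry is not None:
        kw = dict(
            pixel_size_um=manifest_entry.pixel_size_um,
            field_id=manifest_entry.field_id,
            condition=manifest_entry.condition,
        )
    return ZStack(planes=planes, **kw)


def autoscale(plane: np.ndarray, p_low: float = 1.0, p_high: float = 99.0) -> np.ndarray:
    """Percentile contrast stretch to 8-bit.

    The ``p_low`` percentile of the intensity multiset maps to 0 and the
    ``p_high`` percentile to 255; values outside are clipped.  A constant
    plane maps to all zeros.  Robust defaults (1/99) suppress specular
    outliers common in brightfield wells.
    """
    plane = np.asarray(plane)
    if plane.size == 0:
        raise InputError("cannot autoscale an empty raster")
    if plane.ndim != 2:
        raise InputError(f"expected a 2-D raster, got shape {plane.shape}")
    if not (0 <= p_low < p_high <= 100):
        raise InputError(f"need 0 <= p_low < p_high <= 100, got {p_low}, {p_high}")
    lo, hi = np.percentile(plane, [p_low, p_high])
    if hi <= lo:
        return np.zeros(plane.shape, dtype=np.uint8)
    scaled = (plane.astype(np.float64) - lo) * (255.0 / (hi - lo))
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Blinded review manifest
# ---------------------------------------------------------------------------

@dataclass
class BlindingManifest:
    """Bijection between blinded IDs and (field_id, object_id) pairs.

    ``order`` is the seed-determined permutation in which crops are presented
    to the reviewer.  The payload shown in review mode (``blinded_id`` plus a
    crop path) carries no condition or field information; the keyfile that
    resolves blinded IDs is written separately and never enters the review
    directory.
    """

    seed: int
    order: list[str]  # blinded_ids in presentation order
    key: dict[str, tuple[str, int]] = field(default_factory=dict)

    REVIEW_COLUMNS = ["blinded_id", "crop_path"]
    KEY_COLUMNS = ["blinded_id", "field_id", "object_id"]

    def resolve(self, blinded_id: str) -> tuple[str, int]:
        if blinded_id not in self.key:
            raise InputError(f"unknown blinded_id: {blinded_id}")
        return self.key[blinded_id]

    def blinded_id_for(self, field_id: str, object_id: int) -> str:
        for bid, item in self.key.items():
            if item == (field_id, object_id):
                return bid
        raise InputError(f"object ({field_id}, {object_id}) not in blinding manifest")

    def save_key(self, path: str | Path) -> None:
        rows = [
            {"blinded_id": bid, "field_id": f, "object_id": o}
            for bid, (f, o) in sorted(self.key.items())
        ]
        df = pd.DataFrame(rows, columns=self.KEY_COLUMNS)
        df.insert(0, "seed", self.seed)
        df["presentation_rank"] = [self.order.index(b) for b in df["blinded_id"]]
        df.to_csv(path, index=False)

    @classmethod
    def load_key(cls, path: str | Path) -> "BlindingManifest":
        df = pd.read_csv(path)
        missing = [c for c in cls.KEY_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"keyfile {path} missing columns: {missing}")
        key = {
            str(r.blinded_id): (str(r.field_id), int(r.object_id))
            for r in df.itertuples()
        }
        order = list(df.sort_values("presentation_rank")["blinded_id"].astype(str))
        seed = int(df["seed"].iloc[0]) if "seed" in df.columns else -1
        return cls(seed=seed, order=order, key=key)


def build_blinding_manifest(
    items: Sequence[tuple[str, int]], seed: int
) -> BlindingManifest:
    """Assign blinded IDs and a randomized presentation order.

    The permutation is drawn from ``numpy.random.default_rng(seed)`` (PCG64),
    so identical ``items`` and ``seed`` reproduce the identical manifest.
    Blinded IDs encode nothing but the presentation rank.
    """
    items = list(items)
    if not items:
        raise InputError("cannot blind an empty item list")
    if len(set(items)) != len(items):
        raise InputError("duplicate (field_id, object_id) items")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(items))
    order: list[str] = []
    key: dict[str, tuple[str, int]] = {}
    for rank, idx in enumerate(perm):
        fid, oid = items[idx]
        bid = f"B{rank + 1:05d}"
        order.append(bid)
        key[bid] = (str(fid), int(oid))
    return BlindingManifest(seed=int(seed), order=order, key=key)


def file_sha256(path: str | Path) -> str:
    """Hex digest of a file, used to stamp outputs for reproducibility checks."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
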