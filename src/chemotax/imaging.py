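"""Worm localization in scanned assay-plate images.

The imaging path turns an 8-bit grayscale endpoint scan into per-arena tables
of worm centroids:

1. **segment** -- global Otsu threshold (pixels strictly greater than the
   threshold are foreground), then one pass of morphological closing with a
   3x3 square to repair binarization defects;
2. **label** -- 8-connected component labeling with centroid, area and
   bounding box per object;
3. **demultiplex** -- the foam inserts are by far the largest objects; their
   ring-shaped components define the arenas, the interior apices give the
   apex-to-apex span ``w`` and the notch side marks the test compound;
4. **filter** -- retain worm-like objects with area strictly between 50 and
   2,500 px (at 1,200 dpi): smaller objects are debris/eggs, larger ones are
   clumps of worms, which are excluded rather than split.

The path is fully deterministic: re-running on the same scan yields identical
tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import closing, footprint_rectangle

__all__ = [
    "GrayscaleScan",
    "LabeledObject",
    "ArenaDetection",
    "LocationTable",
    "ArenaDetectionError",
    "read_scan",
    "write_scan",
    "otsu_threshold",
    "otsu_threshold_hist",
    "segment_foreground",
    "label_components",
    "detect_arenas",
    "filter_worm_objects",
    "locate_worms",
]

MIN_WORM_AREA = 50
MAX_WORM_AREA = 2500
#: insert-area floor, as a multiple of the maximum worm area
INSERT_AREA_FACTOR = 50


class ArenaDetectionError(RuntimeError):
    """Raised when the expected foam inserts cannot be found in a scan."""


@dataclass
class GrayscaleScan:
    """An 8-bit grayscale scan plus its resolution and identifier."""

    pixels: np.ndarray
    dpi: int = 1200
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected 8-bit pixels, got dtype {self.pixels.dtype}")
        if self.pixels.ndim != 2:
            raise ValueError("expected a single-channel 2-D image")


@dataclass
class LabeledObject:
    """One connected foreground component."""

    label: int
    centroid_x: float
    centroid_y: float
    area: int
    bbox: tuple[int, int, int, int]  # (min_x, min_y, max_x, max_y)


@dataclass
class ArenaDetection:
    """One demultiplexed behavioral arena."""

    well_id: str
    slot: int
    insert_label: int
    insert_bbox: tuple[int, int, int, int]
    arena_mask: np.ndarray = field(repr=False)
    apex_test: tuple[float, float]
    apex_control: tuple[float, float]
    w: float

    @property
    def test_side(self) -> str:
        return "left" if self.apex_test[0] < self.apex_control[0] else "right"


@dataclass
class LocationTable:
    """Per-arena worm centroid table (pixel units, full-scan coordinates)."""

    arena_id: str
    rows: pd.DataFrame  # columns worm_id, x_px, y_px
    detection: ArenaDetection | None = None

    @property
    def count(self) -> int:
        return len(self.rows)

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)


def read_scan(path, dpi: int = 1200, image_id: str | None = None) -> GrayscaleScan:
    """Read a single-page 8-bit grayscale TIFF."""
    pixels = tifffile.imread(path)
    if image_id is None:
        import os

        image_id = os.path.splitext(os.path.basename(str(path)))[0]
    return GrayscaleScan(pixels=pixels, dpi=dpi, image_id=image_id)


def write_scan(path, scan: GrayscaleScan | np.ndarray) -> None:
    pixels = scan.pixels if isinstance(scan, GrayscaleScan) else scan
    tifffile.imwrite(path, pixels, photometric="minisblack")


def otsu_threshold(pixels: np.ndarray) -> int:
    """Otsu threshold over the full 0..255 histogram of an 8-bit image.

    The returned threshold is the integer intensity t maximizing the
    between-class variance of the split (<= t) vs (> t); ties resolve to the
    smallest maximizing threshold.
    """
    return otsu_threshold_hist(np.bincount(pixels.ravel(), minlength=256))


def otsu_threshold_hist(counts: np.ndarray) -> int:
    """Otsu threshold for a full 256-bin intensity histogram.

    Between-class variances are compared in exact integer arithmetic
    (``sigma_b^2(t)`` is proportional to ``(S0*W1 - S1*W0)^2 / (W0*W1)``
    with integer class weights W and intensity sums S), so the result is the
    true argmax even when two splits differ by less than float precision.
    """
    counts = np.asarray(counts)
    if counts.shape != (256,):
        raise ValueError("expected a 256-bin histogram")
    c = [int(v) for v in counts]
    total = sum(c)
    s_total = sum(i * v for i, v in enumerate(c))
    best_t = None
    best_num = best_den = 0  # running maximum as an exact fraction num/den
    w0 = s0 = 0
    for t in range(255):
        w0 += c[t]
        s0 += t * c[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        num = (s0 * w1 - (s_total - s0) * w0) ** 2
        den = w0 * w1
        if best_t is None or num * best_den > best_num * den:
            best_t, best_num, best_den = t, num, den
    if best_t is None:  # single populated bin: no valid split
        nz = np.flatnonzero(counts)
        return int(nz[0]) if nz.size else 0
    return best_t


def segment_foreground(scan: GrayscaleScan | np.ndarray, invert: bool = False) -> np.ndarray:
    """Binary foreground mask: strictly above the Otsu threshold, then closed.

    A constant image has no defined threshold; a warning is issued and an
    all-background mask returned.  ``invert`` handles dark-on-bright scans.
    """
    pixels = scan.pixels if isinstance(scan, GrayscaleScan) else np.asarray(scan)
    if pixels.dtype != np.uint8:
        raise ValueError("segment_foreground expects 8-bit input")
    if invert:
        pixels = np.uint8(255) - pixels
    if pixels.min() == pixels.max():
        warnings.warn("constant image: Otsu threshold undefined, empty foreground")
        return np.zeros(pixels.shape, dtype=bool)
    t = otsu_threshold(pixels)
    mask = pixels > t
    return closing(mask, footprint_rectangle((3, 3)))


def label_components(mask: np.ndarray) -> tuple[list[LabeledObject], np.ndarray]:
    """8-connected component labeling.

    Returns the objects (label, centroid, area, bbox) and the label image so
    downstream stages can address individual components without relabeling.
    """
    labels = sk_label(mask, connectivity=2)
    objects = []
    for rp in regionprops(labels):
        (min_r, min_c, max_r, max_c) = rp.bbox
        cy, cx = rp.centroid
        objects.append(
            LabeledObject(
                label=int(rp.label),
                centroid_x=float(cx),
                centroid_y=float(cy),
                area=int(rp.area),
                bbox=(int(min_c), int(min_r), int(max_c), int(max_r)),
            )
        )
    return objects, labels


def _arena_from_insert(obj: LabeledObject, labels: np.ndarray) -> ArenaDetection | None:
    """Build an arena from one insert component, or None if it has no interior."""
    min_x, min_y, max_x, max_y = obj.bbox
    crop = labels[min_y:max_y, min_x:max_x] == obj.label
    interior = ndimage.binary_fill_holes(crop) & ~crop
    if not interior.any():
        return None
    rows_i, cols_i = np.nonzero(interior)
    cmin, cmax = cols_i.min(), cols_i.max()
    apex_left = (float(min_x + cmin), float(min_y + rows_i[cols_i == cmin].mean()))
    apex_right = (float(min_x + cmax), float(min_y + rows_i[cols_i == cmax].mean()))
    w = apex_right[0] - apex_left[0]
    # notch tab on the test side makes that half of the insert heavier
    rows_f, cols_f = np.nonzero(crop)
    mid = (cmin + cmax) / 2.0
    left_mass = int(np.sum(cols_f < mid))
    right_mass = int(np.sum(cols_f >= mid))
    if left_mass >= right_mass:
        apex_test, apex_control = apex_left, apex_right
    else:
        apex_test, apex_control = apex_right, apex_left
    full_mask = np.zeros(labels.shape, dtype=bool)
    full_mask[min_y:max_y, min_x:max_x] = interior
    return ArenaDetection(
        well_id="?", slot=0, insert_label=obj.label, insert_bbox=obj.bbox,
        arena_mask=full_mask, apex_test=apex_test, apex_control=apex_control, w=w,
    )


def detect_arenas(
    objects: list[LabeledObject],
    scan: GrayscaleScan,
    wells_per_plate: int = 4,
    expected_plates: int | None = None,
    insert_min_area: float | None = None,
    max_worm_area: int = MAX_WORM_AREA,
    label_image: np.ndarray | None = None,
) -> list[ArenaDetection]:
    """Demultiplex a scan into arenas via its foam-insert components.

    Inserts are the largest objects by a wide margin; candidates are objects
    above an area floor (default ``100 x max_worm_area`` scaled to the scan
    dpi) that enclose an interior.  Well IDs are assigned by sorted position,
    row-major across the scan; consecutive groups of ``wells_per_plate``
    arenas share a scanner slot.
    """
    if insert_min_area is None:
        insert_min_area = INSERT_AREA_FACTOR * max_worm_area * (scan.dpi / 1200.0) ** 2
    if label_image is None:
        mask = segment_foreground(scan)
        _, label_image = label_components(mask)

    candidates = [o for o in objects if o.area >= insert_min_area]
    detections = []
    for obj in sorted(candidates, key=lambda o: -o.area):
        det = _arena_from_insert(obj, label_image)
        if det is not None:
            detections.append(det)

    expected = None if expected_plates is None else expected_plates * wells_per_plate
    if not detections or (expected is not None and len(detections) < expected):
        found = sorted((o.area for o in objects), reverse=True)[:8]
        raise ArenaDetectionError(
            f"found {len(detections)} insert(s), expected "
            f"{expected if expected is not None else '>=1'}; "
            f"largest object areas: {found} (floor {insert_min_area:.0f} px)"
        )
    if expected is not None:
        detections = sorted(detections, key=lambda d: -_bbox_area(d.insert_bbox))[:expected]

    # row-major ordering across the scan by insert bbox position
    detections.sort(key=lambda d: (d.insert_bbox[1], d.insert_bbox[0]))
    for i, det in enumerate(detections):
        det.slot = i // wells_per_plate + 1
        det.well_id = "ABCDEFGH"[i % wells_per_plate]
    return detections


def _bbox_area(bbox: tuple[int, int, int, int]) -> int:
    min_x, min_y, max_x, max_y = bbox
    return (max_x - min_x) * (max_y - min_y)


def filter_worm_objects(
    objects: list[LabeledObject],
    min_area: int = MIN_WORM_AREA,
    max_area: int = MAX_WORM_AREA,
) -> list[LabeledObject]:
    """Retain worm-like objects with ``min_area < area < max_area`` (strict).

    Strict on both bounds: an object of exactly 50 or 2,500 px is rejected.
    Idempotent by construction.
    """
    return [o for o in objects if min_area < o.area < max_area]


def locate_worms(
    scan: GrayscaleScan,
    min_area: int = MIN_WORM_AREA,
    max_area: int = MAX_WORM_AREA,
    wells_per_plate: int = 4,
    expected_plates: int | None = None,
    invert: bool = False,
    insert_min_area: float | None = None,
) -> list[LocationTable]:
    """Full imaging path: segment, label, demultiplex, filter, tabulate.

    Returns one :class:`LocationTable` per detected arena with worm centroids
    in full-scan pixel coordinates.  ``min_area``/``max_area`` are in native
    pixels of the scan (pass scaled bounds for reduced-dpi images).  Objects
    are assigned to the arena whose interior contains their centroid; the
    insert components themselves are excluded.
    """
    mask = segment_foreground(scan, invert=invert)
    objects, labels = label_components(mask)
    detections = detect_arenas(
        objects, scan, wells_per_plate=wells_per_plate,
        expected_plates=expected_plates, max_worm_area=max_area,
        label_image=labels, insert_min_area=insert_min_area,
    )
    insert_labels = {d.insert_label for d in detections}
    tables = []
    for det in detections:
        members = []
        for obj in objects:
            if obj.label in insert_labels:
                continue
            r, c = int(round(obj.centroid_y)), int(round(obj.centroid_x))
            if 0 <= r < det.arena_mask.shape[0] and 0 <= c < det.arena_mask.shape[1] \
                    and det.arena_mask[r, c]:
                members.append(obj)
        kept = filter_worm_objects(members, min_area=min_area, max_area=max_area)
        rows = pd.DataFrame(
            {
                "worm_id": np.arange(len(kept)),
                "x_px": [o.centroid_x for o in kept],
                "y_px": [o.centroid_y for o in kept],
            }
        )
        arena_id = f"{scan.image_id}_{det.slot}_{det.well_id}" if scan.image_id else \
            f"{det.slot}_{det.well_id}"
        tables.append(LocationTable(arena_id=arena_id, rows=rows, detection=det))
    return tables
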