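"""Gradient-axis coordinates and chemotaxis metrics for one assay arena.

An endpoint assay scores the distribution of worms along the chemical
gradient.  Pixel positions measured from the test-compound apex are mapped to
a centered millimeter coordinate ``z`` (positive toward the test compound)::

    z = (w/2 - x) * 25.4 / dpi

where ``w`` is the apex-to-apex span in pixels and ``x`` the worm's pixel
position along the gradient axis measured from the test apex.  At the nominal
geometry (w = 3,041 px, 1,200 dpi) ``z`` spans about -32.2..+32.2 mm; the
nominal arena half-width is taken as 32.5 mm.

Two metrics are computed per arena:

* the classical **chemotaxis index** ``(p - q) / (p + q)`` over nine equal
  segments of the gradient axis (four test-side segments count ``p``, four
  control-side segments count ``q``, the central ninth is the starting zone
  and is excluded), and
* the **mean worm position** (mm), the plain average of ``z`` over all worms,
  including those still in the starting zone.

Assays with fewer than 150 worms are flagged by QC: below that size the
index variance has not yet reached its floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "ArenaGeometry",
    "PositionTable",
    "AssaySummary",
    "IndexResult",
    "NOMINAL_HALF_WIDTH_MM",
    "QC_MIN_WORMS",
    "to_gradient_coords",
    "chemotaxis_index",
    "mean_position",
    "qc_pass",
    "summarize_arena",
]

NOMINAL_HALF_WIDTH_MM = 32.5
QC_MIN_WORMS = 150
MM_PER_INCH = 25.4


@dataclass
class ArenaGeometry:
    """Apex-to-apex span ``w`` (px), scan resolution, and test-compound side."""

    w: float
    dpi: float = 1200.0
    test_side: str = "left"

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("apex-to-apex distance w must be > 0")
        if self.dpi <= 0:
            raise ValueError("dpi must be > 0")

    @property
    def w_mm(self) -> float:
        return self.w * MM_PER_INCH / self.dpi


@dataclass
class PositionTable:
    """Per-worm gradient coordinates ``z`` (mm) for one arena."""

    z: np.ndarray
    y_mm: np.ndarray | None = None
    arena_id: str = ""

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)

    @property
    def n(self) -> int:
        return int(self.z.size)


class IndexResult(NamedTuple):
    index: float  # nan when undefined (p + q == 0)
    p_count: int
    q_count: int
    defined: bool


@dataclass
class AssaySummary:
    """Per-arena summary row: counts, index, mean position, QC and metadata."""

    n_total: int
    p_count: int
    q_count: int
    chemotaxis_index: float
    mean_position: float
    w_px: float
    compound_id: str = ""
    strain_id: str = ""
    image_id: str = ""
    plate_id: str = ""
    arena_id: str = ""
    qc_pass: bool = False
    index_defined: bool = True


def to_gradient_coords(x_px, geometry: ArenaGeometry) -> PositionTable:
    """Map pixel positions along the gradient axis to centered mm coordinates.

    ``x_px`` is measured from the test-compound apex, so the returned ``z`` is
    ``+w_mm/2`` at the test apex, 0 at the arena center and ``-w_mm/2`` at the
    control apex.  The map is affine and exactly invertible.

    Raises ``ValueError`` if any position falls outside ``[0, w]``.
    """
    x = np.asarray(x_px, dtype=float)
    if x.size and (x.min() < 0 or x.max() > geometry.w):
        bad = x[(x < 0) | (x > geometry.w)]
        raise ValueError(
            f"{bad.size} position(s) outside [0, w={geometry.w}] px: "
            f"first offending value {bad[0]:.2f}"
        )
    z = (geometry.w / 2.0 - x) * MM_PER_INCH / geometry.dpi
    return PositionTable(z=z)


def segment_of(z, w_mm: float) -> np.ndarray:
    """Nine-segment bin index (0..8, control to test) for gradient positions.

    Segments are nine equal intervals of ``[-w_mm/2, +w_mm/2]``; segment 4 is
    the central starting zone.  A worm exactly on a boundary is assigned to
    the segment nearer the test side (deterministic tie-break, measure-zero
    on real data).  Positions outside the range clip to the outer segments.
    """
    z = np.asarray(z, dtype=float)
    seg_w = w_mm / 9.0
    # boundary z = -w/2 + (k) * seg_w separates segments k-1 | k; ties go up
    k = np.floor((z + w_mm / 2.0) / seg_w).astype(int)
    return np.clip(k, 0, 8)


def chemotaxis_index(positions: PositionTable, w_mm: float = 2 * NOMINAL_HALF_WIDTH_MM) -> IndexResult:
    """Chemotaxis index ``(p - q) / (p + q)`` over nine gradient segments.

    ``p`` counts worms in the four test-side segments (``z >= w_mm/18`` with
    the boundary tie going toward the test side), ``q`` those in the four
    control-side segments (``z < -w_mm/18``); the central ninth (starting
    zone) is excluded.  When no worm is outside the starting zone the index
    is undefined (``nan``, ``defined=False``), not zero.
    """
    if w_mm <= 0:
        raise ValueError("w_mm must be > 0")
    seg = segment_of(positions.z, w_mm)
    p = int(np.sum(seg > 4))
    q = int(np.sum(seg < 4))
    if p + q == 0:
        return IndexResult(float("nan"), 0, 0, False)
    return IndexResult((p - q) / (p + q), p, q, True)


def mean_position(positions: PositionTable) -> float:
    """Mean gradient coordinate (mm) over *all* worms, starting zone included."""
    if positions.n < 1:
        raise ValueError("mean position undefined for an empty table")
    return float(np.mean(positions.z))


def qc_pass(n_total: int, threshold: int = QC_MIN_WORMS) -> bool:
    """True iff the arena holds at least ``threshold`` worms (inclusive)."""
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    return n_total >= threshold


def summarize_arena(
    positions: PositionTable,
    geometry: ArenaGeometry,
    *,
    compound_id: str = "",
    strain_id: str = "",
    image_id: str = "",
    plate_id: str = "",
    arena_id: str = "",
    qc_threshold: int = QC_MIN_WORMS,
    w_mm: float | None = None,
) -> AssaySummary:
    """Assemble the per-arena summary row (counts, index, mean position, QC).

    The index is computed on the nominal arena width by default; pass
    ``w_mm=geometry.w_mm`` to use the measured span instead.
    """
    if w_mm is None:
        w_mm = 2 * NOMINAL_HALF_WIDTH_MM
    res = chemotaxis_index(positions, w_mm=w_mm)
    return AssaySummary(
        n_total=positions.n,
        p_count=res.p_count,
        q_count=res.q_count,
        chemotaxis_index=res.index,
        mean_position=mean_position(positions) if positions.n else float("nan"),
        w_px=geometry.w,
        compound_id=compound_id,
        strain_id=strain_id,
        image_id=image_id,
        plate_id=plate_id,
        arena_id=arena_id or positions.arena_id,
        qc_pass=qc_pass(positions.n, qc_threshold),
        index_defined=res.defined,
    )
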