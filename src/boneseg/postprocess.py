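"""Anatomical postprocessing of the raw humeral-head segmentation.

The raw level-set/cluster mask usually carries over the scapular edge
and parts of the biceps/subscapularis tendons, which share the bone's
PD intensity and sit at the periphery of the enlarged ROI circle on
the shoulder side. Postprocessing:

1. detects the shoulder side from the image's intensity mass,
2. erodes the mask inside the peripheral annulus of the ROI in the
   scapula sector (a disk structuring element disconnects the thin
   bridges to scapula/tendon),
3. keeps the connected component that best overlaps the shrunken
   Hough disk and restores its eroded rim by dilation (an opening
   discipline — the output never exceeds the input mask),
4. fills interior holes left by bright bone edema, and
5. traces the final 8-connected boundary for display/export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as disk_element

from .hough_roi import CircleROI, disk_mask
from .io_types import BinaryMask, Image2D

__all__ = ["SideInfo", "detect_side", "suppress_attachments", "fill_holes",
           "extract_boundary", "postprocess_mask"]

DEFAULT_ELEMENT_RADIUS = 3
DEFAULT_SECTOR_WIDTH = np.pi / 2  # 90 degrees


@dataclass
class SideInfo:
    """Shoulder side and the angular sector where scapula suppression applies.

    Angles are measured from the +col axis, counter-clockwise in (row,
    col) display convention; ``scapula_sector`` is ``(lo, hi)`` radians
    centered on the direction of the shoulder-side image border.
    """

    side: str                              # {"left", "right"}
    scapula_sector: tuple[float, float]

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be left/right, got {self.side!r}")
        lo, hi = self.scapula_sector
        if not (0 < hi - lo <= np.pi):
            raise ValueError("sector width must be in (0, pi]")


def detect_side(image: Image2D, sector_width: float = DEFAULT_SECTOR_WIDTH) -> SideInfo:
    """Determine the shoulder side from the image intensity histogram.

    The image half (left vs. right columns) with the larger total
    intensity mass holds the shoulder; the scapula sector points toward
    that side's border. An exact tie defaults to "right" with a warning.
    """
    arr = image.pixels
    half = arr.shape[1] // 2
    left_mass = arr[:, :half].sum()
    right_mass = arr[:, half:].sum()
    if left_mass == right_mass:
        warnings.warn("left/right intensity mass tied; defaulting to side='right'")
        side = "right"
    else:
        side = "left" if left_mass > right_mass else "right"
    center_angle = np.pi if side == "left" else 0.0  # direction of that border
    sector = (center_angle - sector_width / 2, center_angle + sector_width / 2)
    return SideInfo(side=side, scapula_sector=sector)


def _sector_mask(shape: tuple[int, int], roi: CircleROI,
                 sector: tuple[float, float]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    # -row so that angles follow the usual CCW math convention on screen
    ang = np.arctan2(-(rr - roi.center[0]), cc - roi.center[1])
    lo, hi = sector
    width = hi - lo
    rel = np.mod(ang - lo, 2 * np.pi)
    return rel <= width


def suppress_attachments(mask: BinaryMask, roi: CircleROI, side: SideInfo,
                         element_radius: int = DEFAULT_ELEMENT_RADIUS) -> BinaryMask:
    """Remove scapula/tendon attachments from the raw mask.

    Erosion with a disk element is applied only inside the annulus
    [0.8, 1.0] x enlarged_radius intersected with the scapula sector;
    the connected component overlapping the shrunken (0.9 x radius)
    Hough disk best is kept, re-dilated, and clipped to the input mask.
    Falls back to the largest input component (with a warning) if the
    selection empties out.
    """
    m = mask.astype_bool()
    shape = m.shape
    elem = disk_element(element_radius)

    annulus = (disk_mask(roi.center, roi.enlarged_radius, shape)
               & ~disk_mask(roi.center, 0.8 * roi.enlarged_radius, shape))
    zone = annulus & _sector_mask(shape, roi, side.scapula_sector)

    eroded = ndi.binary_erosion(m, structure=elem)
    worked = np.where(zone, eroded, m)

    labels, n = ndi.label(worked)
    ref = disk_mask(roi.center, 0.9 * roi.radius, shape)
    if n == 0:
        warnings.warn("suppression emptied the mask; falling back to largest component")
        return _largest_component(mask)
    overlaps = ndi.sum_labels(ref.astype(float), labels, index=np.arange(1, n + 1))
    if overlaps.max() <= 0:
        # nothing touches the head disk; keep the largest surviving piece
        sizes = ndi.sum_labels(np.ones(shape), labels, index=np.arange(1, n + 1))
        best = 1 + int(np.argmax(sizes))
    else:
        best = 1 + int(np.argmax(overlaps))
    kept = labels == best
    restored = ndi.binary_dilation(kept, structure=elem) & m
    if not restored.any():
        warnings.warn("suppression emptied the mask; falling back to largest component")
        return _largest_component(mask)
    return BinaryMask.from_bool(restored)


def _largest_component(mask: BinaryMask) -> BinaryMask:
    m = mask.astype_bool()
    labels, n = ndi.label(m)
    if n <= 1:
        return BinaryMask.from_bool(m)
    sizes = ndi.sum_labels(np.ones(m.shape), labels, index=np.arange(1, n + 1))
    return BinaryMask.from_bool(labels == 1 + int(np.argmax(sizes)))


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill background regions not connected to the image border.

    Closes the interior holes that bright bone edema leaves in the
    two-phase segmentation. Monotone (never removes pixels) and
    idempotent.
    """
    return BinaryMask.from_bool(ndi.binary_fill_holes(mask.astype_bool()))


_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def extract_boundary(mask: BinaryMask) -> list[tuple[int, int]]:
    """Moore-neighbor trace of the largest component's outer boundary.

    Returns the 8-connected boundary pixels in closed polygon order.
    """
    m = _largest_component(mask).astype_bool()
    if not m.any():
        raise ValueError("empty mask has no boundary")
    rows, cols = np.nonzero(m)
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost foreground pixel
    first = np.lexsort((cols, rows))[0]
    start = (int(rows[first]), int(cols[first]))

    def at(p):
        r, c = p
        return 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and m[r, c]

    if not any(at((start[0] + dr, start[1] + dc)) for dr, dc in _MOORE):
        return [start]  # isolated pixel

    boundary = [start]
    # backtrack starts pointing at the pixel "above" the start (exterior)
    prev_dir = 6  # came from the west: search from north-west onward
    cur = start
    while True:
        found = False
        for i in range(8):
            d = (prev_dir + 1 + i) % 8
            nxt = (cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1])
            if at(nxt):
                if nxt == start and len(boundary) > 1:
                    return boundary
                boundary.append(nxt)
                cur = nxt
                prev_dir = (d + 4) % 8  # direction back to where we came from
                found = True
                break
        if not found:
            return boundary
        if len(boundary) > 4 * m.size:  # safety net; cannot trace longer
            return boundary


def postprocess_mask(mask: BinaryMask, roi: CircleROI, image: Image2D,
                     element_radius: int = DEFAULT_ELEMENT_RADIUS,
                     sector_width: float = DEFAULT_SECTOR_WIDTH) -> BinaryMask:
    """Full postprocessing: side detection, suppression, hole filling."""
    side = detect_side(image, sector_width=sector_width)
    cleaned = suppress_attachments(mask, roi, side, element_radius=element_radius)
    return fill_holes(cleaned)
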