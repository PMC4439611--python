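"""Circular-Hough detection of the humeral head and ROI construction.

The humeral head has a round cross-section in axial shoulder slices, so
a circular Hough transform on a Canny edge map localizes it robustly —
including heads with boundary gaps from edema or a Hill-Sachs notch.
The detected circle is enlarged (default factor 1.2) to form the
working region of interest, and the initial level-set contour is placed
concentrically at half the detected radius, strictly inside the bone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny
from skimage.transform import hough_circle

from .io_types import BinaryMask, Image2D

__all__ = ["CircleROI", "detect_humeral_circle", "initial_level_set", "LevelSetField"]

DEFAULT_ENLARGEMENT = 1.2
_PEAK_THRESHOLD = 0.25  # min fraction of circle perimeter supported by edges


class DetectionFailure(RuntimeError):
    """No sufficiently supported circle in the accumulator."""


@dataclass
class LevelSetField:
    """Signed field phi whose zero set is the contour; phi > 0 inside."""

    phi: np.ndarray
    epsilon: float = 1.5

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi must be finite")

    def mask(self) -> BinaryMask:
        return BinaryMask.from_bool(self.phi > 0)


@dataclass
class CircleROI:
    """Detected circle plus the enlarged working region of interest."""

    center: tuple[int, int]          # (row, col)
    radius: float
    enlarged_radius: float
    roi_mask: BinaryMask

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.enlarged_radius < self.radius:
            raise ValueError("enlarged_radius must be >= radius")

    @classmethod
    def from_circle(cls, center: tuple[int, int], radius: float,
                    shape: tuple[int, int],
                    enlargement: float = DEFAULT_ENLARGEMENT) -> "CircleROI":
        enlarged = enlargement * radius
        mask = disk_mask(center, enlarged, shape)
        return cls(center=center, radius=radius, enlarged_radius=enlarged,
                   roi_mask=BinaryMask.from_bool(mask))


def disk_mask(center: tuple[float, float], radius: float,
              shape: tuple[int, int]) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def detect_humeral_circle(image: Image2D, r_min: int | None = None,
                          r_max: int | None = None,
                          enlargement: float = DEFAULT_ENLARGEMENT) -> CircleROI:
    """Detect the humeral head circle on a Canny edge map.

    Radii are searched over ``[r_min, r_max]`` (defaults 0.1 and 0.4 of
    the shorter image side). Ties among equal accumulator peaks break
    deterministically: largest radius, then smallest row, then smallest
    col. Raises :class:`DetectionFailure` when no circle reaches the
    support threshold (e.g. a blank image).
    """
    h, w = image.shape
    short = min(h, w)
    if r_min is None:
        r_min = max(2, int(round(0.1 * short)))
    if r_max is None:
        r_max = int(round(0.4 * short))
    if not (2 <= r_min < r_max <= short // 2):
        raise ValueError(f"invalid radius range [{r_min}, {r_max}] for shape {image.shape}")

    arr = image.pixels
    span = arr.max() - arr.min()
    if span <= 0:
        raise DetectionFailure("blank image: no edges")
    norm = (arr - arr.min()) / span
    edges = canny(norm, sigma=2.0)
    if not edges.any():
        raise DetectionFailure("no edges detected")

    radii = np.arange(r_min, r_max + 1)
    accum = hough_circle(edges, radii, normalize=True, full_output=False)
    peak = float(accum.max())
    if peak < _PEAK_THRESHOLD:
        raise DetectionFailure(f"best accumulator peak {peak:.3f} below threshold")

    # deterministic tie-break among near-equal peaks
    cand = np.argwhere(accum >= peak - 1e-12)
    order = np.lexsort((cand[:, 2], cand[:, 1], -cand[:, 0]))
    ri, row, col = cand[order[0]]
    radius = int(radii[ri])
    return CircleROI.from_circle((int(row), int(col)), float(radius), image.shape,
                                 enlargement=enlargement)


def initial_level_set(roi: CircleROI, shape: tuple[int, int],
                      epsilon: float = 1.5) -> LevelSetField:
    """Signed distance to a circle at half the detected radius.

    phi > 0 inside the initial circle (so phi at the ROI center equals
    +0.5 * radius), placing the initial contour strictly inside the
    bone — a start position suiting both the global ACWE model and the
    local SPF model.
    """
    r0 = 0.5 * roi.radius
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.sqrt((rr - roi.center[0]) ** 2 + (cc - roi.center[1]) ** 2)
    return LevelSetField(phi=r0 - dist, epsilon=epsilon)
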