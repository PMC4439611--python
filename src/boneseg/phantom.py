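"""Synthetic axial-shoulder phantoms with ground truth.

No public PD-weighted shoulder dataset exists, so the package ships a
seeded generator that emulates the structures a real axial slice
presents to the pipeline: a bright quasi-circular humeral head on a
dark background, an optional hyperintense edema blob inside the head,
an optional cortical notch (Hill-Sachs compression) carved from the
head, an adjacent scapula arc and a tendon band of bone-like intensity
on the shoulder side, a smooth multiplicative low-frequency bias field
(two seeded cosine modes), partial-volume blur of the scene (PD slices
show a smooth transition zone between bone and soft tissue, not a step
edge), and Rician noise built from its two-channel Gaussian definition

    out = sqrt((clean + g1*sigma)^2 + (g2*sigma)^2).

Default conditions are the standard test slice: 256 x 256 pixels, head
radius 45, head/background intensities 180/20 MR units, Rician sigma
at 10% of the head intensity and bias amplitude 0.3. The ground truth
is the head including edema and excluding the notch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .hough_roi import disk_mask
from .io_types import BinaryMask, Image2D

__all__ = ["EdemaSpec", "NotchSpec", "ScapulaSpec", "TendonSpec", "BiasSpec",
           "PhantomSpec", "make_phantom", "make_cohort"]


@dataclass
class EdemaSpec:
    """Hyperintense blob inside the head (post-traumatic bone edema).

    Edema sits peripherally in the head (near the impact site) and
    smears the adjacent bone border: the scene is additionally blurred
    with ``border_blur_sigma`` inside a margin around the blob.
    """
    center_offset: tuple[float, float] = (8.0, -26.0)  # (drow, dcol) from head center
    radius: float = 12.0
    intensity_multiplier: float = 1.5
    border_blur_sigma: float = 4.0
    border_blur_margin: float = 6.0


@dataclass
class NotchSpec:
    """Hill-Sachs compression: a circular bite carved from the head rim.

    ``depth_fraction`` is the bite radius as a fraction of the head
    radius; the bite center sits on the head circle at ``angle``
    (radians, CCW from +col). The compressed zone is not an empty void:
    it fills with joint fluid and reactive edema (``fill_fraction`` x
    head intensity, hyperintense like edema) and the fracture border is
    smeared (``rim_blur_sigma``), so its segmentation contrast is poor
    and its intensity distribution differs from intact bone.
    """
    angle: float = np.pi / 3
    depth_fraction: float = 0.3
    fill_fraction: float = 1.3
    rim_blur_sigma: float = 3.0
    rim_blur_margin: float = 5.0


@dataclass
class ScapulaSpec:
    """Annular arc of bone-like intensity on the shoulder side.

    ``gap`` is the radial joint space separating the arc from the head
    surface. ``bridge_width`` > 0 adds a narrow radial connector of arc
    intensity at the arc's center angle, emulating a contact point that
    fuses head and scapula in the raw segmentation (the case the
    postprocessing erosion is built to cut).
    """
    gap: float = 6.0            # radial joint space to the head surface, px
    thickness: float = 6.0
    span: float = np.deg2rad(100.0)
    intensity: float = 170.0
    bridge_width: float = 0.0   # px; 0 = no contact bridge


@dataclass
class TendonSpec:
    """Band of tendon tissue running from the head toward the side border."""
    width: float = 8.0
    intensity: float = 160.0
    gap: float = 4.0
    row_offset_frac: float = 0.5  # band row = head row + frac * radius


@dataclass
class BiasSpec:
    """Smooth multiplicative field 1 + amplitude * s(x, y), |s| <= 1."""
    amplitude: float = 0.3
    smooth_scale: float = 1.0   # spatial periods across the image per mode

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude < 1.0):
            raise ValueError("bias amplitude must be in [0, 1)")


@dataclass
class PhantomSpec:
    size: tuple[int, int] = (256, 256)
    side: str = "left"
    head_center: tuple[float, float] = (128.0, 128.0)
    head_radius: float = 45.0
    head_intensity: float = 180.0
    background_intensity: float = 20.0
    edema: Optional[EdemaSpec] = None
    notch: Optional[NotchSpec] = None
    scapula: Optional[ScapulaSpec] = field(default_factory=ScapulaSpec)
    tendon: Optional[TendonSpec] = field(default_factory=TendonSpec)
    bias: BiasSpec = field(default_factory=BiasSpec)
    # the head is quasi-circular, not an exact circle: low-order radial
    # harmonics r(theta) = r0 * (1 + sum a_k cos(k theta + phase))
    shape_harmonics: tuple = ((3, 0.02, 0.7), (5, 0.015, 2.1), (8, 0.01, 4.0))
    blur_sigma: float = 2.0     # partial-volume smoothing of the clean scene, px
    noise_sigma: float = 18.0   # Rician sigma; default 10% of head intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")
        r, c = self.head_center
        h, w = self.size
        rad = self.head_radius
        if not (rad < r < h - rad and rad < c < w - rad):
            raise ValueError("head must lie fully inside the image")
        if self.head_intensity <= 0 or self.background_intensity <= 0:
            raise ValueError("intensities must be positive")


def _bias_field(shape: tuple[int, int], bias: BiasSpec, rng: np.random.Generator
                ) -> np.ndarray:
    if bias.amplitude == 0:
        return np.ones(shape)
    h, w = shape
    rr = np.arange(h)[:, None] / h
    cc = np.arange(w)[None, :] / w
    k = bias.smooth_scale
    ph = rng.uniform(0, 2 * np.pi, size=4)
    s = (np.cos(2 * np.pi * k * rr + ph[0]) * np.cos(2 * np.pi * k * cc + ph[1])
         + np.cos(2 * np.pi * k * (rr + cc) / 2 + ph[2] + ph[3]))
    s = s / np.max(np.abs(s))
    return 1.0 + bias.amplitude * s


def _head_mask(spec: PhantomSpec) -> np.ndarray:
    """Quasi-circular head: disk with low-order radial harmonics."""
    h, w = spec.size
    rr, cc = np.ogrid[:h, :w]
    dr = rr - spec.head_center[0]
    dc = cc - spec.head_center[1]
    dist = np.sqrt(dr**2 + dc**2)
    theta = np.arctan2(-dr, dc)
    radius = np.full((h, w), float(spec.head_radius))
    for k, amp, phase in spec.shape_harmonics:
        radius = radius + spec.head_radius * amp * np.cos(k * theta + phase)
    return dist <= radius


def _clean_scene(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    h, w = spec.size
    img = np.full((h, w), spec.background_intensity, dtype=float)
    head = _head_mask(spec)

    bite = None
    if spec.notch is not None:
        br = spec.notch.depth_fraction * spec.head_radius
        ang = spec.notch.angle
        bc = (spec.head_center[0] - spec.head_radius * np.sin(ang),
              spec.head_center[1] + spec.head_radius * np.cos(ang))
        bite = disk_mask(bc, br, (h, w)) & head
        head = head & ~bite

    img[head] = spec.head_intensity
    if bite is not None:
        img[bite] = spec.notch.fill_fraction * spec.head_intensity
    truth = head.copy()

    if spec.edema is not None:
        ec = (spec.head_center[0] + spec.edema.center_offset[0],
              spec.head_center[1] + spec.edema.center_offset[1])
        blob = disk_mask(ec, spec.edema.radius, (h, w)) & head
        img[blob] = spec.edema.intensity_multiplier * spec.head_intensity
        truth |= blob  # already subset of head; edema belongs to the bone

    toward = np.pi if spec.side == "left" else 0.0
    if spec.scapula is not None:
        sc = spec.scapula
        rr, cc = np.ogrid[:h, :w]
        dist = np.sqrt((rr - spec.head_center[0]) ** 2 + (cc - spec.head_center[1]) ** 2)
        ang = np.arctan2(-(rr - spec.head_center[0]), cc - spec.head_center[1])
        rel = np.mod(ang - (toward - sc.span / 2), 2 * np.pi)
        r0 = spec.head_radius + sc.gap
        arc = ((dist >= r0) & (dist <= r0 + sc.thickness) & (rel <= sc.span))
        if sc.bridge_width > 0:
            # radial connector at the arc's center angle (head-scapula contact)
            mid = toward
            u_r = -np.sin(mid)   # unit vector, (row, col) screen convention
            u_c = np.cos(mid)
            along = (rr - spec.head_center[0]) * u_r + (cc - spec.head_center[1]) * u_c
            across = -(rr - spec.head_center[0]) * u_c + (cc - spec.head_center[1]) * u_r
            bridge = ((np.abs(across) <= sc.bridge_width / 2)
                      & (along >= spec.head_radius - 1) & (along <= r0 + 1))
            arc = arc | bridge
        img[arc & ~head] = sc.intensity

    if spec.tendon is not None:
        td = spec.tendon
        row0 = spec.head_center[0] + td.row_offset_frac * spec.head_radius
        band = np.zeros((h, w), dtype=bool)
        r_lo = int(round(row0 - td.width / 2))
        r_hi = int(round(row0 + td.width / 2))
        band[max(r_lo, 0): min(r_hi, h)] = True
        keep_out = disk_mask(spec.head_center, spec.head_radius + td.gap, (h, w))
        if spec.side == "left":
            band[:, int(spec.head_center[1]):] = False
        else:
            band[:, : int(spec.head_center[1])] = False
        band &= ~keep_out
        img[band] = td.intensity

    return img, truth


def make_phantom(spec: PhantomSpec | None = None) -> tuple[Image2D, BinaryMask]:
    """Render a phantom slice and its ground-truth head mask.

    The clean scene is multiplied by the bias field, then corrupted with
    Rician noise; identical seeds give bit-identical outputs.
    """
    spec = spec or PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    clean, truth = _clean_scene(spec)
    if spec.notch is not None and spec.notch.rim_blur_sigma > 0:
        br = spec.notch.depth_fraction * spec.head_radius
        ang = spec.notch.angle
        bc = (spec.head_center[0] - spec.head_radius * np.sin(ang),
              spec.head_center[1] + spec.head_radius * np.cos(ang))
        zone = disk_mask(bc, br + spec.notch.rim_blur_margin, spec.size)
        smeared = ndi.gaussian_filter(clean, spec.notch.rim_blur_sigma)
        clean = np.where(zone, smeared, clean)
    if spec.edema is not None and spec.edema.border_blur_sigma > 0:
        ec = (spec.head_center[0] + spec.edema.center_offset[0],
              spec.head_center[1] + spec.edema.center_offset[1])
        zone = disk_mask(ec, spec.edema.radius + spec.edema.border_blur_margin,
                         spec.size)
        smeared = ndi.gaussian_filter(clean, spec.edema.border_blur_sigma)
        clean = np.where(zone, smeared, clean)
    if spec.blur_sigma > 0:
        clean = ndi.gaussian_filter(clean, spec.blur_sigma)
    biased = clean * _bias_field(spec.size, spec.bias, rng)
    if spec.noise_sigma > 0:
        g1 = rng.standard_normal(spec.size)
        g2 = rng.standard_normal(spec.size)
        out = np.sqrt((biased + g1 * spec.noise_sigma) ** 2
                      + (g2 * spec.noise_sigma) ** 2)
    else:
        out = biased
    return Image2D(out), BinaryMask.from_bool(truth)


def make_cohort(n_normal: int, n_edema: int, n_notch: int, seed: int = 0,
                base: PhantomSpec | None = None
                ) -> list[tuple[Image2D, BinaryMask, str]]:
    """Seeded cohort with per-case parameter jitter.

    Radius jitters by +/-15%, intensities by +/-10%; the edema blob is
    drawn peripherally in the head and the notch angle inside the
    shoulder-facing half. Groups: ``normal``, ``edema``, ``hill_sachs``.
    """
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    cases: list[tuple[Image2D, BinaryMask, str]] = []
    plan = (["normal"] * n_normal + ["edema"] * n_edema + ["hill_sachs"] * n_notch)
    for i, group in enumerate(plan):
        radius = base.head_radius * rng.uniform(0.85, 1.15)
        harmonics = tuple((k, amp, rng.uniform(0, 2 * np.pi))
                          for k, amp, _ in base.shape_harmonics)
        head_i = base.head_intensity * rng.uniform(0.9, 1.1)
        bg_i = base.background_intensity * rng.uniform(0.9, 1.1)
        edema = None
        notch = None
        if group == "edema":
            # amount and distribution of edema vary widely case to case
            er = radius * rng.uniform(0.2, 0.5)
            theta = rng.uniform(0, 2 * np.pi)
            # peripheral placement: post-traumatic edema sits near the rim
            rho = rng.uniform(max(radius - 1.5 * er, 0.5 * radius), radius - 0.5 * er)
            edema = EdemaSpec(center_offset=(rho * np.sin(theta), rho * np.cos(theta)),
                              radius=er,
                              intensity_multiplier=rng.uniform(1.4, 1.6))
        elif group == "hill_sachs":
            toward = np.pi if base.side == "left" else 0.0
            notch = NotchSpec(angle=toward + rng.uniform(-np.pi / 2, np.pi / 2),
                              depth_fraction=rng.uniform(0.2, 0.35))
        spec = replace(base,
                       head_radius=radius,
                       shape_harmonics=harmonics,
                       head_intensity=head_i,
                       background_intensity=bg_i,
                       noise_sigma=base.noise_sigma * head_i / base.head_intensity,
                       edema=edema,
                       notch=notch,
                       seed=int(rng.integers(0, 2**31 - 1)))
        img, truth = make_phantom(spec)
        cases.append((img, truth, group))
    return cases
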