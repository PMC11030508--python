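"""Whole-organoid and rosette morphometrics from binary masks.

Shape metrics follow common image-analysis definitions: area, equivalent
diameter √(4A/π), perimeter, circularity 4πA/P², solidity A/A_hull, and
aspect ratio from the moment-matched ellipse.  The perimeter is measured on
the smoothed marching-squares boundary rather than by pixel-edge counting —
raw edge counting overestimates P by up to 4/π and would push ideal disks
far below circularity 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import find_contours, label, regionprops

__all__ = [
    "ShapeMetrics",
    "RosetteRecord",
    "boundary_perimeter",
    "compute_shape_metrics",
    "compute_rosette_metrics",
    "count_rosettes",
]


@dataclass
class ShapeMetrics:
    """Six shape descriptors of a single binary region (µm units)."""

    area: float
    equivalent_diameter: float
    perimeter: float
    circularity: float
    solidity: float
    aspect_ratio: float
    feret_diameter: float


@dataclass
class RosetteRecord:
    """Rosette/lumen shape pairing with lumen-centeredness measures."""

    rosette: ShapeMetrics
    lumen: ShapeMetrics
    rosette_circularity: float
    lumen_circularity: float
    centeredness_um: float
    centeredness_normalized: float


def boundary_perimeter(mask: np.ndarray, smooth_window: int | None = None) -> float:
    """Boundary length of ``mask`` in pixels via smoothed sub-pixel contours.

    Marching-squares contours at the 0.5 level are circularly smoothed with a
    short moving average before summing segment lengths; this removes the
    pixelation staircase (which inflates smooth boundaries ~5%) while leaving
    straight edges essentially exact.  The window scales mildly with contour
    length so the estimate is stable under image upsampling.
    """
    mask = np.asarray(mask, dtype=bool)
    total = 0.0
    for c in find_contours(np.pad(mask.astype(float), 1), 0.5):
        closed = np.allclose(c[0], c[-1])
        pts = c[:-1] if closed else c
        n = len(pts)
        w = smooth_window if smooth_window is not None else max(5, n // 64)
        if closed and n >= w + 2:
            k = np.ones(w) / w
            sm = np.stack(
                [
                    np.convolve(np.r_[pts[-w:, i], pts[:, i], pts[:w, i]], k, "same")[
                        w:-w
                    ]
                    for i in (0, 1)
                ],
                axis=1,
            )
            d = np.diff(np.vstack([sm, sm[:1]]), axis=0)
        else:
            d = np.diff(c, axis=0)
        total += np.hypot(d[:, 0], d[:, 1]).sum()
    return total


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab = label(mask, connectivity=2)
    n = lab.max()
    if n == 0:
        raise ValueError("mask is empty")
    if n > 1:
        warnings.warn(
            f"mask has {n} components; keeping the largest", stacklevel=3
        )
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        mask = lab == sizes.argmax()
    return mask


def compute_shape_metrics(mask: np.ndarray, pixel_size: float = 1.0) -> ShapeMetrics:
    """Compute the six shape metrics of a single-component binary mask.

    Multi-component masks keep the largest component (with a warning);
    empty masks raise ``ValueError``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    mask = _largest_component(np.asarray(mask, dtype=bool))
    props = regionprops(mask.astype(np.uint8))[0]
    area_px = props.area
    per_px = boundary_perimeter(mask)
    circ = min(1.0, 4.0 * np.pi * area_px / per_px**2) if per_px > 0 else 0.0
    minor = props.axis_minor_length
    aspect = props.axis_major_length / minor if minor > 0 else np.inf
    return ShapeMetrics(
        area=area_px * pixel_size**2,
        equivalent_diameter=float(np.sqrt(4.0 * area_px / np.pi)) * pixel_size,
        perimeter=per_px * pixel_size,
        circularity=float(circ),
        solidity=float(props.solidity),
        aspect_ratio=float(aspect),
        feret_diameter=float(props.feret_diameter_max) * pixel_size,
    )


def _centroid(mask: np.ndarray) -> np.ndarray:
    return np.array(ndi.center_of_mass(mask))


def compute_rosette_metrics(
    rosette_mask: np.ndarray, lumen_mask: np.ndarray, pixel_size: float = 1.0
) -> RosetteRecord:
    """Circularities plus lumen centeredness for one rosette/lumen pair.

    Centeredness is the Euclidean distance between the rosette centroid and
    the lumen centroid (µm); the normalized form divides by the rosette's
    equivalent radius.  The lumen must lie within the rosette region (the
    filled rosette footprint: a lumen is interior by definition).
    """
    rosette_mask = np.asarray(rosette_mask, dtype=bool)
    lumen_mask = np.asarray(lumen_mask, dtype=bool)
    if rosette_mask.shape != lumen_mask.shape:
        raise ValueError("rosette and lumen masks incongruent")
    filled = ndi.binary_fill_holes(rosette_mask)
    if np.any(lumen_mask & ~filled):
        raise ValueError("lumen mask extends outside the rosette region")
    ros = compute_shape_metrics(rosette_mask, pixel_size)
    lum = compute_shape_metrics(lumen_mask, pixel_size)
    dist_px = float(np.linalg.norm(_centroid(rosette_mask) - _centroid(lumen_mask)))
    eq_radius = ros.equivalent_diameter / 2.0
    return RosetteRecord(
        rosette=ros,
        lumen=lum,
        rosette_circularity=ros.circularity,
        lumen_circularity=lum.circularity,
        centeredness_um=dist_px * pixel_size,
        centeredness_normalized=dist_px * pixel_size / eq_radius,
    )


def count_rosettes(rosette_mask: np.ndarray, connectivity: int = 2) -> int:
    """Number of connected rosette components in a field of view.

    Touching rosettes merge into one component under the default
    8-connectivity and are counted once (a warning is emitted when any
    component looks like a merger, i.e. none here — counting is purely
    component-based).
    """
    lab = label(np.asarray(rosette_mask, dtype=bool), connectivity=connectivity)
    return int(lab.max())
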