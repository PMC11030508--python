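"""Oil-Red-O / Hematoxylin histology quantification.

RGB transmission images are converted to optical density per Beer–Lambert,
unmixed into per-stain density maps by inverting a stain matrix whose
columns are unit OD vectors (Ruifrok–Johnston color deconvolution), and the
red (ORO) density is thresholded and counted as lipid particles normalized
by tissue area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "StainMatrix",
    "ParticleStats",
    "DEFAULT_STAIN_MATRIX",
    "rgb_to_od",
    "od_to_rgb",
    "densities_to_rgb",
    "color_deconvolve",
    "threshold_and_count",
]


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


#: FastRed / FastBlue OD vectors from the standard published color
#: deconvolution vector set (ImageJ preset), plus an orthogonal residual.
_FASTRED = _unit([0.21393921, 0.85112669, 0.47794022])
_FASTBLUE = _unit([0.74890292, 0.60624161, 0.26731082])


@dataclass(frozen=True)
class StainMatrix:
    """3×3 matrix of unit OD column vectors: red stain, blue stain, residual."""

    red: np.ndarray
    blue: np.ndarray
    residual: np.ndarray | None = None

    @classmethod
    def fastred_fastblue(cls) -> "StainMatrix":
        return cls(red=_FASTRED.copy(), blue=_FASTBLUE.copy())

    def as_array(self) -> np.ndarray:
        red, blue = _unit(self.red), _unit(self.blue)
        if self.residual is None:
            res = np.cross(red, blue)
            nrm = np.linalg.norm(res)
            if nrm < 1e-9:
                raise ValueError("stain vectors are collinear")
            res = res / nrm
        else:
            res = _unit(self.residual)
        m = np.column_stack([red, blue, res])
        if abs(np.linalg.det(m)) < 1e-9:
            raise ValueError("stain matrix is singular")
        return m


DEFAULT_STAIN_MATRIX = StainMatrix.fastred_fastblue().as_array()


@dataclass
class ParticleStats:
    """ORO particle quantification for one image."""

    particle_count: int
    positive_pixels: int
    tissue_pixels: int
    normalized_density: float
    threshold: float


def rgb_to_od(image: np.ndarray, intensity_ceiling: float = 255.0) -> np.ndarray:
    """Beer–Lambert conversion OD = −log10(I / I0) per channel.

    Zero intensities are clipped to one count (or 1e-6 for unit-scale
    images) so the logarithm stays finite; saturated black pixels therefore
    map to the maximum representable OD rather than infinity.
    """
    img = np.asarray(image, dtype=np.float64)
    if np.any(img > intensity_ceiling):
        raise ValueError("intensities exceed the stated ceiling")
    img = np.clip(img, 1.0 if intensity_ceiling > 1.0 else 1e-6, None)
    return -np.log10(img / intensity_ceiling)


def od_to_rgb(od: np.ndarray, intensity_ceiling: float = 255.0) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`: I = I0 · 10^(−OD)."""
    return intensity_ceiling * np.power(10.0, -np.asarray(od, dtype=np.float64))


def densities_to_rgb(
    red_density: np.ndarray,
    blue_density: np.ndarray,
    matrix: np.ndarray | StainMatrix | None = None,
    intensity_ceiling: float = 255.0,
) -> np.ndarray:
    """Mix per-stain densities into a transmitted-light RGB image."""
    if np.any(np.asarray(red_density) < 0) or np.any(np.asarray(blue_density) < 0):
        raise ValueError("stain densities must be >= 0")
    m = _as_matrix(matrix)
    d = np.stack([red_density, blue_density, np.zeros_like(red_density)], axis=-1)
    od = d @ m.T
    return od_to_rgb(od, intensity_ceiling)


def _as_matrix(matrix) -> np.ndarray:
    if matrix is None:
        return DEFAULT_STAIN_MATRIX
    if isinstance(matrix, StainMatrix):
        return matrix.as_array()
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3) or abs(np.linalg.det(m)) < 1e-9:
        raise ValueError("stain matrix must be an invertible 3x3 array")
    return m


def color_deconvolve(
    od_image: np.ndarray, matrix: np.ndarray | StainMatrix | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unmix an OD image into (red, blue, residual) density maps."""
    m = _as_matrix(matrix)
    inv = np.linalg.inv(m)
    d = od_image @ inv.T
    return d[..., 0], d[..., 1], d[..., 2]


def threshold_and_count(
    red_density: np.ndarray,
    tissue_mask: np.ndarray,
    threshold: float | None = None,
    min_particle_px: int = 4,
    connectivity: int = 2,
    closing_px: int = 0,
) -> ParticleStats:
    """Threshold the red-stain density and count particles inside tissue.

    ``threshold=None`` selects Otsu's threshold on the within-tissue red
    density.  Components smaller than ``min_particle_px`` are discarded;
    8-connectivity by default (``connectivity=2``).  ``closing_px > 0``
    applies a binary closing of that radius before labelling, merging
    particles separated by sub-resolution gaps.
    """
    red = np.asarray(red_density, dtype=float)
    tissue = np.asarray(tissue_mask, dtype=bool)
    if red.shape != tissue.shape:
        raise ValueError("density map incongruent with tissue mask")
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue mask is empty")
    if threshold is None:
        from skimage.filters import threshold_otsu

        vals = red[tissue]
        threshold = float(threshold_otsu(vals)) if vals.ptp() > 0 else np.inf
    positive = (red >= threshold) & tissue
    if closing_px > 0:
        from skimage.morphology import disk as _disk

        positive = ndi.binary_closing(positive, structure=_disk(closing_px))
    structure = ndi.generate_binary_structure(2, connectivity)
    lab, n_comp = ndi.label(positive, structure=structure)
    if n_comp and min_particle_px > 1:
        sizes = np.bincount(lab.ravel())
        small = np.flatnonzero(sizes < min_particle_px)
        small = small[small > 0]
        if small.size:
            positive &= ~np.isin(lab, small)
            lab, n_comp = ndi.label(positive, structure=structure)
    n_pos = int(positive.sum())
    return ParticleStats(
        particle_count=int(n_comp),
        positive_pixels=n_pos,
        tissue_pixels=n_tissue,
        normalized_density=n_pos / n_tissue,
        threshold=float(threshold),
    )
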