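"""Synthetic organoid phantoms and forward simulation of the imaging chain.

Ground-truth phantoms are 2D refractive-index sections of a neural organoid:
an elliptical body of cytoplasm containing neural rosettes (radial cell
arrangements around a lumen), fissures flanked by elongated "directional"
cells, scattered nuclei, and high-RI lipid droplets.  Every placed structure
is recorded in an integer label map, so downstream metrics can always be
checked against construction-time truth.

The acquisition simulator shares its phase transfer function with the
reconstruction module (:mod:`organoidqpi.recon`): phantom refractive index is
converted to optical phase, forward-projected to two orthogonal differential
phase contrast channels, and emitted as four oblique-illumination intensity
frames with configurable shot-to-shot Gaussian noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .recon import PhaseTransferModel, RawFrameSet, forward_project
from .ri import OpticalConfig, ri_to_phase

# Compartment label codes (stable public contract).
LABELS = {
    "background": 0,
    "cytoplasm": 1,
    "rosette": 2,
    "lumen": 3,
    "droplet": 4,
    "directional_cell": 5,
    "fissure": 6,
    "nucleus": 7,
}

#: Default refractive index per compartment.  The medium value is the PDMS
#: scattering medium used as imaging background (1.3440); droplets sit above
#: the lipid/nucleic segmentation threshold of 1.46, everything else below.
DEFAULT_COMPARTMENT_RI: Mapping[str, float] = {
    "background": 1.3440,
    "medium": 1.3440,
    "cytoplasm": 1.3600,
    "rosette": 1.3700,
    "lumen": 1.3480,
    "droplet": 1.5000,
    "directional_cell": 1.3850,
    "fissure": 1.3500,
    "nucleus": 1.3950,
}

RI_SEGMENTATION_THRESHOLD = 1.46


class PlacementError(RuntimeError):
    """Raised when requested structure density cannot be realized."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic organoid section.

    Lengths are in µm; densities in cells/mm²; ``droplet_area_fraction`` is
    the target fraction of organoid pixels labelled droplet.
    """

    image_size: int = 512
    pixel_size: float = 1.0
    organoid_axes: tuple[float, float] = (220.0, 185.0)
    rosette_count: int = 5
    rosette_radius_range: tuple[float, float] = (25.0, 40.0)
    lumen_offset_fraction: float = 0.0
    fissure_count: int = 3
    directional_cell_density: float = 3000.0
    directional_cell_aspect: float = 2.5
    directional_cell_length: float = 18.0
    nucleus_density: float = 600.0
    droplet_area_fraction: float = 0.02
    droplet_diameter_range: tuple[float, float] = (3.0, 8.0)
    compartment_ri: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPARTMENT_RI)
    )
    texture_amplitude: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.image_size < 16:
            raise ValueError("image_size too small")
        if not (0.0 <= self.lumen_offset_fraction < 1.0):
            raise ValueError("lumen_offset_fraction must be in [0, 1)")
        if not (0.0 <= self.droplet_area_fraction <= 0.3):
            raise ValueError("droplet_area_fraction must be in [0, 0.3]")
        if self.directional_cell_aspect < 1.0:
            raise ValueError("directional_cell_aspect must be >= 1")
        ri = self.compartment_ri
        if ri["droplet"] <= RI_SEGMENTATION_THRESHOLD:
            raise ValueError("droplet RI must exceed the segmentation threshold")
        if ri.get("medium", ri["background"]) >= RI_SEGMENTATION_THRESHOLD:
            raise ValueError("medium RI must lie below the segmentation threshold")


@dataclass
class GroundTruthPhantom:
    """Compartment-labelled refractive-index map of one organoid section."""

    ri_map: np.ndarray
    labels: np.ndarray
    spec: PhantomSpec

    @property
    def organoid_mask(self) -> np.ndarray:
        return self.labels != LABELS["background"]

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]

    def droplet_fraction(self) -> float:
        """Droplet pixels as a fraction of organoid pixels."""
        org = int(self.organoid_mask.sum())
        if org == 0:
            return 0.0
        return float(self.label_mask("droplet").sum()) / org


@dataclass(frozen=True)
class AcquisitionSpec:
    """Optical acquisition parameters of the four-frame oblique setup.

    Four LED sources at 90° spacing illuminate along ±x and ±y; the section
    thickness ``dz`` sets the phase accumulated per unit refractive-index
    contrast.  ``snr_db`` is the intensity signal-to-noise ratio of a flat
    background region (additive Gaussian model); ``None`` disables noise.
    """

    wavelength_nm: float = 720.0
    dz_um: float = 2.5
    numerical_aperture: float = 0.45
    gain: float = 0.3
    background: float = 1.0
    snr_db: float | None = 20.0
    poisson: bool = False

    def transfer_model(self) -> PhaseTransferModel:
        return PhaseTransferModel(
            wavelength_nm=self.wavelength_nm,
            numerical_aperture=self.numerical_aperture,
            gain=self.gain,
        )

    def optical_config(self, n_medium: float = 1.3440) -> OpticalConfig:
        return OpticalConfig(
            wavelength_nm=self.wavelength_nm, dz_um=self.dz_um, n_medium=n_medium
        )


# ---------------------------------------------------------------------------
# phantom construction helpers


def _stamp_ellipse(labels, r, c, r_rad, c_rad, rotation, code, allowed):
    rr, cc = draw_ellipse(
        r, c, r_rad, c_rad, shape=labels.shape, rotation=rotation
    )
    keep = np.isin(labels[rr, cc], allowed)
    labels[rr[keep], cc[keep]] = code


def _fissure_polyline(rng, center, radius_px, n_seg=4):
    """Random smooth polyline crossing the organoid interior."""
    theta = rng.uniform(0, 2 * np.pi)
    # chord endpoints at ~80% radius, perturbed midpoints
    p0 = center + 0.8 * radius_px * np.array([np.cos(theta), np.sin(theta)])
    p1 = center + 0.8 * radius_px * np.array(
        [np.cos(theta + np.pi + rng.uniform(-0.5, 0.5)),
         np.sin(theta + np.pi + rng.uniform(-0.5, 0.5))]
    )
    ts = np.linspace(0, 1, n_seg + 1)
    pts = np.outer(1 - ts, p0) + np.outer(ts, p1)
    normal = np.array([-(p1 - p0)[1], (p1 - p0)[0]])
    normal = normal / (np.linalg.norm(normal) + 1e-12)
    for i in range(1, n_seg):
        pts[i] += normal * rng.normal(0, 0.08 * radius_px)
    return pts


def generate_organoid_phantom(spec: PhantomSpec) -> GroundTruthPhantom:
    """Build a compartment-labelled RI phantom from ``spec``.

    Deterministic under ``spec.seed``.  Raises :class:`PlacementError` when a
    requested structure count/density cannot be placed within the organoid.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size
    px = spec.pixel_size
    labels = np.zeros((n, n), dtype=np.uint8)

    center = np.array([n / 2.0, n / 2.0])
    ax_r, ax_c = (a / px for a in spec.organoid_axes)
    ax_r = min(ax_r, n / 2 - 2)
    ax_c = min(ax_c, n / 2 - 2)
    rr, cc = draw_ellipse(center[0], center[1], ax_r, ax_c, shape=labels.shape)
    labels[rr, cc] = LABELS["cytoplasm"]
    organoid_area_px = len(rr)
    mean_radius_px = math.sqrt(ax_r * ax_c)

    # --- fissures + directional cells -------------------------------------
    band_halfwidth_um = 10.0
    cell_len_px = spec.directional_cell_length / px
    cell_wid_px = cell_len_px / spec.directional_cell_aspect
    for _ in range(spec.fissure_count):
        pts = _fissure_polyline(rng, center, mean_radius_px)
        seg_vecs = np.diff(pts, axis=0)
        seg_lens = np.linalg.norm(seg_vecs, axis=1)
        total_len_um = seg_lens.sum() * px
        band_area_mm2 = total_len_um * 2 * band_halfwidth_um / 1e6
        n_cells = rng.poisson(spec.directional_cell_density * band_area_mm2)
        # flanking directional cells, aligned with the local tangent
        for _ in range(n_cells):
            i = rng.choice(len(seg_lens), p=seg_lens / seg_lens.sum())
            t = rng.uniform()
            pos = pts[i] + t * seg_vecs[i]
            tangent = seg_vecs[i] / (seg_lens[i] + 1e-12)
            normal = np.array([-tangent[1], tangent[0]])
            offset = rng.uniform(-band_halfwidth_um, band_halfwidth_um) / px
            pos = pos + normal * offset
            ang = math.atan2(tangent[0], tangent[1]) + rng.normal(0, 0.15)
            _stamp_ellipse(
                labels, pos[0], pos[1], cell_wid_px / 2, cell_len_px / 2,
                -ang, LABELS["directional_cell"], (LABELS["cytoplasm"],),
            )
        # fissure cleft on top of the cells
        fissure_w = max(1, int(round(2.0 / px)))
        for i in range(len(seg_vecs)):
            npts = max(2, int(seg_lens[i]) * 2)
            for t in np.linspace(0, 1, npts):
                p = pts[i] + t * seg_vecs[i]
                r0, c0 = int(round(p[0])), int(round(p[1]))
                sl = labels[
                    max(r0 - fissure_w // 2, 0): r0 + (fissure_w + 1) // 2,
                    max(c0 - fissure_w // 2, 0): c0 + (fissure_w + 1) // 2,
                ]
                sl[np.isin(sl, (LABELS["cytoplasm"], LABELS["directional_cell"]))] = (
                    LABELS["fissure"]
                )

    # --- rosettes ----------------------------------------------------------
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < spec.rosette_count:
        attempts += 1
        if attempts > 400 * max(spec.rosette_count, 1):
            raise PlacementError(
                f"could not place {spec.rosette_count} rosettes of radius "
                f"{spec.rosette_radius_range} µm inside organoid"
            )
        r_um = rng.uniform(*spec.rosette_radius_range)
        r_px = r_um / px
        # position inside the organoid ellipse with margin
        u = rng.uniform(0, 2 * np.pi)
        rad = math.sqrt(rng.uniform()) * 0.95
        pos = center + np.array(
            [rad * (ax_r - r_px - 2) * np.cos(u), rad * (ax_c - r_px - 2) * np.sin(u)]
        )
        if ((pos[0] - center[0]) / max(ax_r - r_px - 1, 1)) ** 2 + (
            (pos[1] - center[1]) / max(ax_c - r_px - 1, 1)
        ) ** 2 > 1:
            continue
        if any(
            np.hypot(pos[0] - q[0], pos[1] - q[1]) < r_px + q[2] + 3 for q in placed
        ):
            continue
        placed.append((pos[0], pos[1], r_px))
        rr, cc = draw_disk((pos[0], pos[1]), r_px, shape=labels.shape)
        labels[rr, cc] = LABELS["rosette"]
        # lumen, offset along a random direction by the requested fraction
        lum_r = 0.35 * r_px
        off = spec.lumen_offset_fraction * (r_px - lum_r)
        ang = rng.uniform(0, 2 * np.pi)
        lum_pos = (pos[0] + off * np.cos(ang), pos[1] + off * np.sin(ang))
        rr, cc = draw_disk(lum_pos, lum_r, shape=labels.shape)
        keep = labels[rr, cc] == LABELS["rosette"]
        labels[rr[keep], cc[keep]] = LABELS["lumen"]

    # --- nuclei ------------------------------------------------------------
    area_mm2 = organoid_area_px * px * px / 1e6
    n_nuc = rng.poisson(spec.nucleus_density * area_mm2)
    nuc_r_px = 3.0 / px
    for _ in range(n_nuc):
        u = rng.uniform(0, 2 * np.pi)
        rad = math.sqrt(rng.uniform())
        pos = (
            center[0] + rad * (ax_r - nuc_r_px - 1) * np.cos(u),
            center[1] + rad * (ax_c - nuc_r_px - 1) * np.sin(u),
        )
        rr, cc = draw_disk(pos, nuc_r_px, shape=labels.shape)
        keep = labels[rr, cc] == LABELS["cytoplasm"]
        labels[rr[keep], cc[keep]] = LABELS["nucleus"]

    # --- droplets ----------------------------------------------------------
    target_px = spec.droplet_area_fraction * organoid_area_px
    droplet_px = 0
    attempts = 0
    interior = (labels != LABELS["background"]) & (labels != LABELS["lumen"])
    while droplet_px < target_px:
        attempts += 1
        if attempts > 50000:
            raise PlacementError(
                f"droplet_area_fraction={spec.droplet_area_fraction} infeasible"
            )
        d_um = rng.uniform(*spec.droplet_diameter_range)
        r_px_d = d_um / (2 * px)
        u = rng.uniform(0, 2 * np.pi)
        rad = math.sqrt(rng.uniform())
        pos = (
            center[0] + rad * (ax_r - r_px_d - 1) * np.cos(u),
            center[1] + rad * (ax_c - r_px_d - 1) * np.sin(u),
        )
        if not interior[int(pos[0]), int(pos[1])]:
            continue
        rr, cc = draw_disk(pos, r_px_d, shape=labels.shape)
        keep = interior[rr, cc] & (labels[rr, cc] != LABELS["droplet"])
        droplet_px += int(keep.sum())
        labels[rr[keep], cc[keep]] = LABELS["droplet"]

    # --- refractive index map ----------------------------------------------
    ri = dict(spec.compartment_ri)
    lut = np.full(256, ri.get("medium", ri["background"]), dtype=np.float64)
    for name, code in LABELS.items():
        lut[code] = ri.get(name, ri["cytoplasm"])
    ri_map = lut[labels]

    if spec.texture_amplitude > 0:
        # smooth intracellular texture; bounded so it never crosses the
        # droplet segmentation threshold
        from scipy.ndimage import gaussian_filter

        noise = gaussian_filter(rng.standard_normal(labels.shape), 2.0)
        noise *= spec.texture_amplitude / (noise.std() + 1e-12)
        tissue = np.isin(
            labels,
            (LABELS["cytoplasm"], LABELS["rosette"], LABELS["directional_cell"],
             LABELS["nucleus"]),
        )
        ri_map = ri_map + noise * tissue

    return GroundTruthPhantom(ri_map=ri_map, labels=labels, spec=spec)


# ---------------------------------------------------------------------------
# acquisition simulation


def simulate_qobm_acquisition(
    truth: GroundTruthPhantom, acq: AcquisitionSpec | None = None
) -> RawFrameSet:
    """Simulate the four-frame oblique-illumination acquisition of ``truth``.

    The phantom RI is converted to optical phase, forward-projected through
    the shared phase transfer function, and emitted as intensity frames
    ``background * (1 ± dpc)`` per source pair, plus Gaussian noise at the
    configured SNR.  Non-positive intensities are clipped with a warning.
    """
    acq = acq or AcquisitionSpec()
    n_m = truth.spec.compartment_ri.get(
        "medium", truth.spec.compartment_ri["background"]
    )
    cfg = acq.optical_config(n_medium=n_m)
    phase = ri_to_phase(truth.ri_map - n_m, cfg)
    model = acq.transfer_model()
    dpc = forward_project(phase, model, truth.spec.pixel_size)

    bg = acq.background
    frames = np.stack(
        [
            bg * (1 + dpc.dpc_x),
            bg * (1 - dpc.dpc_x),
            bg * (1 + dpc.dpc_y),
            bg * (1 - dpc.dpc_y),
        ]
    )
    rng = np.random.default_rng(truth.spec.seed + 0x5EED)
    if acq.poisson:
        frames = rng.poisson(np.clip(frames, 0, None) * 1000.0) / 1000.0
    if acq.snr_db is not None:
        sigma = bg / (10 ** (acq.snr_db / 20.0))
        frames = frames + rng.normal(0.0, sigma, frames.shape)
    n_clipped = int((frames <= 0).sum())
    if n_clipped:
        warnings.warn(f"{n_clipped} non-positive intensities clipped", stacklevel=2)
        frames = np.clip(frames, 1e-6 * bg, None)
    return RawFrameSet(
        frames=frames,
        pixel_size=truth.spec.pixel_size,
        wavelength_nm=acq.wavelength_nm,
        n_clipped=n_clipped,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class GroupTrend:
    """Per-week dynamics of one cohort arm.

    Retention rates multiply the structure density for every week after the
    differentiation switch; droplet growth is an absolute area-fraction
    increment per post-switch week.  Both arms are therefore statistically
    identical before the switch, as in the emulated study design.
    """

    directional_retention: float = 1.0
    rosette_retention: float = 1.0
    droplet_growth: float = 0.005

    def validate(self) -> None:
        for v in (self.directional_retention, self.rosette_retention,
                  self.droplet_growth):
            if v < 0:
                raise ValueError("trend rates must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Two-arm longitudinal cohort design.

    Defaults emulate the study conditions at reduced scale: control
    directional cells and surface rosettes decay after the differentiation
    media switch while the experimental arm retains them, and high-RI droplet
    content grows faster in the experimental arm.
    """

    n_control: int = 6
    n_experimental: int = 6
    weeks: tuple[int, ...] = (3, 4, 5, 6)
    differentiation_switch_week: int = 4
    control: GroupTrend = field(
        default_factory=lambda: GroupTrend(
            directional_retention=0.5, rosette_retention=0.6, droplet_growth=0.005
        )
    )
    experimental: GroupTrend = field(
        default_factory=lambda: GroupTrend(
            directional_retention=1.0, rosette_retention=1.0, droplet_growth=0.015
        )
    )
    base_spec: PhantomSpec = field(
        default_factory=lambda: PhantomSpec(image_size=256, organoid_axes=(110.0, 95.0),
                                            rosette_count=5, rosette_radius_range=(18.0, 26.0),
                                            fissure_count=2, droplet_area_fraction=0.01)
    )
    organoid_jitter: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        self.control.validate()
        self.experimental.validate()
        if self.differentiation_switch_week not in self.weeks:
            raise ValueError("switch week must be a member of weeks")
        if self.n_control < 1 or self.n_experimental < 1:
            raise ValueError("need at least one organoid per arm")


def expected_ground_truth(cspec: CohortSpec, group: str, week: int) -> dict:
    """Expected structure parameters for ``group`` at ``week`` (no jitter)."""
    trend = cspec.control if group == "control" else cspec.experimental
    base = cspec.base_spec
    post = max(0, week - cspec.differentiation_switch_week)
    return {
        "directional_cell_density":
            base.directional_cell_density * trend.directional_retention ** post,
        "rosette_count": base.rosette_count * trend.rosette_retention ** post,
        "droplet_area_fraction":
            base.droplet_area_fraction + trend.droplet_growth * post,
    }


def generate_two_group_cohort(
    cspec: CohortSpec,
) -> list[tuple[GroundTruthPhantom, dict]]:
    """Generate per-organoid, per-week phantoms following the group trends.

    Returns a list of ``(phantom, metadata)`` pairs; metadata carries
    ``group``, ``week``, ``organoid_id`` and the ground-truth parameters used.
    """
    cspec.validate()
    rng = np.random.default_rng(cspec.seed)
    out: list[tuple[GroundTruthPhantom, dict]] = []
    arms = [("control", cspec.n_control), ("experimental", cspec.n_experimental)]
    for group, n_arm in arms:
        for i in range(n_arm):
            oid = f"{group[:4]}_{i:02d}"
            jit = 1.0 + rng.normal(0.0, cspec.organoid_jitter)
            jit = float(np.clip(jit, 0.6, 1.4))
            for week in cspec.weeks:
                exp = expected_ground_truth(cspec, group, week)
                count = int(rng.binomial(
                    cspec.base_spec.rosette_count,
                    min(1.0, exp["rosette_count"] / max(cspec.base_spec.rosette_count, 1)),
                )) if exp["rosette_count"] < cspec.base_spec.rosette_count else (
                    cspec.base_spec.rosette_count
                )
                spec = replace(
                    cspec.base_spec,
                    directional_cell_density=exp["directional_cell_density"] * jit,
                    rosette_count=count,
                    droplet_area_fraction=min(
                        0.3, exp["droplet_area_fraction"] * jit
                    ),
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                phantom = generate_organoid_phantom(spec)
                meta = {
                    "group": group,
                    "week": week,
                    "organoid_id": oid,
                    "post_switch": week > cspec.differentiation_switch_week,
                    **{f"truth_{k}": v for k, v in exp.items()},
                    "truth_droplet_fraction_actual": phantom.droplet_fraction(),
                }
                out.append((phantom, meta))
    return out


# ---------------------------------------------------------------------------
# histology simulation


def simulate_oro_histology(
    truth: GroundTruthPhantom,
    stain_matrix: np.ndarray | None = None,
    red_density: float = 1.0,
    blue_density: float = 0.6,
    intensity_ceiling: float = 255.0,
) -> np.ndarray:
    """Render an Oil-Red-O / Hematoxylin RGB image of a phantom section.

    Red stain optical density is deposited on droplet labels, blue on nucleus
    labels, and the Beer–Lambert law converts densities to transmitted RGB:
    ``I = I0 * 10**(-M @ d)``.
    """
    from .histology import DEFAULT_STAIN_MATRIX, densities_to_rgb

    if red_density < 0 or blue_density < 0:
        raise ValueError("stain densities must be >= 0")
    m = DEFAULT_STAIN_MATRIX if stain_matrix is None else stain_matrix
    red = red_density * truth.label_mask("droplet").astype(np.float64)
    blue = blue_density * truth.label_mask("nucleus").astype(np.float64)
    return densities_to_rgb(red, blue, m, intensity_ceiling=intensity_ceiling)


def brightfield_silhouette(truth: GroundTruthPhantom) -> np.ndarray:
    """Binary whole-organoid silhouette as seen in brightfield.

    Brightfield projection images resolve only the organoid outline; the
    silhouette is the union of all non-background labels.
    """
    return truth.organoid_mask.copy()


# ---------------------------------------------------------------------------
# analytic fixtures


def make_fractal_fixture(kind: str, size: int) -> np.ndarray:
    """Deterministic binary fixtures with known box-counting dimension.

    ``filled_square`` (D = 2), ``line`` (D = 1) and ``sierpinski_carpet``
    (D = log 8 / log 3 ≈ 1.893; ``size`` must be a power of 3).
    """
    if size < 3:
        raise ValueError("size must be >= 3")
    if kind == "filled_square":
        return np.ones((size, size), dtype=bool)
    if kind == "line":
        img = np.zeros((size, size), dtype=bool)
        img[size // 2, :] = True
        return img
    if kind == "sierpinski_carpet":
        depth = round(math.log(size, 3))
        if 3**depth != size:
            raise ValueError("sierpinski_carpet size must be a power of 3")
        img = np.ones((1, 1), dtype=bool)
        for _ in range(depth):
            img = np.block(
                [
                    [img, img, img],
                    [img, np.zeros_like(img), img],
                    [img, img, img],
                ]
            )
        return img
    raise ValueError(f"unknown fixture kind: {kind!r}")
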