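"""Quantitative phase recovery from four-frame oblique-illumination sets.

Two opposing illumination directions give one differential phase contrast
(DPC) channel, ``(I_a - I_b) / (I_a + I_b)``; two orthogonal channels are
deconvolved jointly with an antisymmetric phase transfer function (PTF)

    H_j(k) = i * gain * (s_j · k / |k|) * A(|k|),        H_j(0) = 0,

where ``s_j`` is the obliquity axis of channel j and ``A`` a radial low-pass
envelope with cutoff ``2 NA / λ`` (incoherent passband limit).  The inverse
is a Tikhonov-regularized Fourier deconvolution; because the two obliquity
axes are orthogonal, ``Σ_j |H_j|² = gain² A(k)²`` is isotropic and the
inverse is well conditioned everywhere inside the passband except at DC,
where the lost additive constant is restored by a background-reference rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
import numpy as np

__all__ = [
    "RawFrameSet",
    "DPCPair",
    "PhaseTransferModel",
    "ReconConfig",
    "PhaseMap",
    "compute_dpc",
    "build_transfer_function",
    "forward_project",
    "reconstruct_phase",
]


@dataclass
class RawFrameSet:
    """Four positive intensity frames ordered (+x, −x, +y, −y)."""

    frames: np.ndarray  # (4, H, W)
    pixel_size: float  # µm / px
    wavelength_nm: float = 720.0
    n_clipped: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.shape[0] != 4 or self.frames.ndim != 3:
            raise ValueError("RawFrameSet requires four congruent frames")
        if not np.all(self.frames > 0):
            raise ValueError("intensities must be strictly positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")


@dataclass
class DPCPair:
    """Normalized DPC images for the two orthogonal obliquity axes."""

    dpc_x: np.ndarray
    dpc_y: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        if self.dpc_x.shape != self.dpc_y.shape:
            raise ValueError("DPC channels must be congruent")


@dataclass(frozen=True)
class PhaseTransferModel:
    """Parametric antisymmetric PTF shared by simulator and reconstructor.

    ``gain`` (rad⁻¹) scales phase to DPC contrast; ``envelope_scale``
    multiplies the cutoff frequency and exists to express model mismatch
    (e.g. a 10% mis-specified envelope) in robustness studies.
    """

    wavelength_nm: float = 720.0
    numerical_aperture: float = 0.45
    gain: float = 0.3
    envelope_scale: float = 1.0

    @property
    def cutoff(self) -> float:
        """Incoherent cutoff frequency 2·NA/λ in µm⁻¹."""
        lam_um = self.wavelength_nm / 1000.0
        return self.envelope_scale * 2.0 * self.numerical_aperture / lam_um

    def envelope(self, k_radial: np.ndarray) -> np.ndarray:
        """Radial low-pass profile A(|k|): cosine taper, A(0)=1, A(kc)=0."""
        x = np.clip(k_radial / self.cutoff, 0.0, 1.0)
        return np.cos(0.5 * np.pi * x)


@dataclass(frozen=True)
class ReconConfig:
    """Tikhonov deconvolution settings.

    ``beta`` is the scalar regularizer added to ``Σ|H|²``;
    ``background_border_px`` is the width of the image border band whose
    median fixes the additive phase constant (the medium reference).
    """

    beta: float = 1e-3
    background_border_px: int = 8
    background_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be > 0")


@dataclass
class PhaseMap:
    """Reconstructed quantitative phase in radians."""

    phase: np.ndarray
    pixel_size: float
    wavelength_nm: float = 720.0
    dz_um: float = 2.5

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.phase)):
            raise ValueError("phase map must be finite")


def compute_dpc(raw: RawFrameSet) -> DPCPair:
    """Form the two normalized DPC channels from a four-frame set.

    Zero-sum pixels (possible only for degenerate synthetic input) map to 0
    with a warning.
    """
    f = raw.frames
    out = []
    for a, b in ((0, 1), (2, 3)):
        num = f[a] - f[b]
        den = f[a] + f[b]
        bad = den == 0
        if bad.any():
            warnings.warn(f"{int(bad.sum())} zero-sum DPC pixels set to 0",
                          stacklevel=2)
            den = np.where(bad, 1.0, den)
            num = np.where(bad, 0.0, num)
        out.append(num / den)
    return DPCPair(dpc_x=out[0], dpc_y=out[1], pixel_size=raw.pixel_size)


def _freq_grid(shape: tuple[int, int], pixel_size: float):
    ky = np.fft.fftfreq(shape[0], d=pixel_size)[:, None]
    kx = np.fft.fftfreq(shape[1], d=pixel_size)[None, :]
    return ky, kx


def build_transfer_function(
    model: PhaseTransferModel, shape: tuple[int, int], pixel_size: float
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate H_x, H_y on the FFT frequency grid of ``shape``.

    Both filters are purely imaginary, odd in k (real impulse response) and
    exactly zero at DC.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    ky, kx = _freq_grid(shape, pixel_size)
    k = np.hypot(ky, kx)
    k_safe = np.where(k == 0, 1.0, k)
    a = model.envelope(k)
    h_x = 1j * model.gain * (kx / k_safe) * a
    h_y = 1j * model.gain * (ky / k_safe) * a
    h_x[0, 0] = 0.0
    h_y[0, 0] = 0.0
    return h_x, h_y


def forward_project(
    phase: np.ndarray | PhaseMap,
    model: PhaseTransferModel,
    pixel_size: float | None = None,
) -> DPCPair:
    """Project a phase image to its two DPC channels (simulator forward model)."""
    if isinstance(phase, PhaseMap):
        pixel_size = phase.pixel_size
        phase = phase.phase
    if pixel_size is None:
        raise ValueError("pixel_size required when phase is a bare array")
    h_x, h_y = build_transfer_function(model, phase.shape, pixel_size)
    spec = np.fft.fft2(phase)
    dpc_x = np.fft.ifft2(h_x * spec).real
    dpc_y = np.fft.ifft2(h_y * spec).real
    return DPCPair(dpc_x=dpc_x, dpc_y=dpc_y, pixel_size=pixel_size)


def _border_band(shape: tuple[int, int], width: int) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    w = max(1, min(width, min(shape) // 2))
    m[:w, :] = m[-w:, :] = True
    m[:, :w] = m[:, -w:] = True
    return m


def reconstruct_phase(
    dpc: DPCPair,
    model: PhaseTransferModel,
    cfg: ReconConfig | None = None,
    wavelength_nm: float | None = None,
    dz_um: float = 2.5,
) -> PhaseMap:
    """Tikhonov-regularized joint deconvolution of the two DPC channels.

    φ̂ = IFFT( Σ_j conj(H_j)·FFT(DPC_j) / (Σ_j |H_j|² + β) ), then the
    additive constant is fixed by zeroing the median of the background
    reference region (image border band unless a mask is supplied).
    """
    cfg = cfg or ReconConfig()
    h_x, h_y = build_transfer_function(model, dpc.dpc_x.shape, dpc.pixel_size)
    num = np.conj(h_x) * np.fft.fft2(dpc.dpc_x) + np.conj(h_y) * np.fft.fft2(dpc.dpc_y)
    den = np.abs(h_x) ** 2 + np.abs(h_y) ** 2 + cfg.beta
    phi = np.fft.ifft2(num / den).real
    ref = (
        cfg.background_mask
        if cfg.background_mask is not None
        else _border_band(phi.shape, cfg.background_border_px)
    )
    phi = phi - np.median(phi[ref])
    return PhaseMap(
        phase=phi,
        pixel_size=dpc.pixel_size,
        wavelength_nm=wavelength_nm or model.wavelength_nm,
        dz_um=dz_um,
    )
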