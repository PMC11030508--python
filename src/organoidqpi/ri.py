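"""Phase-to-refractive-index conversion and high-RI segmentation.

The measured phase of a section of effective thickness Δz relates linearly
to the refractive-index contrast against the surrounding medium:

    Δn = λ · Δφ / (2π · Δz),        n₀ = n_m + Δn,

with λ and Δz in consistent length units.  High-RI material (lipid droplets,
membranes, nucleic material) is segmented at an absolute index threshold,
n ≥ 1.46 by default, against the PDMS-like medium index n_m = 1.3440.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "OpticalConfig",
    "RIMap",
    "HighRIResult",
    "phase_to_ri",
    "ri_to_phase",
    "segment_high_ri",
    "track_fraction",
]

DEFAULT_RI_THRESHOLD = 1.46


@dataclass(frozen=True)
class OpticalConfig:
    """Wavelength (nm), effective section thickness Δz (µm), medium index."""

    wavelength_nm: float = 720.0
    dz_um: float = 2.5
    n_medium: float = 1.3440

    def __post_init__(self) -> None:
        if self.wavelength_nm <= 0 or self.dz_um <= 0 or self.n_medium <= 0:
            raise ValueError("optical parameters must be positive")

    @property
    def phase_per_delta_n(self) -> float:
        """Radians of phase per unit refractive-index contrast: 2πΔz/λ."""
        lam_um = self.wavelength_nm / 1000.0
        return 2.0 * np.pi * self.dz_um / lam_um


@dataclass
class RIMap:
    """Refractive-index image: contrast Δn = n₀ − n_m and absolute n₀."""

    delta_n: np.ndarray
    provenance: OpticalConfig

    @property
    def n_abs(self) -> np.ndarray:
        return self.delta_n + self.provenance.n_medium


@dataclass
class HighRIResult:
    """High-RI segmentation mask and its organoid-relative area fraction."""

    mask: np.ndarray
    area_fraction: float
    threshold: float
    threshold_on: str = "absolute"


def phase_to_ri(phase, cfg: OpticalConfig | None = None) -> RIMap:
    """Convert a medium-referenced phase map (rad) to refractive index."""
    cfg = cfg or OpticalConfig()
    arr = phase.phase if hasattr(phase, "phase") else np.asarray(phase, dtype=float)
    if hasattr(phase, "wavelength_nm"):
        cfg = OpticalConfig(
            wavelength_nm=phase.wavelength_nm,
            dz_um=phase.dz_um,
            n_medium=cfg.n_medium,
        )
    return RIMap(delta_n=arr / cfg.phase_per_delta_n, provenance=cfg)


def ri_to_phase(delta_n: np.ndarray, cfg: OpticalConfig | None = None) -> np.ndarray:
    """Inverse of :func:`phase_to_ri`: Δφ = 2πΔzΔn/λ (radians)."""
    cfg = cfg or OpticalConfig()
    return np.asarray(delta_n, dtype=float) * cfg.phase_per_delta_n


def segment_high_ri(
    ri: RIMap,
    organoid_mask: np.ndarray,
    threshold: float = DEFAULT_RI_THRESHOLD,
    threshold_on: str = "absolute",
) -> HighRIResult:
    """Threshold high-RI material inside the organoid.

    ``threshold_on`` selects whether ``threshold`` applies to the absolute
    index n₀ (default) or the contrast Δn.
    """
    organoid_mask = np.asarray(organoid_mask, dtype=bool)
    if organoid_mask.shape != ri.delta_n.shape:
        raise ValueError("organoid mask incongruent with RI map")
    n_org = int(organoid_mask.sum())
    if n_org == 0:
        raise ValueError("organoid mask is empty")
    field = ri.n_abs if threshold_on == "absolute" else ri.delta_n
    mask = (field >= threshold) & organoid_mask
    return HighRIResult(
        mask=mask,
        area_fraction=float(mask.sum()) / n_org,
        threshold=threshold,
        threshold_on=threshold_on,
    )


def track_fraction(
    fractions, metadata=None, group_key: str = "group", week_key: str = "week"
) -> pd.DataFrame:
    """Summarize high-RI area fractions per group × week.

    Accepts either a tidy DataFrame with ``fraction`` plus metadata columns,
    or a sequence of fractions with a parallel sequence of metadata dicts.
    Returns mean, sd (NaN flagged as 0-variance when n = 1) and n.
    """
    if isinstance(fractions, pd.DataFrame):
        df = fractions.copy()
    else:
        rows = []
        for frac, meta in zip(fractions, metadata, strict=True):
            rows.append({"fraction": float(frac), **meta})
        df = pd.DataFrame(rows)
    for key in (group_key, week_key, "fraction"):
        if key not in df.columns:
            raise KeyError(f"missing metadata column {key!r}")
    out = (
        df.groupby([group_key, week_key])["fraction"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd_defined"] = out["n"] > 1
    return out
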