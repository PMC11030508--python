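"""End-to-end pipeline orchestration plus the device shear-stress utility.

``run_pipeline`` chains simulate → reconstruct → segment → morphometrics →
features → analyze over a synthetic two-arm cohort, writing stage outputs
and a manifest (seeds, configs, checksums) into a run directory.  A single
global seed fans out to per-stage seeds as ``seed + stage index`` so any
stage can be reproduced in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as qio
from .features import FeatureConfig, extract_feature_table
from .morphometrics import compute_shape_metrics, count_rosettes
from .phantoms import (
    AcquisitionSpec,
    CohortSpec,
    generate_two_group_cohort,
    simulate_qobm_acquisition,
)
from .recon import ReconConfig, compute_dpc, reconstruct_phase
from .ri import OpticalConfig, phase_to_ri, segment_high_ri, track_fraction
from .stats import longitudinal_compare

log = logging.getLogger(__name__)

STAGES = ("simulate", "recon", "segment", "morpho", "features", "analyze")


@dataclass(frozen=True)
class DeviceGeometry:
    """Microfluidic channel geometry for the wall shear-stress estimate.

    SI units: viscosity in Pa·s, flow rate in m³/s, width and height in m.
    """

    viscosity: float = 1.0e-3
    flow_rate: float = 1.667e-9  # 100 µL/min
    channel_width: float = 2.0e-3
    channel_height: float = 2.5e-3

    def __post_init__(self) -> None:
        for name in ("viscosity", "flow_rate", "channel_width", "channel_height"):
            if getattr(self, name) < 0 or (
                name != "flow_rate" and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")


def shear_stress(geom: DeviceGeometry) -> dict[str, float]:
    """Wall shear stress T = 5µQ/(w·h²) in Pa and dyn/cm².

    The dyn/cm² figure (1 Pa = 10 dyn/cm²) is the conventional unit for
    cell-culture shear bounds; both are reported because published bounds
    sometimes omit the unit system.
    """
    t_pa = 5.0 * geom.viscosity * geom.flow_rate / (
        geom.channel_width * geom.channel_height**2
    )
    return {"pa": t_pa, "dyn_per_cm2": t_pa * 10.0}


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    recon: ReconConfig = field(default_factory=ReconConfig)
    optics: OpticalConfig = field(default_factory=OpticalConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    ri_threshold: float = 1.46
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    output_dir: str = "runs/demo"
    save_images: bool = False

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.cohort.validate()

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        """Build a RunConfig from a (YAML-loaded) nested mapping.

        Unknown keys are rejected so config typos fail before any stage runs.
        """
        data = dict(data)
        kwargs: dict = {}
        sub = {
            "cohort": CohortSpec,
            "acquisition": AcquisitionSpec,
            "recon": ReconConfig,
            "optics": OpticalConfig,
            "features": FeatureConfig,
        }
        for key, klass in sub.items():
            if key in data:
                payload = data.pop(key)
                names = {f.name for f in dataclasses.fields(klass)}
                bad = set(payload) - names
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                for fname, val in list(payload.items()):
                    if isinstance(val, list):
                        payload[fname] = tuple(val)
                kwargs[key] = klass(**payload)
        names = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - names
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if isinstance(data.get("stages"), list):
            data["stages"] = tuple(data["stages"])
        return cls(**kwargs, **data)


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


class MissingDependencyError(RuntimeError):
    def __init__(self, stage: str, needs: str):
        super().__init__(
            f"stage {stage!r} requires output of disabled stage {needs!r}"
        )


def _checksum(obj) -> str:
    if isinstance(obj, pd.DataFrame):
        payload = obj.to_csv(index=False).encode()
    elif isinstance(obj, np.ndarray):
        payload = obj.tobytes()
    else:
        payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    return int(global_seed) + STAGES.index(stage)


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured stages; return the run directory.

    Outputs: ``fractions.csv``, ``morphometrics.csv``, ``features.csv``,
    ``per_week_stats.csv``, ``pre_post.csv`` and ``manifest.json``.  Any
    stage failure aborts with a stage-named error; outputs of completed
    stages are preserved.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in config.stages},
        "config_checksum": _checksum(qio.dataclass_to_dict(config)),
        "stages": {},
    }
    from . import __version__

    manifest["version"] = __version__
    state: dict = {}

    def run_stage(name, fn, needs=()):
        if name not in config.stages:
            return
        for dep in needs:
            if dep not in state:
                raise MissingDependencyError(name, dep)
        try:
            result = fn()
        except MissingDependencyError:
            raise
        except Exception as err:  # preserve partial outputs, name the stage
            raise StageError(name, err) from err
        state[name] = result
        manifest["stages"][name] = {"checksum": _checksum(result)}
        log.info("stage %s done", name)

    def _simulate():
        cspec = dataclasses.replace(
            config.cohort, seed=stage_seed(config.seed, "simulate")
        )
        cohort = generate_two_group_cohort(cspec)
        if config.save_images:
            for i, (ph, meta) in enumerate(cohort):
                qio.write_label_tiff(out / f"labels_{i:03d}.tif", ph.labels)
        return cohort

    def _recon():
        model = config.acquisition.transfer_model()
        phases = []
        for ph, meta in state["simulate"]:
            raw = simulate_qobm_acquisition(ph, config.acquisition)
            rec = reconstruct_phase(compute_dpc(raw), model, config.recon)
            phases.append(rec)
        return phases

    def _segment():
        rows, ri_maps = [], []
        for (ph, meta), rec in zip(state["simulate"], state["recon"]):
            rim = phase_to_ri(rec, config.optics)
            seg = segment_high_ri(
                rim, ph.organoid_mask, threshold=config.ri_threshold
            )
            ri_maps.append(rim)
            rows.append(
                {
                    "organoid_id": meta["organoid_id"],
                    "group": meta["group"],
                    "week": meta["week"],
                    "fraction": seg.area_fraction,
                    "truth_fraction": meta["truth_droplet_fraction_actual"],
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "fractions.csv", index=False)
        track_fraction(df).to_csv(out / "fractions_by_group_week.csv", index=False)
        return {"table": df, "ri_maps": ri_maps}

    def _morpho():
        rows = []
        for ph, meta in state["simulate"]:
            sm = compute_shape_metrics(ph.organoid_mask, ph.spec.pixel_size)
            rows.append(
                {
                    "organoid_id": meta["organoid_id"],
                    "group": meta["group"],
                    "week": meta["week"],
                    "rosette_count": count_rosettes(ph.label_mask("rosette")),
                    **{
                        k: getattr(sm, k)
                        for k in (
                            "area", "equivalent_diameter", "circularity",
                            "solidity", "aspect_ratio",
                        )
                    },
                }
            )
        df = pd.DataFrame(rows)
        df.to_csv(out / "morphometrics.csv", index=False)
        return df

    def _features():
        imgs = [r.n_abs for r in state["segment"]["ri_maps"]]
        metas = [
            {k: meta[k] for k in ("organoid_id", "group", "week")}
            for _, meta in state["simulate"]
        ]
        px = state["simulate"][0][0].spec.pixel_size
        table = extract_feature_table(imgs, metas, px, config.features)
        table.to_csv(out / "features.csv", index=False)
        return table

    def _analyze():
        table = state["features"]
        skip = {"image_index", "tile_row", "tile_col", "organoid_id", "group", "week"}
        featcols = [c for c in table.columns if c not in skip]
        res = longitudinal_compare(
            table,
            featcols,
            switch_week=config.cohort.differentiation_switch_week,
        )
        res["per_week"].to_csv(out / "per_week_stats.csv", index=False)
        res["pre_post"].to_csv(out / "pre_post.csv", index=False)
        return res["per_week"]

    run_stage("simulate", _simulate)
    run_stage("recon", _recon, needs=("simulate",))
    run_stage("segment", _segment, needs=("simulate", "recon"))
    run_stage("morpho", _morpho, needs=("simulate",))
    run_stage("features", _features, needs=("simulate", "segment"))
    run_stage("analyze", _analyze, needs=("features",))

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
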