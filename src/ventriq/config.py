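"""Run configuration: parameter ranges, unit mappings, and the printed-defaults profile.

A :class:`RunConfig` bundles everything a reproducible run needs — DOE
ranges and sizes, chamber/spheroid geometry, circulation constants, the
surrogate hyperparameter grid and all seeds — and round-trips losslessly
through YAML.

The ``paper2019`` profile encodes the published study conditions: active
ranges ``l0`` 0.0015–0.0028, ``t0`` 0.075–0.25, ``Tmax`` 0.65–1.9 for both
ventricles (80 cycles, 77/3 split, 401 samples per cycle), passive ranges
``a`` 0.229e-3–9.881e-3, ``a_f`` 0.5e-3–49.901e-3, ``a_s`` 9.1e-5–6.986e-3,
``a_fs`` 7.568e-5–3.952e-3 MPa (120 models, 100/20 split, 576 endocardial
elements, D = 0.2 MPa^-1, P_ED = 16.38 mmHg), and the 3x3x3 grid with
3-fold CV.  Printed active ranges are mapped to physical units once, at
configuration time: ``l0`` is read at the sarcomere scale (x1000 -> um)
and ``Tmax`` at the 10^5 Pa scale (x100 -> kPa); the mapping is recorded
in the config and every dataset sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import yaml

from .constitutive import ActiveParams, PassiveParams
from .doe import ParameterRanges
from .reduced_lv import (
    ChamberGeometry,
    ChamberSpec,
    CirculationParams,
    SpheroidGeometry,
)
from .surrogate import HyperparamGrid

__all__ = ["Seeds", "PVExperimentConfig", "StressExperimentConfig", "RunConfig",
           "paper2019", "load_config", "save_config", "config_hash"]

#: printed-range -> physical-unit multipliers for the active features
ACTIVE_UNIT_MAP: Dict[str, Tuple[float, str]] = {
    "l0": (1000.0, "um"),
    "t0": (1.0, "s"),
    "Tmax": (100.0, "kPa"),
}


@dataclass(frozen=True)
class Seeds:
    """Independent seeds for every stochastic stage, all below 2^31."""

    doe: int = 12345
    maximin: int = 23456
    split: int = 34567
    train: int = 45678

    @classmethod
    def from_master(cls, master: int) -> "Seeds":
        import numpy as np

        state = np.random.SeedSequence(int(master)).generate_state(4)
        doe, maximin, split, train = (int(s) % (2**31) for s in state)
        return cls(doe=doe, maximin=maximin, split=split, train=train)


@dataclass(frozen=True)
class PVExperimentConfig:
    """Study conditions for the pressure/volume experiment."""

    printed_ranges: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "l0": (0.0015, 0.0028),
            "t0": (0.075, 0.25),
            "Tmax": (0.65, 1.9),
        }
    )
    n_samples: int = 80
    n_train: int = 77
    n_test: int = 3
    n_out: int = 401
    maximin_iters: int = 300
    lv_geometry: ChamberGeometry = field(
        default_factory=lambda: ChamberGeometry(Ri=28.0, wall_volume=70e3, n_layers=5)
    )
    rv_geometry: ChamberGeometry = field(
        default_factory=lambda: ChamberGeometry(Ri=30.0, wall_volume=35e3, n_layers=5)
    )
    passive: PassiveParams = field(default_factory=PassiveParams)
    # lR is the generator's activation-length calibration: it places the
    # sampled l0 range on the attainable sarcomere-length branch so every
    # design point remains contractile (see docs/methods.md).
    active_base: ActiveParams = field(default_factory=lambda: ActiveParams(lR=3.0))
    circulation: CirculationParams = field(default_factory=CirculationParams)

    def feature_ranges(self) -> ParameterRanges:
        """Six-dimensional DOE ranges in physical units (um, s, kPa)."""
        items = []
        for base in ("l0", "t0", "Tmax"):
            scale, unit = ACTIVE_UNIT_MAP[base]
            lo, hi = self.printed_ranges[base]
            for chamber in ("LV", "RV"):
                items.append((f"{base}_{chamber}", lo * scale, hi * scale, unit))
        # column order of the dataset schema: l0_LV,l0_RV,t0_LV,t0_RV,Tmax_LV,Tmax_RV
        order = ["l0_LV", "l0_RV", "t0_LV", "t0_RV", "Tmax_LV", "Tmax_RV"]
        items.sort(key=lambda it: order.index(it[0]))
        return ParameterRanges.from_items(items)


@dataclass(frozen=True)
class StressExperimentConfig:
    """Study conditions for the end-diastolic stress experiment."""

    ranges_mpa: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "a": (0.229e-3, 9.881e-3),
            "a_s": (9.1e-5, 6.986e-3),
            "a_f": (0.5e-3, 49.901e-3),
            "a_fs": (7.568e-5, 3.952e-3),
        }
    )
    n_samples: int = 120
    n_train: int = 100
    n_test: int = 20
    PED: float = 16.38          # mmHg
    D_mpa_inv: float = 0.2      # MPa^-1
    maximin_iters: int = 300
    geometry: SpheroidGeometry = field(default_factory=SpheroidGeometry)
    exponents: Dict[str, float] = field(
        default_factory=lambda: {"b": 8.023, "b_f": 16.026, "b_s": 11.120, "b_fs": 11.436}
    )
    targets: Tuple[str, ...] = ("S11", "S22", "S12")

    def feature_ranges(self) -> ParameterRanges:
        """Four-dimensional DOE ranges in MPa (dataset feature scale)."""
        return ParameterRanges.from_items(
            [(name, *self.ranges_mpa[name], "MPa") for name in ("a", "a_s", "a_f", "a_fs")]
        )

    def base_passive(self) -> PassiveParams:
        return PassiveParams(
            a=1.0, a_f=1.0, a_s=1.0, a_fs=1.0,
            b=self.exponents["b"], b_f=self.exponents["b_f"],
            b_s=self.exponents["b_s"], b_fs=self.exponents["b_fs"],
            D=self.D_mpa_inv * 1.0e-3,  # MPa^-1 -> kPa^-1
        )


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end run."""

    pv: PVExperimentConfig = field(default_factory=PVExperimentConfig)
    stress: StressExperimentConfig = field(default_factory=StressExperimentConfig)
    grid: HyperparamGrid = field(default_factory=HyperparamGrid)
    seeds: Seeds = field(default_factory=Seeds)
    profile: str = "paper2019"

    def lv_spec(self) -> ChamberSpec:
        return ChamberSpec(self.pv.lv_geometry, self.pv.passive, self.pv.active_base)

    def rv_spec(self) -> ChamberSpec:
        return ChamberSpec(self.pv.rv_geometry, self.pv.passive, self.pv.active_base)


def paper2019(master_seed: Optional[int] = None) -> RunConfig:
    """The printed-defaults profile; optionally derive all seeds from one."""
    seeds = Seeds.from_master(master_seed) if master_seed is not None else Seeds()
    return RunConfig(seeds=seeds)


# -- serialization -----------------------------------------------------------


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(cfg: RunConfig) -> dict:
    return _to_plain(cfg)


def _pairs(d: dict) -> dict:
    return {k: tuple(v) for k, v in d.items()}


def config_from_dict(d: dict) -> RunConfig:
    pv = d.get("pv", {})
    stress = d.get("stress", {})
    pv_cfg = PVExperimentConfig(
        printed_ranges=_pairs(pv.get("printed_ranges", PVExperimentConfig().printed_ranges)),
        n_samples=pv.get("n_samples", 80),
        n_train=pv.get("n_train", 77),
        n_test=pv.get("n_test", 3),
        n_out=pv.get("n_out", 401),
        maximin_iters=pv.get("maximin_iters", 300),
        lv_geometry=ChamberGeometry(**pv["lv_geometry"]) if "lv_geometry" in pv
        else PVExperimentConfig().lv_geometry,
        rv_geometry=ChamberGeometry(**pv["rv_geometry"]) if "rv_geometry" in pv
        else PVExperimentConfig().rv_geometry,
        passive=PassiveParams.from_dict(pv.get("passive", {})) if pv.get("passive")
        else PassiveParams(),
        active_base=ActiveParams.from_dict(pv.get("active_base", {})) if pv.get("active_base")
        else ActiveParams(),
        circulation=CirculationParams(**pv["circulation"]) if "circulation" in pv
        else CirculationParams(),
    )
    stress_cfg = StressExperimentConfig(
        ranges_mpa=_pairs(stress.get("ranges_mpa", StressExperimentConfig().ranges_mpa)),
        n_samples=stress.get("n_samples", 120),
        n_train=stress.get("n_train", 100),
        n_test=stress.get("n_test", 20),
        PED=stress.get("PED", 16.38),
        D_mpa_inv=stress.get("D_mpa_inv", 0.2),
        maximin_iters=stress.get("maximin_iters", 300),
        geometry=SpheroidGeometry(**stress["geometry"]) if "geometry" in stress
        else SpheroidGeometry(),
        exponents=dict(stress.get("exponents", StressExperimentConfig().exponents)),
        targets=tuple(stress.get("targets", ("S11", "S22", "S12"))),
    )
    grid_d = d.get("grid", {})
    grid = HyperparamGrid(
        learning_rate=tuple(grid_d.get("learning_rate", (0.01, 0.05, 0.1))),
        n_estimators=tuple(grid_d.get("n_estimators", (500, 1000, 1500))),
        max_depth=tuple(grid_d.get("max_depth", (7, 15, 20))),
        cv_folds=grid_d.get("cv_folds", 3),
    )
    seeds = Seeds(**d.get("seeds", {}))
    return RunConfig(pv=pv_cfg, stress=stress_cfg, grid=grid, seeds=seeds,
                     profile=d.get("profile", "custom"))


def save_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(config_to_dict(cfg), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
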