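"""Run configuration: defaults, YAML loading with strict validation, and the
high-level drivers that wire geometry, materials, air state and boundary
conditions into a simulation.

The packaged defaults reproduce the reference drying run: 42 °C / 0.75 m/s /
8 % RH air, a 5×8 mm kernel in a 1 mm shell, measured component properties
and diffusivities, initial tissue temperature 20 °C, dt = 60 s to 1230 min.
The surface-resistance factor ``f_s`` carries the frozen value from the
one-off calibration of the whole-pod drying rate (see :mod:`poddry.calibrate`);
the equilibrium moisture M_e = 0.02 g/g d.b. comes from a modified-Henderson
peanut isotherm evaluated at the drying-air state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .geometry import AxiMesh, PodGeometry, build_geometry, generate_mesh
from .properties import (
    AirState,
    MaterialModel,
    TransferCoefficients,
    equivalent_sphere_diameter,
    hot_air_properties,
    kernel_material,
    pod_material,
    shell_material,
    transfer_coefficients,
)
from .solver import BoundaryConditions, SimulationConfig, SimulationResult, run_simulation

#: Frozen surface-resistance factor from the whole-pod drying-rate calibration.
DEFAULT_F_S = 7.466733220689005e-06


@dataclass
class AirBlock:
    Ta: float = 42.0      # °C
    va: float = 0.75      # m/s
    RH: float = 0.08      # fraction


@dataclass
class GeometryBlock:
    a_kernel: float = 0.005
    b_kernel: float = 0.008
    t_shell: float = 0.001
    mode: str = "two_component"


@dataclass
class MaterialBlock:
    rho: float
    k_slope: float
    k_intercept: float
    cp_slope: float
    cp_intercept: float
    D_eff: float
    M0: float


@dataclass
class MaterialsBlock:
    shell: MaterialBlock = field(
        default_factory=lambda: MaterialBlock(560.0, 0.17062, 0.07753, 4.04506, 2.05226, 1.63249e-10, 1.24)
    )
    kernel: MaterialBlock = field(
        default_factory=lambda: MaterialBlock(1000.0, 0.32528, 0.12559, 1.96152, 1.15307, 2.91731e-10, 0.74)
    )
    pod_D_eff: float = 5.7512e-10
    pod_M0: float = 0.83
    h_g: float = 2_256_267.0


@dataclass
class BCBlock:
    T0: float = 20.0        # °C
    M_e: float = 0.02       # g/g d.b.
    f_s: float = DEFAULT_F_S
    d: float | None = None  # equivalent diameter; None -> volume-equivalent sphere
    nu_exponent: float = 0.53


@dataclass
class NumericsBlock:
    dt: float = 60.0
    t_end: float = 73_800.0
    mesh_h: float = 5e-4


@dataclass
class OutputBlock:
    snapshot_times: tuple[float, ...] = (
        0.0, 60.0, 300.0, 1800.0, 3600.0, 7200.0, 14_400.0, 36_000.0, 72_000.0, 73_800.0
    )


@dataclass
class RunConfig:
    air: AirBlock = field(default_factory=AirBlock)
    geometry: GeometryBlock = field(default_factory=GeometryBlock)
    materials: MaterialsBlock = field(default_factory=MaterialsBlock)
    bc: BCBlock = field(default_factory=BCBlock)
    numerics: NumericsBlock = field(default_factory=NumericsBlock)
    output: OutputBlock = field(default_factory=OutputBlock)

    def resolved(self) -> dict:
        """JSON-serializable echo of every effective setting (audit trail)."""
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.resolved(), indent=2, default=list)


def _update_block(block, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"config section {path!r} must be a mapping")
    names = {f.name: f for f in dataclasses.fields(block)}
    unknown = set(data) - set(names)
    if unknown:
        raise ConfigError(f"unknown keys under {path!r}: {sorted(unknown)}")
    for key, value in data.items():
        current = getattr(block, key)
        if dataclasses.is_dataclass(current) and isinstance(value, dict):
            _update_block(current, value, f"{path}.{key}")
        elif key == "snapshot_times":
            setattr(block, key, tuple(float(v) for v in value))
        else:
            setattr(block, key, value)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus an optional
    override mapping; unspecified fields keep the packaged defaults.  Unknown
    keys and out-of-range values raise :class:`ConfigError` naming them."""
    cfg = RunConfig()
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        data = loaded
    if overrides:
        for section, vals in overrides.items():
            data.setdefault(section, {})
            if isinstance(vals, dict):
                data[section] = {**data[section], **vals}
            else:
                raise ConfigError(f"override section {section!r} must be a mapping")
    _update_block(cfg, data, "config")
    validate_config(cfg)
    return cfg


def validate_config(cfg: RunConfig) -> None:
    if not 0.0 <= cfg.air.Ta <= 100.0:
        raise ConfigError(f"air.Ta={cfg.air.Ta} °C outside [0, 100]")
    if cfg.air.va < 0:
        raise ConfigError("air.va must be non-negative")
    if not 0.0 <= cfg.air.RH <= 1.0:
        raise ConfigError("air.RH must be a fraction in [0, 1]")
    if cfg.bc.f_s <= 0:
        raise ConfigError("bc.f_s must be positive")
    if cfg.bc.M_e < 0:
        raise ConfigError("bc.M_e must be non-negative")
    if cfg.numerics.dt <= 0 or cfg.numerics.t_end < cfg.numerics.dt:
        raise ConfigError("numerics: need dt > 0 and t_end >= dt")
    if cfg.numerics.mesh_h <= 0:
        raise ConfigError("numerics.mesh_h must be positive")
    build_geometry(
        cfg.geometry.a_kernel, cfg.geometry.b_kernel, cfg.geometry.t_shell, cfg.geometry.mode
    )


def _material(name: str, blk: MaterialBlock, h_g: float) -> MaterialModel:
    return MaterialModel(
        name=name,
        rho=blk.rho,
        k_of_M=(blk.k_slope, blk.k_intercept),
        cp_of_M=(blk.cp_slope, blk.cp_intercept),
        D_eff=blk.D_eff,
        M0=blk.M0,
        h_g=h_g,
    )


def build_materials(cfg: RunConfig, geom: PodGeometry) -> dict[str, MaterialModel]:
    """Materials for every region of the configured mode."""
    shell = _material("shell", cfg.materials.shell, cfg.materials.h_g)
    kernel = _material("kernel", cfg.materials.kernel, cfg.materials.h_g)
    mats: dict[str, MaterialModel] = {}
    if "shell" in geom.regions:
        mats["shell"] = shell
    if "kernel" in geom.regions:
        mats["kernel"] = kernel
    if "pod" in geom.regions:
        fv = geom.analytic_region_volume("shell") / geom.analytic_region_volume("pod")
        mats["pod"] = dataclasses.replace(
            pod_material(
                shell,
                kernel,
                shell_volume_fraction=fv,
                D_eff=cfg.materials.pod_D_eff,
                M0=cfg.materials.pod_M0,
            ),
            h_g=cfg.materials.h_g,
        )
    return mats


def equivalent_diameter(cfg: RunConfig, geom: PodGeometry) -> float:
    """Transfer-coefficient length scale: the configured value, or the
    volume-equivalent-sphere diameter of the mode's outer surface."""
    if cfg.bc.d is not None:
        return cfg.bc.d
    if geom.mode == "kernel_only":
        return equivalent_sphere_diameter(geom.a_kernel, geom.b_kernel)
    return equivalent_sphere_diameter(geom.a_outer, geom.b_outer)


def build_run(cfg: RunConfig, mesh: AxiMesh | None = None):
    """Resolve a config into (mesh, materials, bc, sim, air, tc)."""
    geom = build_geometry(
        cfg.geometry.a_kernel, cfg.geometry.b_kernel, cfg.geometry.t_shell, cfg.geometry.mode
    )
    if mesh is None:
        mesh = generate_mesh(geom, cfg.numerics.mesh_h)
    elif mesh.geometry != geom:
        raise ConfigError("supplied mesh does not match the configured geometry")
    air = hot_air_properties(cfg.air.Ta, cfg.air.va, cfg.air.RH)
    tc = transfer_coefficients(
        air, equivalent_diameter(cfg, geom), f_s=cfg.bc.f_s, nu_exponent=cfg.bc.nu_exponent
    )
    bc = BoundaryConditions(
        T0=cfg.bc.T0 + 273.15,
        Ta=air.Ta_K,
        h_T=tc.h_T,
        h_m_eff=tc.h_m_eff,
        M_e=cfg.bc.M_e,
    )
    sim = SimulationConfig(
        dt=cfg.numerics.dt,
        t_end=cfg.numerics.t_end,
        snapshot_times=cfg.output.snapshot_times,
    )
    return mesh, build_materials(cfg, geom), bc, sim, air, tc


def simulate(cfg: RunConfig, mesh: AxiMesh | None = None) -> SimulationResult:
    """Run the configured simulation end to end."""
    mesh, materials, bc, sim, _, _ = build_run(cfg, mesh)
    return run_simulation(mesh, materials, bc, sim)
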