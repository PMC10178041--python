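"""Transient coupled heat and moisture transport on the axisymmetric mesh.

Model
-----
Moisture (dry-basis M, g/g) moves by Fickian diffusion with a region-wise
constant effective diffusivity D_i; written in conservative composite form so
that water mass ρ_i·M is conserved across the shell/kernel interface:

    ρ ∂M/∂t = ∇·(ρ D ∇M),    −ρ D ∂M/∂n = ρ h_m_eff (M − M_e)  on the surface.

Heat conduction carries an evaporative sink proportional to the local drying
rate (water evaporates inside the tissue, consuming latent heat):

    ρ c_p(M) ∂T/∂t = ∇·(k(M) ∇T) + ρ h_g ∂M/∂t,
    −k ∂T/∂n = h_T (T − T_a)  on the surface.

Symmetry edges (the rotation axis r = 0 and, for the shell ring alone, the
inner surface) are zero flux.  M and T are continuous across the interface;
the conforming mesh enforces flux continuity weakly.

Discretization: linear triangles with the 2πr axisymmetric weight (the 2π
cancels and is omitted), lumped mass and lumped Robin matrices, implicit
first-order (backward Euler) time stepping, and single-pass lagged (Picard)
coefficient updates: each step first advances M with time-constant
coefficients, then advances T using that interval's ∂M/∂t and k, c_p
evaluated at the start-of-step moisture.  Everything is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import ConfigError, DomainError, NumericalError
from .geometry import AxiMesh
from .postprocess import component_average
from .properties import KELVIN_OFFSET, MaterialModel
from .slab import DryingCurve


@dataclass(frozen=True)
class BoundaryConditions:
    """Initial and surface conditions (temperatures in K)."""

    T0: float
    Ta: float
    h_T: float
    h_m_eff: float
    M_e: float

    def __post_init__(self) -> None:
        if self.h_T < 0 or self.h_m_eff < 0:
            raise DomainError("transfer coefficients must be non-negative")
        if self.M_e < 0:
            raise DomainError("equilibrium moisture must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Time-stepping controls; dt and t_end in seconds."""

    dt: float = 60.0
    t_end: float = 73_800.0  # 1230 min
    snapshot_times: tuple[float, ...] = (
        0.0, 60.0, 300.0, 1800.0, 3600.0, 7200.0, 14_400.0, 36_000.0, 72_000.0, 73_800.0
    )

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end < self.dt:
            raise ConfigError("need dt > 0 and t_end >= dt")


@dataclass
class FieldState:
    """Nodal temperature (K) and moisture (g/g d.b.) at one time."""

    t: float
    T: np.ndarray
    M: np.ndarray


@dataclass
class SimulationResult:
    """Per-step component-average curves plus field snapshots."""

    mesh: AxiMesh
    times: np.ndarray                      # (n_steps+1,)
    M_region: dict[str, np.ndarray]        # region -> averaged d.b. moisture
    M_pod: np.ndarray                      # dry-mass-weighted whole-body average
    T_mean: np.ndarray                     # K, volume mean
    T_surface: np.ndarray                  # K, outer-boundary mean
    T_center: np.ndarray                   # K, node nearest the origin
    max_dT: np.ndarray                     # K, max nodal |T - Ta|
    snapshots: list[FieldState]
    mass_change: np.ndarray                # kg water per step, d(∫ρM dV)
    boundary_loss: np.ndarray              # kg water per step through surface

    def moisture_curve(self, region: str = "pod") -> DryingCurve:
        """Averaged drying curve; region 'pod' is the whole-body average."""
        values = self.M_pod if region == "pod" and region not in self.M_region else self.M_region[region]
        return DryingCurve(t=self.times, value=values, kind="moisture")

    def snapshot_at(self, t: float) -> FieldState:
        best = min(self.snapshots, key=lambda s: abs(s.t - t))
        if abs(best.t - t) > 1e-6 + 1e-9 * max(1.0, abs(t)):
            raise DomainError(f"no snapshot stored at t={t} s (nearest: {best.t} s)")
        return best

    def to_frame(self):
        import pandas as pd

        data = {"time_s": self.times}
        for reg, vals in self.M_region.items():
            data[f"M_{reg}_db"] = vals
        data["M_pod_db"] = self.M_pod
        data["T_mean_K"] = self.T_mean
        data["T_surface_K"] = self.T_surface
        data["T_center_K"] = self.T_center
        return pd.DataFrame(data)


class _Assembly:
    """Precomputed FEM arrays for one mesh."""

    def __init__(self, mesh: AxiMesh):
        self.mesh = mesh
        nodes, tri = mesh.nodes, mesh.elements
        r, z = nodes[:, 0], nodes[:, 1]
        i, j, k = tri.T
        self.area = mesh.element_areas()
        self.r_c = mesh.element_centroid_r()
        # P1 gradient coefficients: ∇φ_m = (b_m, c_m) / (2A)
        b = np.stack([z[j] - z[k], z[k] - z[i], z[i] - z[j]], axis=1)
        c = np.stack([r[k] - r[j], r[i] - r[k], r[j] - r[i]], axis=1)
        inv2A = 1.0 / (2.0 * self.area)
        gb = b * inv2A[:, None]
        gc = c * inv2A[:, None]
        # geometric stiffness kernel: G[e,m,n] = r_c A (∇φ_m · ∇φ_n)
        self.G = (self.r_c * self.area)[:, None, None] * (
            gb[:, :, None] * gb[:, None, :] + gc[:, :, None] * gc[:, None, :]
        )
        self.rows = np.repeat(tri, 3, axis=1).ravel()
        self.cols = np.tile(tri, (1, 3)).ravel()
        # lumped mass weights: w[e,m] = A (2 r_m + r_n + r_p) / 12
        rv = r[tri]
        self.w = self.area[:, None] / 12.0 * (rv + rv.sum(axis=1, keepdims=True))
        self.n_nodes = len(nodes)
        # lumped Robin weights on the outer boundary: ∫ r φ dl per edge node
        self.robin_w = np.zeros(self.n_nodes)
        p, q = mesh.boundary_edges.T
        length = np.hypot(r[p] - r[q], z[p] - z[q])
        np.add.at(self.robin_w, p, length * (2 * r[p] + r[q]) / 6.0)
        np.add.at(self.robin_w, q, length * (r[p] + 2 * r[q]) / 6.0)
        self.boundary_nodes = np.unique(mesh.boundary_edges)
        self.center_node = int(np.argmin(r**2 + z**2))
        # region of each element as index into mesh.geometry.regions
        self.regions = mesh.geometry.regions
        lookup = {reg: idx for idx, reg in enumerate(self.regions)}
        self.region_idx = np.asarray([lookup[reg] for reg in mesh.region], dtype=int)
        # boundary edges lie on the outermost band, whose region is the last
        # label in geometry order for every mode
        self.surface_region = self.regions[-1]

    def stiffness(self, coeff: np.ndarray) -> sp.csr_matrix:
        data = (coeff[:, None, None] * self.G).ravel()
        return sp.coo_matrix(
            (data, (self.rows, self.cols)), shape=(self.n_nodes, self.n_nodes)
        ).tocsr()

    def lumped(self, coeff: np.ndarray) -> np.ndarray:
        out = np.zeros(self.n_nodes)
        np.add.at(out, self.mesh.elements, coeff[:, None] * self.w)
        return out

    def elem_values(self, per_region: dict[str, float]) -> np.ndarray:
        vals = np.array([per_region[reg] for reg in self.regions])
        return vals[self.region_idx]


def step_moisture(M: np.ndarray, lu, diag_rho: np.ndarray, robin_vec: np.ndarray,
                  dt: float, M_e: float) -> np.ndarray:
    """One backward-Euler moisture step given the prefactorized system."""
    rhs = diag_rho / dt * M + robin_vec * M_e
    M_new = lu.solve(rhs)
    if not np.all(np.isfinite(M_new)):
        raise NumericalError("moisture solve produced non-finite values")
    return M_new


def run_simulation(
    mesh: AxiMesh,
    materials: dict[str, MaterialModel],
    bc: BoundaryConditions,
    sim: SimulationConfig = SimulationConfig(),
) -> SimulationResult:
    """Integrate the coupled system to ``sim.t_end`` and return averaged
    curves and snapshots.  ``materials`` maps every mesh region name to its
    :class:`MaterialModel`."""
    geom = mesh.geometry
    for reg in geom.regions:
        if reg not in materials:
            raise ConfigError(f"no material supplied for region {reg!r}")
    asm = _Assembly(mesh)

    rho_e = asm.elem_values({r: materials[r].rho for r in geom.regions})
    D_e = asm.elem_values({r: materials[r].D_eff for r in geom.regions})
    hg_e = asm.elem_values({r: materials[r].h_g for r in geom.regions})
    M0_by_region = {r: materials[r].M0 for r in geom.regions}
    max_M0 = max(M0_by_region.values())
    if not bc.M_e < min(M0_by_region.values()):
        raise ConfigError("equilibrium moisture must lie below every initial moisture")

    # --- constant moisture system (conservative ρD form) -----------------
    diag_rho = asm.lumped(rho_e)
    K_M = asm.stiffness(rho_e * D_e)
    rho_surface = materials[asm.surface_region].rho
    robin_m = bc.h_m_eff * rho_surface * asm.robin_w
    A_M = sp.csr_matrix(K_M + sp.diags(diag_rho / sim.dt + robin_m))
    lu_M = splu(A_M.tocsc())

    robin_T = bc.h_T * asm.robin_w
    hg_lump = asm.lumped(rho_e * hg_e)

    n_steps = int(round(sim.t_end / sim.dt))
    times = np.arange(n_steps + 1) * sim.dt

    M = mesh.node_region_values(M0_by_region)
    T = np.full(asm.n_nodes, bc.T0)

    surf_w = asm.robin_w[asm.boundary_nodes]

    def averages(Mf, Tf):
        reg_avg = {r: component_average(mesh, Mf, r) for r in geom.regions}
        pod = component_average(mesh, Mf, "all", density=rho_e)
        t_mean = component_average(mesh, Tf, "all")
        t_surf = float(surf_w @ Tf[asm.boundary_nodes] / surf_w.sum())
        return reg_avg, pod, t_mean, t_surf

    M_region = {r: np.empty(n_steps + 1) for r in geom.regions}
    M_pod = np.empty(n_steps + 1)
    T_mean = np.empty(n_steps + 1)
    T_surface = np.empty(n_steps + 1)
    T_center = np.empty(n_steps + 1)
    max_dT = np.empty(n_steps + 1)
    mass_change = np.empty(n_steps)
    boundary_loss = np.empty(n_steps)
    snapshots: list[FieldState] = []
    snap_steps = {int(round(t / sim.dt)) for t in sim.snapshot_times if t <= sim.t_end + 1e-9}

    def record(step, Mf, Tf):
        reg_avg, pod, t_mean, t_surf = averages(Mf, Tf)
        for r, v in reg_avg.items():
            M_region[r][step] = v
        M_pod[step] = pod
        T_mean[step] = t_mean
        T_surface[step] = t_surf
        T_center[step] = Tf[asm.center_node]
        max_dT[step] = np.max(np.abs(Tf - bc.Ta))
        if step in snap_steps:
            snapshots.append(FieldState(t=times[step], T=Tf.copy(), M=Mf.copy()))

    record(0, M, T)

    for step in range(1, n_steps + 1):
        M_new = step_moisture(M, lu_M, diag_rho, robin_m, sim.dt, bc.M_e)
        dMdt = (M_new - M) / sim.dt

        # water-mass bookkeeping (2π factors restored for absolute kg)
        mass_change[step - 1] = 2.0 * math.pi * float(diag_rho @ (M_new - M))
        boundary_loss[step - 1] = 2.0 * math.pi * sim.dt * float(
            robin_m @ (M_new - bc.M_e)
        )

        # lagged coefficients from start-of-step moisture, element means
        M_bar = M[mesh.elements].mean(axis=1)
        k_e = np.empty(len(M_bar))
        cp_e = np.empty(len(M_bar))
        for ri, reg in enumerate(geom.regions):
            sel = asm.region_idx == ri
            mat = materials[reg]
            Mc = np.clip(M_bar[sel], 0.0, mat.M0)
            k_e[sel] = mat.conductivity(Mc)
            cp_e[sel] = mat.specific_heat(Mc)

        diag_T = asm.lumped(rho_e * cp_e)
        A_T = sp.csr_matrix(asm.stiffness(k_e) + sp.diags(diag_T / sim.dt + robin_T))
        rhs = diag_T / sim.dt * T + robin_T * bc.Ta + hg_lump * dMdt
        T_new = splu(A_T.tocsc()).solve(rhs)
        if not np.all(np.isfinite(T_new)):
            raise NumericalError(f"temperature solve diverged at step {step}")

        M, T = M_new, T_new
        record(step, M, T)

    return SimulationResult(
        mesh=mesh,
        times=times,
        M_region=M_region,
        M_pod=M_pod,
        T_mean=T_mean,
        T_surface=T_surface,
        T_center=T_center,
        max_dT=max_dT,
        snapshots=snapshots,
        mass_change=mass_change,
        boundary_loss=boundary_loss,
    )
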