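"""Axisymmetric two-region pod geometry and its triangulation.

The pod is modelled as a prolate spheroid of revolution: a kernel ellipse
(equatorial semi-axis ``a_kernel``, polar semi-axis ``b_kernel``) nested in a
shell ring of uniform thickness ``t_shell``.  The computational domain is the
(r, z) half-section, r ≥ 0; revolving it about the z axis recovers the 3D
body, so integrals carry a 2πr weight.

Meshing is a mapped (structured) triangulation built from concentric
elliptical rings, which guarantees a conforming shell/kernel interface (the
two regions share the nodes of the kernel ellipse) and deterministic output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, MeshError

MODES = ("two_component", "shell_only", "kernel_only", "pod_homogeneous")


@dataclass(frozen=True)
class PodGeometry:
    """Half-section geometry of the pod (lengths in m)."""

    a_kernel: float = 0.005
    b_kernel: float = 0.008
    t_shell: float = 0.001
    mode: str = "two_component"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        for name in ("a_kernel", "b_kernel", "t_shell"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def a_outer(self) -> float:
        return self.a_kernel + self.t_shell

    @property
    def b_outer(self) -> float:
        return self.b_kernel + self.t_shell

    @property
    def regions(self) -> tuple[str, ...]:
        return {
            "two_component": ("kernel", "shell"),
            "shell_only": ("shell",),
            "kernel_only": ("kernel",),
            "pod_homogeneous": ("pod",),
        }[self.mode]

    def analytic_region_area(self, region: str) -> float:
        """Analytic half-section area (m^2) of a region."""
        half = lambda a, b: 0.5 * math.pi * a * b
        if region == "kernel":
            return half(self.a_kernel, self.b_kernel)
        if region == "shell":
            return half(self.a_outer, self.b_outer) - half(self.a_kernel, self.b_kernel)
        if region == "pod":
            return half(self.a_outer, self.b_outer)
        raise ConfigError(f"unknown region {region!r}")

    def analytic_region_volume(self, region: str) -> float:
        """Analytic solid-of-revolution volume (m^3) of a region."""
        vol = lambda a, b: 4.0 / 3.0 * math.pi * a * a * b
        if region == "kernel":
            return vol(self.a_kernel, self.b_kernel)
        if region == "shell":
            return vol(self.a_outer, self.b_outer) - vol(self.a_kernel, self.b_kernel)
        if region == "pod":
            return vol(self.a_outer, self.b_outer)
        raise ConfigError(f"unknown region {region!r}")


def build_geometry(
    a_kernel: float = 0.005,
    b_kernel: float = 0.008,
    t_shell: float = 0.001,
    mode: str = "two_component",
) -> PodGeometry:
    """Validate dimensions and return a :class:`PodGeometry`."""
    return PodGeometry(a_kernel=a_kernel, b_kernel=b_kernel, t_shell=t_shell, mode=mode)


@dataclass(frozen=True)
class AxiMesh:
    """Triangulated (r, z) half-section with region labels.

    nodes: (N, 2) float array of (r, z); elements: (E, 3) int array (CCW);
    region: (E,) array of region-name strings; boundary_edges: (B, 2) node
    pairs on the outer (convective) surface; axis_edges: edges on r = 0;
    interface_edges: shell/kernel interface edges (empty unless two_component);
    inner_edges: inner hole boundary (shell_only ring only), zero flux.
    """

    geometry: PodGeometry
    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    boundary_edges: np.ndarray
    axis_edges: np.ndarray
    interface_edges: np.ndarray
    inner_edges: np.ndarray

    # ---- derived element quantities -------------------------------------
    def element_areas(self) -> np.ndarray:
        r, z = self.nodes[:, 0], self.nodes[:, 1]
        i, j, k = self.elements.T
        return 0.5 * (
            (r[j] - r[i]) * (z[k] - z[i]) - (r[k] - r[i]) * (z[j] - z[i])
        )

    def element_centroid_r(self) -> np.ndarray:
        return self.nodes[self.elements, 0].mean(axis=1)

    def region_area(self, region: str) -> float:
        """Planar half-section area (m^2) of a region."""
        mask = self._region_mask(region)
        return float(self.element_areas()[mask].sum())

    def region_volume(self, region: str) -> float:
        """Solid-of-revolution volume 2π ∫∫ r dA (m^3) of a region."""
        mask = self._region_mask(region)
        areas = self.element_areas()
        return float(2.0 * math.pi * (areas[mask] * self.element_centroid_r()[mask]).sum())

    def _region_mask(self, region: str) -> np.ndarray:
        if region == "all":
            return np.ones(len(self.elements), dtype=bool)
        if region not in self.geometry.regions:
            raise ConfigError(
                f"unknown region {region!r}; mesh has {self.geometry.regions}"
            )
        return self.region == region

    def node_region_values(self, per_region: dict[str, float]) -> np.ndarray:
        """Nodal field from per-region constants; nodes shared by two regions
        (the interface ring) get the arithmetic mean of the adjacent values."""
        vals = np.zeros(len(self.nodes))
        counts = np.zeros(len(self.nodes))
        for reg in self.geometry.regions:
            mask = self.region == reg
            nodes = np.unique(self.elements[mask])
            vals[nodes] += per_region[reg]
            counts[nodes] += 1.0
        if np.any(counts == 0):
            raise MeshError("mesh has orphan nodes")
        return vals / counts


def _ring_nodes(a: float, b: float, thetas: np.ndarray) -> np.ndarray:
    r = a * np.cos(thetas)
    z = b * np.sin(thetas)
    r[0] = 0.0
    r[-1] = 0.0
    return np.column_stack([r, z])


def generate_mesh(geom: PodGeometry, target_h: float = 5e-4) -> AxiMesh:
    """Mapped triangulation of the half-section at nominal element size
    ``target_h`` (m).

    For modes containing the shell, ``target_h`` must resolve the shell
    thickness (at least two element layers through it).
    """
    if target_h <= 0:
        raise MeshError(f"target_h must be positive, got {target_h}")
    has_shell = geom.mode in ("two_component", "shell_only")
    if has_shell and target_h >= geom.t_shell:
        raise MeshError(
            f"target_h={target_h} too coarse to resolve the {geom.t_shell} m shell; "
            "need target_h < t_shell"
        )

    if geom.mode in ("two_component", "kernel_only"):
        a_in, b_in = geom.a_kernel, geom.b_kernel
    else:  # pod_homogeneous (full body) / shell_only (ring)
        a_in, b_in = geom.a_outer, geom.b_outer

    n_theta = max(12, math.ceil(math.pi * geom.b_outer / target_h))
    thetas = np.linspace(-0.5 * math.pi, 0.5 * math.pi, n_theta + 1)

    rings: list[tuple[float, float]] = []
    ring_region: list[str] = []  # region of the band *inside* each ring

    if geom.mode == "shell_only":
        n_s = max(2, math.ceil(geom.t_shell / target_h))
        for j in range(n_s + 1):
            f = j / n_s
            rings.append((geom.a_kernel + f * geom.t_shell, geom.b_kernel + f * geom.t_shell))
            ring_region.append("shell")
        has_center = False
        core_region = "shell"
    else:
        core_region = "pod" if geom.mode == "pod_homogeneous" else "kernel"
        n_in = max(2, math.ceil(max(a_in, b_in) / target_h))
        for j in range(1, n_in + 1):
            f = j / n_in
            rings.append((f * a_in, f * b_in))
            ring_region.append(core_region)
        if geom.mode == "two_component":
            n_s = max(2, math.ceil(geom.t_shell / target_h))
            for j in range(1, n_s + 1):
                f = j / n_s
                rings.append(
                    (geom.a_kernel + f * geom.t_shell, geom.b_kernel + f * geom.t_shell)
                )
                ring_region.append("shell")
        has_center = True

    n_ring_nodes = n_theta + 1
    nodes_list = []
    if has_center:
        nodes_list.append(np.array([[0.0, 0.0]]))
    for a, b in rings:
        nodes_list.append(_ring_nodes(a, b, thetas))
    nodes = np.vstack(nodes_list)

    def ring_start(j: int) -> int:
        return (1 if has_center else 0) + j * n_ring_nodes

    elements = []
    regions = []
    if has_center:
        s = ring_start(0)
        for i in range(n_theta):
            elements.append((0, s + i, s + i + 1))
            regions.append(ring_region[0])
    for j in range(len(rings) - 1):
        s0, s1 = ring_start(j), ring_start(j + 1)
        reg = ring_region[j + 1]
        for i in range(n_theta):
            a0, b0 = s0 + i, s0 + i + 1
            a1, b1 = s1 + i, s1 + i + 1
            elements.append((a0, b0, b1))
            elements.append((a0, b1, a1))
            regions.append(reg)
            regions.append(reg)
    elements = np.asarray(elements, dtype=np.int64)
    regions = np.asarray(regions, dtype=object).astype(str)

    # enforce CCW orientation
    r, z = nodes[:, 0], nodes[:, 1]
    i, j, k = elements.T
    signed = 0.5 * ((r[j] - r[i]) * (z[k] - z[i]) - (r[k] - r[i]) * (z[j] - z[i]))
    flip = signed < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]
    signed = np.abs(signed)
    if np.any(signed <= 0):
        raise MeshError("degenerate (zero-area) elements generated")

    outer = ring_start(len(rings) - 1)
    boundary_edges = np.array(
        [(outer + i, outer + i + 1) for i in range(n_theta)], dtype=np.int64
    )
    if geom.mode == "shell_only":
        inner0 = ring_start(0)
        inner_edges = np.array(
            [(inner0 + i, inner0 + i + 1) for i in range(n_theta)], dtype=np.int64
        )
    else:
        inner_edges = np.empty((0, 2), dtype=np.int64)

    axis = []
    for j in range(len(rings) - 1):
        s0, s1 = ring_start(j), ring_start(j + 1)
        axis.append((s0, s1))
        axis.append((s0 + n_theta, s1 + n_theta))
    if has_center:
        axis.append((0, ring_start(0)))
        axis.append((0, ring_start(0) + n_theta))
    axis_edges = np.asarray(axis, dtype=np.int64)

    if geom.mode == "two_component":
        n_in = ring_region.index("shell")  # rings below this index are kernel
        iface0 = ring_start(n_in - 1)
        interface_edges = np.array(
            [(iface0 + i, iface0 + i + 1) for i in range(n_theta)], dtype=np.int64
        )
    else:
        interface_edges = np.empty((0, 2), dtype=np.int64)

    return AxiMesh(
        geometry=geom,
        nodes=nodes,
        elements=elements,
        region=regions,
        boundary_edges=boundary_edges,
        axis_edges=axis_edges,
        interface_edges=interface_edges,
        inner_edges=inner_edges,
    )
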