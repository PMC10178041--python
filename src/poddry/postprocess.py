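"""Summary quantities derived from simulated fields or drying curves:
volume-weighted component averages, drying rates, curve-vs-curve relative
error and safe-moisture threshold crossing times."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError
from .geometry import AxiMesh
from .slab import DryingCurve


def _lumped_r_weights(mesh: AxiMesh, mask: np.ndarray, coeff: np.ndarray | float = 1.0):
    """Nodal weights w_i = Σ_e coeff_e ∫_e r φ_i dA over the masked elements.

    For linear r on a triangle, ∫ r φ_i dA = A (2 r_i + r_j + r_k) / 12.
    """
    r = mesh.nodes[:, 0]
    areas = mesh.element_areas()
    tri = mesh.elements[mask]
    A = areas[mask]
    c = np.asarray(coeff, dtype=float)
    if c.ndim == 0:
        c = np.full(A.shape, float(c))
    rv = r[tri]  # (E, 3)
    # (2 r_i + r_j + r_k) = r_i + (r_i + r_j + r_k)
    w_elem = (A * c)[:, None] / 12.0 * (rv + rv.sum(axis=1, keepdims=True))
    w = np.zeros(len(mesh.nodes))
    np.add.at(w, tri, w_elem)
    return w


def component_average(
    mesh: AxiMesh,
    field: np.ndarray,
    region: str = "all",
    density: np.ndarray | float = 1.0,
) -> float:
    """Axisymmetric volume-weighted mean of a nodal field over a region:
    ∫ r·field dA / ∫ r dA.  ``density`` (per-element) adds dry-mass weighting,
    which is how whole-pod moisture combines the two components."""
    field = np.asarray(field, dtype=float)
    if field.shape != (len(mesh.nodes),):
        raise DomainError("field must be a nodal array")
    mask = mesh._region_mask(region)
    if not mask.any():
        raise ConfigError(f"region {region!r} has no elements")
    if np.ndim(density):
        density = np.asarray(density, dtype=float)[mask]
    w = _lumped_r_weights(mesh, mask, density)
    return float(w @ field / w.sum())


def drying_rate(curve: DryingCurve, t_start: float, t_end: float) -> float:
    """Moisture-reduction rate in dry-basis percentage points per hour:
    (M(t_start) − M(t_end)) × 100 / hours elapsed."""
    if t_end <= t_start:
        raise DomainError("t_end must exceed t_start")
    if t_start < curve.t[0] - 1e-9 or t_end > curve.t[-1] + 1e-9:
        raise DomainError("curve does not cover the requested interval")
    m0, m1 = curve.interp([t_start, t_end])
    return float((m0 - m1) * 100.0 / ((t_end - t_start) / 3600.0))


def max_relative_error(sim: DryingCurve, ref: DryingCurve) -> float:
    """Maximum |sim − ref|/ref × 100 over the common time support, with the
    simulated curve linearly interpolated onto the reference times."""
    t_lo = max(sim.t[0], ref.t[0])
    t_hi = min(sim.t[-1], ref.t[-1])
    if t_hi <= t_lo:
        raise DomainError("curves have no overlapping time support")
    mask = (ref.t >= t_lo) & (ref.t <= t_hi)
    ref_v = ref.value[mask]
    if np.any(ref_v <= 0):
        raise DomainError("reference curve must be positive where compared")
    sim_v = sim.interp(ref.t[mask])
    return float(np.max(np.abs(sim_v - ref_v) / ref_v) * 100.0)


def threshold_time(curve: DryingCurve, threshold: float = 0.10) -> float | None:
    """First time the curve falls to ``threshold`` (linear interpolation
    between samples); 0.0 if it starts at or below; None if never reached."""
    v = curve.value
    if v[0] <= threshold:
        return 0.0
    below = np.nonzero(v <= threshold)[0]
    if len(below) == 0:
        return None
    i = below[0]
    t0, t1 = curve.t[i - 1], curve.t[i]
    v0, v1 = v[i - 1], v[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (v0 - threshold) / (v0 - v1) * (t1 - t0))


@dataclass(frozen=True)
class SummaryMetrics:
    drying_rate: float
    t_safe: float | None
    max_rel_error: float | None
    dT_center_surface: float | None
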