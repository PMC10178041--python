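"""Fickian infinite-slab series solution and the log-slope inverse method for
the effective moisture diffusivity, plus drying-curve containers and I/O.

The moisture ratio of a slab of half-thickness L drying from both faces with
a fixed-surface condition is

    MR(t) = 8/π² · Σ_{n≥0} 1/(2n+1)² · exp(−(2n+1)² π² D t / (4L²)),

whose leading term gives ln MR = ln(8/π²) − D π² t / (4L²): the effective
diffusivity follows from the slope of ln MR against time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, EstimationError

_LN_8_PI2 = math.log(8.0 / math.pi**2)


@dataclass
class DryingCurve:
    """Time series of mass (g) or averaged dry-basis moisture (g/g)."""

    t: np.ndarray
    value: np.ndarray
    kind: str = "moisture"  # "mass" | "moisture"
    m_dry: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.kind not in ("mass", "moisture"):
            raise DomainError(f"kind must be 'mass' or 'moisture', got {self.kind!r}")
        if self.t.shape != self.value.shape or self.t.ndim != 1:
            raise DomainError("t and value must be 1-D arrays of equal length")
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise DomainError("times must be strictly increasing")
        if np.any(self.value < 0):
            raise DomainError("curve values must be non-negative")

    def interp(self, times) -> np.ndarray:
        return np.interp(times, self.t, self.value)

    # ---- CSV round trip --------------------------------------------------
    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.t, "value": self.value, "kind": self.kind}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DryingCurve":
        df = pd.read_csv(path)
        missing = {"time_s", "value"} - set(df.columns)
        if missing:
            raise DomainError(f"drying-curve CSV missing columns: {sorted(missing)}")
        kind = str(df["kind"].iloc[0]) if "kind" in df.columns else "moisture"
        return cls(t=df["time_s"].to_numpy(), value=df["value"].to_numpy(), kind=kind)


def moisture_from_mass(curve: DryingCurve, m_dry: float | None = None) -> DryingCurve:
    """Convert a mass curve m_t (g) to dry-basis moisture W_t = (m_t − m)/m."""
    m = curve.m_dry if m_dry is None else m_dry
    if m is None or m <= 0:
        raise DomainError(f"dry-matter mass must be positive, got {m!r}")
    if curve.kind != "mass":
        raise DomainError("moisture_from_mass expects a mass-kind curve")
    W = (curve.value - m) / m
    if np.any(W < -1e-9):
        raise DomainError("mass curve drops below the dry-matter mass")
    return DryingCurve(t=curve.t, value=np.clip(W, 0.0, None), kind="moisture", m_dry=m)


def slab_MR(D: float, L: float, t, n_terms: int = 50):
    """Truncated slab moisture-ratio series; scalar or array ``t`` (s)."""
    if D <= 0 or L <= 0:
        raise DomainError("D and L must be positive")
    if n_terms < 1:
        raise DomainError("n_terms must be at least 1")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise DomainError("times must be non-negative")
    n = np.arange(n_terms)
    odd = 2 * n + 1
    rate = (math.pi**2) * D / (4.0 * L * L)
    terms = np.exp(-np.multiply.outer(t_arr, odd**2 * rate)) / odd**2
    out = 8.0 / math.pi**2 * terms.sum(axis=-1)
    return out if t_arr.ndim else float(out)


@dataclass(frozen=True)
class DeffEstimate:
    """Result of the log-slope inverse fit."""

    D_eff: float
    slope: float
    intercept: float
    r_squared: float
    L: float
    n_points: int


def estimate_deff(
    curve: DryingCurve,
    L: float,
    M_e: float = 0.0,
    M0: float | None = None,
    fit_window: tuple[float, float] | None = None,
    mr_max: float = 0.6,
) -> DeffEstimate:
    """Estimate the effective diffusivity from a moisture drying curve.

    MR is formed as (M − M_e)/(M0 − M_e) with M0 the first curve value unless
    given, and a least-squares line of ln MR against t yields
    D_eff = −slope · 4L²/π².  Points with MR ≥ ``mr_max`` (default 0.6) are
    excluded: the single-term slope formula is only valid once the higher
    series terms have decayed.  ``fit_window`` optionally restricts the fit
    to times in [t_lo, t_hi].  Non-positive-MR points are dropped.
    """
    if curve.kind != "moisture":
        raise DomainError("estimate_deff expects a moisture-kind curve")
    if L <= 0:
        raise DomainError("half-thickness L must be positive")
    M = curve.value
    M0 = float(M[0]) if M0 is None else M0
    if M0 <= M_e:
        raise EstimationError("initial moisture must exceed the equilibrium moisture")
    MR = (M - M_e) / (M0 - M_e)
    mask = (MR > 0.0) & (MR < mr_max)
    if fit_window is not None:
        t_lo, t_hi = fit_window
        mask &= (curve.t >= t_lo) & (curve.t <= t_hi)
    n_used = int(mask.sum())
    if n_used < 3:
        raise EstimationError(
            f"only {n_used} usable points with 0 < MR < {mr_max}; need at least 3"
        )
    t_fit = curve.t[mask]
    y = np.log(MR[mask])
    fit = stats.linregress(t_fit, y)
    if not fit.slope < 0:
        raise EstimationError(
            f"non-negative ln MR slope ({fit.slope:.3g} 1/s): curve is not drying"
        )
    D = -fit.slope * 4.0 * L * L / math.pi**2
    return DeffEstimate(
        D_eff=D,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        L=L,
        n_points=n_used,
    )


def synthesize_curve(
    D: float,
    L: float,
    M0: float,
    M_e: float,
    times,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_terms: int = 50,
) -> DryingCurve:
    """Synthetic slab drying curve M(t) = M_e + (M0 − M_e)·MR(t), optionally
    with multiplicative Gaussian noise of relative s.d. ``noise_sd``."""
    if M0 <= M_e or M_e < 0:
        raise DomainError("need M0 > M_e >= 0")
    times = np.asarray(times, dtype=float)
    M = M_e + (M0 - M_e) * slab_MR(D, L, times, n_terms=n_terms)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        M = M * (1.0 + noise_sd * rng.standard_normal(M.shape))
    return DryingCurve(t=times, value=np.clip(M, 0.0, None), kind="moisture")
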