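"""One-off deterministic calibration of the surface-resistance factor f_s.

The raw Sherwood-correlation mass transfer coefficient is a vapor-
concentration-basis air-side quantity; driving a dry-basis surface flux with
it directly gives a mass Biot number of order 1e8 — a near-fixed-value
surface that dries orders of magnitude faster than the tissue can supply.
The dimensionless factor f_s rescales it into the moisture-content-basis
coefficient h_m_eff = f_s·h_m actually used by the boundary condition.

f_s is fixed by a single scalar condition: the two-component simulation must
reproduce the whole-pod average drying rate (3.53 dry-basis percentage points
per hour over 1230 min).  Nothing else is tuned; every component-level
quantity is a held-out prediction of the calibrated model.  The search is a
bounded Brent root find in log10 f_s, preceded by a monotonicity sweep, and
is fully deterministic.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .config import RunConfig, build_run, simulate
from .errors import CalibrationError
from .geometry import generate_mesh
from .postprocess import drying_rate

logger = logging.getLogger(__name__)

#: Whole-pod simulated drying rate used as the calibration fixed point, %/h.
DEFAULT_TARGET_RATE = 3.53


@dataclass(frozen=True)
class CalibrationResult:
    f_s: float
    M_e: float
    objective: float      # |simulated rate - target|, %/h
    rate: float           # simulated pod rate at f_s, %/h
    target_rate: float
    n_evals: int
    frozen: bool = True


def pod_rate(cfg: RunConfig, mesh=None) -> float:
    """Whole-pod average drying rate of the configured run, %/h."""
    res = simulate(cfg, mesh=mesh)
    curve = res.moisture_curve("pod")
    return drying_rate(curve, 0.0, float(curve.t[-1]))


def calibrate_surface(
    cfg: RunConfig | None = None,
    target_rate: float = DEFAULT_TARGET_RATE,
    bounds: tuple[float, float] = (1e-9, 1e-4),
    log_xtol: float = 1e-4,
    sweep_points: int = 4,
) -> CalibrationResult:
    """Find f_s such that the two-component pod drying rate equals
    ``target_rate``.  Raises :class:`CalibrationError` if the bounds do not
    bracket the target or the sweep is not monotone."""
    cfg = dataclasses.replace(cfg) if cfg is not None else RunConfig()
    if cfg.geometry.mode != "two_component":
        raise CalibrationError("calibration is defined for the two_component mode")
    mesh, *_ = build_run(cfg)  # build once, reuse for every evaluation

    n_evals = 0

    def rate_at(f_s: float) -> float:
        nonlocal n_evals
        n_evals += 1
        trial = dataclasses.replace(cfg, bc=dataclasses.replace(cfg.bc, f_s=f_s))
        r = pod_rate(trial, mesh=mesh)
        logger.info("calibration eval f_s=%.6e -> rate=%.4f %%/h", f_s, r)
        return r

    lo, hi = bounds
    sweep_fs = np.logspace(np.log10(lo), np.log10(hi), sweep_points)
    sweep_rates = np.array([rate_at(f) for f in sweep_fs])
    if np.any(np.diff(sweep_rates) <= 0):
        raise CalibrationError(
            f"drying rate is not monotone in f_s over {bounds}: {sweep_rates}"
        )
    if not sweep_rates[0] < target_rate < sweep_rates[-1]:
        raise CalibrationError(
            f"target rate {target_rate} %/h not bracketed by bounds {bounds}: "
            f"rates span [{sweep_rates[0]:.4f}, {sweep_rates[-1]:.4f}] %/h"
        )
    # restrict to the bracketing sweep interval before the root find
    idx = int(np.searchsorted(sweep_rates, target_rate))
    x_lo, x_hi = np.log10(sweep_fs[idx - 1]), np.log10(sweep_fs[idx])

    x_root = brentq(lambda x: rate_at(10.0**x) - target_rate, x_lo, x_hi, xtol=log_xtol)
    f_s = float(10.0**x_root)
    rate = rate_at(f_s)
    return CalibrationResult(
        f_s=f_s,
        M_e=cfg.bc.M_e,
        objective=abs(rate - target_rate),
        rate=rate,
        target_rate=target_rate,
        n_evals=n_evals,
    )
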