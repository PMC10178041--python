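"""Independent analytic/numerical reference solutions used to validate the
finite-element solver and the slab series.  These are deliberately coded
from the classical closed forms, not by calling the package."""

import numpy as np
from scipy.optimize import brentq


def sphere_mean_MR_dirichlet(Fo: float, n_terms: int = 200) -> float:
    """Volume-mean moisture ratio of a sphere with fixed surface value:
    MR = 6/π² Σ (1/n²) exp(−n²π²Fo)."""
    n = np.arange(1, n_terms + 1)
    return float(6.0 / np.pi**2 * np.sum(np.exp(-(n**2) * np.pi**2 * Fo) / n**2))


def sphere_center_theta_robin(Bi: float, Fo: float, n_roots: int = 30) -> float:
    """Center temperature ratio θ/θ0 of a convectively cooled/heated sphere:
    θ/θ0 = Σ Cn exp(−ζn² Fo), 1 − ζ cot ζ = Bi,
    Cn = 4 (sin ζ − ζ cos ζ) / (2ζ − sin 2ζ)."""
    roots = []
    for i in range(1, n_roots + 1):
        lo = (i - 1) * np.pi + 1e-9
        hi = i * np.pi - 1e-9
        roots.append(brentq(lambda z: 1.0 - z / np.tan(z) - Bi, lo, hi))
    z = np.asarray(roots)
    Cn = 4.0 * (np.sin(z) - z * np.cos(z)) / (2.0 * z - np.sin(2.0 * z))
    return float(np.sum(Cn * np.exp(-(z**2) * Fo)))


def slab_mean_MR_fd(D: float, L: float, t_end: float, nx: int = 201, nt: int = 2000) -> float:
    """Volume-mean moisture ratio of a symmetric slab (half-thickness L, zero
    surface value) by Crank–Nicolson finite differences on [0, L] with a
    symmetry condition at x = 0."""
    x = np.linspace(0.0, L, nx)
    dx = x[1] - x[0]
    dt = t_end / nt
    lam = D * dt / (2.0 * dx * dx)
    main = np.full(nx, 1.0 + 2.0 * lam)
    lower = np.full(nx - 1, -lam)
    upper = np.full(nx - 1, -lam)
    # symmetry at node 0: mirror neighbour
    upper[0] = -2.0 * lam
    # Dirichlet at node nx-1
    main[-1] = 1.0
    lower[-1] = 0.0
    A = np.diag(main) + np.diag(lower, -1) + np.diag(upper, 1)
    u = np.ones(nx)
    u[-1] = 0.0
    from scipy.linalg import lu_factor, lu_solve

    lu = lu_factor(A)
    for _ in range(nt):
        rhs = u.copy()
        rhs[0] = u[0] + 2.0 * lam * (u[1] - u[0])
        rhs[1:-1] = u[1:-1] + lam * (u[2:] - 2.0 * u[1:-1] + u[:-2])
        rhs[-1] = 0.0
        u = lu_solve(lu, rhs)
    return float(np.trapezoid(u, x) / L)
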