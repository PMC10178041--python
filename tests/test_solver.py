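import dataclasses

import numpy as np
import pytest

import poddry
from poddry.config import RunConfig, simulate
from poddry.errors import ConfigError
from poddry.properties import MaterialModel
from poddry.solver import BoundaryConditions, SimulationConfig, run_simulation

from .oracles import sphere_center_theta_robin, sphere_mean_MR_dirichlet

T0_K, TA_K = 293.15, 315.15


@pytest.fixture(scope="module")
def sphere_mesh():
    geom = poddry.build_geometry(a_kernel=0.005, b_kernel=0.005, mode="kernel_only")
    return poddry.generate_mesh(geom, 2.5e-4)


def _const_material(D=2.91731e-10, k=0.3, cp_kJ=2.0, rho=1000.0, M0=1.0, h_g=0.0):
    return MaterialModel(
        name="kernel", rho=rho, k_of_M=(0.0, k), cp_of_M=(0.0, cp_kJ),
        D_eff=D, M0=M0, h_g=h_g,
    )


class TestEquilibriumFixedPoints:
    def test_uniform_equilibrium_state_is_unchanged(self, sphere_mesh):
        """At M = M_e and T = T_a every field stays put for all steps."""
        mat = _const_material(M0=1.0)
        bc = BoundaryConditions(T0=TA_K, Ta=TA_K, h_T=30.0, h_m_eff=1e-5, M_e=0.3)
        sim = SimulationConfig(dt=60.0, t_end=600.0, snapshot_times=())
        res = run_simulation(sphere_mesh, {"kernel": mat}, bc, sim)
        # start the moisture at equilibrium by choosing M0 = M_e
        mat_eq = _const_material(M0=0.3000001)
        bc_eq = BoundaryConditions(T0=TA_K, Ta=TA_K, h_T=30.0, h_m_eff=1e-5, M_e=0.3)
        res_eq = run_simulation(sphere_mesh, {"kernel": mat_eq}, bc_eq, sim)
        np.testing.assert_allclose(res_eq.M_region["kernel"], 0.3000001, atol=1e-7)
        np.testing.assert_allclose(res.T_mean, TA_K, atol=1e-9)

    def test_closed_system_conserves_water(self, sphere_mesh):
        """With zero surface mass transfer the total water mass is constant to
        linear-solver precision."""
        mat = _const_material()
        bc = BoundaryConditions(T0=T0_K, Ta=TA_K, h_T=30.0, h_m_eff=0.0, M_e=0.0)
        sim = SimulationConfig(dt=60.0, t_end=3600.0, snapshot_times=())
        res = run_simulation(sphere_mesh, {"kernel": mat}, bc, sim)
        assert np.max(np.abs(res.mass_change)) < 1e-12
        np.testing.assert_allclose(res.M_region["kernel"], 1.0, atol=1e-10)


class TestOracleEquivalence:
    def test_sphere_moisture_matches_series_solution(self, sphere_mesh):
        """Homogeneous sphere, near-fixed surface: volume-mean MR at Fo = 0.1
        agrees with the classical Dirichlet series within 1%."""
        R, D = 0.005, 2.91731e-10
        Fo = 0.1
        t_end = Fo * R * R / D
        mat = _const_material(D=D)
        bc = BoundaryConditions(T0=TA_K, Ta=TA_K, h_T=0.0, h_m_eff=1.0, M_e=0.0)
        sim = SimulationConfig(dt=t_end / 500, t_end=t_end, snapshot_times=())
        res = run_simulation(sphere_mesh, {"kernel": mat}, bc, sim)
        MR = res.M_region["kernel"][-1]
        assert MR == pytest.approx(sphere_mean_MR_dirichlet(Fo), rel=0.01)

    def test_sphere_heat_conduction_matches_series_solution(self, sphere_mesh):
        """Constant properties, no evaporation: center temperature at Fo = 0.2
        agrees with the Robin-sphere series within 0.5%."""
        R, k, rho, cp = 0.005, 0.3, 1000.0, 2000.0
        h_T = 32.0
        alpha = k / (rho * cp)
        Fo = 0.2
        t_end = Fo * R * R / alpha
        mat = _const_material(k=k, cp_kJ=cp / 1000.0, rho=rho, h_g=0.0)
        bc = BoundaryConditions(T0=T0_K, Ta=TA_K, h_T=h_T, h_m_eff=0.0, M_e=0.0)
        sim = SimulationConfig(dt=t_end / 400, t_end=t_end, snapshot_times=())
        res = run_simulation(sphere_mesh, {"kernel": mat}, bc, sim)
        theta = (res.T_center[-1] - TA_K) / (T0_K - TA_K)
        expected = sphere_center_theta_robin(Bi=h_T * R / k, Fo=Fo)
        assert theta == pytest.approx(expected, rel=0.005)


class TestEvaporativeCoupling:
    def test_drying_depresses_temperature(self, sphere_mesh):
        """With the latent sink active the mean temperature stays strictly
        below the no-evaporation trajectory at every step."""
        common = dict(D=2.91731e-10, k=0.3, cp_kJ=2.0, rho=1000.0)
        bc = BoundaryConditions(T0=T0_K, Ta=TA_K, h_T=32.0, h_m_eff=1e-5, M_e=0.02)
        sim = SimulationConfig(dt=60.0, t_end=3600.0, snapshot_times=())
        wet = run_simulation(
            sphere_mesh, {"kernel": _const_material(h_g=2_256_267.0, **common)}, bc, sim
        )
        dry = run_simulation(
            sphere_mesh, {"kernel": _const_material(h_g=0.0, **common)}, bc, sim
        )
        assert np.all(wet.T_mean[1:] < dry.T_mean[1:])


class TestDefaultRunInvariants:
    def test_mass_balance_per_step(self, two_component_result):
        """Change in total water mass each step equals the surface flux
        integral within 0.1% of the larger term."""
        res = two_component_result
        num = np.abs(res.mass_change + res.boundary_loss)
        den = np.maximum(np.abs(res.mass_change), np.abs(res.boundary_loss))
        assert np.max(num / den) < 1e-3

    def test_discrete_maximum_principle(self, two_component_result):
        res = two_component_result
        for snap in res.snapshots:
            assert snap.T.min() >= T0_K - 0.01 and snap.T.max() <= TA_K + 0.01
            assert snap.M.min() >= 0.02 - 1e-6 and snap.M.max() <= 1.24 + 1e-6

    def test_reruns_are_bit_identical(self, default_cfg, two_component_result):
        res2 = simulate(default_cfg)
        assert np.array_equal(res2.M_pod, two_component_result.M_pod)
        assert np.array_equal(res2.T_mean, two_component_result.T_mean)

    def test_long_time_limits(self, default_cfg):
        """At ten times the nominal duration the fields approach M_e and T_a
        uniformly (coarse mesh, large steps)."""
        cfg = dataclasses.replace(
            default_cfg,
            numerics=dataclasses.replace(
                default_cfg.numerics, dt=600.0, t_end=738_000.0, mesh_h=8e-4
            ),
        )
        res = simulate(cfg)
        assert res.M_pod[-1] == pytest.approx(0.02, abs=1e-6)
        assert res.T_mean[-1] == pytest.approx(TA_K, abs=1e-6)

    def test_first_order_temporal_convergence(self, default_cfg):
        """Successive dt halvings shrink the curve change by a factor of two,
        the signature of a first-order scheme."""
        def run(dt):
            cfg = dataclasses.replace(
                default_cfg,
                numerics=dataclasses.replace(default_cfg.numerics, dt=dt, t_end=14_400.0),
            )
            return simulate(cfg)

        a, b, c = run(60.0), run(30.0), run(15.0)
        for reg in ("shell", "kernel"):
            d1 = np.max(np.abs(a.M_region[reg] - b.M_region[reg][::2]))
            d2 = np.max(np.abs(b.M_region[reg] - c.M_region[reg][::2]))
            assert 1.5 < d1 / d2 < 2.6, f"{reg}: halving ratio {d1 / d2:.2f}"

    def test_missing_material_rejected(self, sphere_mesh):
        bc = BoundaryConditions(T0=T0_K, Ta=TA_K, h_T=30.0, h_m_eff=0.0, M_e=0.0)
        with pytest.raises(ConfigError):
            run_simulation(sphere_mesh, {}, bc, SimulationConfig(dt=60, t_end=60))
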