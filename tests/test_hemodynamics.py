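"""Rheology, network flow, hematocrit phase separation and interstitium."""

import numpy as np
import pytest

from tmesim.angiogenesis import VesselNetwork
from tmesim.grid import LatticeSpec, ScalarField
from tmesim.hemodynamics import (
    MMHG_TO_PA,
    PA_TO_DYN_CM2,
    FluidParams,
    blood_viscosity,
    couple_flow_interstitium,
    distribute_hematocrit,
    hematocrit_factor,
    ifp_source_field,
    poiseuille_flow,
    relative_viscosity,
    solve_interstitial,
    solve_network_flow,
    starling_flux,
    wall_shear_stress,
)


@pytest.fixture
def fluid():
    return FluidParams()


class TestRheology:
    def test_large_diameter_limit(self):
        assert np.isclose(relative_viscosity(1e6), 3.2, atol=1e-9)

    def test_small_diameter_large_finite(self):
        mu = relative_viscosity(3.0)
        assert 3.2 < mu < 20.0

    def test_pries_formula_at_10um(self):
        d = 10.0
        expected = 3.2 + 6 * np.exp(-0.85) - 2.44 * np.exp(-0.06 * 10**0.645)
        assert np.isclose(relative_viscosity(d), expected, rtol=1e-12)

    def test_hematocrit_factor_normalization(self):
        assert np.isclose(hematocrit_factor(0.45, 12.0, 0.45), 1.0)
        assert hematocrit_factor(0.0, 12.0) == 0.0

    def test_hematocrit_factor_monotone(self):
        hs = np.linspace(0.0, 0.8, 50)
        for d in (4.0, 10.0, 40.0):
            f = hematocrit_factor(hs, d)
            assert np.all(np.diff(f) > 0)

    def test_blood_viscosity_plasma_limit(self, fluid):
        mu = blood_viscosity(1e5, 0.0, fluid)
        assert np.isclose(mu, fluid.mu_plasma, rtol=1e-4)

    def test_blood_viscosity_composition_oracle(self, fluid):
        d, h = 15.0, 0.3
        mu_n = relative_viscosity(d)
        f = hematocrit_factor(h, d, fluid.H_D_n)
        wall = (d / (d - 1.1)) ** 2
        expected = (1 + (mu_n - 1) * f * wall) * wall * fluid.mu_plasma
        assert np.isclose(blood_viscosity(d, h, fluid), expected, rtol=1e-12)

    def test_collapsed_pole_rejected(self, fluid):
        with pytest.raises(ValueError):
            blood_viscosity(1.0, 0.3, fluid)


class TestElementaryFlows:
    def test_zero_pressure_drop(self):
        assert poiseuille_flow(0.0, 10.0, 50.0, 1e-3) == 0.0

    def test_fourth_power_law(self):
        q1 = poiseuille_flow(10.0, 10.0, 50.0, 1e-3)
        q2 = poiseuille_flow(10.0, 20.0, 50.0, 1e-3)
        assert np.isclose(q2 / q1, 16.0)

    def test_hand_value(self):
        # dp=10 mmHg, d=10 um, L=50 um, mu=3e-3 Pa s
        expected = (np.pi / 128) * (10 * MMHG_TO_PA) * 1e4 / (50 * 3e-3)
        assert np.isclose(poiseuille_flow(10.0, 10.0, 50.0, 3e-3), expected)

    def test_starling_equilibrium(self, fluid):
        assert np.isclose(starling_flux(10.0, 50.0, fluid.osmotic_jump, fluid), 0.0)

    def test_starling_sign_follows_bracket(self, fluid):
        assert starling_flux(10.0, 50.0, fluid.osmotic_jump + 1.0, fluid) > 0
        assert starling_flux(10.0, 50.0, fluid.osmotic_jump - 1.0, fluid) < 0

    def test_starling_hand_value(self, fluid):
        expected = np.pi * 10.0 * 50.0 * fluid.L_p * (20.0 - fluid.osmotic_jump)
        assert np.isclose(starling_flux(10.0, 50.0, 20.0, fluid), expected)


def pipe_network(lat, sites, d_v=10.0, p_in=30.0, p_out=20.0):
    net = VesselNetwork(lat)
    net.add_node(sites[0], kind="primary", fixed_pressure=p_in)
    for s in sites[1:-1]:
        net.add_node(s)
    net.add_node(sites[-1], kind="primary", fixed_pressure=p_out)
    for a, b in zip(sites, sites[1:]):
        net.add_segment(a, b, d_v, 1.0)
        net.graph.edges[a, b]["d_v_def"] = d_v
    return net


class TestNetworkFlow:
    def test_single_pipe_matches_closed_form(self, fluid):
        lat = LatticeSpec(9, 9, 9, 50.0)
        fluid.L_p = 0.0  # no leak
        net = pipe_network(lat, [(2, 4, 4), (3, 4, 4), (4, 4, 4)])
        p_ins = ScalarField.uniform(lat, 0.0, "p_ins")
        sol = solve_network_flow(net, p_ins, fluid)
        mu = blood_viscosity(10.0, 0.0, fluid)
        q_expected = poiseuille_flow(10.0 / 2, 10.0, 50.0, mu)  # 5 mmHg per segment
        for *_, d in net.graph.edges(data=True):
            assert np.isclose(d["Q_lum"], q_expected, rtol=1e-9)
            tau_expected = 32 * mu * q_expected / (np.pi * 1e3) * PA_TO_DYN_CM2
            assert np.isclose(d["tau"], tau_expected, rtol=1e-9)
        assert sol.residual < 1e-9

    def test_symmetric_y_equal_branch_flows(self, fluid):
        lat = LatticeSpec(9, 9, 9, 50.0)
        fluid.L_p = 0.0
        net = VesselNetwork(lat)
        net.add_node((2, 4, 4), kind="primary", fixed_pressure=30.0)
        net.add_node((3, 4, 4))
        net.add_node((4, 5, 4), kind="primary", fixed_pressure=20.0)
        net.add_node((4, 3, 4), kind="primary", fixed_pressure=20.0)
        net.add_segment((2, 4, 4), (3, 4, 4), 10.0, 1.0)
        net.add_segment((3, 4, 4), (4, 5, 4), 8.0, 1.0)
        net.add_segment((3, 4, 4), (4, 3, 4), 8.0, 1.0)
        p_ins = ScalarField.uniform(lat, 0.0, "p_ins")
        solve_network_flow(net, p_ins, fluid)
        q1 = net.graph.edges[(3, 4, 4), (4, 5, 4)]["Q_lum"]
        q2 = net.graph.edges[(3, 4, 4), (4, 3, 4)]["Q_lum"]
        assert np.isclose(abs(q1), abs(q2), rtol=1e-9)
        q_parent = net.graph.edges[(2, 4, 4), (3, 4, 4)]["Q_lum"]
        assert np.isclose(abs(q_parent), abs(q1) + abs(q2), rtol=1e-9)

    def test_global_mass_balance_with_leak(self, fluid):
        lat = LatticeSpec(11, 11, 11, 50.0)
        sites = [(i, 5, 5) for i in range(2, 9)]
        net = pipe_network(lat, sites, d_v=12.0)
        p_ins = ScalarField.uniform(lat, 1.0, "p_ins")
        sol = solve_network_flow(net, p_ins, fluid)
        assert sol.total_leak != 0.0
        assert np.isclose(sol.total_inflow, sol.total_outflow + sol.total_leak,
                          rtol=1e-8)
        assert sol.residual < 1e-10 * sol.total_inflow  # relative to throughput

    def test_tau_dual_computation_identity(self, fluid):
        lat = LatticeSpec(9, 9, 9, 50.0)
        net = pipe_network(lat, [(2, 4, 4), (3, 4, 4), (4, 4, 4)], d_v=14.0)
        p_ins = ScalarField.uniform(lat, 0.0, "p_ins")
        solve_network_flow(net, p_ins, fluid)
        for *_, d in net.graph.edges(data=True):
            assert np.isclose(
                d["tau"], wall_shear_stress(d["mu_blood"], d["Q_lum"], 14.0),
                rtol=1e-12,
            )

    def test_unreferenced_component_flowless(self, fluid):
        lat = LatticeSpec(9, 9, 9, 50.0)
        net = VesselNetwork(lat)
        net.add_node((2, 2, 2))
        net.add_node((3, 2, 2))
        net.add_segment((2, 2, 2), (3, 2, 2), 10.0, 1.0)
        fluid.L_p = 0.0
        p_ins = ScalarField.uniform(lat, 0.0, "p_ins")
        with pytest.warns(UserWarning):
            solve_network_flow(net, p_ins, fluid)
        assert net.graph.edges[(2, 2, 2), (3, 2, 2)]["Q_lum"] == 0.0


class TestHematocrit:
    def _y_split(self, fluid, d1=8.0, d2=8.0, p1=20.0, p2=20.0):
        lat = LatticeSpec(9, 9, 9, 50.0)
        net = VesselNetwork(lat)
        net.add_node((2, 4, 4), kind="primary", fixed_pressure=30.0)
        net.add_node((3, 4, 4))
        net.add_node((4, 5, 4), kind="primary", fixed_pressure=p1)
        net.add_node((4, 3, 4), kind="primary", fixed_pressure=p2)
        net.add_segment((2, 4, 4), (3, 4, 4), 12.0, 1.0)
        net.add_segment((3, 4, 4), (4, 5, 4), d1, 1.0)
        net.add_segment((3, 4, 4), (4, 3, 4), d2, 1.0)
        fluid.L_p = 0.0
        p_ins = ScalarField.uniform(lat, 0.0, "p_ins")
        solve_network_flow(net, p_ins, fluid)
        distribute_hematocrit(net, fluid)
        return net

    def test_equal_daughters_two_thirds_one_third(self, fluid):
        net = self._y_split(fluid)
        hp = fluid.H_D_n
        h1 = net.graph.edges[(3, 4, 4), (4, 5, 4)]["H_D"]
        h2 = net.graph.edges[(3, 4, 4), (4, 3, 4)]["H_D"]
        hs = sorted([h1, h2])
        assert np.isclose(hs[1], 2 * hp / 3, rtol=1e-9)
        assert np.isclose(hs[0], hp / 3, rtol=1e-9)
        assert np.isclose(h1 + h2, hp, rtol=1e-12)

    def test_fast_branch_takes_all_beyond_threshold(self, fluid):
        # narrow fast daughter vs wide slow daughter: velocity ratio >> r_th
        net = self._y_split(fluid, d1=12.0, d2=3.0, p1=10.0, p2=19.5)
        e_fast = net.graph.edges[(3, 4, 4), (4, 5, 4)]
        e_slow = net.graph.edges[(3, 4, 4), (4, 3, 4)]
        u = lambda e, d: abs(e["Q_lum"]) / (np.pi * d**2 / 4)
        assert u(e_fast, 12.0) / u(e_slow, 3.0) > fluid.r_th
        assert np.isclose(e_fast["H_D"], fluid.H_D_n)
        assert e_slow["H_D"] == 0.0

    def test_split_conserves_parent_hematocrit(self, fluid):
        for (d1, d2) in [(8, 8), (10, 6), (12, 5), (7, 9)]:
            net = self._y_split(fluid, d1=float(d1), d2=float(d2))
            h1 = net.graph.edges[(3, 4, 4), (4, 5, 4)]["H_D"]
            h2 = net.graph.edges[(3, 4, 4), (4, 3, 4)]["H_D"]
            assert np.isclose(h1 + h2, fluid.H_D_n, rtol=1e-12)


class TestInterstitium:
    def test_no_vessels_zero_everywhere(self, fluid):
        lat = LatticeSpec(15, 15, 15, 50.0)
        net = VesselNetwork(lat)
        src = ifp_source_field(net, ScalarField.uniform(lat, 0.0, "p"), fluid)
        assert np.allclose(src.values, 0.0)
        p, u = solve_interstitial(net, fluid)
        assert np.allclose(p.values, 0.0, atol=1e-12)
        assert np.allclose(u.ux, 0.0)

    def test_starling_equilibrium_zero_source(self, fluid):
        lat = LatticeSpec(9, 9, 9, 50.0)
        net = pipe_network(lat, [(2, 4, 4), (3, 4, 4), (4, 4, 4)])
        for n in net.graph.nodes:
            net.graph.nodes[n]["p_lum"] = fluid.osmotic_jump
        src = ifp_source_field(net, ScalarField.uniform(lat, 0.0, "p"), fluid)
        assert np.allclose(src.values, 0.0, atol=1e-14)

    def test_single_node_source_hand_value(self, fluid):
        lat = LatticeSpec(9, 9, 9, 50.0)
        net = VesselNetwork(lat)
        net.add_node((4, 4, 4), kind="primary", fixed_pressure=30.0)
        net.graph.nodes[(4, 4, 4)]["p_lum"] = 30.0
        src = ifp_source_field(net, ScalarField.uniform(lat, 2.0, "p"), fluid)
        expected = fluid.L_p * fluid.S_over_V / fluid.K_ins * \
            (30.0 - 2.0 - fluid.osmotic_jump)
        assert np.isclose(src.values[4, 4, 4], expected)
        assert np.count_nonzero(src.values) == 1

    def test_leaky_vessel_peak_and_outward_flow(self, fluid):
        lat = LatticeSpec(21, 21, 21, 50.0)
        sites = [(i, 10, 10) for i in range(8, 13)]
        net = pipe_network(lat, sites, d_v=20.0)
        p_ins = ScalarField.uniform(lat, 0.0, "p_ins")
        solve_network_flow(net, p_ins, fluid)
        p, u = solve_interstitial(net, fluid)
        peak = np.unravel_index(np.argmax(p.values), p.values.shape)
        assert peak[1] == 10 and peak[2] == 10 and 8 <= peak[0] <= 12
        # Darcy velocity points away from the vessel line
        assert u.uy[10, 14, 10] > 0 and u.uy[10, 6, 10] < 0
        assert u.uz[10, 10, 14] > 0 and u.uz[10, 10, 6] < 0

    def test_flux_balance_divergence_theorem(self, fluid):
        # total Starling filtration equals the Darcy outflux through a box
        lat = LatticeSpec(41, 41, 41, 50.0)
        sites = [(i, 20, 20) for i in range(17, 24)]
        net = pipe_network(lat, sites, d_v=20.0)
        p_ins = ScalarField.uniform(lat, 0.0, "p_ins")
        solve_network_flow(net, p_ins, fluid)
        p, u = solve_interstitial(net, fluid)
        # source strength as the Poisson right side integrated over volume
        src = ifp_source_field(net, p, fluid)
        total_src = src.values.sum() * lat.h**3 * fluid.K_ins  # um^3/s
        # surface integral of u over the domain boundary faces
        h2 = lat.h**2
        flux = (
            u.ux[-1, :, :].sum() - u.ux[0, :, :].sum()
            + u.uy[:, -1, :].sum() - u.uy[:, 0, :].sum()
            + u.uz[:, :, -1].sum() - u.uz[:, :, 0].sum()
        ) * h2
        assert np.isclose(flux, total_src, rtol=0.05)


class TestCoupling:
    def test_no_leak_converges_immediately(self, fluid):
        lat = LatticeSpec(9, 9, 9, 50.0)
        fluid.L_p = 0.0
        net = pipe_network(lat, [(2, 4, 4), (3, 4, 4), (4, 4, 4)])
        flow, p, u, iters = couple_flow_interstitium(net, fluid, tol=1e-9)
        assert iters <= 2
        assert np.allclose(p.values, 0.0, atol=1e-12)

    def test_converged_residual_below_tol(self, fluid):
        lat = LatticeSpec(11, 11, 11, 50.0)
        sites = [(i, 5, 5) for i in range(2, 9)]
        net = pipe_network(lat, sites, d_v=15.0)
        tol = 1e-6
        flow1, p1, _, it1 = couple_flow_interstitium(net, fluid, tol=tol)
        # re-coupling from the converged state changes nothing beyond tol
        flow2, p2, _, it2 = couple_flow_interstitium(net, fluid, p_ins_init=p1,
                                                     tol=tol)
        assert np.max(np.abs(p2.values - p1.values)) < 10 * tol
        for n, v in flow1.node_pressure.items():
            if v is not None:
                assert abs(flow2.node_pressure[n] - v) < 10 * tol
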