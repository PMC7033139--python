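"""Sprouting, tip migration, lumenogenesis, adaptation and disruption."""

import numpy as np
import pytest

from tmesim.angiogenesis import (
    AdaptationParams,
    ComplianceParams,
    DisruptionParams,
    LumenParams,
    SproutingParams,
    TipCell,
    VesselNetwork,
    adapt_diameter,
    adaptation_stimuli,
    anastomose,
    deform_diameter,
    disrupt_vessels,
    extend_sprout,
    lumen_diameter,
    maybe_branch,
    select_sprout_sites,
    stalk_growth_step,
    tec_move_probabilities,
)
from tmesim.grid import NEIGHBOR_OFFSETS, LatticeSpec, ScalarField
from tmesim.tumor_cells import MotilityParams


@pytest.fixture
def lat():
    return LatticeSpec(15, 15, 15, 50.0)


@pytest.fixture
def lumen():
    return LumenParams()


def build_chain(lat, sites, lumen, kinds=None):
    net = VesselNetwork(lat)
    for i, s in enumerate(sites):
        kind = (kinds or ["neo"] * len(sites))[i]
        net.add_node(s, kind=kind, fixed_pressure=30.0 if kind == "primary" else None)
    for a, b in zip(sites, sites[1:]):
        ka = net.graph.nodes[a]["kind"]
        kb = net.graph.nodes[b]["kind"]
        net.add_segment(a, b, 10.0, 1.0,
                        kind="primary" if ka == kb == "primary" else "neo")
    return net


class TestSproutSelection:
    def test_no_vegf_no_sprouts(self, lat, rng):
        sp = SproutingParams()
        ring = [(2, y, 7) for y in range(2, 12)]
        c_v = ScalarField.uniform(lat, 0.0, "c_v")
        assert select_sprout_sites(ring, c_v, sp, rng) == []

    def test_close_candidates_notch_exclusion(self, lat, rng):
        sp = SproutingParams(min_spacing=150.0)
        ring = [(2, 5, 7), (2, 6, 7)]  # 50 um apart < 150 um spacing
        c_v = ScalarField.uniform(lat, 1.0, "c_v")
        out = select_sprout_sites(ring, c_v, sp, rng)
        assert len(out) == 1

    def test_accepted_set_pairwise_spaced(self, lat, rng):
        sp = SproutingParams(min_spacing=120.0)
        ring = [(2, y, z) for y in range(1, 14) for z in range(1, 14, 2)]
        for _ in range(10):
            c_v = ScalarField(lat, rng.uniform(0, 0.05, lat.shape), "c_v")
            out = select_sprout_sites(ring, c_v, sp, rng)
            # brute-force pair scan
            for i in range(len(out)):
                for j in range(i + 1, len(out)):
                    d = np.linalg.norm(
                        (np.asarray(out[i]) - np.asarray(out[j])) * lat.h
                    )
                    assert d > sp.min_spacing
                assert c_v.values[out[i]] >= sp.c_v_sprout


class TestTipMigration:
    def test_isotropic_uniform_fields(self, lat):
        tip = TipCell((7, 7, 7))
        u = ScalarField.uniform
        probs = tec_move_probabilities(tip, u(lat, 0.5, "c_v"), u(lat, 1.0, "c_e"),
                                       u(lat, 0.0, "pb"), MotilityParams(), 600.0)
        assert np.isclose(probs.sum(), 1.0)
        assert np.allclose(probs[1:], probs[1], rtol=1e-12)

    def test_saturation_limit_suppresses_chemotaxis(self, lat):
        x = np.broadcast_to(np.arange(15)[:, None, None] * 0.2, lat.shape).copy()
        c_v = ScalarField(lat, x, "c_v")
        c_e = ScalarField(lat, 1.0 - 0.02 * x, "c_e")
        pb = ScalarField.uniform(lat, 0.0, "pb")
        tip = TipCell((7, 7, 7))
        sat = tec_move_probabilities(tip, c_v, c_e, pb,
                                     MotilityParams(alpha=1e9), 600.0)
        hapto_only = tec_move_probabilities(tip, ScalarField.uniform(lat, 0.5, "c_v"),
                                            c_e, pb, MotilityParams(beta_c=0.0), 600.0)
        assert np.allclose(sat, hapto_only, rtol=1e-4, atol=1e-7)

    def test_drift_up_vegf_gradient(self, lat, rng):
        x = np.broadcast_to(np.arange(15)[:, None, None] * 0.02, lat.shape).copy()
        c_v = ScalarField(lat, x, "c_v")
        c_e = ScalarField.uniform(lat, 1.0, "c_e")
        pb = ScalarField.uniform(lat, 0.0, "pb")
        tip = TipCell((7, 7, 7))
        probs = tec_move_probabilities(tip, c_v, c_e, pb, MotilityParams(), 600.0)
        from tmesim.tumor_cells import sample_moves_batch

        draws = sample_moves_batch(np.tile(probs, (1000, 1)), rng)
        assert draws[:, 0].mean() > 0.01  # net +x drift over 1000 samples

    def test_no_immediate_backtracking(self, lat):
        tip = TipCell((7, 7, 7), prev_site=(6, 7, 7))
        u = ScalarField.uniform
        probs = tec_move_probabilities(tip, u(lat, 0.5, "c_v"), u(lat, 1.0, "c_e"),
                                       u(lat, 0.0, "pb"), MotilityParams(), 600.0)
        back = [i for i, e in enumerate(NEIGHBOR_OFFSETS)
                if tuple(e) == (-1, 0, 0)][0]
        assert probs[back] == 0.0


class TestGraphOperations:
    def test_diagonal_segment_lengths(self, lat, lumen):
        net = build_chain(lat, [(2, 2, 2)], lumen)
        tip = TipCell((2, 2, 2))
        net.tips.append(tip)
        extend_sprout(tip, (1, 1, 0), net, lumen)
        extend_sprout(tip, (1, 1, 1), net, lumen)
        lengths = sorted(d["L"] for *_, d in net.graph.edges(data=True))
        assert np.allclose(lengths, [np.sqrt(2) * 50.0, np.sqrt(3) * 50.0])
        net.validate()

    def test_move_into_existing_node_fuses(self, lat, lumen):
        net = build_chain(lat, [(2, 2, 2), (3, 2, 2), (4, 2, 2)], lumen)
        tip = TipCell((6, 2, 2))
        net.add_node((6, 2, 2))
        net.graph.nodes[(6, 2, 2)]["is_tip"] = True
        net.tips.append(tip)
        extend_sprout(tip, (-1, 0, 0), net, lumen)  # moves onto a free site
        extend_sprout(tip, (-1, 0, 0), net, lumen)  # onto (4,2,2): anastomosis
        assert not tip.alive
        assert net.graph.has_edge((5, 2, 2), (4, 2, 2))
        net.validate()

    def test_tip_tip_fusion_retires_both(self, lat, lumen):
        net = VesselNetwork(lat)
        net.add_node((2, 2, 2))
        net.add_node((4, 2, 2))
        t1 = TipCell((2, 2, 2))
        t2 = TipCell((4, 2, 2))
        net.graph.nodes[(4, 2, 2)]["is_tip"] = True
        net.tips += [t1, t2]
        extend_sprout(t1, (1, 0, 0), net, lumen)   # new node (3,2,2)
        anastomose(t1, (4, 2, 2), net, lumen)
        assert not t1.alive and not t2.alive
        net.validate()

    def test_ec_mask_tracks_nodes(self, lat, lumen):
        net = build_chain(lat, [(2, 2, 2)], lumen)
        tip = TipCell((2, 2, 2))
        net.tips.append(tip)
        before = net.ec_mask().sum()
        extend_sprout(tip, (0, 1, 0), net, lumen)
        after = net.ec_mask()
        assert after.sum() == before + 1
        assert after[(2, 3, 2)]


class TestBranching:
    def _net_with_stalk(self, lat, lumen, n=8):
        sites = [(2 + i, 7, 7) for i in range(n)]
        return build_chain(lat, sites, lumen)

    def test_below_threshold_no_branch(self, lat, lumen, rng):
        net = self._net_with_stalk(lat, lumen)
        c_v = ScalarField.uniform(lat, 0.0, "c_v")
        assert maybe_branch(net, c_v, SproutingParams(), rng, 600.0) == []

    def test_branch_above_threshold(self, lat, lumen):
        net = self._net_with_stalk(lat, lumen, n=10)
        c_v = ScalarField.uniform(lat, 10.0, "c_v")
        sp = SproutingParams(branch_rate=1.0, min_spacing=50.0)
        rng = np.random.default_rng(0)
        tips = maybe_branch(net, c_v, sp, rng, 600.0)
        assert len(tips) >= 1
        for t in tips:
            assert net.graph.nodes[t.site]["is_tip"]

    def test_branch_spacing_respected(self, lat, lumen):
        net = self._net_with_stalk(lat, lumen, n=12)
        c_v = ScalarField.uniform(lat, 10.0, "c_v")
        sp = SproutingParams(branch_rate=1.0, min_spacing=120.0)
        rng = np.random.default_rng(3)
        for _ in range(20):
            maybe_branch(net, c_v, sp, rng, 600.0)
        branch_sites = [t.site for t in net.tips]
        for i in range(len(branch_sites)):
            for j in range(i + 1, len(branch_sites)):
                d = np.linalg.norm((np.asarray(branch_sites[i])
                                    - np.asarray(branch_sites[j])) * lat.h)
                assert d > sp.min_spacing


class TestLumenogenesis:
    def test_no_ligands_death_and_aging_only(self, lumen):
        g1 = stalk_growth_step(1.0, 0.0, 0.0, 0.0, 1.0, lumen)
        assert np.isclose(g1 - 1.0, -lumen.delta + lumen.k_age)

    def test_saturated_limit(self, lumen):
        g1 = stalk_growth_step(1.0, 1e9, 1e9, 1e-9, 1.0, lumen)
        expected = lumen.alpha_p - lumen.omega_m + lumen.k_age
        assert np.isclose(g1 - 1.0, expected, rtol=1e-6)

    def test_midrange_term_by_term_oracle(self, lumen):
        cv, a1, a2, dt = 0.03, 0.4, 0.2, 100.0
        prolif = lumen.alpha_p * cv / (cv + lumen.theta_p)
        ratio = a1 / a2
        mat = lumen.omega_m * (cv / (cv + lumen.theta_m)) * (ratio / (ratio + lumen.rho_m))
        death = (1 - cv / (cv + lumen.theta_d)) * lumen.delta
        expected = 1.0 + dt * (prolif - mat - death + lumen.k_age)
        assert np.isclose(stalk_growth_step(1.0, cv, a1, a2, dt, lumen), expected)

    def test_lumen_diameter_curve(self, lumen):
        assert lumen_diameter(0.0, lumen) == 0.0
        assert np.isclose(lumen_diameter(lumen.G_0, lumen), lumen.d_c / 2.0)
        assert np.isclose(lumen_diameter(1e12, lumen), lumen.d_c, rtol=1e-9)

    def test_nascent_state_gives_nascent_diameter(self, lumen):
        assert np.isclose(lumen_diameter(lumen.G_s_nascent, lumen), lumen.d_nascent)


class TestAdaptation:
    @pytest.fixture
    def ap(self):
        return AdaptationParams()

    def test_wss_stimulus_log10(self, ap):
        s = adaptation_stimuli(10.0 - ap.tau_ref, 30.0, 1.0, 0.45, 0.0, ap.d_0,
                               ap, Q_ref=1.0)
        assert np.isclose(s[0], 1.0)

    def test_metabolic_stimulus_at_reference_flow(self, ap):
        s = adaptation_stimuli(1.0, 30.0, 2.0, 0.5, 0.0, ap.d_0, ap, Q_ref=1.0)
        assert np.isclose(s[2], ap.k_m * np.log10(2.0))

    def test_vegf_stimulus_zero_at_stress_free_diameter(self, ap):
        s = adaptation_stimuli(1.0, 30.0, 1.0, 0.45, 0.3, ap.d_0, ap, Q_ref=1.0)
        assert s[3] == 0.0

    def test_low_pressure_clamped_to_plateau(self, ap):
        # below 10 mmHg the empirical fit is clamped to its 14 dyn/cm^2 plateau
        s_low = adaptation_stimuli(1.0, 2.0, 1.0, 0.45, 0.0, ap.d_0, ap, Q_ref=1.0)
        s_ten = adaptation_stimuli(1.0, 10.0, 1.0, 0.45, 0.0, ap.d_0, ap, Q_ref=1.0)
        assert np.isclose(s_low[1], s_ten[1])
        assert np.isclose(s_ten[1], -ap.k_p * np.log10(14.0))

    def test_shrinkage_only_decreases(self, ap):
        d1 = adapt_diameter(20.0, (0.0, 0.0, 0.0, 0.0), 100.0, ap)
        assert d1 < 20.0

    def test_equilibrium_unchanged(self, ap):
        stim = (ap.S_Sh / 4,) * 4
        assert adapt_diameter(20.0, stim, 100.0, ap) == 20.0

    def test_update_is_hand_sum(self):
        ap = AdaptationParams(k_d=1.0, d_max=1e9)
        stim = (0.3, -0.1, 0.2, 0.05)
        expected = 20.0 + 5.0 * (sum(stim) - ap.S_Sh)
        assert np.isclose(adapt_diameter(20.0, stim, 5.0, ap), expected)

    def test_bounds_enforced(self, ap):
        assert adapt_diameter(0.1, (-10.0,) * 4, 1e6, ap) == 0.0
        assert adapt_diameter(59.0, (10.0,) * 4, 1e6, ap) == ap.d_max


class TestDeformation:
    def test_unit_ratio_identity(self):
        cp = ComplianceParams()
        d, collapsed = deform_diameter(12.0, cp.E - cp.p_c + 3.0, 3.0, cp)
        assert np.isclose(d, 12.0)
        assert not collapsed

    def test_collapse_under_stress(self):
        cp = ComplianceParams()
        d, collapsed = deform_diameter(12.0, 10.0, 10.0 + cp.p_c + 1.0, cp)
        assert d == 0.0 and collapsed

    def test_linear_compliance_halves(self):
        cp = ComplianceParams(cp=1.0)
        d, _ = deform_diameter(12.0, cp.E / 2.0 - cp.p_c, 0.0, cp)
        assert np.isclose(d, 6.0)


class TestDisruption:
    def _network(self, lat, lumen):
        sites = [(2, 7, 7), (3, 7, 7), (4, 7, 7), (5, 7, 7)]
        net = build_chain(lat, sites, lumen,
                          kinds=["primary", "neo", "neo", "neo"])
        for *_, d in net.graph.edges(data=True):
            d["tau"] = 1.0
        return net

    def test_chronic_low_wss_removed(self, lat, lumen):
        net = self._network(lat, lumen)
        dp = DisruptionParams(tau_th=0.5, t_s=100.0)
        far = net.graph.edges[(4, 7, 7), (5, 7, 7)]
        far["tau"] = 0.1
        c_v = ScalarField.uniform(lat, 0.0, "c_v")
        inside = np.zeros(lat.shape, bool)
        disrupt_vessels(net, c_v, inside, 60.0, dp)
        assert net.graph.has_edge((4, 7, 7), (5, 7, 7))
        disrupt_vessels(net, c_v, inside, 60.0, dp)
        assert not net.graph.has_edge((4, 7, 7), (5, 7, 7))
        assert (5, 7, 7) not in net.graph  # orphan pruned

    def test_recovery_resets_timer(self, lat, lumen):
        net = self._network(lat, lumen)
        dp = DisruptionParams(tau_th=0.5, t_s=100.0)
        e = net.graph.edges[(4, 7, 7), (5, 7, 7)]
        c_v = ScalarField.uniform(lat, 0.0, "c_v")
        inside = np.zeros(lat.shape, bool)
        e["tau"] = 0.1
        disrupt_vessels(net, c_v, inside, 60.0, dp)
        e["tau"] = 1.0  # recovers before t_s
        disrupt_vessels(net, c_v, inside, 60.0, dp)
        assert e["low_wss_timer"] == 0.0
        e["tau"] = 0.1
        disrupt_vessels(net, c_v, inside, 60.0, dp)
        assert net.graph.has_edge((4, 7, 7), (5, 7, 7))

    def test_vegf_disruption_inside_tumor_only(self, lat, lumen):
        net = self._network(lat, lumen)
        dp = DisruptionParams(tau_th=0.0, c_v_th=0.5, t_s=50.0)
        c_v = ScalarField.uniform(lat, 1.0, "c_v")
        inside = np.zeros(lat.shape, bool)
        disrupt_vessels(net, c_v, inside, 60.0, dp)
        assert net.n_neo_segments() == 3  # outside the tumor: untouched
        inside[:] = True
        disrupt_vessels(net, c_v, inside, 60.0, dp)
        assert net.n_neo_segments() == 0

    def test_primary_ring_never_removed(self, lat, lumen):
        net = self._network(lat, lumen)
        dp = DisruptionParams(tau_th=10.0, t_s=10.0)
        c_v = ScalarField.uniform(lat, 10.0, "c_v")
        inside = np.ones(lat.shape, bool)
        for _ in range(5):
            disrupt_vessels(net, c_v, inside, 60.0, dp)
        assert (2, 7, 7) in net.graph
        assert net.n_neo_segments() == 0
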