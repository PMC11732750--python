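import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from sedmoc.core_model import RedoxConfig, build_model
from sedmoc.reactions import (ReactionNetwork, cascade_rates, chain_rates,
                              geopolymerization_rates, hydrolysis_rates,
                              redox_partition, sorption_exchange)
from sedmoc.solver import build_system


@pytest.fixture(scope="module")
def network():
    system = build_system(build_model(), n_cells=12)
    return system


def _random_state(system, rng, scale=1.0):
    n, S = system.n_cells, system.n_species
    base = np.maximum(np.tile(system.scales, (n, 1)), 1e-3)
    return scale * base * rng.uniform(0.0, 2.0, (n, S))


class TestCascade:
    def test_pairwise_transfer(self):
        net = cascade_rates(np.array([0.5, 0.0]), np.array([2.0]))
        np.testing.assert_allclose(net, [-1.0, 1.0])

    def test_null_rates(self):
        net = cascade_rates(np.array([1.0, 2.0, 3.0]), np.zeros(2))
        np.testing.assert_allclose(net, 0.0)

    def test_conserves_total_carbon(self):
        rng = np.random.default_rng(3)
        doc = rng.uniform(0, 5, (20, 4))
        net = cascade_rates(doc, np.array([1.0, 3.0, 10.0]))
        np.testing.assert_allclose(net.sum(axis=1), 0.0, atol=1e-12)

    def test_closed_cascade_matches_matrix_exponential(self):
        # independent oracle: the 4-pool linear chain solved exactly by expm
        lam = np.array([2.0, 0.7, 0.3])
        A = np.zeros((4, 4))
        for i, l in enumerate(lam):
            A[i, i] -= l
            A[i + 1, i] += l
        c0 = np.array([1.0, 0.5, 0.25, 0.0])
        t = 1.7
        exact = expm(A * t) @ c0
        # integrate with the rate function (RK4, small steps)
        c = c0.copy()
        dt = 1e-3
        for _ in range(int(t / dt)):
            k1 = cascade_rates(c, lam)
            k2 = cascade_rates(c + 0.5 * dt * k1, lam)
            k3 = cascade_rates(c + 0.5 * dt * k2, lam)
            k4 = cascade_rates(c + dt * k3, lam)
            c = c + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        np.testing.assert_allclose(c, exact, rtol=1e-7)
        assert c.sum() == pytest.approx(c0.sum(), rel=1e-10)


class TestGeopolymerizationChain:
    def test_decoupled_when_influx_zero(self):
        net = geopolymerization_rates(np.array([2.0]), np.array([[1.0, 1.0]]),
                                      np.array([0.0, 0.5, 0.2]))
        assert net[0, 0] == 0.0  # DOC_m untouched

    def test_telescoping_conservation(self):
        net = geopolymerization_rates(np.array([2.0]), np.array([[1.0, 3.0]]),
                                      np.array([1.0, 0.5, 0.2]))
        assert net.sum() == pytest.approx(0.0, abs=1e-14)

    def test_linear_chain_steady_state_levels(self):
        # with constant source S into a chain, each pool settles at S/λ_out
        lam = np.array([0.8, 0.4])
        S = 2.0
        pools = np.array([S / lam[0], S / lam[1]])
        net = chain_rates(pools, lam)
        assert net[0] == pytest.approx(-S)   # balanced by the external source
        assert net[1] == pytest.approx(0.0, abs=1e-14)
        assert net[-1] == pytest.approx(S)   # export equals throughflow


class TestSorptionExchange:
    def test_detailed_balance_fixed_point(self):
        d, s = sorption_exchange(cd=0.5, sd=100.0 * 0.5, k_sorp=3.0, kd_sorp=100.0)
        assert d == pytest.approx(0.0, abs=1e-14)
        assert s == pytest.approx(0.0, abs=1e-14)

    def test_pure_forward_sorption(self):
        d, s = sorption_exchange(cd=1.0, sd=0.0, k_sorp=1.0, kd_sorp=100.0)
        assert d == pytest.approx(-1.0)
        assert s == pytest.approx(1.0)

    def test_relaxation_eigenvalue(self):
        # two-box system d/dt [c, s] relaxes with rate k_sorp (1 + 1/Kd)
        k, kd = 50.0, 4.0
        c, s = 1.0, 0.0
        dt = 1e-5
        lam = k * (1.0 + 1.0 / kd)
        ratio0 = s - kd * c
        t = 0.02
        for _ in range(int(t / dt)):
            d, ds = sorption_exchange(c, s, k, kd)
            c, s = c + dt * d, s + dt * ds
        deviation = s - kd * c
        assert deviation / ratio0 == pytest.approx(np.exp(-lam * t), rel=1e-3)


class TestRedoxPartition:
    def test_aerobic_saturation_limit(self):
        rdx = RedoxConfig()
        f = redox_partition(o2=1e3 * rdx.km_o2, no3=0.01, mno2=1.0,
                            feoh3=10.0, so4=28.0, redox=rdx)
        assert f[0] == pytest.approx(1.0, abs=2e-3)
        assert np.all(f[1:] < 2e-3)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        rdx = RedoxConfig()
        f = redox_partition(
            o2=rng.uniform(0, 0.3, 5), no3=rng.uniform(0, 0.05, 5),
            mno2=rng.uniform(0, 20, 5), feoh3=rng.uniform(0, 200, 5),
            so4=rng.uniform(0, 30, 5), redox=rdx)
        np.testing.assert_allclose(f.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(f >= -1e-12)


class TestHydrolysis:
    def test_first_order_sink(self):
        sinks = hydrolysis_rates(np.array([1.0]), np.array([0.1]))
        assert sinks[0] == pytest.approx(0.1)

    def test_direct_lrdoc_split(self):
        m = build_model(overrides={"pools.f_lrdoc_direct": 0.1})
        system = build_system(m, n_cells=6)
        state = system.y0.reshape(system.n_cells, system.n_species)
        _, diag = system.net.rates(state, diagnostics=True)
        total = diag["hydrolysis_total"]
        np.testing.assert_allclose(diag["hydrolysis_to_lrdoc"], 0.1 * total,
                                   rtol=1e-12)
        np.testing.assert_allclose(diag["hydrolysis_to_doc1"], 0.9 * total,
                                   rtol=1e-12)

    def test_zero_rates_zero_source(self):
        m = build_model(overrides={"pools.k_hyd": [0.0] * 7,
                                   "pools.poc_fractions": [1 / 7] * 7})
        system = build_system(m, n_cells=6)
        _, diag = system.net.rates(
            system.y0.reshape(system.n_cells, system.n_species),
            diagnostics=True)
        np.testing.assert_allclose(diag["hydrolysis_total"], 0.0)


class TestNetworkClosures:
    def test_carbon_closure(self, network, rng):
        # all transformation terms plus the DIC/CH4 sources cancel exactly
        state = _random_state(network, rng)
        R = network.net.rates(state)
        carbon = network.net.carbon_columns()
        np.testing.assert_allclose(
            R[:, carbon].sum(axis=1), 0.0,
            atol=1e-10 * np.abs(R[:, carbon]).max())

    def test_sulfur_closure(self, network, rng):
        state = _random_state(network, rng)
        R = network.net.rates(state)
        net = network.net
        s_balance = (R[:, net.i_so4] + R[:, net.i_h2s] + R[:, net.i_s0]
                     + R[:, net.i_fes] + 2.0 * R[:, net.i_fes2])
        scale = max(np.abs(R[:, net.i_so4]).max(), 1.0)
        np.testing.assert_allclose(s_balance, 0.0, atol=1e-10 * scale)

    def test_moc_pools_inert_without_exchange(self, rng):
        overrides = {f"sorption.k_sorp_{cls}": 0.0
                     for cls in ("doc", "gps", "lrdoc")}
        system = build_system(build_model(overrides=overrides), n_cells=8)
        state = _random_state(system, rng)
        R = system.net.rates(state)
        np.testing.assert_allclose(R[:, system.net.idx.moc], 0.0, atol=0.0)

    def test_secondary_rates_zero_without_reactants(self, network):
        # no reduced species and no methane -> the secondary network is silent
        state = network.y0.reshape(network.n_cells, network.n_species).copy()
        for nm in ("Fe2", "Mn2", "H2S", "CH4", "FeS", "FeS2", "S0"):
            state[:, network.net.idx.name_to_col[nm]] = 0.0
        sec = network.net._secondary(state)
        # softplus smoothing leaves a residue of order k·(δ/2): for the
        # fastest constant (1e4 cm3/umol/yr) and δ=1e-6 that is ~2e-3
        assert np.abs(sec).max() < 1e-2

    def test_all_secondary_constants_zero(self, rng):
        overrides = {f"redox.{k}": 0.0 for k in
                     ("k_fe_ox", "k_mn_ox", "k_h2s_ox", "k_ch4_ox", "k_aom",
                      "k_fes_ppt", "k_fes_diss", "k_fes2", "k_s0_disp",
                      "k_h2s_feoh3", "k_h2s_mno2")}
        system = build_system(build_model(overrides=overrides), n_cells=6)
        state = _random_state(system, rng)
        np.testing.assert_allclose(system.net._secondary(state), 0.0, atol=0.0)

    def test_network_audit_table(self, network):
        df = network.net.network_table()
        assert {"reaction", "stoichiometry", "rate_law", "constants"} <= set(df.columns)
        assert len(df) >= 10
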