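import numpy as np
import pytest

from sedmoc.core_model import SedimentConfig, SpeciesSpec
from sedmoc.transport import (assemble_operator, burial_velocities,
                              column_profiles, make_grid, porosity_profile)
from sedmoc.validation import transport_oracle_error


def _sediment(**kwargs):
    defaults = dict(phi0=0.9, phi_inf=0.7, phi_atten=20.0, w_inf=0.1,
                    db0=5.0, alpha0=0.0, domain_depth=100.0, pe_horizon=50.0)
    defaults.update(kwargs)
    return SedimentConfig(**defaults)


class TestPorosity:
    def test_surface_value(self):
        sed = _sediment()
        assert porosity_profile(sed, np.array([0.0]))[0] == pytest.approx(0.9)

    def test_infinite_attenuation_limit(self):
        sed = _sediment(phi_atten=1e12)
        phi = porosity_profile(sed, np.linspace(0, 100, 50))
        np.testing.assert_allclose(phi, 0.9, rtol=1e-9)

    def test_closed_form_value(self):
        # 0.7 + 0.2 e^-1 at one attenuation depth
        sed = _sediment()
        val = porosity_profile(sed, np.array([20.0]))[0]
        assert val == pytest.approx(0.7 + 0.2 * np.exp(-1.0), rel=1e-12)


class TestBurialVelocities:
    def test_no_compaction_constant_velocities(self):
        sed = _sediment(phi0=0.8, phi_inf=0.8)
        phi = porosity_profile(sed, np.linspace(0, 100, 30))
        v_d, v_p = burial_velocities(sed, phi)
        np.testing.assert_allclose(v_d, 0.1, rtol=1e-12)
        np.testing.assert_allclose(v_p, 0.1, rtol=1e-12)

    def test_surface_solid_velocity_compaction_identity(self):
        sed = _sediment(phi0=0.9, phi_inf=0.7, w_inf=0.1)
        _, v_p = burial_velocities(sed, np.array([0.9]))
        # eps(inf) * w_inf / eps(0) = 0.3*0.1/0.1
        assert v_p[0] == pytest.approx(0.3, rel=1e-12)

    def test_steady_compaction_identities(self):
        sed = _sediment()
        z = np.linspace(0, 100, 200)
        phi = porosity_profile(sed, z)
        v_d, v_p = burial_velocities(sed, phi)
        np.testing.assert_allclose(phi * v_d, sed.phi_inf * sed.w_inf, rtol=1e-10)
        np.testing.assert_allclose((1 - phi) * v_p,
                                   (1 - sed.phi_inf) * sed.w_inf, rtol=1e-10)

    def test_full_porosity_rejected(self):
        sed = _sediment()
        with pytest.raises(Exception):
            burial_velocities(sed, np.array([1.0]))


class TestOperator:
    def _tracer(self, kd_eq=0.0, d_mol=100.0):
        return SpeciesSpec(name="tracer", phase="dissolved", diffusible=True,
                           d_mol=d_mol, kd_eq=kd_eq)

    def test_closed_column_conserves_mass(self):
        sed = _sediment(alpha0=0.0)
        grid = make_grid(100.0, 60)
        prof = column_profiles(sed, grid)
        op = assemble_operator(self._tracer(kd_eq=2.0), prof, bc_top=None,
                               bc_bottom="closed")
        rng = np.random.default_rng(0)
        c = rng.uniform(0.1, 1.0, grid.n_cells)
        # column integral of the operator action telescopes to zero
        total_rate = float((op.apply(c) * grid.dz).sum())
        assert abs(total_rate) < 1e-12 * float((np.abs(c) * grid.dz).sum())

    def test_column_sum_equals_net_boundary_flux(self):
        sed = _sediment(alpha0=0.0)
        grid = make_grid(100.0, 40)
        prof = column_profiles(sed, grid)
        op = assemble_operator(self._tracer(), prof, bc_top=1.0)
        rng = np.random.default_rng(1)
        c = rng.uniform(0.0, 2.0, grid.n_cells)
        flux = op.face_flux(c)
        lhs = float((op.apply(c) * grid.dz).sum())
        assert lhs == pytest.approx(flux[0] - flux[-1], rel=1e-12, abs=1e-12)

    def test_zero_kd_reduces_to_molecular_terms(self):
        sed = _sediment()
        grid = make_grid(100.0, 30)
        prof = column_profiles(sed, grid)
        op0 = assemble_operator(self._tracer(kd_eq=0.0), prof, bc_top=1.0)
        # hand-built coefficients: phi*D diffusion + phi*v_d advection only
        d_f = prof.phi_f * prof.apparent_diffusivity_f(100.0)
        v_f = prof.phi_f * prof.vd_f
        np.testing.assert_allclose(op0.accfac, prof.phi_c, rtol=1e-14)
        # the top face flux with C=0 equals the Dirichlet-driven influx
        influx = op0.face_flux(np.zeros(grid.n_cells))[0]
        assert influx > 0
        assert influx == pytest.approx(
            (d_f[0] / grid.z[0] *
             max(0.0, (1 - 0.1 * abs(v_f[0] * grid.z[0] / d_f[0])) ** 5)
             + max(v_f[0], 0.0)) * 1.0, rel=1e-12)

    def test_equilibrium_adsorption_retards_migration(self):
        # a buried pulse moves more slowly the larger K_d (retardation)
        sed = _sediment(phi0=0.8, phi_inf=0.8, db0=0.0, w_inf=0.5)
        grid = make_grid(100.0, 200)
        prof = column_profiles(sed, grid)
        from scipy.linalg import expm
        centroids = []
        for kd in (0.0, 1.0, 5.0):
            op = assemble_operator(self._tracer(kd_eq=kd, d_mol=10.0), prof,
                                   bc_top=None, bc_bottom="closed")
            n = grid.n_cells
            A = np.zeros((n, n))
            i = np.arange(n)
            A[i, i] = op.diag
            A[i[1:], i[1:] - 1] = op.lower[1:]
            A[i[:-1], i[:-1] + 1] = op.upper[:-1]
            A /= op.accfac[:, None]
            c0 = np.exp(-0.5 * ((grid.z - 20.0) / 3.0) ** 2)
            c = expm(A * 20.0) @ c0
            centroids.append(float((grid.z * c * grid.dz).sum()
                                   / (c * grid.dz).sum()))
        assert centroids[0] > centroids[1] > centroids[2]

    def test_steady_state_matches_analytic_solution(self):
        assert transport_oracle_error(n_cells=600) < 1e-3

    def test_grid_refinement_convergence(self):
        e1 = transport_oracle_error(n_cells=150)
        e2 = transport_oracle_error(n_cells=300)
        assert e2 < 0.7 * e1  # at least first-order


class TestGrid:
    def test_faces_cover_domain(self):
        g = make_grid(500.0, 80)
        assert g.zf[0] == 0.0
        assert g.zf[-1] == pytest.approx(500.0)
        assert np.all(np.diff(g.zf) > 0)
        assert g.dz[0] <= 0.1 + 1e-12  # refined near the interface

    def test_profiles_export(self):
        sed = _sediment()
        g = make_grid(100.0, 30)
        df = column_profiles(sed, g).to_dataframe()
        assert list(df.columns) == ["z_cm", "phi", "v_d_cm_yr", "v_p_cm_yr",
                                    "D_b_cm2_yr", "alpha_yr"]
        assert len(df) == 30
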