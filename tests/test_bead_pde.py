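import math

import numpy as np
import pytest

from immobead import (
    AxiMesh,
    effectiveness_factor,
    extract_radial_profile,
    steady_axisymmetric,
    steady_sphere_1d,
    transient_solve,
)
from immobead.bead_pde import write_field_csv

from conftest import first_order_profile


class TestMesh:
    def test_nodes_inside_unit_quarter_disc(self, mesh32):
        rho2 = np.einsum("ij,ij->i", mesh32.nodes, mesh32.nodes)
        assert np.all(rho2 <= 1.0 + 1e-9)
        assert np.all(mesh32.nodes >= -1e-12)

    def test_surface_nodes_on_unit_circle(self, mesh32):
        rho2 = np.einsum("ij,ij->i", mesh32.nodes, mesh32.nodes)
        assert np.all(np.abs(rho2[mesh32.surface] - 1.0) < 1e-9)

    def test_boundary_tags(self, mesh32):
        assert mesh32.axis.sum() >= mesh32.n  # one axis node per ring + center
        assert mesh32.midplane.sum() >= mesh32.n
        assert mesh32.surface.sum() == mesh32.ntheta + 1

    def test_too_coarse_rejected(self):
        with pytest.raises(ValueError):
            AxiMesh.build(8)


class TestSteady1D:
    def test_no_reaction_gives_uniform_unit_field(self):
        fld = steady_sphere_1d(0.0, 1.0, 64)
        assert np.all(fld.cs == 1.0)
        assert fld.converged

    def test_first_order_closed_form_midpoint(self):
        fld = steady_sphere_1d(1.0, 0.0, 64)
        # C(0.5) = sinh(1.5)/(0.5*sinh 3)
        expected = math.sinh(1.5) / (0.5 * math.sinh(3.0))
        assert fld.cs[32] == pytest.approx(expected, abs=1e-3)
        assert expected == pytest.approx(0.4251, abs=1e-4)

    def test_center_starves_at_large_thiele_modulus(self):
        fld = steady_sphere_1d(30.0, 0.0, 64)
        assert fld.center_concentration < 1e-10

    def test_profile_monotone_and_bounded(self):
        for phi, beta in [(1.0, 0.0), (3.0, 2.0), (10.0, 50.0)]:
            fld = steady_sphere_1d(phi, beta, 64)
            assert np.all(np.diff(fld.cs) >= -1e-12)
            assert np.all(fld.cs >= 0.0) and np.all(fld.cs <= 1.0)
            assert fld.residual_norm < 1e-10


class TestSteady2D:
    def test_no_reaction_gives_uniform_unit_field(self, mesh32):
        fld = steady_axisymmetric(0.0, 3.0, mesh=mesh32)
        assert np.all(fld.cs == 1.0)

    def test_first_order_closed_form(self, mesh64):
        fld = steady_axisymmetric(1.0, 0.0, mesh=mesh64)
        rho = np.hypot(mesh64.nodes[:, 0], mesh64.nodes[:, 1])
        err = np.max(np.abs(fld.cs - first_order_profile(rho, 1.0)))
        assert err < 1e-2

    def test_solution_is_radially_symmetric(self, mesh64):
        # uniform Dirichlet data on a sphere: Cs depends on rho only
        fld = steady_axisymmetric(3.0, 2.0, mesh=mesh64)
        nt = mesh64.ntheta
        spread = 0.0
        for j in range(1, mesh64.n + 1):
            ring = fld.cs[1 + (j - 1) * (nt + 1): 1 + j * (nt + 1)]
            spread = max(spread, float(ring.max() - ring.min()))
        assert spread < 5e-3

    def test_matches_radial_solver_along_ray(self, mesh64):
        fld2 = steady_axisymmetric(3.0, 5.0, mesh=mesh64)
        fld1 = steady_sphere_1d(3.0, 5.0, 64)
        _, prof = extract_radial_profile(fld2)
        assert np.max(np.abs(prof - fld1.cs)) < 1e-2

    def test_maximum_principle(self, mesh32):
        for phi, beta in [(0.5, 0.0), (10.0, 1.0), (180.0, 3.0)]:
            fld = steady_axisymmetric(phi, beta, mesh=mesh32)
            assert np.all(fld.cs >= 0.0) and np.all(fld.cs <= 1.0)


class TestTransient:
    def test_pure_diffusion_relaxes_to_saturation(self, mesh32):
        snaps = transient_solve(0.0, 0.0, lam=1.0, tau_end=8.0, mesh=mesh32,
                                n_snapshots=2)
        assert np.max(np.abs(snaps[-1].cs - 1.0)) < 1e-6
        assert np.max(snaps[-1].cp) < 1e-12  # no source, no product

    def test_sum_obeys_discrete_heat_equation_at_unit_lambda(self, mesh32):
        snaps = transient_solve(1.0, 0.5, lam=1.0, tau_end=10.0, mesh=mesh32,
                                n_snapshots=4)
        w = snaps[-1].cs + snaps[-1].cp
        assert np.max(np.abs(w - 1.0)) < 1e-6

    def test_monotone_in_time_and_reaches_steady_state(self, mesh32):
        snaps = transient_solve(2.0, 1.0, lam=1.0, tau_end=10.0, mesh=mesh32,
                                n_snapshots=4)
        for a, b in zip(snaps, snaps[1:]):
            assert np.all(b.cs >= a.cs - 1e-9)
        steady = steady_axisymmetric(2.0, 1.0, mesh=mesh32)
        assert np.max(np.abs(snaps[-1].cs - steady.cs)) < 1e-6

    def test_invalid_arguments_rejected(self, mesh32):
        with pytest.raises(ValueError):
            transient_solve(1.0, 0.0, lam=0.0, tau_end=1.0, mesh=mesh32)
        with pytest.raises(ValueError):
            transient_solve(1.0, 0.0, tau_end=-1.0, mesh=mesh32)


class TestEffectivenessFactor:
    def test_kinetic_control_limit(self):
        eff = effectiveness_factor(steady_sphere_1d(1e-3, 0.0, 64))
        assert eff.eta == pytest.approx(1.0, abs=1e-5)

    def test_first_order_closed_form(self):
        # eta = (1/phi)(coth 3phi - 1/(3phi)) at phi = 1
        eff = effectiveness_factor(steady_sphere_1d(1.0, 0.0, 64))
        assert eff.eta == pytest.approx(1 / math.tanh(3) - 1 / 3, abs=1e-3)

    def test_strictly_decreasing_in_thiele_modulus(self):
        etas = [
            effectiveness_factor(steady_sphere_1d(phi, 0.5, 64)).eta
            for phi in (0.1, 0.3, 1.0, 3.0, 10.0)
        ]
        assert all(a > b for a, b in zip(etas, etas[1:]))

    def test_agrees_between_1d_and_2d_fields(self, mesh32):
        e1 = effectiveness_factor(steady_sphere_1d(2.0, 1.0, 32)).eta
        e2 = effectiveness_factor(steady_axisymmetric(2.0, 1.0, mesh=mesh32)).eta
        assert e1 == pytest.approx(e2, abs=5e-3)

    def test_unconverged_field_rejected(self, mesh32):
        snap = transient_solve(1.0, 0.0, tau_end=0.1, mesh=mesh32,
                               n_snapshots=1)[0]
        with pytest.raises(ValueError):
            effectiveness_factor(snap)


class TestFieldOutput:
    def test_2d_field_csv_columns(self, mesh32, tmp_path):
        import pandas as pd

        fld = steady_axisymmetric(1.0, 0.0, mesh=mesh32)
        path = tmp_path / "field.csv"
        write_field_csv(fld, path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["r_dot", "z_dot", "Cs", "Cp"]
        assert len(frame) == len(mesh32)

    def test_1d_profile_csv_columns(self, tmp_path):
        import pandas as pd

        fld = steady_sphere_1d(1.0, 0.0, 32)
        path = tmp_path / "profile.csv"
        write_field_csv(fld, path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["rho", "Cs"]
        assert frame["Cs"].iloc[-1] == 1.0
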