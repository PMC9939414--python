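"""Solver contracts: sinks, divergence, penalization, Newtonian reduction."""

import dataclasses

import numpy as np
import pytest

from coilflow import (
    CoilModel,
    FlowState,
    RheologyParams,
    Solver,
    SolverConfig,
    momentum_sink,
    permeability,
)
from coilflow import _kernels


class TestPermeability:
    def test_kozeny_carman_values(self):
        # direct evaluation of d_w^2 phi^3 / (180 (1-phi)^2)
        assert permeability(0.89, 2.5e-4) == pytest.approx(2.0230e-8, rel=1e-3)
        assert permeability(0.79, 2.5e-4) == pytest.approx(3.8820e-9, rel=1e-3)

    def test_increasing_in_porosity(self):
        phis = np.linspace(0.1, 0.95, 40)
        K = [permeability(p, 2.5e-4) for p in phis]
        assert np.all(np.diff(K) > 0)

    def test_wire_diameter_scaling(self):
        assert permeability(0.8, 5e-4) == pytest.approx(4 * permeability(0.8, 2.5e-4))

    @pytest.mark.parametrize("phi", [0.0, 1.0, -0.2, 1.3])
    def test_degenerate_porosity_rejected(self, phi):
        with pytest.raises(ValueError):
            permeability(phi, 2.5e-4)


class TestMomentumSink:
    def test_zero_velocity_zero_sink(self, coarse_geometry):
        nx, ny = coarse_geometry.nx, coarse_geometry.ny
        state = FlowState(u=np.zeros((nx + 1, ny)), v=np.zeros((nx, ny + 1)),
                          p=np.zeros((nx, ny)), mu=np.full((nx, ny), 3.5e-3), t=0.0)
        fx, fy = momentum_sink(state, coarse_geometry, None, eps=1e-4, rho=1060.0)
        assert np.all(fx == 0.0) and np.all(fy == 0.0)

    def test_darcy_magnitude_in_coil(self, coarse_geometry):
        from coilflow import coil_mask

        geo = coil_mask(coarse_geometry, 1.0)
        coil = CoilModel(porosity=0.79)
        nx, ny = geo.nx, geo.ny
        mu0 = 3.5e-3
        state = FlowState(u=np.full((nx + 1, ny), 0.2), v=np.zeros((nx, ny + 1)),
                          p=np.zeros((nx, ny)), mu=np.full((nx, ny), mu0), t=0.0)
        fx, _ = momentum_sink(state, geo, coil, eps=1e-4, rho=1060.0)
        inside = geo.coil_mask
        assert np.allclose(np.abs(fx[inside]), mu0 * 0.2 / coil.K, rtol=1e-12)
        solid = ~geo.lumen_mask
        assert np.allclose(np.abs(fx[solid]), 1060.0 / 1e-4 * 0.2, rtol=1e-12)


class TestStep:
    def test_zero_inflow_is_fixed_point(self, straight_geometry, newtonian):
        s = Solver(straight_geometry, newtonian, inflow=lambda t: 0.0)
        for _ in range(5):
            s.step(1e-4)
        assert np.all(s.u == 0.0) and np.all(s.v == 0.0)

    def test_divergence_and_mass_balance(self, coarse_geometry, newtonian):
        u_in = 0.3
        s = Solver(coarse_geometry, newtonian, inflow=lambda t: u_in * min(t / 0.02, 1.0))
        dt = s.cfg.cfl * s.dx / (1.2 * 1.6 * u_in)
        for _ in range(400):
            s.step(dt)
        u_peak = 1.5 * u_in
        div_lumen = np.abs(s.divergence()[coarse_geometry.lumen_mask])
        assert np.max(div_lumen) <= 1e-6 * u_peak / s.dx
        q_in = np.sum(s.u[0]) * s.dx
        q_out = np.sum(s.u[-1]) * s.dx
        assert abs(q_in - q_out) <= 0.005 * q_in
        assert s.max_solid_speed() <= 1e-3 * u_peak

    def test_penalization_slip_scales_with_eps(self, coarse_geometry, newtonian):
        slips = []
        for eps in (4e-4, 2e-4):
            cfg = SolverConfig(penalization_time=eps)
            s = Solver(coarse_geometry, newtonian, config=cfg,
                       inflow=lambda t: 0.3 * min(t / 0.02, 1.0))
            dt = 1e-4
            for _ in range(400):
                s.step(dt)
            slips.append(s.max_solid_speed())
        assert slips[1] <= 0.65 * slips[0]

    def test_newtonian_reduction(self, coarse_geometry):
        """H = 0 through the Casson path matches an explicitly Newtonian run."""
        fields = []
        for rheo in (RheologyParams(H=0.0), RheologyParams(H=0.0, newtonian=True)):
            s = Solver(coarse_geometry, rheo, inflow=lambda t: 0.3 * min(t / 0.02, 1.0))
            for _ in range(60):
                s.step(1e-4)
            fields.append((s.u.copy(), s.v.copy(), s.p.copy()))
        for a, b in zip(*fields):
            assert np.max(np.abs(a - b)) < 1e-10

    def test_nan_aborts_with_diagnostic(self, straight_geometry, newtonian):
        s = Solver(straight_geometry, newtonian, inflow=lambda t: 0.3)
        s.u[5, 5] = np.nan
        with pytest.raises(RuntimeError, match="diverged"):
            s.step(1e-4)


class TestKernelEquivalence:
    """The numba kernels must reproduce the numpy reference stencils."""

    @pytest.mark.skipif(not _kernels.HAVE_NUMBA, reason="numba unavailable")
    def test_kernels_match_numpy(self, coarse_geometry, rng):
        rheo = RheologyParams(H=0.45)
        s = Solver(coarse_geometry, rheo, inflow=lambda t: 0.3)
        s.u = rng.normal(scale=0.1, size=s.u.shape)
        s.v = rng.normal(scale=0.1, size=s.v.shape)
        mu = s._viscosity()
        try:
            _kernels.HAVE_NUMBA = False
            adv_ref = s._advect()
            dif_ref = s._diffuse(mu)
            mu_ref = s._viscosity()
        finally:
            _kernels.HAVE_NUMBA = True
        adv = s._advect()
        dif = s._diffuse(mu)
        scale = np.max(np.abs(dif_ref[0]))
        assert np.allclose(adv[0], adv_ref[0], atol=1e-12)
        assert np.allclose(adv[1], adv_ref[1], atol=1e-12)
        assert np.allclose(dif[0], dif_ref[0], atol=1e-12 * scale)
        assert np.allclose(dif[1], dif_ref[1], atol=1e-12 * scale)
        assert np.allclose(mu, mu_ref, atol=1e-15)


class TestSpectralSolvers:
    """The DST/DCT fast-diagonalisation solvers must agree with the dense
    eigendecomposition reference for every operator/BC combination."""

    def test_matches_dense_reference(self, rng):
        from coilflow.solver import _FastDiag, _SpectralDiag, _tridiag

        nx, ny = 37, 23
        dx2 = (1.3e-4) ** 2
        c = 5e-5 * 1.6e-4

        du = np.full(nx, -2.0)
        du[-1] = -1.0
        dyu = np.full(ny, -2.0)
        dyu[0] = dyu[-1] = -3.0
        dense_u = _FastDiag(_tridiag(nx, du), _tridiag(ny, dyu), dx2)
        spec_u = _SpectralDiag(nx, ny, ("dst", 1), ("dst", 2), dx2, rank1_last=True)
        F = rng.normal(size=(nx, ny))
        a = dense_u.solve_helmholtz(F, c)
        b = spec_u.solve_helmholtz(F, c)
        assert np.max(np.abs(a - b)) < 1e-10 * np.max(np.abs(a))

        dv = np.full(nx, -2.0)
        dv[0], dv[-1] = -3.0, -1.0
        dense_v = _FastDiag(_tridiag(nx, dv), _tridiag(ny, np.full(ny, -2.0)), dx2)
        spec_v = _SpectralDiag(nx, ny, ("dst", 4), ("dst", 1), dx2)
        a = dense_v.solve_helmholtz(F, c)
        b = spec_v.solve_helmholtz(F, c)
        assert np.max(np.abs(a - b)) < 1e-10 * np.max(np.abs(a))

        dpx = np.full(nx, -2.0)
        dpx[0], dpx[-1] = -1.0, -3.0
        dpy = np.full(ny, -2.0)
        dpy[0] = dpy[-1] = -1.0
        dense_p = _FastDiag(_tridiag(nx, dpx), _tridiag(ny, dpy), dx2)
        spec_p = _SpectralDiag(nx, ny, ("dct", 4), ("dct", 2), dx2)
        a = dense_p.solve_poisson(F)
        b = spec_p.solve_poisson(F)
        assert np.max(np.abs(a - b)) < 1e-9 * np.max(np.abs(a))


class TestPorousDamping:
    def test_coil_reduces_sac_energy(self, coarse_geometry, newtonian):
        """Steady inflow: sac kinetic energy ordered uncoiled > phi=0.89 > 0.79."""
        from coilflow import coil_mask

        ke = {}
        for phi in (None, 0.89, 0.79):
            geo = coil_mask(coarse_geometry, 1.0) if phi else coarse_geometry
            coil = CoilModel(porosity=phi) if phi else None
            s = Solver(geo, newtonian, coil=coil,
                       inflow=lambda t: 0.3 * min(t / 0.02, 1.0))
            dt = 1e-4
            for _ in range(600):
                s.step(dt)
            ke[phi] = s.sac_kinetic_energy()
        assert ke[None] > ke[0.89] > ke[0.79]


def test_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(cfl=0.8).validate()
    with pytest.raises(ValueError):
        SolverConfig(cycles=2).validate()
    with pytest.raises(ValueError):
        SolverConfig(poisson_rel_tol=1e-6).validate()
    SolverConfig().validate()
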